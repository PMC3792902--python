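"""State-space reconstruction and blind source separation.

A single observed brightness series x(t) is assumed to be one read-out of
the cardio-respiratory dynamical system.  Its state space is reconstructed
by delay-coordinate embedding: the m x n matrix X whose row i is x shifted
by i*d samples (delay d, dimension m; here m=3, d=1).  The embedding mixes
the physiological source with noise and residual trend, so FastICA is run
on X to recover m maximally non-Gaussian source signals; the component
whose one-sided power spectrum concentrates the largest fraction of its
0-8 Hz power in a single bin is taken as the physiological one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram
from scipy.stats import skew
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .preprocess import NormalizedSeries

#: upper edge (Hz) of the band over which total spectral power is summed
TOTAL_POWER_BAND_HZ = 8.0


class ICAConvergenceError(RuntimeError):
    """FastICA failed to converge within the iteration budget."""

    def __init__(self, max_iter: int):
        super().__init__(f"FastICA did not converge within {max_iter} "
                         "iterations")
        self.max_iter = max_iter


@dataclass
class EmbeddingMatrix:
    """Delay-coordinate embedding X with X[i, j] = x[j + i*d]."""

    X: np.ndarray       # (m, n)
    m: int
    d: int
    tau: float          # s, = d / f_s
    frame_rate: float

    @property
    def n(self) -> int:
        return self.X.shape[1]


@dataclass
class SourceSet:
    """ICA decomposition X_centered ~= A @ Y with unit-variance rows of Y."""

    Y: np.ndarray        # (m, n) independent sources
    A: np.ndarray        # (m, m) mixing matrix
    W: np.ndarray        # (m, m) de-mixing matrix
    mean: np.ndarray     # (m,) row means removed before unmixing
    frame_rate: float
    n_iter: int = 0


def build_embedding(x: NormalizedSeries | np.ndarray, m: int, d: int,
                    frame_rate: float | None = None) -> EmbeddingMatrix:
    """Build the m x n delay matrix from a series of length N, n = N-(m-1)d."""
    if isinstance(x, NormalizedSeries):
        values, fs = x.values, x.frame_rate
    else:
        values = np.asarray(x, dtype=float)
        if frame_rate is None:
            raise ValueError("frame_rate required for a bare array")
        fs = frame_rate
    if m < 1 or d < 1:
        raise ValueError("need m >= 1 and d >= 1")
    N = values.size
    n = N - (m - 1) * d
    if n < m:
        raise ValueError(
            f"series of length {N} too short for m={m}, d={d}")
    X = np.empty((m, n))
    for i in range(m):
        X[i] = values[i * d:i * d + n]
    return EmbeddingMatrix(X=X, m=m, d=d, tau=d / fs, frame_rate=fs)


def fastica_decompose(emb: EmbeddingMatrix, seed: int = 0,
                      max_iter: int = 500, tol: float = 1e-6,
                      strict: bool = True) -> SourceSet:
    """Unmix the embedding into independent sources by kurtosis FastICA.

    Symmetric (parallel) decorrelation with the cubic contrast, seeded
    random initialisation; components come out with unit variance.  Raises
    :class:`ICAConvergenceError` if the fixed-point iteration does not
    converge, and ``ValueError`` on a rank-deficient embedding.

    With ``strict=False`` the decomposition reached at the iteration cap is
    returned instead of raising.  For a near-periodic embedding the
    whitened sources span a sine/cosine pair whose kurtosis landscape is
    flat under rotation, so the fixed point can wander indefinitely — yet
    any rotation inside that subspace leaves each component's spectral
    content (and hence the rate estimate) unchanged, making the capped
    result fully usable downstream.
    """
    X = emb.X
    mean = X.mean(axis=1)
    Xc = X - mean[:, None]
    if np.linalg.matrix_rank(Xc) < emb.m:
        raise ValueError("embedding matrix is rank deficient after centering")
    ica = FastICA(n_components=emb.m, algorithm="parallel", fun="cube",
                  whiten="unit-variance", tol=tol, max_iter=max_iter,
                  random_state=int(seed))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        Y = ica.fit_transform(X.T).T        # (m, n)
    if strict and any(issubclass(w.category, ConvergenceWarning)
                      for w in caught):
        raise ICAConvergenceError(max_iter)
    A = ica.mixing_                          # (m, m): Xc.T ~= Y.T @ A.T
    W = ica.components_
    return SourceSet(Y=Y, A=A, W=W, mean=ica.mean_,
                     frame_rate=emb.frame_rate, n_iter=ica.n_iter_)


def peak_power_ratio(y: np.ndarray, f_s: float) -> float:
    """Highest single-bin power over total power within (0, min(8, f_s/2)] Hz.

    Rectangular-window periodogram without zero padding; the DC bin is
    excluded from numerator and denominator.  Near 1 for a clean tone,
    small for wideband noise.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 8:
        raise ValueError("need at least 8 samples")
    if not np.any(y != y[0]) and y[0] == 0:
        raise ValueError("all-zero input has no spectrum")
    freqs, power = periodogram(y, fs=f_s, window="boxcar",
                               detrend=False)
    band = (freqs > 0) & (freqs <= min(TOTAL_POWER_BAND_HZ, f_s / 2))
    total = power[band].sum()
    if total == 0:
        raise ValueError("zero spectral energy in the analysis band")
    return float(power[band].max() / total)


def select_component(sources: SourceSet,
                     f_s: float | None = None) -> tuple[int, np.ndarray]:
    """Pick the source with the highest peak-power-density ratio.

    Ties break toward the lowest index.  ICA leaves sign arbitrary, so the
    returned signal is flipped to non-negative skewness (a blood-volume
    pulse has a sharp upstroke, giving a canonical orientation).
    """
    fs = f_s if f_s is not None else sources.frame_rate
    ratios = [peak_power_ratio(row, fs) for row in sources.Y]
    idx = int(np.argmax(ratios))         # argmax returns the first maximum
    signal = sources.Y[idx]
    if skew(signal) < 0:
        signal = -signal
    return idx, signal
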