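"""Bland-Altman agreement between a method and a reference rate series."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.stats import pearsonr


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman summary of paired rate differences (method - reference).

    ``sd_diff`` uses the sample (n-1) convention; ``rmse`` is the root of
    the plain mean of squared differences; the limits of agreement are
    mean +- 1.96 sd.
    """

    n_pairs: int
    mean_diff: float
    sd_diff: float
    upper_limit: float
    lower_limit: float
    rmse: float
    r: float

    def to_dict(self) -> dict:
        return asdict(self)


def bland_altman(method, reference) -> AgreementStats:
    """Agreement statistics between two equally long rate series."""
    m = np.asarray(method, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if m.shape != ref.shape or m.ndim != 1:
        raise ValueError("method and reference must be equal-length 1-D")
    if m.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.std(m) == 0 or np.std(ref) == 0:
        raise ValueError("constant input: correlation undefined")
    diffs = m - ref
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    rmse = float(np.sqrt(np.mean(diffs ** 2)))
    r = float(pearsonr(m, ref).statistic)
    return AgreementStats(n_pairs=m.size, mean_diff=mean_diff,
                          sd_diff=sd_diff,
                          upper_limit=mean_diff + 1.96 * sd_diff,
                          lower_limit=mean_diff - 1.96 * sd_diff,
                          rmse=rmse, r=r)


def read_pairs_csv(path: str | Path):
    """Read a paired-rates CSV with columns t, method_rate, reference_rate."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"method_rate", "reference_rate"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must contain columns {sorted(required)}")
    return df["method_rate"].to_numpy(), df["reference_rate"].to_numpy()


def plot_bland_altman(method, reference, stats: AgreementStats,
                      path: str | Path, title: str = "Bland-Altman") -> None:
    """Classic Bland-Altman scatter with mean and 1.96-SD limit lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = np.asarray(method, dtype=float)
    ref = np.asarray(reference, dtype=float)
    means = (m + ref) / 2
    diffs = m - ref
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=14, alpha=0.7)
    ax.axhline(stats.mean_diff, color="k", lw=1)
    for lim in (stats.upper_limit, stats.lower_limit):
        ax.axhline(lim, color="r", lw=1, ls="--")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (method - reference)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
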