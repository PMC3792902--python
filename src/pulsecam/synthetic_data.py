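"""Synthetic frame sequences and brightness series with known ground truth.

Real recordings pair a camera with a contact reference (ECG, piezo belt);
neither is available to an automated test, so this module manufactures the
signal model the measurement chain assumes: a quasi-periodic cardiac
brightness modulation confined to a "skin" ROI, a quasi-periodic
respiratory modulation confined to a "chest" ROI, a slow illumination
drift and additive sensor noise shared by every pixel region, quantised to
8-bit.  Inanimate scenes carry drift and noise only.  Every generator is
deterministic per seed, and the ground truth (HR, RR) is known exactly,
so each downstream stage can be tested end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np

from .video_io import FrameSeries, ObservedSeries, Rect, write_frames

#: offsets mixed into the user seed so the cardiac, respiratory and frame
#: noise streams are independent but jointly reproducible
_STREAM = {"cardiac": 0, "respiratory": 1, "frames": 2}


@dataclass(frozen=True)
class SceneParams:
    """Parameters of a synthetic scene.

    Defaults describe a resting adult filmed at 15 fps for 30 s: heart rate
    72 bpm (1.2 Hz), respiration 15 breaths/min (0.25 Hz), brightness
    modulations of a few grey levels on a mid-grey baseline, a slow
    illumination drift well below the respiratory band, and sensor noise
    giving an amplitude-to-noise ratio of 5.
    """

    frame_rate: float = 15.0          # Hz
    duration: float = 30.0            # s
    hr_freq: float = 1.2              # Hz, cardiac fundamental
    rr_freq: float = 0.25             # Hz, respiratory fundamental
    cardiac_amp: float = 2.0          # brightness units
    resp_amp: float = 3.0             # brightness units
    drift_amp: float = 4.0            # brightness units
    drift_period: float = 25.0        # s (0.04 Hz, below the vital bands)
    noise_sd: float = 0.4             # brightness units (marginal sd)
    noise_ar: float = 0.0             # AR(1) coefficient of the noise
    baseline: float = 128.0           # brightness units, 0-255
    frame_shape: tuple[int, int] = (48, 64)   # (H, W) pixels
    skin_roi: Rect = field(default_factory=lambda: Rect(8, 6, 20, 16))
    chest_roi: Rect = field(default_factory=lambda: Rect(8, 30, 32, 12))
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.hr_freq > self.rr_freq > 0):
            raise ValueError("need hr_freq > rr_freq > 0")
        if self.frame_rate <= 2 * self.hr_freq:
            raise ValueError(
                f"frame_rate {self.frame_rate} violates Nyquist for "
                f"hr_freq {self.hr_freq}")
        if self.duration <= 0 or self.drift_period <= 0:
            raise ValueError("duration and drift_period must be positive")
        if min(self.cardiac_amp, self.resp_amp, self.drift_amp,
               self.noise_sd) < 0:
            raise ValueError("amplitudes must be non-negative")
        if not -1 < self.noise_ar < 1:
            raise ValueError("noise_ar must lie in (-1, 1)")
        if not 0 <= self.baseline <= 255:
            raise ValueError("baseline must lie in [0, 255]")
        h, w = self.frame_shape
        for name, roi in (("skin_roi", self.skin_roi),
                          ("chest_roi", self.chest_roi)):
            if not roi.inside(h, w):
                raise ValueError(f"{name} {roi} outside frame {h}x{w}")
        if self.skin_roi.overlaps(self.chest_roi):
            raise ValueError("skin_roi and chest_roi must not overlap")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    @property
    def hr_bpm(self) -> float:
        return self.hr_freq * 60.0

    @property
    def rr_bpm(self) -> float:
        return self.rr_freq * 60.0

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def manifest(self) -> dict:
        d = asdict(self)
        d["skin_roi"] = asdict(self.skin_roi)
        d["chest_roi"] = asdict(self.chest_roi)
        return {"hr_bpm": self.hr_bpm, "rr_bpm": self.rr_bpm,
                "seed": self.seed, "params": d}


def _rng(params: SceneParams, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(params.seed), _STREAM[stream]]))


def cardiac_waveform(t: np.ndarray, freq: float) -> np.ndarray:
    """Unit-amplitude asymmetric pulse: fundamental plus 10% 2nd harmonic.

    The small harmonic makes the waveform a non-sinusoidal pulse, as a real
    blood-volume pulse is, without moving the spectral peak off the
    fundamental.
    """
    return np.sin(2 * np.pi * freq * t) + 0.1 * np.sin(4 * np.pi * freq * t)


def respiratory_waveform(t: np.ndarray, freq: float) -> np.ndarray:
    return np.sin(2 * np.pi * freq * t)


def _drift(params: SceneParams, t: np.ndarray) -> np.ndarray:
    return params.drift_amp * np.sin(2 * np.pi * t / params.drift_period)


def _component(params: SceneParams, which: str, t: np.ndarray) -> np.ndarray:
    if which == "cardiac":
        return params.cardiac_amp * cardiac_waveform(t, params.hr_freq)
    if which == "respiratory":
        return params.resp_amp * respiratory_waveform(t, params.rr_freq)
    raise ValueError(f"unknown component {which!r}")


def _noise(rng: np.random.Generator, shape, sd: float,
           rho: float) -> np.ndarray:
    """Gaussian noise along the first axis; AR(1)-correlated when rho != 0,
    with marginal standard deviation sd either way."""
    white = rng.normal(0.0, sd, shape)
    if rho == 0.0 or sd == 0.0:
        return white
    from scipy.signal import lfilter
    innov = white * np.sqrt(1 - rho ** 2)
    innov[0] = white[0]                 # stationary start
    return lfilter([1.0], [1.0, -rho], innov, axis=0)


def generate_vital_series(params: SceneParams, which: str) -> ObservedSeries:
    """Generate the 1-D observed brightness series for one vital sign.

    Returns baseline + modulation + drift + Gaussian noise (white by
    default, AR(1)-correlated when ``noise_ar`` is set), of length
    ``round(duration * frame_rate)``; ``which`` selects the cardiac pulse
    or the respiratory sinusoid.
    """
    t = params.times()
    values = (params.baseline + _component(params, which, t)
              + _drift(params, t)
              + _noise(_rng(params, which), t.size, params.noise_sd,
                       params.noise_ar))
    label = "bvp" if which == "cardiac" else "resp"
    roi = params.skin_roi if which == "cardiac" else params.chest_roi
    return ObservedSeries(values=values, frame_rate=params.frame_rate,
                          roi=roi, label=label)


def generate_frame_sequence(params: SceneParams) -> FrameSeries:
    """Generate 8-bit frames carrying both vital modulations.

    Pixels inside ``skin_roi`` carry the cardiac modulation, pixels inside
    ``chest_roi`` the respiratory one; every pixel carries the illumination
    drift plus independent per-pixel Gaussian noise.  Components are summed
    in float and then quantised to uint8 with clipping at [0, 255].
    """
    t = params.times()
    h, w = params.frame_shape
    cardiac = _component(params, "cardiac", t)
    resp = _component(params, "respiratory", t)
    base = params.baseline + _drift(params, t)

    frames = np.broadcast_to(base[:, None, None], (t.size, h, w)).copy()
    ys, xs = params.skin_roi.slices()
    frames[:, ys, xs] += cardiac[:, None, None]
    ys, xs = params.chest_roi.slices()
    frames[:, ys, xs] += resp[:, None, None]
    if params.noise_sd > 0:
        frames += _noise(_rng(params, "frames"), frames.shape,
                         params.noise_sd, params.noise_ar)
    frames = np.clip(np.rint(frames), 0, 255).astype(np.uint8)
    return FrameSeries(frames=frames, frame_rate=params.frame_rate,
                       channel_label="mono")


def generate_inanimate_sequence(params: SceneParams) -> FrameSeries:
    """Drift+noise-only frames: a static figure under the same conditions."""
    return generate_frame_sequence(
        replace(params, cardiac_amp=0.0, resp_amp=0.0))


def generate_inanimate_series(params: SceneParams) -> ObservedSeries:
    """Drift+noise-only 1-D brightness series (inanimate control)."""
    dead = replace(params, cardiac_amp=0.0, resp_amp=0.0)
    s = generate_vital_series(dead, "cardiac")
    s.label = "inanimate"
    return s


def write_scene(params: SceneParams, out_dir: str | Path,
                fmt: str = "pgm") -> Path:
    """Write the frame sequence plus a JSON ground-truth manifest."""
    frames = generate_frame_sequence(params)
    out = write_frames(frames, out_dir, fmt=fmt)
    (Path(out) / "ground_truth.json").write_text(
        json.dumps(params.manifest(), indent=2))
    return Path(out)


def params_from_json(path: str | Path) -> SceneParams:
    raw = json.loads(Path(path).read_text())
    raw = raw.get("params", raw)
    for key in ("skin_roi", "chest_roi"):
        if key in raw and isinstance(raw[key], dict):
            raw[key] = Rect(**raw[key])
    if "frame_shape" in raw:
        raw["frame_shape"] = tuple(raw["frame_shape"])
    return SceneParams(**raw)
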