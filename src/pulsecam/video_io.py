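"""Frame-sequence input, ROI geometry, and spatial averaging.

The measurement chain starts from an ordered sequence of single-channel
8-bit frames at a known frame rate.  Each frame is reduced to one sample
of an observed brightness time series x(t) by averaging the pixels inside
a rectangular region of interest (ROI): the skin/face ROI yields the
blood-volume-pulse (BVP) series, a chest/shoulder ROI yields the
respiratory series.  For colour input the green channel is used, since
haemoglobin absorption peaks in green/yellow light.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

_FRAME_SUFFIXES = (".pgm", ".png", ".tif", ".tiff", ".bmp")
MANIFEST_NAME = "frames.json"


@dataclass(frozen=True)
class Rect:
    """Axis-aligned pixel rectangle, 0-based, half-open [x, x+w) x [y, y+h)."""

    x: int
    y: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"Rect must have positive size, got {self}")
        if self.x < 0 or self.y < 0:
            raise ValueError(f"Rect origin must be non-negative, got {self}")

    @property
    def x2(self) -> int:
        return self.x + self.width

    @property
    def y2(self) -> int:
        return self.y + self.height

    def inside(self, height: int, width: int) -> bool:
        return self.x2 <= width and self.y2 <= height

    def overlaps(self, other: "Rect") -> bool:
        return (self.x < other.x2 and other.x < self.x2
                and self.y < other.y2 and other.y < self.y2)

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y, self.y2), slice(self.x, self.x2)


@dataclass
class FrameSeries:
    """Ordered single-channel frames with their sampling metadata.

    ``frames`` is a (T, H, W) uint8 array; ``frame_rate`` is in Hz, so the
    sampling interval is ``1 / frame_rate`` seconds.
    """

    frames: np.ndarray
    frame_rate: float
    channel_label: str = "mono"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if len(self.frames) == 0:
            raise ValueError("frame sequence is empty")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def sampling_interval(self) -> float:
        return 1.0 / self.frame_rate


@dataclass
class ObservedSeries:
    """1-D brightness time series with sampling metadata."""

    values: np.ndarray
    frame_rate: float
    roi: Rect | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 2:
            raise ValueError("observed series must be 1-D with length >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("observed series contains non-finite values")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")

    def __len__(self) -> int:
        return len(self.values)


def _natural_key(path: Path) -> list:
    return [int(tok) if tok.isdigit() else tok
            for tok in re.split(r"(\d+)", path.name)]


def _extract_channel(img: np.ndarray, channel: str, source: str) -> np.ndarray:
    if img.ndim == 2:
        if channel == "green":
            warnings.warn(
                f"{source}: input is single-plane; 'green' falls back to the "
                "sole channel", stacklevel=3)
            logger.warning("%s: mono input, green channel unavailable", source)
        return img
    if img.ndim == 3:
        if channel == "green":
            return img[..., 1]
        # mono requested on colour input: ITU-R 601 luma would change units;
        # keep the green plane, which is the working channel anyway.
        return img[..., 1]
    raise ValueError(f"{source}: unsupported image dimensionality {img.ndim}")


def read_frames(path: str | Path, channel: str = "green",
                frame_rate: float | None = None) -> FrameSeries:
    """Read a frame sequence from a directory of images or a video file.

    A directory is expected to contain numbered PGM/PNG frames and,
    optionally, a ``frames.json`` manifest with a ``frame_rate`` entry;
    an explicit ``frame_rate`` argument overrides the manifest.  Video
    containers (AVI etc.) are delegated to imageio and require an ffmpeg
    backend.
    """
    if channel not in ("green", "mono"):
        raise ValueError("channel must be 'green' or 'mono'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    import imageio.v3 as iio

    if path.is_dir():
        files = sorted((p for p in path.iterdir()
                        if p.suffix.lower() in _FRAME_SUFFIXES),
                       key=_natural_key)
        if not files:
            raise ValueError(f"no frames found in {path}")
        if frame_rate is None:
            manifest = path / MANIFEST_NAME
            if manifest.exists():
                frame_rate = json.loads(manifest.read_text()).get("frame_rate")
        if frame_rate is None:
            raise ValueError(
                f"frame rate unknown for {path}: no manifest and no override")
        planes = [_extract_channel(iio.imread(f), channel, f.name)
                  for f in files]
        frames = np.stack(planes).astype(np.uint8)
    else:
        try:
            raw = iio.imread(path, index=None)
        except Exception as exc:  # pragma: no cover - backend dependent
            raise ValueError(
                f"cannot read video container {path} (an ffmpeg-enabled "
                f"imageio backend is required): {exc}") from exc
        raw = np.asarray(raw)
        if raw.ndim == 3 and raw.shape[-1] in (3, 4):
            raw = raw[None]
        if raw.ndim == 2:
            raw = raw[None]
        frames = np.stack([_extract_channel(f, channel, path.name)
                           for f in raw]).astype(np.uint8)
        if frame_rate is None:
            try:
                meta = iio.immeta(path)
                frame_rate = meta.get("fps")
            except Exception:
                frame_rate = None
        if frame_rate is None:
            raise ValueError(
                f"frame rate not present in {path} metadata; pass an override")
    if len(frames) == 0:
        raise ValueError(f"zero frames read from {path}")
    return FrameSeries(frames=frames, frame_rate=float(frame_rate),
                       channel_label=channel)


def write_frames(series: FrameSeries, out_dir: str | Path,
                 fmt: str = "pgm", manifest_extra: dict | None = None) -> Path:
    """Write frames as numbered images plus a ``frames.json`` manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    import imageio.v3 as iio

    digits = max(5, len(str(len(series) - 1)))
    for i, frame in enumerate(series.frames):
        iio.imwrite(out_dir / f"frame_{i:0{digits}d}.{fmt}",
                    np.ascontiguousarray(frame))
    manifest = {"frame_rate": series.frame_rate,
                "n_frames": len(series),
                "channel_label": series.channel_label}
    if manifest_extra:
        manifest.update(manifest_extra)
    (out_dir / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2))
    return out_dir


def derive_rois(face: Rect, upper_body: Rect) -> tuple[Rect, Rect]:
    """Derive the BVP and respiratory ROIs from face and upper-body boxes.

    The BVP ROI is the centred 60%-width by 80%-height sub-rectangle of the
    face box.  The respiratory ROI is the horizontal band between the bottom
    of the face and the bottom of the upper body, 80% of the upper-body
    width, centred on the upper body.  Fractional sizes floor to integers.
    """
    bw = int(face.width * 0.60)
    bh = int(face.height * 0.80)
    if bw <= 0 or bh <= 0:
        raise ValueError("face box too small to derive a BVP ROI")
    bvp = Rect(face.x + (face.width - bw) // 2,
               face.y + (face.height - bh) // 2, bw, bh)

    chest_top = face.y2
    chest_bottom = upper_body.y2
    if chest_bottom <= chest_top:
        raise ValueError("face bottom at or below upper-body bottom: "
                         "no chest band available")
    rw = int(upper_body.width * 0.80)
    if rw <= 0:
        raise ValueError("upper-body box too narrow for a respiratory ROI")
    resp = Rect(upper_body.x + (upper_body.width - rw) // 2,
                chest_top, rw, chest_bottom - chest_top)
    return bvp, resp


def extract_roi_series(frames: FrameSeries, roi: Rect,
                       label: str = "") -> ObservedSeries:
    """Spatially average the pixels inside ``roi`` for every frame."""
    h, w = frames.shape
    if not roi.inside(h, w):
        raise ValueError(f"roi {roi} outside frame shape {(h, w)}")
    ys, xs = roi.slices()
    values = frames.frames[:, ys, xs].mean(axis=(1, 2), dtype=np.float64)
    return ObservedSeries(values=values, frame_rate=frames.frame_rate,
                          roi=roi, label=label)


def detect_rois(frames: FrameSeries, cascade_dir: str | Path,
                frame_index: int = 0) -> tuple[Rect, Rect]:
    """Detect face and upper-body boxes with pretrained Haar cascades.

    Optional adapter: consumes standard XML cascade model files through
    OpenCV and feeds :func:`derive_rois`.  The core pipeline does not
    depend on it — any source of ``Rect`` boxes works.
    """
    try:
        import cv2
    except ImportError as exc:
        raise ImportError(
            "automatic ROI detection requires opencv-python; "
            "pass explicit ROI rectangles instead") from exc
    cascade_dir = Path(cascade_dir)
    face_model = cv2.CascadeClassifier(
        str(cascade_dir / "haarcascade_frontalface_default.xml"))
    body_model = cv2.CascadeClassifier(
        str(cascade_dir / "haarcascade_upperbody.xml"))
    img = frames.frames[frame_index]
    faces = face_model.detectMultiScale(img)
    bodies = body_model.detectMultiScale(img)
    if len(faces) == 0 or len(bodies) == 0:
        raise ValueError("no face/upper-body detection on the given frame")
    fx, fy, fw, fh = max(faces, key=lambda r: r[2] * r[3])
    bx, by, bw, bh = max(bodies, key=lambda r: r[2] * r[3])
    return derive_rois(Rect(int(fx), int(fy), int(fw), int(fh)),
                       Rect(int(bx), int(by), int(bw), int(bh)))
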