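"""Frame loading, temporal down-sampling, background modelling and chamber ROIs.

The scoring pipeline operates on grayscale frames of backlit chambers at
1 frame per second.  Flies appear as dark silhouettes on a light background,
so segmentation downstream works on ``background - frame`` clipped at zero.
The static background is the pixel-wise mean of a random sample of frames,
which erases the (moving) flies while keeping chamber walls and illumination
gradients.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FrameSequence",
    "ChamberROI",
    "ChamberLayout",
    "Background",
    "load_frame_sequence",
    "build_background",
    "split_chambers",
]


class InputError(ValueError):
    """Unreadable or empty frame source."""


class ParameterError(ValueError):
    """Invalid user-supplied parameter."""


class LayoutError(ValueError):
    """Chamber layout inconsistent with the frame geometry."""


@dataclass
class FrameSequence:
    """Time-ordered single-channel frames at a fixed rate.

    Parameters
    ----------
    frames : list of 2-D arrays
        Grayscale intensity grids, all the same shape.
    fps : float
        Frames per second after any down-sampling.
    timestamps : array of float
        Seconds from recording start, strictly increasing.
    """

    frames: list[np.ndarray]
    fps: float
    timestamps: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ParameterError("fps must be positive")
        if self.timestamps is None:
            self.timestamps = np.arange(len(self.frames)) / self.fps
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.timestamps) != len(self.frames):
            raise InputError("one timestamp per frame required")
        if len(self.frames) > 1:
            shapes = {f.shape for f in self.frames}
            if len(shapes) != 1:
                raise InputError("all frames must share one shape")
            if np.any(np.diff(self.timestamps) <= 0):
                raise InputError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape


@dataclass(frozen=True)
class ChamberROI:
    """Rectangular region of interest, half-open in pixel coordinates."""

    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self) -> None:
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise LayoutError("ROI must have positive extent")

    def overlaps(self, other: "ChamberROI") -> bool:
        return not (
            self.row1 <= other.row0
            or other.row1 <= self.row0
            or self.col1 <= other.col0
            or other.col1 <= self.col0
        )


@dataclass
class ChamberLayout:
    """Up to four chamber ROIs plus the physical scale of the image.

    ``pixel_scale`` defaults to 0.12 mm/px, the scale at which a fly body is
    about 19 px long; ``expected_flies`` is the number of males loaded per
    chamber (six in the standard assay).
    """

    chambers: list[ChamberROI]
    pixel_scale: float = 0.12
    expected_flies: int = 6

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0:
            raise LayoutError("pixel_scale must be positive")
        for i, a in enumerate(self.chambers):
            for b in self.chambers[i + 1 :]:
                if a.overlaps(b):
                    raise LayoutError("chamber ROIs must not overlap")

    def validate_for(self, frame_shape: tuple[int, int]) -> None:
        h, w = frame_shape
        for roi in self.chambers:
            if roi.row0 < 0 or roi.col0 < 0 or roi.row1 > h or roi.col1 > w:
                raise LayoutError(f"ROI {roi} outside frame of shape {frame_shape}")

    @classmethod
    def single(cls, frame_shape: tuple[int, int], **kw) -> "ChamberLayout":
        """Layout with one ROI covering the whole frame."""
        h, w = frame_shape
        return cls(chambers=[ChamberROI(0, 0, h, w)], **kw)


@dataclass
class Background:
    """Static background estimate: mean of ``n_samples`` randomly picked frames."""

    image: np.ndarray
    n_samples: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ParameterError("n_samples must be >= 1")


_NUM_RE = re.compile(r"(\d+)")


def _numeric_key(p: Path) -> tuple:
    """Sort file names by embedded frame numbers (frame_2 before frame_10)."""
    return tuple(int(t) if t.isdigit() else t for t in _NUM_RE.split(p.name))


def _read_source(source) -> tuple[list[np.ndarray], float | None]:
    """Return raw frames and the source fps if the container states one."""
    if isinstance(source, FrameSequence):
        return list(source.frames), source.fps
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.is_dir():
            files = sorted(
                (p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}),
                key=_numeric_key,
            )
            if not files:
                raise InputError(f"no PNG/TIFF frames in {path}")
            frames = [_to_gray(iio.imread(f)) for f in files]
            return frames, None
        if not path.exists():
            raise InputError(f"source {path} does not exist")
        try:
            raw = iio.imread(path)
            meta = iio.immeta(path)
        except Exception as exc:  # pragma: no cover - codec specific
            raise InputError(f"cannot decode {path}: {exc}") from exc
        fps = meta.get("fps")
        raw = np.asarray(raw)
        if raw.ndim == 2:
            frames = [raw]
        else:
            frames = [_to_gray(f) for f in raw]
        return frames, fps
    frames = [np.asarray(f) for f in source]
    return frames, None


def _to_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    return img


def load_frame_sequence(
    source,
    target_fps: float = 1.0,
    source_fps: float | None = None,
) -> FrameSequence:
    """Load frames and down-sample to ``target_fps``.

    Down-sampling keeps the first frame of each ``1/target_fps`` interval, so a
    12-min recording at 30 fps reduced to 1 fps yields exactly 720 frames.

    Parameters
    ----------
    source : path, FrameSequence or sequence of 2-D arrays
        A video container, a directory of numbered PNG/TIFF frames, an
        existing sequence, or in-memory frames.
    target_fps : float
        Output rate; must not exceed the source rate.
    source_fps : float, optional
        Rate of ``source``.  Required for frame directories and in-memory
        lists; read from metadata for video containers; taken from the
        sequence itself for a ``FrameSequence`` input.
    """
    if target_fps <= 0:
        raise ParameterError("target_fps must be positive")
    frames, meta_fps = _read_source(source)
    if not frames:
        raise InputError("empty frame source")
    fps_in = source_fps if source_fps is not None else meta_fps
    if fps_in is None:
        raise ParameterError("source fps unknown; pass source_fps")
    if target_fps > fps_in + 1e-9:
        raise ParameterError(
            f"target_fps {target_fps} exceeds source fps {fps_in}"
        )

    step = fps_in / target_fps
    duration = len(frames) / fps_in
    n_out = math.floor(duration * target_fps)
    n_out = max(n_out, 1)
    idx = [min(math.floor(i * step), len(frames) - 1) for i in range(n_out)]
    out = [np.asarray(frames[i], dtype=float) for i in idx]
    return FrameSequence(frames=out, fps=target_fps)


def build_background(
    seq: FrameSequence, n: int = 40, seed: int | None = None
) -> Background:
    """Mean of ``n`` frames sampled uniformly without replacement.

    If ``n`` exceeds the number of frames, every frame is used and a warning
    is logged.  The moving flies average out; what remains is the chamber.
    """
    if len(seq) == 0:
        raise InputError("cannot build background from empty sequence")
    if n < 1:
        raise ParameterError("n must be >= 1")
    n_avail = len(seq)
    if n > n_avail:
        logger.warning(
            "requested %d background samples but only %d frames; using all", n, n_avail
        )
        n = n_avail
    rng = np.random.default_rng(seed)
    picks = rng.choice(n_avail, size=n, replace=False)
    stack = np.stack([np.asarray(seq.frames[i], dtype=float) for i in picks])
    return Background(image=stack.mean(axis=0), n_samples=n, seed=seed)


def split_chambers(
    frame: np.ndarray, layout: ChamberLayout
) -> list[tuple[ChamberROI, np.ndarray]]:
    """Cut a frame into per-chamber views.

    Returns ``(roi, subframe)`` pairs; the ROI records the offset so poses
    measured in chamber coordinates map back to full-frame coordinates by
    adding ``(roi.row0, roi.col0)``.
    """
    frame = np.asarray(frame)
    layout.validate_for(frame.shape)
    return [
        (roi, frame[roi.row0 : roi.row1, roi.col0 : roi.col1])
        for roi in layout.chambers
    ]
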