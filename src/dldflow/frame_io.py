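"""Reading video frames into ordered 8-bit grayscale arrays.

All downstream vision operations consume :class:`GrayFrame` objects: 2-D
``uint8`` rasters in (row, col) convention, origin top-left, with flow
running left→right.  Sources can be a directory of numbered PNG/TIFF
images, a multi-page TIFF stack, or a video container that imageio can
decode.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "GrayFrame",
    "FrameSequence",
    "read_frames",
    "write_frames",
    "to_gray",
    "FrameIOError",
    "EmptyInputError",
    "FormatError",
]


class FrameIOError(IOError):
    """Unreadable or unsupported video source."""


class EmptyInputError(FrameIOError):
    """The source contains zero frames."""


class FormatError(FrameIOError):
    """Frames in a sequence disagree in shape or type."""


# Rec. 601 luma weights, the standard for grayscale conversion of video.
_LUMA = np.array([0.299, 0.587, 0.114])

_IMAGE_EXTS = {".png", ".tif", ".tiff", ".bmp"}


def to_gray(pixels: np.ndarray) -> np.ndarray:
    """Convert an image array to 8-bit single-channel intensity.

    Already-gray 8-bit input is returned unchanged (identity).  RGB(A) is
    collapsed with Rec. 601 luma weights; 16-bit input is rescaled linearly
    onto [0, 255] since every downstream threshold is defined on 8-bit
    intensities.
    """
    arr = np.asarray(pixels)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            arr = arr @ _LUMA
        elif arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise FormatError(f"unsupported channel count {arr.shape[2]}")
    elif arr.ndim != 2:
        raise FormatError(f"expected 2-D or 3-D image, got ndim={arr.ndim}")
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        return (arr.astype(np.float64) * (255.0 / 65535.0)).round().astype(np.uint8)
    return np.clip(np.asarray(arr, dtype=np.float64).round(), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class GrayFrame:
    """A single grayscale video frame.

    Attributes
    ----------
    pixels : (H, W) uint8 array of intensities in [0, 255].
    index : 0-based frame number within the source video.
    """

    pixels: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("GrayFrame requires a non-empty 2-D array")
        if px.dtype != np.uint8:
            object.__setattr__(self, "pixels", to_gray(px))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class FrameSequence:
    """An ordered, shape-homogeneous list of frames plus frame-rate metadata."""

    frames: list[GrayFrame] = field(default_factory=list)
    frame_rate: float | None = None

    def __post_init__(self) -> None:
        if self.frames:
            shape = self.frames[0].pixels.shape
            for f in self.frames:
                if f.pixels.shape != shape:
                    raise FormatError(
                        f"inconsistent frame dimensions: {f.pixels.shape} vs {shape}"
                    )

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> GrayFrame:
        return self.frames[i]

    def __iter__(self) -> Iterator[GrayFrame]:
        return iter(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].pixels.shape

    def pairs(self) -> Iterator[tuple[GrayFrame, GrayFrame]]:
        """Iterate over strictly consecutive (previous, current) frame pairs."""
        for prev, curr in zip(self.frames, self.frames[1:]):
            yield prev, curr


def _numeric_key(p: Path) -> tuple:
    # frame_0002.png sorts after frame_10.png lexically; sort on the numbers
    parts = re.split(r"(\d+)", p.name)
    return tuple(int(s) if s.isdigit() else s for s in parts)


def _read_directory(path: Path) -> list[np.ndarray]:
    files = sorted(
        (p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTS),
        key=_numeric_key,
    )
    if not files:
        raise EmptyInputError(f"no image files found in {path}")
    return [iio.imread(p) for p in files]


def _read_file(path: Path) -> list[np.ndarray]:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            return [stack]
        return list(stack)
    if suffix in (".png", ".bmp"):
        return [iio.imread(path)]
    # video container: delegate to imageio (requires an ffmpeg plugin)
    try:
        return [fr for fr in iio.imiter(path)]
    except Exception as exc:  # pragma: no cover - plugin availability varies
        raise FrameIOError(f"cannot decode {path}: {exc}") from exc


def read_frames(
    path: str | Path,
    start: int = 0,
    count: int | None = None,
    frame_rate: float | None = None,
) -> FrameSequence:
    """Read a video source into a :class:`FrameSequence`.

    Parameters
    ----------
    path
        Directory of numbered images, a multi-page TIFF, a single image,
        or a video container.
    start, count
        Optional frame window: skip ``start`` frames, keep at most ``count``.
    frame_rate
        Camera frame rate in frames/s, carried as metadata only.

    Raises
    ------
    FrameIOError / EmptyInputError / FormatError
        On unreadable sources, zero frames, or inconsistent dimensions.
    """
    path = Path(path)
    if not path.exists():
        raise FrameIOError(f"no such file or directory: {path}")
    raw = _read_directory(path) if path.is_dir() else _read_file(path)
    raw = raw[start:]
    if count is not None:
        raw = raw[:count]
    if not raw:
        raise EmptyInputError(f"{path} yielded zero frames")
    shapes = {to_gray(r).shape for r in raw[:1]}
    frames = []
    for i, r in enumerate(raw):
        g = to_gray(r)
        if g.shape != next(iter(shapes)):
            raise FormatError(
                f"frame {i} has shape {g.shape}, expected {next(iter(shapes))}"
            )
        frames.append(GrayFrame(g, index=i))
    return FrameSequence(frames, frame_rate=frame_rate)


def write_frames(
    seq: FrameSequence | Sequence[GrayFrame],
    path: str | Path,
    fmt: str = "png",
) -> list[Path]:
    """Write frames losslessly.

    ``fmt='png'`` / ``'tif'`` writes a numbered image sequence into the
    directory ``path``; ``fmt='stack'`` writes a single multi-page TIFF at
    ``path``.  Round-trips through :func:`read_frames` are pixel-exact.
    """
    frames = list(seq)
    path = Path(path)
    if fmt == "stack":
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, np.stack([f.pixels for f in frames]))
        return [path]
    path.mkdir(parents=True, exist_ok=True)
    out = []
    for i, f in enumerate(frames):
        p = path / f"frame_{i:05d}.{fmt}"
        iio.imwrite(p, f.pixels)
        out.append(p)
    return out
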