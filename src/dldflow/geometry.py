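"""Frame geometry: de-skew, observation-window localisation, wall detection.

The outlet channels of the DLD device must be horizontal before any
detection runs.  Skew is estimated from the mean angle of near-horizontal
line segments found by a probabilistic Hough transform, and removed by an
iterative rotate–crop–re-estimate loop with a damping rule that prevents
the correction from running away when successive estimates disagree.

The observation window — the rectangle covering the 12 outlet channels —
is located horizontally by normalized-cross-correlation template matching
(one template marks the upper end of the array, one the lower end) and
vertically by the outermost Hough line segments.  Channel walls inside the
window are found by pooling row votes from Canny edges and Hough segments,
grouping consecutive rows, and taking each group's most-voted row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import canny, match_template
from skimage.transform import probabilistic_hough_line, rotate

from .frame_io import GrayFrame

__all__ = [
    "LineParams",
    "EdgeParams",
    "RotationResult",
    "ObservationWindow",
    "TemplatePair",
    "ChannelGeometry",
    "estimate_skew_angle",
    "auto_rotate",
    "rotate_and_crop",
    "locate_horizontal_bounds",
    "locate_vertical_bounds",
    "detect_walls",
    "group_rows",
    "GeometryError",
    "NoLinesError",
    "LowConfidenceError",
    "InvalidWindowError",
    "InsufficientWallsError",
]


class GeometryError(RuntimeError):
    """Base class for geometry-stage failures."""


class NoLinesError(GeometryError):
    """The line detector found no usable segments."""


class LowConfidenceError(GeometryError):
    """Best template-match score fell below the confidence floor."""


class InvalidWindowError(GeometryError):
    """Derived observation window is degenerate."""


class InsufficientWallsError(GeometryError):
    """Fewer than two channel walls were detected."""


@dataclass
class LineParams:
    """Probabilistic Hough configuration.

    ``min_length_frac`` is the minimum segment length as a fraction of the
    image width; walls span most of the window, and demanding long segments
    keeps stair-step fragments of anti-aliased edges (whose angles are
    biased toward zero) out of the skew estimate.  ``max_angle_deg``
    restricts both the Hough normal band and the segments kept for skew
    estimation to near-horizontal lines.
    """

    threshold: int = 10
    min_length_frac: float = 0.5
    max_gap: int = 5
    max_angle_deg: float = 15.0
    canny_sigma: float = 1.5

    def theta(self) -> np.ndarray:
        d = math.radians(self.max_angle_deg)
        n = max(int(self.max_angle_deg * 4), 8)
        return np.concatenate(
            [
                np.linspace(-math.pi / 2, -math.pi / 2 + d, n),
                np.linspace(math.pi / 2 - d, math.pi / 2, n),
            ]
        )


@dataclass
class EdgeParams:
    """Canny configuration; thresholds are gradient-magnitude quantiles,
    an automatic rule that adapts to contrast (median-anchored)."""

    sigma: float = 1.5
    low_quantile: float = 0.5
    high_quantile: float = 0.9


@dataclass(frozen=True)
class RotationResult:
    """Outcome of :func:`auto_rotate`.

    ``total_angle`` is the cumulative rotation applied to the frame in
    degrees, counterclockwise positive.
    """

    total_angle: float
    iterations: int
    converged: bool


@dataclass(frozen=True)
class ObservationWindow:
    """Pixel bounds of the outlet-channel region: rows [top_row, bottom_row),
    columns [left_col, right_col)."""

    left_col: int
    right_col: int
    top_row: int
    bottom_row: int

    def __post_init__(self) -> None:
        if not (0 <= self.left_col < self.right_col):
            raise InvalidWindowError(
                f"bad column bounds [{self.left_col}, {self.right_col})"
            )
        if not (0 <= self.top_row < self.bottom_row):
            raise InvalidWindowError(
                f"bad row bounds [{self.top_row}, {self.bottom_row})"
            )

    def crop(self, pixels: np.ndarray) -> np.ndarray:
        return pixels[self.top_row : self.bottom_row, self.left_col : self.right_col]


@dataclass(frozen=True)
class TemplatePair:
    """Small reference images marking the upper and lower ends of the
    outlet-channel array."""

    top_template: GrayFrame
    bottom_template: GrayFrame

    def validate_against(self, frame: GrayFrame) -> None:
        for t in (self.top_template, self.bottom_template):
            if t.height >= frame.height or t.width >= frame.width:
                raise ValueError("template must be strictly smaller than the frame")


@dataclass(frozen=True)
class ChannelGeometry:
    """Ordered wall rows and the outlet channels they delimit.

    ``channels`` holds ``(upper_wall_row, lower_wall_row, channel_id)`` with
    1-based ids counted top→bottom; channels tile [first wall, last wall].
    """

    wall_rows: tuple[int, ...]
    channels: tuple[tuple[int, int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        walls = tuple(int(w) for w in self.wall_rows)
        if len(walls) < 2:
            raise InsufficientWallsError(f"need >= 2 walls, got {len(walls)}")
        if any(b <= a for a, b in zip(walls, walls[1:])):
            raise ValueError("wall rows must be strictly increasing")
        object.__setattr__(self, "wall_rows", walls)
        chans = tuple(
            (walls[i], walls[i + 1], i + 1) for i in range(len(walls) - 1)
        )
        object.__setattr__(self, "channels", chans)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_of(self, row: float) -> int | None:
        """Channel id for a detection row: channel i covers
        (wall[i-1], wall[i]]; rows outside the wall span -> None."""
        walls = np.asarray(self.wall_rows, dtype=float)
        i = int(np.searchsorted(walls, row, side="left"))
        if i == 0 or i == len(walls):  # at/above first wall or below last
            return None
        return i

    def shifted(self, offset: int) -> "ChannelGeometry":
        return ChannelGeometry(tuple(w + offset for w in self.wall_rows))


def _hough_segments(
    pixels: np.ndarray, params: LineParams, seed: int = 0
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    edges = canny(pixels, sigma=params.canny_sigma)
    min_len = max(10, int(params.min_length_frac * pixels.shape[1]))
    return probabilistic_hough_line(
        edges,
        threshold=params.threshold,
        line_length=min_len,
        line_gap=params.max_gap,
        theta=params.theta(),
        rng=seed,
    )


def _segment_angle(seg) -> float:
    """Angle of a Hough segment from horizontal, degrees.

    Segments come as ((x0, y0), (x1, y1)) in (col, row) order; image rows
    grow downward, so a visually counterclockwise tilt (up to the right)
    gives a positive angle.
    """
    (x0, y0), (x1, y1) = seg
    if x1 < x0:
        x0, y0, x1, y1 = x1, y1, x0, y0
    return math.degrees(math.atan2(y0 - y1, x1 - x0))


def estimate_skew_angle(
    frame: GrayFrame, line_params: LineParams | None = None
) -> float:
    """Mean angle-from-horizontal of detected line segments, in degrees.

    Positive = content tilted counterclockwise.  Raises
    :class:`NoLinesError` when no near-horizontal segments are found.
    """
    params = line_params or LineParams()
    segs = _hough_segments(frame.pixels, params)
    angles = [
        a
        for a in (_segment_angle(s) for s in segs)
        if abs(a) <= params.max_angle_deg
    ]
    if not angles:
        raise NoLinesError("no near-horizontal line segments detected")
    return float(np.mean(angles))


def _max_interior_rect(w: int, h: int, angle_deg: float) -> tuple[int, int]:
    """Dimensions of the largest axis-aligned rectangle fully inside a
    w×h rectangle rotated by ``angle_deg`` (no fill pixels)."""
    a = abs(math.sin(math.radians(angle_deg)))
    b = abs(math.cos(math.radians(angle_deg)))
    if a < 1e-12:
        return w, h
    long_side, short_side = (w, h) if w >= h else (h, w)
    if short_side <= 2 * a * b * long_side or abs(a - b) < 1e-10:
        x = 0.5 * short_side
        wr, hr = (x / a, x / b) if w >= h else (x / b, x / a)
    else:
        cos2 = b * b - a * a
        wr = (w * b - h * a) / cos2
        hr = (h * b - w * a) / cos2
    return max(1, int(wr)), max(1, int(hr))


def rotate_and_crop(frame: GrayFrame, angle_deg: float) -> GrayFrame:
    """Rotate about the frame center (counterclockwise positive) and crop to
    the largest interior rectangle free of fill pixels."""
    if abs(angle_deg) < 1e-12:
        return frame
    rot = rotate(frame.pixels, angle_deg, resize=False, preserve_range=True, order=1)
    h, w = rot.shape
    cw, ch = _max_interior_rect(w, h, angle_deg)
    r0 = (h - ch) // 2
    c0 = (w - cw) // 2
    out = np.clip(rot[r0 : r0 + ch, c0 : c0 + cw].round(), 0, 255).astype(np.uint8)
    return GrayFrame(out, index=frame.index)


def auto_rotate(
    frame: GrayFrame,
    tolerance: float = 0.5,
    max_iterations: int = 5,
    line_params: LineParams | None = None,
) -> tuple[GrayFrame, RotationResult]:
    """Iteratively de-skew a frame until the residual is within tolerance.

    Each pass estimates the skew of the current frame, adds the correction
    to the running total, re-rotates the *original* frame by the total (so
    crops do not compound), and re-verifies.  Damping rule: when the
    cumulative requested rotation exceeds twice the first correction in
    magnitude, 1.5x the first correction is applied instead — successive
    over-shooting estimates cannot run away.

    Returns the rotated frame and a :class:`RotationResult`; non-convergence
    is reported via ``converged=False``, not an exception.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    current = frame
    total = 0.0
    first_correction: float | None = None
    for it in range(1, max_iterations + 1):
        est = estimate_skew_angle(current, line_params)
        if abs(est) <= tolerance:
            return current, RotationResult(total, it, True)
        correction = -est
        if first_correction is None:
            first_correction = correction
        requested = total + correction
        if abs(requested) > 2 * abs(first_correction):
            requested = 1.5 * first_correction
        current = rotate_and_crop(frame, requested)
        total = requested
    return current, RotationResult(total, max_iterations, False)


def locate_horizontal_bounds(
    frame: GrayFrame,
    templates: TemplatePair,
    min_score: float = 0.5,
) -> tuple[int, int]:
    """Left/right observation-window columns from template matching.

    Each template is slid over the (de-skewed) frame with normalized
    cross-correlation; the best match's upper-left corner is taken.  The
    left bound is the mean of the two matched columns and the right bound
    adds the mean template width, both clamped to the frame.
    """
    templates.validate_against(frame)
    cols = []
    widths = []
    for tmpl in (templates.top_template, templates.bottom_template):
        score = match_template(
            frame.pixels.astype(np.float64), tmpl.pixels.astype(np.float64)
        )
        best = float(score.max())
        if best < min_score:
            raise LowConfidenceError(
                f"template match score {best:.3f} below floor {min_score}"
            )
        _, col = np.unravel_index(int(np.argmax(score)), score.shape)
        cols.append(int(col))
        widths.append(tmpl.width)
    left = int(round(np.mean(cols)))
    right = left + int(round(np.mean(widths)))
    left = max(0, min(left, frame.width - 1))
    right = max(left + 1, min(right, frame.width))
    return left, right


def locate_vertical_bounds(
    frame: GrayFrame,
    left_col: int,
    right_col: int,
    line_params: LineParams | None = None,
    min_span: int = 5,
) -> tuple[int, int]:
    """Top/bottom window rows: the extreme rows touched by detected line
    segments within [left_col, right_col) — i.e. the outermost walls.

    A span below ``min_span`` rows means only a single wall line was seen
    (both Canny flanks of one wall) and is rejected as degenerate.
    """
    params = line_params or LineParams()
    strip = frame.pixels[:, left_col:right_col]
    segs = _hough_segments(strip, params)
    if not segs:
        raise NoLinesError("no line segments inside the column bounds")
    rows = [y for (x0, y0), (x1, y1) in segs for y in (y0, y1)]
    top, bottom = int(min(rows)), int(max(rows))
    if bottom - top < min_span:
        raise InvalidWindowError(
            f"degenerate window: line structure spans rows {top}-{bottom} only"
        )
    return top, bottom


def group_rows(
    votes: list[int] | np.ndarray, gap_threshold: int
) -> list[tuple[int, int]]:
    """Collapse a multiset of row votes into (wall_row, vote_count) per group.

    The sorted unique rows are split wherever the gap to the next row
    exceeds ``gap_threshold``; within each group the most-voted row wins,
    ties going to the smaller row index.
    """
    votes = np.asarray(votes, dtype=int)
    if votes.size == 0:
        return []
    rows, counts = np.unique(votes, return_counts=True)
    walls = []
    start = 0
    for i in range(1, len(rows) + 1):
        if i == len(rows) or rows[i] - rows[i - 1] > gap_threshold:
            grp_rows = rows[start:i]
            grp_counts = counts[start:i]
            best = int(np.argmax(grp_counts))  # argmax -> first = smallest row
            walls.append((int(grp_rows[best]), int(grp_counts[best])))
            start = i
    return walls


def detect_walls(
    window_pixels: np.ndarray,
    edge_params: EdgeParams | None = None,
    line_params: LineParams | None = None,
    gap_threshold: int = 3,
) -> ChannelGeometry:
    """Detect outlet-channel walls inside the observation window.

    Row votes are pooled from (a) every Canny edge pixel's row and (b) every
    row covered by a probabilistic-Hough segment, then grouped with
    :func:`group_rows`; each group contributes one wall.  Requires the
    window to be de-skewed (walls horizontal).
    """
    if window_pixels.shape[0] < 3:
        raise InvalidWindowError("window must be at least 3 rows tall")
    ep = edge_params or EdgeParams()
    lp = line_params or LineParams()
    edges = canny(
        window_pixels,
        sigma=ep.sigma,
        low_threshold=ep.low_quantile,
        high_threshold=ep.high_quantile,
        use_quantiles=True,
    )
    votes: list[int] = list(np.nonzero(edges)[0])
    segs = probabilistic_hough_line(
        edges,
        threshold=lp.threshold,
        line_length=max(10, int(lp.min_length_frac * window_pixels.shape[1])),
        line_gap=lp.max_gap,
        theta=lp.theta(),
        rng=0,
    )
    for (x0, y0), (x1, y1) in segs:
        lo, hi = sorted((y0, y1))
        votes.extend(range(lo, hi + 1))
    walls = [w for w, _ in group_rows(votes, gap_threshold)]
    if len(walls) < 2:
        raise InsufficientWallsError(
            f"detected {len(walls)} wall(s); need at least 2"
        )
    return ChannelGeometry(tuple(walls))
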