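"""Particle detection with repeat-detection suppression.

Counting works frame-pair by frame-pair.  A static background is built
from the zeroth frame (any particles caught in it are patched with the
mean of the non-particle pixels of their own rows), each frame has the
background subtracted, consecutive residuals are differenced with
negatives clamped to zero — what survives is the newly occupied particle
positions — and surviving blobs are filtered by area and circularity over
an intensity-threshold sweep.

A particle advecting left→right is re-detected in every frame pair it
remains visible.  The suppression rule set compares the current centroids
against the previous pair's: a centroid whose row is within the one-pixel
row tolerance of a previous centroid while its column changed is the same
particle moved downstream and is suppressed; a centroid whose row differs
from every previous row by more than the tolerance is a new particle; an
exactly identical (row, col) repeat is also a new particle, because a
real particle can never be stationary in the flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import regionprops

from .geometry import ChannelGeometry

__all__ = [
    "BlobParams",
    "Background",
    "Detection",
    "DetectionLedger",
    "RunSummary",
    "build_background",
    "subtract_background",
    "frame_difference",
    "detect_blobs",
    "filter_new_particles",
    "assign_channels",
    "summarize_run",
]

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity for blob components


@dataclass
class BlobParams:
    """Blob filter configuration.

    ``min_area``/``max_area`` bound the component pixel area, circularity is
    4π·area/perimeter² (1 for a perfect disk), and the threshold range
    ``(low, high, step)`` sweeps binarisation levels; a blob must reappear at
    ``min_repeatability`` thresholds within ``merge_dist`` pixels to count.
    """

    min_area: float = 30.0
    max_area: float = 2000.0
    min_circularity: float = 0.6
    intensity_threshold_range: tuple[float, float, float] = (10.0, 220.0, 10.0)
    min_repeatability: int = 2
    merge_dist: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.min_area <= self.max_area:
            raise ValueError("need 0 < min_area <= max_area")
        if not 0 <= self.min_circularity <= 1:
            raise ValueError("min_circularity must lie in [0, 1]")

    @classmethod
    def for_particle(
        cls, diameter_um: float, um_per_px: float = 1.0, **kw
    ) -> "BlobParams":
        """Derive area bounds from the nominal particle diameter and the
        image scale: min_area is half the projected disk area, max_area
        four times it."""
        r_px = diameter_um / (2.0 * um_per_px)
        area = np.pi * r_px**2
        kw.setdefault("min_area", max(4.0, 0.5 * area))
        kw.setdefault("max_area", 4.0 * area)
        return cls(**kw)


def _accepted_components(
    matrix: np.ndarray, params: BlobParams
) -> list[tuple[float, tuple[float, float], np.ndarray]]:
    """All components passing the area/circularity filters over the
    threshold sweep, as (threshold, centroid, mask-slice) records."""
    low, high, step = params.intensity_threshold_range
    out = []
    peak = float(matrix.max()) if matrix.size else 0.0
    for t in np.arange(low, high + 1e-9, step):
        if t > peak:
            break
        mask = matrix >= t
        labels, n = ndimage.label(mask, structure=_EIGHT)
        if n == 0:
            continue
        # cheap area prefilter: skip regionprops for specks and giants
        areas = np.bincount(labels.ravel())[1:]
        keep = np.nonzero(
            (areas >= params.min_area) & (areas <= params.max_area)
        )[0] + 1
        if keep.size == 0:
            continue
        pruned = np.where(np.isin(labels, keep), labels, 0)
        for prop in regionprops(pruned):
            if not (params.min_area <= prop.area <= params.max_area):
                continue
            perim = prop.perimeter
            circ = 4.0 * np.pi * prop.area / perim**2 if perim > 0 else 1.0
            if circ < params.min_circularity:
                continue
            out.append((float(t), prop.centroid, prop))
    return out


def detect_blobs(
    matrix: np.ndarray, params: BlobParams
) -> list[tuple[float, float]]:
    """Centroids of blobs stable across the intensity-threshold sweep.

    Per-threshold centroids are greedily clustered (within ``merge_dist``);
    clusters seen at fewer than ``min_repeatability`` thresholds are
    dropped.  Returns (row, col) float centroids; empty list is valid.
    """
    recs = _accepted_components(np.asarray(matrix, dtype=np.float64), params)
    clusters: list[list[tuple[float, float]]] = []
    for _, (r, c), _ in recs:
        for cl in clusters:
            mr = float(np.mean([p[0] for p in cl]))
            mc = float(np.mean([p[1] for p in cl]))
            if (mr - r) ** 2 + (mc - c) ** 2 <= params.merge_dist**2:
                cl.append((r, c))
                break
        else:
            clusters.append([(r, c)])
    return [
        (float(np.mean([p[0] for p in cl])), float(np.mean([p[1] for p in cl])))
        for cl in clusters
        if len(cl) >= params.min_repeatability
    ]


@dataclass
class Background:
    """Static scene estimate built from the zeroth frame."""

    pixels: np.ndarray
    source_frame: int = 0
    patched_regions: list[tuple[int, int, int, int]] = field(default_factory=list)
    full_row_fallbacks: list[int] = field(default_factory=list)


def build_background(zeroth, params: BlobParams) -> Background:
    """Construct the background from the zeroth frame.

    Any region the blob detector flags as a particle is replaced, row by
    row, with the mean of that row's non-blob pixels; a row consisting
    entirely of blob pixels falls back to the global non-blob mean and is
    recorded in ``full_row_fallbacks``.
    """
    pixels = np.asarray(getattr(zeroth, "pixels", zeroth))
    recs = _accepted_components(pixels.astype(np.float64), params)
    if not recs:
        return Background(pixels.copy())
    blob_mask = np.zeros(pixels.shape, dtype=bool)
    bboxes = []
    for _, _, prop in recs:
        r0, c0, r1, c1 = prop.bbox
        blob_mask[r0:r1, c0:c1][prop.image] = True
        bboxes.append((r0, c0, r1, c1))
    out = pixels.astype(np.float64).copy()
    global_mean = out[~blob_mask].mean() if (~blob_mask).any() else out.mean()
    full_rows = []
    for r in np.nonzero(blob_mask.any(axis=1))[0]:
        keep = ~blob_mask[r]
        if keep.any():
            out[r, ~keep] = out[r, keep].mean()
        else:
            out[r, :] = global_mean
            full_rows.append(int(r))
    # dedupe overlapping bboxes while preserving order
    seen: list[tuple[int, int, int, int]] = []
    for b in bboxes:
        if b not in seen:
            seen.append(b)
    return Background(
        np.clip(out.round(), 0, 255).astype(pixels.dtype),
        patched_regions=seen,
        full_row_fallbacks=full_rows,
    )


def subtract_background(frame, bg: Background) -> np.ndarray:
    """frame − background, negatives clamped to 0 (moving bright objects)."""
    pixels = np.asarray(getattr(frame, "pixels", frame))
    if pixels.shape != bg.pixels.shape:
        raise ValueError(f"shape mismatch {pixels.shape} vs {bg.pixels.shape}")
    diff = pixels.astype(np.int16) - bg.pixels.astype(np.int16)
    return np.clip(diff, 0, 255).astype(np.uint8)


def frame_difference(curr_residual: np.ndarray, prev_residual: np.ndarray) -> np.ndarray:
    """current − previous residual, negatives clamped to 0.

    Nonzero support approximates the newly occupied particle positions of
    the current frame."""
    if curr_residual.shape != prev_residual.shape:
        raise ValueError(
            f"shape mismatch {curr_residual.shape} vs {prev_residual.shape}"
        )
    diff = curr_residual.astype(np.int16) - prev_residual.astype(np.int16)
    return np.clip(diff, 0, 255).astype(np.uint8)


@dataclass
class Detection:
    """A unique particle detection: float centroid plus the (later) frame
    of the pair it was first seen in; channel assigned downstream."""

    row: float
    col: float
    frame_index: int
    channel_id: int | None = None


def _round01(x: float) -> float:
    # collapse precision to 0.1 px so duplicate suppression is well-defined
    return round(float(x), 1)


@dataclass
class DetectionLedger:
    """Cumulative unique detections plus the per-pair state the repeat
    rules need (the previous pair's centroid set)."""

    row_tolerance: float = 1.0
    previous_centroids: list[tuple[float, float]] = field(default_factory=list)
    unique_detections: list[Detection] = field(default_factory=list)

    @property
    def total(self) -> int:
        return len(self.unique_detections)


def filter_new_particles(
    current: Sequence[tuple[float, float]],
    ledger: DetectionLedger,
    frame_index: int,
) -> list[Detection]:
    """Classify the current pair's centroids against the previous pair's.

    A centroid is NEW when its row is farther than the row tolerance from
    every previous centroid's row, or when it exactly coincides with a
    previous centroid (a stationary repeat cannot be a real particle in a
    moving flow, so it is counted as a new arrival).  Anything else — row
    within tolerance of a previous row while the position is not identical
    — is a downstream repeat and is suppressed.  Duplicates within the
    current set are collapsed to unique positions first.  The ledger's
    previous set is then replaced by the full current set.
    """
    rounded: list[tuple[float, float]] = []
    for r, c in current:
        p = (_round01(r), _round01(c))
        if p not in rounded:
            rounded.append(p)
    prev = ledger.previous_centroids
    new: list[Detection] = []
    for r, c in rounded:
        if (r, c) in prev:
            new.append(Detection(r, c, frame_index))
            continue
        if all(abs(r - pr) > ledger.row_tolerance for pr, _ in prev):
            new.append(Detection(r, c, frame_index))
        # else: same row within tolerance, position changed -> repeat
    ledger.unique_detections.extend(new)
    ledger.previous_centroids = rounded
    return new


def assign_channels(
    detections: Iterable[Detection], geometry: ChannelGeometry
) -> list[Detection]:
    """Assign each detection the outlet channel whose wall interval
    (upper_wall, lower_wall] contains its row; rows outside the wall span
    stay unassigned."""
    out = list(detections)
    for d in out:
        d.channel_id = geometry.channel_of(d.row)
    return out


@dataclass
class RunSummary:
    """Per-run detection summary: the per-particle table, per-outlet counts
    and percentages, and run metadata."""

    counts: np.ndarray
    percentages: np.ndarray
    total: int
    unassigned: int
    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return len(self.counts)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, lineterminator="\n")

    def to_json_dict(self) -> dict:
        return {
            "total": int(self.total),
            "unassigned": int(self.unassigned),
            "per_channel_counts": [int(c) for c in self.counts],
            "per_channel_percentages": [round(float(p), 4) for p in self.percentages],
            "metadata": self.metadata,
        }


def summarize_run(
    ledger: DetectionLedger,
    geometry: ChannelGeometry,
    metadata: dict | None = None,
) -> RunSummary:
    """Aggregate the finalized ledger into per-outlet counts, percentages
    of the assigned total, and the per-particle table."""
    n = geometry.n_channels
    counts = np.zeros(n, dtype=int)
    unassigned = 0
    rows = []
    for d in ledger.unique_detections:
        if d.channel_id is None:
            unassigned += 1
        else:
            counts[d.channel_id - 1] += 1
        rows.append(
            {
                "frame_index": d.frame_index,
                "row": d.row,
                "col": d.col,
                "channel": d.channel_id if d.channel_id is not None else -1,
            }
        )
    assigned = int(counts.sum())
    pct = counts * (100.0 / assigned) if assigned > 0 else np.zeros(n)
    table = pd.DataFrame(
        rows, columns=["frame_index", "row", "col", "channel"]
    )
    return RunSummary(
        counts=counts,
        percentages=pct,
        total=ledger.total,
        unassigned=unassigned,
        table=table,
        metadata=dict(metadata or {}),
    )
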