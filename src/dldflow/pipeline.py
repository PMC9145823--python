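"""End-to-end detection pipeline: rotate → window → walls → count.

Ties the geometry and detection stages together for a whole video.  The
skew is estimated on the zeroth frame and the same correction is applied
to every frame (the device does not move during a recording); all
detection then happens inside the observation window, in de-skewed frame
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import (
    BlobParams,
    DetectionLedger,
    RunSummary,
    assign_channels,
    build_background,
    detect_blobs,
    filter_new_particles,
    frame_difference,
    subtract_background,
    summarize_run,
)
from .frame_io import FrameSequence, GrayFrame
from .geometry import (
    ChannelGeometry,
    EdgeParams,
    LineParams,
    NoLinesError,
    ObservationWindow,
    RotationResult,
    TemplatePair,
    auto_rotate,
    detect_walls,
    locate_horizontal_bounds,
    locate_vertical_bounds,
    rotate_and_crop,
)

__all__ = ["PipelineSettings", "PipelineState", "analyze_video"]


@dataclass
class PipelineSettings:
    """Everything the vision pipeline needs beyond the video itself."""

    blob: BlobParams = field(default_factory=BlobParams)
    line: LineParams = field(default_factory=LineParams)
    edge: EdgeParams = field(default_factory=EdgeParams)
    rotation_tolerance: float = 0.5
    rotation_max_iterations: int = 5
    wall_gap_threshold: int = 3
    row_tolerance: float = 1.0
    template_min_score: float = 0.5
    # 'bright': particles brighter than background; 'dark': inverted first
    particle_polarity: str = "bright"


@dataclass
class PipelineState:
    """Intermediate geometry kept for QC output and tests."""

    rotation: RotationResult
    window: ObservationWindow
    geometry: ChannelGeometry
    ledger: DetectionLedger


def _oriented(pixels: np.ndarray, settings: PipelineSettings) -> np.ndarray:
    if settings.particle_polarity == "dark":
        return (255 - pixels.astype(np.int16)).astype(np.uint8)
    return pixels


def analyze_video(
    seq: FrameSequence,
    templates: TemplatePair | None = None,
    settings: PipelineSettings | None = None,
    metadata: dict | None = None,
) -> tuple[RunSummary, PipelineState]:
    """Run the full detection pipeline on a video.

    Stages: (1) de-skew from the zeroth frame; (2) locate the observation
    window — template matching for the left/right bounds when templates
    are given (full width otherwise), outermost Hough lines for top/bottom;
    (3) detect outlet walls inside the window; (4) build the background
    from the zeroth frame and count particles over consecutive frame pairs
    with repeat suppression; (5) summarize per-outlet counts.

    Returns the :class:`RunSummary` and the intermediate
    :class:`PipelineState` (rotation, window, wall geometry, ledger).
    """
    st = settings or PipelineSettings()
    if len(seq) == 0:
        raise ValueError("empty frame sequence")

    zeroth = seq[0]
    try:
        _, rotation = auto_rotate(
            zeroth, st.rotation_tolerance, st.rotation_max_iterations, st.line
        )
    except NoLinesError:
        # featureless zeroth frame: fall back to no rotation
        rotation = RotationResult(0.0, 1, False)

    def deskew(fr: GrayFrame) -> GrayFrame:
        if rotation.total_angle == 0.0:
            return fr
        return rotate_and_crop(fr, rotation.total_angle)

    frame0 = deskew(zeroth)

    if templates is not None:
        left, right = locate_horizontal_bounds(
            frame0, templates, st.template_min_score
        )
    else:
        left, right = 0, frame0.width
    top, bottom = locate_vertical_bounds(frame0, left, right, st.line)
    # bounds are the outermost wall rows (inclusive); pad by a few rows so
    # the outermost walls keep both Canny transitions inside the crop
    pad = 4
    window = ObservationWindow(
        left, right, max(0, top - pad), min(bottom + 1 + pad, frame0.height)
    )

    geom_local = detect_walls(
        window.crop(frame0.pixels), st.edge, st.line, st.wall_gap_threshold
    )
    geometry = geom_local.shifted(window.top_row)

    bg = build_background(
        _oriented(window.crop(frame0.pixels), st), st.blob
    )
    ledger = DetectionLedger(row_tolerance=st.row_tolerance)
    prev_residual = subtract_background(
        _oriented(window.crop(frame0.pixels), st), bg
    )
    for frame in list(seq)[1:]:
        fr = deskew(frame)
        residual = subtract_background(_oriented(window.crop(fr.pixels), st), bg)
        diff = frame_difference(residual, prev_residual)
        centroids = detect_blobs(diff, st.blob)
        # shift into de-skewed frame coordinates before ledger bookkeeping
        shifted = [
            (r + window.top_row, c + window.left_col) for r, c in centroids
        ]
        filter_new_particles(shifted, ledger, frame.index)
        prev_residual = residual

    assign_channels(ledger.unique_detections, geometry)
    summary = summarize_run(ledger, geometry, metadata)
    summary.metadata.update(
        {
            "rotation_deg": round(rotation.total_angle, 4),
            "window": [window.top_row, window.bottom_row,
                       window.left_col, window.right_col],
            "wall_rows": list(geometry.wall_rows),
        }
    )
    return summary, PipelineState(rotation, window, geometry, ledger)
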