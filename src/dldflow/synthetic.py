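"""Ground-truthed synthetic fixtures: DLD outlet videos and mode datasets.

The video generator emulates the outlet region of a DLD device as seen by
a high-speed camera: a horizontal array of bright outlet channels (12 by
default) separated by dark wall lines, with particles rendered as
anti-aliased bright disks advecting strictly left→right at constant rows,
optional Gaussian sensor noise, and an optional global skew applied last.
Every fixture ships a ground-truth sidecar (true counts per channel,
per-particle trajectories, wall rows, applied skew) so each pipeline
stage can be tested without external data.

Particles in the same channel are scheduled on row slots separated by
more than the detector's one-pixel row tolerance whenever they are
simultaneously visible; the repeat-suppression rule set cannot tell two
co-row, co-present particles apart (by design — it trades that blind spot
for immunity to double counting), so the generator reuses a row only
after its previous occupant has fully exited.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import rotate

from .frame_io import FrameSequence, GrayFrame
from .geometry import TemplatePair

__all__ = [
    "VideoFixtureConfig",
    "GroundTruth",
    "generate_dld_video",
    "make_templates",
    "generate_mode_dataset",
    "MODE_SUPPORTS",
]


@dataclass
class VideoFixtureConfig:
    """Parameters of a synthetic outlet-region video.

    Intensities are 8-bit; geometry is in pixels; ``advection`` is the
    constant left→right particle speed in px/frame and must stay >= 2 so
    consecutive-frame differencing separates old from new positions.  The
    default (14 px/frame) exceeds the particle diameter, mirroring an
    operator-matched frame rate: each frame pair then leaves the particle's
    full disk in the difference image rather than a thin crescent.
    """

    n_channels: int = 12
    wall_spacing: int = 30          # channel interior height, px
    wall_thickness: int = 2
    frame_width: int = 320
    margin_top: int = 22
    margin_bottom: int = 22
    n_particles: int = 60
    particle_radius: float = 6.0
    advection: float = 14.0
    background_intensity: int = 120
    wall_intensity: int = 40
    particle_intensity: int = 245
    noise_sd: float = 0.0
    skew_angle: float = 0.0
    seed: int = 0
    channel_weights: tuple[float, ...] | None = None  # None -> uniform
    row_separation: int = 3         # min gap between co-present rows, px
    entry_gap: int = 6              # frames between reuses of a row slot
    frame0_particles: int = 0       # stamped in frame 0 only (bg patching)
    n_frames: int | None = None     # None -> until all particles exit

    def __post_init__(self) -> None:
        if self.advection < 2:
            raise ValueError("advection must be >= 2 px/frame")
        usable = self.wall_spacing - 2 * (int(self.particle_radius) + 2)
        if usable < 1:
            raise ValueError(
                "particle radius too large for the channel spacing: "
                "particle footprints must fit within their channels"
            )
        if self.channel_weights is not None and (
            len(self.channel_weights) != self.n_channels
            or min(self.channel_weights) < 0
            or sum(self.channel_weights) <= 0
        ):
            raise ValueError("channel_weights must be n_channels nonnegative weights")

    @property
    def frame_height(self) -> int:
        n_walls = self.n_channels + 1
        return (
            self.margin_top
            + n_walls * self.wall_thickness
            + self.n_channels * self.wall_spacing
            + self.margin_bottom
        )

    def wall_top_rows(self) -> list[int]:
        step = self.wall_spacing + self.wall_thickness
        return [self.margin_top + i * step for i in range(self.n_channels + 1)]

    def wall_center_rows(self) -> list[float]:
        half = (self.wall_thickness - 1) / 2.0
        return [r + half for r in self.wall_top_rows()]


@dataclass
class GroundTruth:
    """Sidecar truth for a synthetic video."""

    true_total: int
    true_per_channel: list[int]
    trajectories: list[list[tuple[int, float, float]]]  # (frame, row, col)
    applied_skew: float
    wall_rows: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "true_total": self.true_total,
                    "true_per_channel": self.true_per_channel,
                    "trajectories": self.trajectories,
                    "applied_skew": self.applied_skew,
                    "wall_rows": self.wall_rows,
                },
                indent=1,
            )
        )


def _stamp_disk(
    img: np.ndarray, row: float, col: float, radius: float, intensity: float
) -> None:
    """Anti-aliased disk: per-pixel coverage = clip(r + 0.5 − dist, 0, 1)."""
    h, w = img.shape
    r0 = max(0, int(np.floor(row - radius - 1)))
    r1 = min(h, int(np.ceil(row + radius + 2)))
    c0 = max(0, int(np.floor(col - radius - 1)))
    c1 = min(w, int(np.ceil(col + radius + 2)))
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dist = np.hypot(rr - row, cc - col)
    cov = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    patch = img[r0:r1, c0:c1]
    img[r0:r1, c0:c1] = patch + cov * (intensity - patch)


def _render_background(cfg: VideoFixtureConfig) -> np.ndarray:
    img = np.full(
        (cfg.frame_height, cfg.frame_width),
        float(cfg.background_intensity),
    )
    for top in cfg.wall_top_rows():
        img[top : top + cfg.wall_thickness, :] = cfg.wall_intensity
    return img


def _schedule(cfg: VideoFixtureConfig, rng: np.random.Generator):
    """Assign each particle a channel, a row slot, and an entry frame such
    that no two particles share a row (within row_separation) while both
    are visible."""
    walls = cfg.wall_top_rows()
    pad = int(np.ceil(cfg.particle_radius)) + 2
    slot_rows: list[tuple[int, float]] = []  # (channel_id, row)
    for ch in range(cfg.n_channels):
        lo = walls[ch] + cfg.wall_thickness + pad
        hi = walls[ch + 1] - pad
        for r in range(lo, hi + 1, cfg.row_separation):
            slot_rows.append((ch + 1, float(r)))
    if cfg.channel_weights is None:
        weights = np.ones(cfg.n_channels)
    else:
        weights = np.asarray(cfg.channel_weights, dtype=float)
    weights = weights / weights.sum()
    channels = rng.choice(cfg.n_channels, size=cfg.n_particles, p=weights) + 1
    transit = int(
        np.ceil((cfg.frame_width + 2 * cfg.particle_radius + 4) / cfg.advection)
    )
    slot_free = {i: 1 for i in range(len(slot_rows))}
    # neighbouring row slots within a channel are closer than a particle
    # diameter; stagger entries by >= 2 frames so co-present disks in the
    # same channel never share a column and merge into one blob
    chan_last_entry = {c: -10 for c in range(1, cfg.n_channels + 1)}
    schedule = []  # (channel, row, entry_frame)
    for ch in channels:
        ch = int(ch)
        cand = [i for i, (c, _) in enumerate(slot_rows) if c == ch]
        i = min(cand, key=lambda j: (slot_free[j], j))
        entry = max(slot_free[i], chan_last_entry[ch] + 2) + int(rng.integers(0, 4))
        schedule.append((ch, slot_rows[i][1], entry))
        chan_last_entry[ch] = entry
        slot_free[i] = entry + transit + cfg.entry_gap
    return schedule, transit


def generate_dld_video(
    config: VideoFixtureConfig,
) -> tuple[FrameSequence, GroundTruth]:
    """Render a seeded synthetic outlet video with its ground truth.

    Frame 0 is particle-free unless ``frame0_particles > 0``, in which case
    that many static disks are stamped into frame 0 only, to exercise
    background patching.  Noise is Gaussian, clipped to [0, 255]; skew is
    applied last (rotation about the center, background-filled).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    bg = _render_background(cfg)
    schedule, transit = _schedule(cfg, rng)
    per_channel = [0] * cfg.n_channels
    for ch, _, _ in schedule:
        per_channel[ch - 1] += 1

    last_exit = max((e + transit for _, _, e in schedule), default=0)
    n_frames = cfg.n_frames if cfg.n_frames is not None else last_exit + 2

    start_col = -cfg.particle_radius - 1.0
    trajectories: list[list[tuple[int, float, float]]] = [[] for _ in schedule]
    frames: list[GrayFrame] = []
    for f in range(n_frames):
        img = bg.copy()
        if f == 0 and cfg.frame0_particles > 0:
            walls = cfg.wall_top_rows()
            pad = cfg.particle_radius + cfg.wall_thickness + 2
            for _ in range(cfg.frame0_particles):
                ch = int(rng.integers(0, cfg.n_channels))
                row = rng.uniform(walls[ch] + pad, walls[ch + 1] - pad + cfg.wall_thickness)
                col = rng.uniform(cfg.particle_radius + 2,
                                  cfg.frame_width - cfg.particle_radius - 2)
                _stamp_disk(img, row, col, cfg.particle_radius,
                            cfg.particle_intensity)
        if f > 0:
            for p, (ch, row, entry) in enumerate(schedule):
                if f < entry:
                    continue
                col = start_col + cfg.advection * (f - entry)
                if col - cfg.particle_radius > cfg.frame_width:
                    continue
                _stamp_disk(img, row, col, cfg.particle_radius,
                            cfg.particle_intensity)
                if 0 <= col < cfg.frame_width:
                    trajectories[p].append((f, row, float(col)))
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, img.shape)
        if cfg.skew_angle != 0.0:
            img = rotate(
                np.clip(img, 0, 255),
                cfg.skew_angle,
                resize=False,
                preserve_range=True,
                order=1,
                cval=cfg.background_intensity,
            )
        frames.append(
            GrayFrame(np.clip(img.round(), 0, 255).astype(np.uint8), index=f)
        )

    truth = GroundTruth(
        true_total=cfg.n_particles,
        true_per_channel=per_channel,
        trajectories=trajectories,
        applied_skew=cfg.skew_angle,
        wall_rows=cfg.wall_center_rows(),
    )
    return FrameSequence(frames), truth


def make_templates(cfg: VideoFixtureConfig, band: int = 8) -> TemplatePair:
    """Template pair for the fixture: horizontal bands straddling the
    outermost walls of the noise-free, un-skewed background.  The bands
    are cropped well inside the frame so they still fit after a skewed
    video has been de-skewed and interior-cropped."""
    bgimg = np.clip(_render_background(cfg).round(), 0, 255).astype(np.uint8)
    walls = cfg.wall_top_rows()
    c0, c1 = 6, max(40, cfg.frame_width - 80)
    t0 = max(0, walls[0] - band)
    t1 = min(cfg.frame_height, walls[0] + cfg.wall_thickness + band)
    b0 = max(0, walls[-1] - band)
    b1 = min(cfg.frame_height, walls[-1] + cfg.wall_thickness + band)
    return TemplatePair(
        GrayFrame(bgimg[t0:t1, c0:c1]),
        GrayFrame(bgimg[b0:b1, c0:c1]),
    )


# Per-mode outlet support bands (1-based outlet ids, top→bottom).  Large
# particles are displaced laterally toward the top wall (bumped), small
# ones follow the streamlines to the bottom outlets (zigzag).
MODE_SUPPORTS = {
    "bumped": (1, 4),
    "mixed": (5, 8),
    "zigzag": (9, 12),
}
_MODE_SIZE = {"zigzag": 10.0, "mixed": 15.0, "bumped": 20.0}


def generate_mode_dataset(
    n_records: int = 66,
    class_balance: dict[str, float] | str = "balanced",
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Seeded labeled dataset of (flow rate, size, 12-outlet distribution).

    Flow rates are uniform on [0.5, 4.0] mL/min; sizes follow the mode
    (10 µm zigzag, 15 µm mixed, 20 µm bumped); distributions are Dirichlet
    draws confined to disjoint 4-outlet support bands per mode, so at
    ``noise_sd=0`` the classes are separable by construction.  ``noise_sd``
    adds Gaussian perturbation to the fractions (clipped, renormalized),
    bleeding mass across bands.
    """
    from .mode_ml import ModeDataset, RunRecord

    if n_records < 15:
        raise ValueError("n_records must be >= 15 (5 per class for 5-fold CV)")
    modes = list(MODE_SUPPORTS)
    if class_balance == "balanced":
        frac = {m: 1 / 3 for m in modes}
    elif isinstance(class_balance, dict):
        if set(class_balance) != set(modes) or min(class_balance.values()) <= 0:
            raise ValueError(f"class_balance must weight all of {modes}")
        tot = sum(class_balance.values())
        frac = {m: v / tot for m, v in class_balance.items()}
    else:
        raise ValueError(f"unknown class_balance {class_balance!r}")
    counts = {m: int(round(frac[m] * n_records)) for m in modes}
    # fix rounding drift deterministically
    drift = n_records - sum(counts.values())
    for m in modes[: abs(drift)]:
        counts[m] += 1 if drift > 0 else -1

    rng = np.random.default_rng(seed)
    records = []
    for m in modes:
        lo, hi = MODE_SUPPORTS[m]
        for _ in range(counts[m]):
            dist = np.zeros(12)
            dist[lo - 1 : hi] = rng.dirichlet(np.full(hi - lo + 1, 2.0))
            if noise_sd > 0:
                dist = np.clip(dist + rng.normal(0.0, noise_sd, 12), 0.0, None)
                s = dist.sum()
                dist = dist / s if s > 0 else np.full(12, 1 / 12)
            records.append(
                RunRecord(
                    flow_rate=float(rng.uniform(0.5, 4.0)),
                    particle_size=_MODE_SIZE[m],
                    distribution=tuple(float(x) for x in dist),
                    mode=m,
                )
            )
    order = rng.permutation(len(records))
    return ModeDataset([records[i] for i in order])
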