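"""Shared fixtures: small ground-truthed videos and a separable dataset.

Everything is generated programmatically and seeded; expensive artifacts
are session-scoped so the pipeline runs once per suite.
"""

from __future__ import annotations

import pytest

from dldflow.detection import BlobParams
from dldflow.pipeline import PipelineSettings, analyze_video
from dldflow.synthetic import (
    VideoFixtureConfig,
    generate_dld_video,
    generate_mode_dataset,
    make_templates,
)


def pipeline_settings() -> PipelineSettings:
    return PipelineSettings(blob=BlobParams.for_particle(12.0))


@pytest.fixture(scope="session")
def small_video():
    """Noise-free 20-particle fixture with templates and ground truth."""
    cfg = VideoFixtureConfig(n_particles=20, seed=1)
    seq, truth = generate_dld_video(cfg)
    return cfg, seq, truth, make_templates(cfg)


@pytest.fixture(scope="session")
def analyzed_small(small_video):
    cfg, seq, truth, tpl = small_video
    summary, state = analyze_video(seq, tpl, pipeline_settings())
    return summary, state, truth


@pytest.fixture(scope="session")
def noisy_video():
    """25 particles with sensor noise, for threshold-robustness checks."""
    cfg = VideoFixtureConfig(n_particles=25, seed=11, noise_sd=5.0)
    seq, truth = generate_dld_video(cfg)
    return cfg, seq, truth, make_templates(cfg)


@pytest.fixture(scope="session")
def separable_dataset():
    """66-record noise-free mode dataset; classes separable by design."""
    return generate_mode_dataset(66, "balanced", 0.0, seed=7)
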