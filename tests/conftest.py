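"""Shared fixtures: small synthetic cohorts and a quickly trained pipeline."""

from __future__ import annotations

import numpy as np
import pytest

from gastrograph.classifier import GcnTrainConfig
from gastrograph.pipeline import PipelineConfig, train_pipeline
from gastrograph.segmentation import SegTrainConfig
from gastrograph.synthetic import generate_cohort


def small_counts(n: int) -> dict:
    return {"C0": {"NED": n, "LGD": n, "HGD": n, "IIN": n}}


@pytest.fixture(scope="session")
def tiny_cohort():
    """12 slides, 256 x 256, one center — enough tissue for 64-px patches."""
    return generate_cohort(small_counts(3), seed=11, width=256, height=256)


@pytest.fixture(scope="session")
def tiny_config() -> PipelineConfig:
    return PipelineConfig(
        patch_size=64,
        seg=SegTrainConfig(epochs=3, batch_size=8, seed=5),
        max_seg_patches=48,
        gcn=GcnTrainConfig(epochs=30, seed=5),
        seed=5,
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_cohort, tiny_config):
    """A small but genuinely trained two-step model shared across tests."""
    return train_pipeline(tiny_cohort, tiny_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
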