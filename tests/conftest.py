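"""Shared fixtures: small phantoms and one session-scoped trained model.

The trained model fixture runs the full desk-scale training recipe (20
synthetic subjects on a 64-voxel grid, reduced 52-voxel patches) once per
session; both the segmentation-accuracy and the reproducibility tests reuse
it.
"""

from __future__ import annotations

import numpy as np
import pytest

from neuroquant.network import ModelConfig
from neuroquant.phantom import PhantomSpec, make_phantom
from neuroquant.training import SubjectData, TrainConfig, train_model

from helpers import normalized_phantom


@pytest.fixture(scope="session")
def small_phantom():
    return make_phantom(PhantomSpec.small(64, seed=11))


@pytest.fixture(scope="session")
def default_phantom():
    return make_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def training_subjects():
    subjects = []
    for i in range(20):
        img, tissue, structural = normalized_phantom(PhantomSpec.small(64, seed=100 + i))
        subjects.append(
            SubjectData(f"s{i:02d}", img, {"tissue": tissue, "structural": structural})
        )
    return subjects


@pytest.fixture(scope="session")
def small_model_config():
    return ModelConfig(patch_side=52, base_filters=8)


@pytest.fixture(scope="session")
def trained_small_model(training_subjects, small_model_config):
    """Model trained with the standard desk-scale recipe (shared across tests)."""
    train_cfg = TrainConfig(max_epochs=20, patches_per_volume=4, patience=10, seed=0)
    net, log = train_model(training_subjects, small_model_config, train_cfg)
    return net, log
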