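"""Shared fixtures: synthetic training data and trained models.

Everything is generated at test time from seeded generators; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from vertascan import synthetic
from vertascan.asm import ProfileModel, build_profile_models
from vertascan.localize import CurvatureModel, build_curvature_model
from vertascan.shapemodel import ShapeModel, build_pca_model, procrustes_align_set


@pytest.fixture(scope="session")
def training_data() -> tuple[list[np.ndarray], list[np.ndarray]]:
    return synthetic.vertebra_training_data(n_images=8, seed=5)


@pytest.fixture(scope="session")
def shape_model(training_data) -> ShapeModel:
    _, shapes = training_data
    aligned, _ = procrustes_align_set(shapes)
    return build_pca_model(aligned)


@pytest.fixture(scope="session")
def profile_model(training_data) -> ProfileModel:
    imgs, shapes = training_data
    return build_profile_models(imgs, shapes, k=6)


@pytest.fixture(scope="session")
def curvature_model() -> CurvatureModel:
    return build_curvature_model(synthetic.curvature_training_samples(30, seed=11))


@pytest.fixture(scope="session")
def default_fixture():
    """One default-noise rendered radiograph with ground truth."""
    return synthetic.render_radiograph(synthetic.SyntheticSpec(seed=3))


@pytest.fixture(scope="session")
def clean_fixture():
    """Noise-free rendered radiograph with ground truth."""
    return synthetic.render_radiograph(synthetic.SyntheticSpec(seed=3, noise_sd=0.0))
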