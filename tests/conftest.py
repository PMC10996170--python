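"""Shared fixtures: small simulation configs, analytic contours, and the
session-scoped default experiment reused by the end-to-end tests."""

import numpy as np
import pytest

from pfmus import features, pipeline
from pfmus.synth_us import SimulationConfig


@pytest.fixture
def noiseless_config():
    """Jitter- and speckle-free simulation on a 100×100 frame."""
    return SimulationConfig(
        frame_width=100, frame_height=100,
        semi_axis_x=20, semi_axis_y=10,
        jitter_px=0.0, speckle_var=0.0,
        n_vertices=360, seed=7,
    )


@pytest.fixture
def default_config():
    return SimulationConfig(seed=11)


def make_ellipse(a=20.0, b=10.0, cx=50.0, cy=50.0, n=360):
    """Analytic ellipse contour as an (n, 2) array of (x, y)."""
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + a * np.cos(theta), cy + b * np.sin(theta)])


def random_star_polygon(rng, n_vertices, r_min=5.0, r_max=40.0, center=(50.0, 50.0)):
    """Random simple polygon: star-shaped around its centre by construction."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(r_min, r_max, n_vertices)
    return np.column_stack([
        center[0] + radii * np.cos(angles),
        center[1] + radii * np.sin(angles),
    ])


@pytest.fixture(scope="session")
def tiny_experiment_config():
    """Desk-scale 4-class experiment small enough for fast e2e tests."""
    return pipeline.ExperimentConfig(
        simulation=SimulationConfig(
            frame_width=96, frame_height=96,
            n_contractions=2, contraction_s=2.0, rest_s=1.5,
            semi_axis_x=22, semi_axis_y=14,
        ),
        n_recordings=16,
        recordings_per_participant=2,
        k_folds=3,
        seed=3,
    )


@pytest.fixture(scope="session")
def default_feature_table():
    """Feature table of the full default experiment (240 clips); built once."""
    config = pipeline.ExperimentConfig(seed=1)
    return config, pipeline.build_dataset(config, None)
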