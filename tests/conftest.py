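"""Shared fixtures: small synthetic scenes and trained classifiers.

Session scope keeps the random-forest fits (the slow part) to a handful per
run.
"""

from __future__ import annotations

import numpy as np
import pytest

from lulctrends.classifier import RFConfig
from lulctrends.pipeline import run_pipeline
from lulctrends.scene import (
    CoverTrendSpec,
    default_phenology,
    generate_landscape,
    generate_trajectories,
    simulate_composites,
    simulate_reference_samples,
)

SMALL_RF = RFConfig(n_trees=101)


@pytest.fixture(scope="session")
def partition():
    # seed chosen so every municipality is large enough (>=120 px) to sustain
    # the prescribed +/-1 px/yr trends without clipping
    return generate_landscape(40, 40, 8, n_biomes=2, n_ecoregions=3, seed=9)


@pytest.fixture(scope="session")
def trend_spec():
    return CoverTrendSpec(
        proportions={"woody": 0.4, "mixed_woody": 0.2, "herb": 0.2, "ag": 0.2},
        slopes_px_per_year={"woody": 1.0, "mixed_woody": -1.0},
    )


@pytest.fixture(scope="session")
def truth(partition, trend_spec):
    return generate_trajectories(partition, trend_spec, years=10, seed=1)


@pytest.fixture(scope="session")
def clean_cube(truth):
    """Noiseless, cloud-free composites: the oracle-friendly limit."""
    return simulate_composites(truth, default_phenology(noise_scale=0.0, cloud_prob=0.0), seed=1)


@pytest.fixture(scope="session")
def clean_records(truth, partition):
    return simulate_reference_samples(
        truth, partition, 120, min_spacing_m=400.0,
        interpreter_noise=0.0, disagreement_rate=0.0, seed=1)


@pytest.fixture(scope="session")
def clean_result(partition, clean_cube, clean_records):
    """Full pipeline on the noiseless scene with a small forest."""
    return run_pipeline(partition, clean_cube, clean_records, config=SMALL_RF, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
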