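"""Shared fixtures: a small end-to-end pipeline reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from statefate.scenarios import (ModelParams, build_pipeline, scenario_normal)


@pytest.fixture(scope="session")
def pipeline_small():
    """A full fitted pipeline on a reduced problem size (fast, shared)."""
    params = ModelParams(grid_shape=(60, 60), points_per_unit=60)
    return build_pipeline(seed=0, n_cells=800, n_genes=120, params=params)


@pytest.fixture(scope="session")
def normal_small(pipeline_small):
    """The calibrated normal-hematopoiesis run on the small pipeline."""
    return scenario_normal(pipeline_small, T=100.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
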