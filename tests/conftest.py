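"""Shared fixtures: small synthetic templates/datasets for unit tests and a
session-scoped study-scale run shared by the acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from talogm.align import gpa
from talogm.simulate import (
    SimulationParams,
    allometric_vectors_with_angles,
    make_template,
    simulate_dataset,
    study_like_preset,
)


@pytest.fixture(scope="session")
def small_template():
    """36-point template: 6 fixed, two 5-point curves, 20 surface points."""
    return make_template(6, [5, 5], 20, seed=1)


@pytest.fixture(scope="session")
def small_dataset(small_template):
    """Two-population, two-sex dataset on the small template."""
    template, base = small_template
    vecs = allometric_vectors_with_angles(
        base, ["A", "B"], {("A", "B"): 45.0}, seed=2
    )
    params = SimulationParams(
        template=template,
        base_mean_shape=base,
        groups=[("A", "F", 6), ("A", "M", 6), ("B", "F", 6), ("B", "M", 6)],
        mu_lncs={"A": 5.7, "B": 5.72},
        sigma_lncs=0.05,
        lncs_dimorphism_d=2.0,
        allometric_vectors=vecs,
        slopes={"A": 0.03, "B": 0.03},
        shape_noise_sd=0.003,
        measurement_noise_sd=0.02,
        seed=3,
    )
    dataset, truth = simulate_dataset(params)
    return dataset, truth, params


@pytest.fixture(scope="session")
def study_preset_run():
    """Study-scale preset dataset aligned with bending-energy sliding;
    shared across acceptance tests (the expensive fixture)."""
    params = study_like_preset(seed=11)
    dataset, truth = simulate_dataset(params)
    aligned = gpa(dataset, sliding="bending_energy")
    return params, dataset, truth, aligned


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
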