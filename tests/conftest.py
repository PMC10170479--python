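"""Shared fixtures: everything is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from mucochip import chip_fluidics as cf
from mucochip import synthetic_data as synth


@pytest.fixture(scope="session")
def chip_solution():
    """Default chip geometry solved once (flow + oxygen) for the session."""
    geom = cf.ChipGeometry()
    params = cf.TransportParams()
    sol = cf.solve_flow(geom, params, nx=364, nz=24)
    cf.solve_oxygen(sol)
    return sol


@pytest.fixture(scope="session")
def brownian_1cp_trajectories():
    """500 Brownian tracks at 1 cP (default 20 nm localization noise)."""
    truth = synth.RheoGroundTruth(
        viscosity_pa_s=1e-3, n_particles=500, n_frames=100, seed=11,
    )
    return truth, synth.simulate_brownian_trajectories(truth)


@pytest.fixture(scope="session")
def maxwell_trajectories():
    """500 Maxwell-medium tracks at eta = 20 cP, G = 1 Pa."""
    truth = synth.RheoGroundTruth(
        viscosity_pa_s=0.02, elastic_modulus_pa=1.0,
        n_particles=500, n_frames=100, seed=12,
    )
    return truth, synth.simulate_viscoelastic_trajectories(truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
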