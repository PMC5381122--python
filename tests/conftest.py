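"""Shared fixtures: field solves are expensive, so they are session-scoped."""

import math

import numpy as np
import pytest

from cytostretch import (
    DEFAULT_MEDIUM,
    CellDielectric,
    ForceEstimator,
    NetworkParams,
    build_network,
    default_chip,
    make_load,
    relax_network,
    solve_potential,
)
from cytostretch.synthetic_data import make_fixture_chip

OMEGA_1MHZ = 2.0 * math.pi * 1e6


@pytest.fixture(scope="session")
def parallel_plate_solution():
    chip = make_fixture_chip("parallel_plate")
    return solve_potential(chip, DEFAULT_MEDIUM, OMEGA_1MHZ)


@pytest.fixture(scope="session")
def default_estimator():
    """Three-way force estimator on the default tip-to-tip chip (2 solves)."""
    return ForceEstimator(default_chip(), CellDielectric(), DEFAULT_MEDIUM)


@pytest.fixture(scope="session")
def small_params():
    """Small, fast network for mechanics tests (seconds per relax)."""
    return NetworkParams(N_AF=150)


@pytest.fixture(scope="session")
def small_relaxed(small_params):
    net = build_network(small_params, seed=3)
    res = relax_network(net, make_load(net, 0.0))
    assert res.converged
    return res.network
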