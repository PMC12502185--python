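"""Shared fixtures: a scaled-down simulated scenario used across tests.

The small scenario (200-kb sex scaffold with a 50-kb SDR, two 100-kb
autosomes) keeps end-to-end runs fast while preserving all the planted
structure of the default reference simulation.
"""
from __future__ import annotations

import numpy as np
import pytest

from uvscan.pipeline import run_detection
from uvscan.simulate import SimParams, simulate_expression, simulate_genome_pair


def small_params(**overrides) -> SimParams:
    base = dict(
        seed=7,
        n_autosomes=2,
        autosome_len=100_000,
        sex_scaffold_len=200_000,
        sdr_interval=(80_000, 130_000),
        # feature counts scale with the quarter-size SDR so that feature
        # density matches the default scenario
        n_gametologs=3,
        n_sex_limited_male=3,
        n_sex_limited_female=3,
        paralog_fraction=1.0,
        genes_per_autosome=10,
        expr_n_biased=12,
    )
    base.update(overrides)
    return SimParams(**base)


@pytest.fixture(scope="session")
def small_sim():
    return simulate_genome_pair(small_params())


@pytest.fixture(scope="session")
def small_detection(small_sim):
    return run_detection(sim=small_sim)


@pytest.fixture(scope="session")
def small_expression(small_sim):
    expr, bias = simulate_expression(small_sim.truth, small_sim.params)
    return expr, bias


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
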