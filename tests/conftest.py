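"""Shared fixtures.

Heavy population fixtures are session-scoped so the stochastic acceptance
checks and the unit tests reuse one generation run.  All randomness is
seeded; simulations use the shipped model definitions.
"""

from __future__ import annotations

import numpy as np
import pytest

from neurodegen import ConductanceVector, build_model
from neurodegen.config import default_config
from neurodegen.populations import (
    generate_dic_population,
    ratio_only_subset,
    sample_random_population,
    scaling_only_subset,
)

RANDOM_POP_N = 100  # random-sampling population size used for PCA checks
DIC_POP_N = 120  # DIC-constrained population size for neuromodulation checks


@pytest.fixture(scope="session")
def stg():
    return build_model("STG")


@pytest.fixture(scope="session")
def da():
    return build_model("DA")


@pytest.fixture(scope="session")
def stg_config():
    return default_config("STG")


@pytest.fixture(scope="session")
def da_config():
    return default_config("DA")


@pytest.fixture(scope="session")
def stg_burster(stg) -> ConductanceVector:
    """A reference STG burster (classic parameter set)."""
    return ConductanceVector.from_dict(
        stg,
        dict(Na=400.0, Kd=100.0, CaT=2.5, A=50.0, CaS=8.0, KCa=20.0, H=0.02,
             leak=0.03),
    )


@pytest.fixture(scope="session")
def da_spiker(da) -> ConductanceVector:
    """A reference DA slow pacemaker."""
    return ConductanceVector.from_dict(
        da,
        dict(Na=30.0, Kd=8.0, CaL=0.05, CaN=0.05, ERG=0.1, leak=0.01),
    )


@pytest.fixture(scope="session")
def stg_random_pop(stg, stg_config):
    """STG random-sampling population (bursting acceptance), seeded."""
    return sample_random_population(
        stg, stg_config.sampling_ranges, stg_config.acceptance, RANDOM_POP_N, seed=42
    )


@pytest.fixture(scope="session")
def da_random_pop(da, da_config):
    """DA random-sampling population (slow-tonic acceptance), seeded."""
    return sample_random_population(
        da, da_config.sampling_ranges, da_config.acceptance, RANDOM_POP_N, seed=42
    )


@pytest.fixture(scope="session")
def stg_dic_pop(stg, stg_config):
    return generate_dic_population(
        stg, stg_config.dic_targets, DIC_POP_N, 3, stg_config.generator_ranges,
        stg_config.solve_channels,
    )


@pytest.fixture(scope="session")
def da_dic_pop(da, da_config):
    return generate_dic_population(
        da, da_config.dic_targets, DIC_POP_N, 3, da_config.generator_ranges,
        da_config.solve_channels,
    )


@pytest.fixture(scope="session")
def stg_scaling_subset(stg, stg_config):
    return scaling_only_subset(
        stg, stg_config.dic_targets, 60, 1, stg_config.generator_ranges,
        stg_config.solve_channels,
    )


@pytest.fixture(scope="session")
def stg_ratio_subset(stg, stg_config):
    return ratio_only_subset(
        stg, stg_config.dic_targets, 60, 2, stg_config.generator_ranges,
        stg_config.solve_channels,
    )


@pytest.fixture(scope="session")
def da_scaling_subset(da, da_config):
    return scaling_only_subset(
        da, da_config.dic_targets, 60, 1, da_config.generator_ranges,
        da_config.solve_channels,
    )


@pytest.fixture(scope="session")
def da_ratio_subset(da, da_config):
    return ratio_only_subset(
        da, da_config.dic_targets, 60, 2, da_config.generator_ranges,
        da_config.solve_channels,
    )
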