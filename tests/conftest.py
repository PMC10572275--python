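"""Shared fixtures: all data are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methpair.datatypes import BetaMatrix, ComparisonDesign
from methpair.experiments import concordance_experiment, paired_dataset
from methpair.simulate import (
    RhoDistribution,
    SimulationConfig,
    simulate_paired_betas,
    simulate_sample_sheet,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A 20-family, 500-probe cohort covering all three designs."""
    return SimulationConfig(
        n_families=20,
        n_probes=500,
        design_pairs={"longitudinal": 60, "tissue": 40, "platform": 50},
        seed=1234,
    )


@pytest.fixture(scope="session")
def small_sheet(small_config) -> pd.DataFrame:
    return simulate_sample_sheet(small_config)


@pytest.fixture(scope="session")
def small_paired(small_config, small_sheet):
    """(BetaMatrix A, BetaMatrix B, true_rho) for the longitudinal design."""
    return simulate_paired_betas(small_config, small_sheet, "longitudinal")


@pytest.fixture(scope="session")
def singleton_paired_results():
    """2000-probe fixture with every individual their own family.

    Returns (za, zb, design, results-ready inputs) used by the
    GEE-reduces-to-Pearson checks.
    """
    cfg = SimulationConfig(
        n_families=200,
        family_template=("sibling",),
        n_probes=2000,
        design_pairs={"longitudinal": 200},
        seed=77,
    )
    A, B, za, zb, cd, true_rho, sheet = paired_dataset(cfg, scale="beta")
    return za, zb, cd


@pytest.fixture(scope="session")
def concordance_results() -> pd.DataFrame:
    """Heterogeneous-rho twin-family run: 200 pairs, 2000 probes, beta scale."""
    return concordance_experiment(n_individuals=200, n_probes=2000, seed=101)
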