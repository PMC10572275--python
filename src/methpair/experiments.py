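"""Reusable validation experiments on synthetic twin-family data.

These functions bundle the standard simulation experiments used to validate
the estimator chain: parameter recovery over a grid of true pairing
correlations, type-I-error calibration under the null, GEE–Pearson
concordance, and QC filter accounting.  Tests and the reproduction script
both call them, so the experimental conditions live in one place.

Parameter identification note: the generator defines the true pairing
correlation rho on the latent z (logit) scale; mapping to bounded beta values
attenuates beta-scale product-moment correlations slightly (the bounded-scale
analog of regression dilution).  Recovery and calibration experiments
therefore analyze logit-transformed values — where rho is the true
correlation — while the analysis pipeline itself operates on beta values as
delivered by the arrays.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import logit

from .correlate import estimate_cpg_correlation
from .datatypes import BetaMatrix, ComparisonDesign
from .preprocess import ResidualMatrix, residualize_technical, standardize_probes
from .simulate import (
    RhoDistribution,
    SimulationConfig,
    simulate_paired_betas,
    simulate_sample_sheet,
)

__all__ = [
    "standardized_chain",
    "paired_dataset",
    "recovery_experiment",
    "null_calibration_experiment",
    "concordance_experiment",
]


def standardized_chain(
    m: BetaMatrix, sheet: pd.DataFrame, scale: str = "beta"
) -> ResidualMatrix:
    """Residualize plate/row and z-score per probe, on the beta or logit scale."""
    if scale == "logit":
        vals = logit(np.clip(m.beta.to_numpy(), 1e-12, 1.0 - 1e-12))
        source = ResidualMatrix(
            values=pd.DataFrame(vals, index=m.beta.index, columns=m.beta.columns)
        )
        return standardize_probes(residualize_technical(source, sheet))
    return standardize_probes(residualize_technical(m, sheet))


def paired_dataset(
    config: SimulationConfig, design: str = "longitudinal", scale: str = "beta"
):
    """Simulate one design and run the preprocessing chain on both matrices."""
    sheet = simulate_sample_sheet(config)
    A, B, true_rho = simulate_paired_betas(config, sheet, design)
    za = standardized_chain(A, sheet, scale=scale)
    zb = standardized_chain(B, sheet, scale=scale)
    cd = ComparisonDesign.from_sheet(sheet, design)
    return A, B, za, zb, cd, true_rho, sheet


def _point_mass_config(
    rho: float,
    n_individuals: int,
    n_probes: int,
    seed: int,
    family_template: tuple[str, ...] = ("sibling",),
    family_share_f: float = 0.0,
) -> SimulationConfig:
    n_families = -(-n_individuals // len(family_template))  # ceil
    return SimulationConfig(
        n_families=n_families,
        family_template=family_template,
        n_probes=n_probes,
        rho_distribution=RhoDistribution(
            point_masses={rho: 1.0}, uniform_weight=0.0
        ),
        family_share_f=family_share_f,
        design_pairs={"longitudinal": n_individuals},
        seed=seed,
    )


def recovery_experiment(
    rho: float,
    n_individuals: int = 200,
    n_probes: int = 2000,
    seed: int = 0,
    scale: str = "logit",
) -> pd.DataFrame:
    """Estimate per-probe correlations when every probe has true rho.

    Independent individuals (families of one) isolate estimator bias; the
    returned frame carries the estimates, and ``mean bias`` is simply
    ``results["gee_estimate"].mean() - rho``.
    """
    cfg = _point_mass_config(rho, n_individuals, n_probes, seed)
    _, _, za, zb, cd, _, _ = paired_dataset(cfg, scale=scale)
    return estimate_cpg_correlation(za, zb, cd)


def null_calibration_experiment(
    n_individuals: int = 200,
    n_probes: int = 5000,
    seed: int = 0,
    family_share_f: float = 0.5,
    scale: str = "logit",
) -> pd.DataFrame:
    """Per-probe results under rho = 0 with family clustering (families of 4).

    The fraction of probes with robust-Wald p < 0.05 estimates the type-I
    error of the clustered test at nominal 0.05.
    """
    cfg = _point_mass_config(
        0.0,
        n_individuals,
        n_probes,
        seed,
        family_template=("parent", "parent", "MZ", "MZ"),
        family_share_f=family_share_f,
    )
    _, _, za, zb, cd, _, _ = paired_dataset(cfg, scale=scale)
    return estimate_cpg_correlation(za, zb, cd)


def concordance_experiment(
    n_individuals: int = 200,
    n_probes: int = 2000,
    seed: int = 0,
    scale: str = "beta",
) -> pd.DataFrame:
    """Heterogeneous-rho dataset for the GEE-vs-Pearson agreement check.

    Uses the default rho mixture and twin-family clustering, on the beta
    scale — the same conditions the full pipeline analyzes.
    """
    cfg = SimulationConfig(
        n_families=-(-n_individuals // 4),
        n_probes=n_probes,
        design_pairs={"longitudinal": n_individuals},
        seed=seed,
    )
    _, _, za, zb, cd, true_rho, _ = paired_dataset(cfg, scale=scale)
    res = estimate_cpg_correlation(za, zb, cd)
    res["true_rho"] = true_rho.reindex(res.index)
    return res
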