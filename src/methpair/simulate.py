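"""Synthetic twin-family methylation data with known pairing correlation.

Emulates the statistical structure of a paired methylation-array study on a
twin-family cohort: each included individual contributes two measurements of
the same CpG panel under one of three designs (two blood draws roughly a
decade apart; blood versus buccal swabs; the same DNA on 450K and EPIC
arrays), with family clustering (MZ/DZ twins, siblings, parents), bimodal
beta-value distributions, plate/row batch effects on the logit scale, and
injectable probe-level QC failures.

Generative model, per probe j and individual i (all on the z scale):

    T_ij = sqrt(f)·F_{fam(i),j} + sqrt(1−f)·I_ij
    y_k  = sqrt(rho_j)·T_ij + sqrt(1−rho_j)·e_k,    k = 1, 2

with F (family factor), I (individual deviation) and e_k independent standard
normals.  By construction corr(y_1, y_2) = rho_j — the target per-CpG pairing
correlation — and the within-family correlation of T is f.  Each y is mapped
to a beta value through a probe-specific logit-normal transform
sigmoid(mu_j + s_j·y), after which plate and row shifts are added on the logit
scale; sigmoid output is clipped to [0, 1] so extreme logits may produce exact
boundary values, which downstream code must tolerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datatypes import (
    DESIGNS,
    RELATIONSHIPS,
    BetaMatrix,
    ComparisonDesign,
    DesignError,
    MethpairError,
    validate_sample_sheet,
)

__all__ = [
    "RhoDistribution",
    "BetaMixtureComponent",
    "BetaMixture",
    "SimulationConfig",
    "simulate_sample_sheet",
    "simulate_paired_betas",
    "inject_qc_failures",
]


@dataclass
class RhoDistribution:
    """Per-probe law of the true pairing correlation rho in [0, 1].

    A mixture of point masses and one uniform component over [0, 1].
    Defaults put mass at rho = 0 (unstable CpGs), a uniform middle, and a
    point mass of highly reliable CpGs, yielding a right-skewed law whose
    bulk sits at low-to-moderate correlations, as per-CpG reliability
    studies of these arrays report.
    """

    point_masses: dict[float, float] = field(
        default_factory=lambda: {0.0: 0.35, 0.9: 0.10}
    )
    uniform_weight: float = 0.55

    def __post_init__(self) -> None:
        weights = list(self.point_masses.values()) + [self.uniform_weight]
        if any(w < 0 for w in weights):
            raise MethpairError("rho mixture weights must be non-negative")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise MethpairError("rho mixture weights must sum to 1")
        if any(not 0.0 <= r <= 1.0 for r in self.point_masses):
            raise MethpairError("rho point masses must lie in [0, 1]")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        locs = list(self.point_masses.keys())
        probs = list(self.point_masses.values()) + [self.uniform_weight]
        comp = rng.choice(len(probs), size=n, p=probs)
        rho = np.empty(n)
        for idx, loc in enumerate(locs):
            rho[comp == idx] = loc
        uni = comp == len(locs)
        rho[uni] = rng.uniform(0.0, 1.0, size=int(uni.sum()))
        return rho


@dataclass
class BetaMixtureComponent:
    """One logit-normal component: probe means mu ~ N(mu, mu_sd) on the logit
    scale, per-individual logit spread s drawn around ``sigma``."""

    weight: float
    mu: float
    mu_sd: float
    sigma: float
    sigma_sd: float = 0.10


@dataclass
class BetaMixture:
    """Three-component logit-normal mixture for probe means and scales.

    Components model hypomethylated, intermediate, and hypermethylated CpGs;
    defaults reproduce the characteristic bimodal beta-value density of
    methylation arrays (most probes near 0 or 1, a thinner middle).
    """

    components: tuple[BetaMixtureComponent, ...] = (
        BetaMixtureComponent(weight=0.40, mu=-2.8, mu_sd=0.55, sigma=0.45),
        BetaMixtureComponent(weight=0.15, mu=0.0, mu_sd=0.90, sigma=0.60),
        BetaMixtureComponent(weight=0.45, mu=2.8, mu_sd=0.55, sigma=0.45),
    )

    def __post_init__(self) -> None:
        if abs(sum(c.weight for c in self.components) - 1.0) > 1e-9:
            raise MethpairError("beta mixture weights must sum to 1")

    def sample_probe_params(
        self, n: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Draw per-probe (mu, s) logit-scale location and scale."""
        w = np.array([c.weight for c in self.components])
        comp = rng.choice(len(self.components), size=n, p=w)
        mu = np.empty(n)
        s = np.empty(n)
        for idx, c in enumerate(self.components):
            sel = comp == idx
            k = int(sel.sum())
            mu[sel] = rng.normal(c.mu, c.mu_sd, size=k)
            s[sel] = np.abs(rng.normal(c.sigma, c.sigma_sd, size=k))
        return mu, s


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the study design the analysis assumes: 197 longitudinal
    pairs, 58 cross-tissue pairs and 83 cross-platform pairs drawn from twin
    families of two parents plus an MZ twin pair.  ``n_probes`` defaults to a
    20,000-CpG panel — per-probe estimates do not depend on panel width, so
    the panel is sized for desk-scale runs rather than the full array.
    """

    n_families: int = 50
    family_template: tuple[str, ...] = ("parent", "parent", "MZ", "MZ")
    n_probes: int = 20_000
    rho_distribution: RhoDistribution = field(default_factory=RhoDistribution)
    family_share_f: float = 0.40
    beta_mixture: BetaMixture = field(default_factory=BetaMixture)
    design_pairs: dict[str, int] = field(
        default_factory=lambda: {"longitudinal": 197, "tissue": 58, "platform": 83}
    )
    n_plates: int = 8
    n_rows: int = 6
    plate_effect_sd: float = 0.20
    row_effect_sd: float = 0.10
    detp_fail_rate: float = 0.002
    beadcount_fail_rate: float = 0.002
    zero_intensity_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise MethpairError("n_families must be >= 1")
        if self.n_probes < 1:
            raise MethpairError("n_probes must be >= 1")
        if not 0.0 <= self.family_share_f <= 1.0:
            raise MethpairError("family_share_f must lie in [0, 1]")
        for name in ("detp_fail_rate", "beadcount_fail_rate", "zero_intensity_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise MethpairError(f"{name} must lie in [0, 1]")
        bad = [r for r in self.family_template if r not in RELATIONSHIPS]
        if bad:
            raise MethpairError(
                f"invalid family_template codes {bad}; allowed: {RELATIONSHIPS}"
            )
        unknown = [d for d in self.design_pairs if d not in DESIGNS]
        if unknown:
            raise MethpairError(f"unknown designs in design_pairs: {unknown}")

    @property
    def n_individuals(self) -> int:
        return self.n_families * len(self.family_template)

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


# Per design: distinguishing attribute values for measurement A and B, and
# shared attributes of both samples.
_DESIGN_SAMPLES = {
    "longitudinal": (
        {"timepoint": 1, "tissue": "blood", "platform": "EPIC"},
        {"timepoint": 2, "tissue": "blood", "platform": "EPIC"},
    ),
    "tissue": (
        {"timepoint": 2, "tissue": "blood", "platform": "EPIC"},
        {"timepoint": 2, "tissue": "buccal", "platform": "EPIC"},
    ),
    "platform": (
        {"timepoint": 2, "tissue": "blood", "platform": "450K"},
        {"timepoint": 2, "tissue": "blood", "platform": "EPIC"},
    ),
}


def simulate_sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    """Generate the cohort sample sheet covering all configured designs.

    Families follow ``config.family_template``; twins/siblings form the
    offspring generation (~19 y at first assessment) and parents the older
    one (~45 y).  Per design, the first ``design_pairs[design]`` individuals
    (cycling through families) each contribute exactly two samples carrying
    the design's distinguishing attribute; plates and rows are assigned
    round-robin over the configured label sets.
    """
    rng = config.rng(salt=1)
    individuals = []
    for fam in range(config.n_families):
        fam_id = f"F{fam:04d}"
        for k, rel in enumerate(config.family_template):
            base_age = 45.0 if rel == "parent" else 19.0
            individuals.append(
                {
                    "individual_id": f"{fam_id}I{k}",
                    "family_id": fam_id,
                    "relationship": rel,
                    "age": round(float(base_age + rng.normal(0, 3.0)), 1),
                    "sex": "M" if rng.random() < 0.5 else "F",
                }
            )
    ind_df = pd.DataFrame(individuals)

    max_pairs = max(config.design_pairs.values(), default=0)
    if max_pairs > len(ind_df):
        raise MethpairError(
            f"design needs {max_pairs} individuals but cohort has {len(ind_df)}"
        )

    plates = [f"P{i + 1:02d}" for i in range(config.n_plates)]
    rows = [f"R{i + 1:02d}" for i in range(config.n_rows)]
    records = []
    slot = 0  # global round-robin counter over plate/row slots
    for design in DESIGNS:
        n_pairs = config.design_pairs.get(design, 0)
        if n_pairs == 0:
            continue
        spec_a, spec_b = _DESIGN_SAMPLES[design]
        chosen = ind_df.iloc[:n_pairs]
        for _, ind in chosen.iterrows():
            for tag, spec in (("a", spec_a), ("b", spec_b)):
                records.append(
                    {
                        "sample_id": f"{ind.individual_id}_{design}_{tag}",
                        "individual_id": ind.individual_id,
                        "family_id": ind.family_id,
                        "relationship": ind.relationship,
                        "tissue": spec["tissue"],
                        "platform": spec["platform"],
                        "timepoint": spec["timepoint"],
                        "age": ind.age
                        if spec["timepoint"] == 1
                        else round(ind.age + 10.0, 1),
                        "sex": ind.sex,
                        "plate": plates[slot % len(plates)],
                        "row": rows[slot % len(rows)],
                        "design": design,
                    }
                )
                slot += 1
    sheet = pd.DataFrame(records)
    return validate_sample_sheet(sheet)


def _probe_index(n_probes: int) -> pd.Index:
    return pd.Index([f"cg{j:08d}" for j in range(n_probes)], name="probe_id")


def simulate_paired_betas(
    config: SimulationConfig,
    sheet: pd.DataFrame,
    design: str,
    batch_effects: bool = True,
) -> tuple[BetaMatrix, BetaMatrix, pd.Series]:
    """Simulate the two aligned beta matrices of one comparison design.

    Returns matrices A and B (probes × paired samples, columns ordered by the
    design's pair table) and the per-probe true pairing correlation.
    """
    if design not in DESIGNS:
        raise DesignError(f"unknown design {design!r}")
    cd = ComparisonDesign.from_sheet(sheet, design)
    pairs = cd.pairs
    n_ind = len(pairs)
    J = config.n_probes

    rng = config.rng(salt=2)
    rho = config.rho_distribution.sample(J, rng)
    mu, s = config.beta_mixture.sample_probe_params(J, rng)

    # latent traits: family factor shared within family, per-design draw
    fam_codes, fam_inv = np.unique(pairs["family_id"].to_numpy(), return_inverse=True)
    rng_d = config.rng(salt=10 + DESIGNS.index(design))
    F = rng_d.normal(size=(len(fam_codes), J))
    I = rng_d.normal(size=(n_ind, J))
    f = config.family_share_f
    T = np.sqrt(f) * F[fam_inv] + np.sqrt(1.0 - f) * I

    sq_rho = np.sqrt(rho)[None, :]
    sq_res = np.sqrt(1.0 - rho)[None, :]
    betas = []
    for k, col in enumerate(("sample_a", "sample_b")):
        e = rng_d.normal(size=(n_ind, J))
        y = sq_rho * T + sq_res * e  # marginally standard normal
        logits = mu[None, :] + s[None, :] * y
        if batch_effects:
            logits = logits + _batch_shifts(config, sheet, pairs[col])[:, None]
        b = np.clip(expit(logits), 0.0, 1.0)
        betas.append(
            pd.DataFrame(b.T, index=_probe_index(J), columns=pairs[col].to_numpy())
        )
    true_rho = pd.Series(rho, index=_probe_index(J), name="true_rho")
    return BetaMatrix(beta=betas[0]), BetaMatrix(beta=betas[1]), true_rho


def _batch_shifts(
    config: SimulationConfig, sheet: pd.DataFrame, sample_ids: pd.Series
) -> np.ndarray:
    """Per-sample additive logit shift from its plate and row levels.

    Level effects are drawn once per config seed, so every matrix simulated
    from the same config sees consistent batch structure.
    """
    rng = config.rng(salt=3)
    plates = [f"P{i + 1:02d}" for i in range(config.n_plates)]
    rows = [f"R{i + 1:02d}" for i in range(config.n_rows)]
    plate_eff = dict(
        zip(plates, rng.normal(0.0, config.plate_effect_sd, size=len(plates)))
    )
    row_eff = dict(zip(rows, rng.normal(0.0, config.row_effect_sd, size=len(rows))))
    meta = sheet.set_index("sample_id").loc[sample_ids.to_numpy()]
    return np.array(
        [plate_eff.get(p, 0.0) + row_eff.get(r, 0.0) for p, r in zip(meta["plate"], meta["row"])]
    )


def inject_qc_failures(m: BetaMatrix, config: SimulationConfig) -> BetaMatrix:
    """Attach detection-p / bead-count / zero-intensity layers with failures.

    Independently per entry: with probability ``detp_fail_rate`` the detection
    p-value is resampled above 0.01 (else uniform in [0, 0.01]); with
    probability ``beadcount_fail_rate`` the bead count is set below 3 (else
    3 + Poisson(12)); with probability ``zero_intensity_rate`` the
    zero-intensity flag is set.  All other entries are pass-compatible.
    """
    rng = config.rng(salt=4)
    shape = m.beta.shape
    detp = rng.uniform(0.0, 0.01, size=shape)
    fail = rng.random(size=shape) < config.detp_fail_rate
    detp[fail] = rng.uniform(0.01, 1.0, size=int(fail.sum())) + 1e-9

    beads = 3.0 + rng.poisson(12.0, size=shape).astype(float)
    fail_b = rng.random(size=shape) < config.beadcount_fail_rate
    beads[fail_b] = rng.integers(0, 3, size=int(fail_b.sum())).astype(float)

    zero = rng.random(size=shape) < config.zero_intensity_rate

    idx, cols = m.beta.index, m.beta.columns
    return BetaMatrix(
        beta=m.beta.copy(),
        detection_p=pd.DataFrame(detp, index=idx, columns=cols),
        bead_count=pd.DataFrame(beads, index=idx, columns=cols),
        intensity_zero=pd.DataFrame(zero, index=idx, columns=cols),
    )


def config_to_dict(config: SimulationConfig) -> dict:
    """JSON/YAML-serializable view of a config (for manifests)."""
    d = asdict(config)
    d["rho_distribution"]["point_masses"] = {
        str(k): v for k, v in d["rho_distribution"]["point_masses"].items()
    }
    return d
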