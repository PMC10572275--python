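"""Synthetic twin-family generator: counting, determinism, marginal laws."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from methpair.datatypes import DesignError, MethpairError
from methpair.simulate import (
    BetaMixture,
    RhoDistribution,
    SimulationConfig,
    inject_qc_failures,
    simulate_paired_betas,
    simulate_sample_sheet,
)


def _pairs_config(n_individuals, n_probes, rho=None, f=0.0, seed=0, **kw):
    rho_dist = (
        RhoDistribution(point_masses={rho: 1.0}, uniform_weight=0.0)
        if rho is not None
        else RhoDistribution()
    )
    return SimulationConfig(
        n_families=n_individuals,
        family_template=("sibling",),
        n_probes=n_probes,
        rho_distribution=rho_dist,
        family_share_f=f,
        design_pairs={"longitudinal": n_individuals},
        seed=seed,
        **kw,
    )


class TestSampleSheet:
    def test_one_family_longitudinal_counts(self):
        """1 family of {parent, parent, MZ, MZ}: 4 individuals, 8 samples, 4 pairs."""
        cfg = SimulationConfig(
            n_families=1, n_probes=10, design_pairs={"longitudinal": 4}
        )
        sheet = simulate_sample_sheet(cfg)
        assert sheet["individual_id"].nunique() == 4
        assert len(sheet) == 8
        assert (sheet.groupby("individual_id").size() == 2).all()

    def test_zero_families_rejected(self):
        with pytest.raises(MethpairError):
            SimulationConfig(n_families=0)

    def test_invalid_relationship_code_rejected(self):
        with pytest.raises(MethpairError, match="family_template"):
            SimulationConfig(family_template=("parent", "cousin"))

    def test_default_config_mirrors_study_cohort(self):
        """Defaults give 197 longitudinal, 58 tissue and 83 platform pairs."""
        cfg = SimulationConfig(n_probes=10)
        sheet = simulate_sample_sheet(cfg)
        pairs = sheet.groupby("design")["individual_id"].nunique()
        assert pairs["longitudinal"] == 197
        assert pairs["tissue"] == 58
        assert pairs["platform"] == 83
        # each individual contributes exactly two samples per design
        per = sheet.groupby(["design", "individual_id"]).size()
        assert (per == 2).all()

    def test_design_axes(self, small_sheet):
        longi = small_sheet[small_sheet["design"] == "longitudinal"]
        assert set(longi["timepoint"]) == {1, 2}
        tissue = small_sheet[small_sheet["design"] == "tissue"]
        assert set(tissue["tissue"]) == {"blood", "buccal"}
        plat = small_sheet[small_sheet["design"] == "platform"]
        assert set(plat["platform"]) == {"450K", "EPIC"}

    def test_plates_rows_round_robin(self, small_config, small_sheet):
        counts = small_sheet["plate"].value_counts()
        assert counts.max() - counts.min() <= 1


class TestPairedBetas:
    def test_rho_one_no_noise_identical_matrices(self):
        """rho=1, f=0, no batch effects: the two matrices coincide entry-wise."""
        cfg = _pairs_config(30, 50, rho=1.0)
        sheet = simulate_sample_sheet(cfg)
        A, B, rho = simulate_paired_betas(cfg, sheet, "longitudinal", batch_effects=False)
        assert np.allclose(A.beta.to_numpy(), B.beta.to_numpy())
        assert (rho == 1.0).all()

    def test_absent_design_raises(self):
        cfg = _pairs_config(10, 20)
        sheet = simulate_sample_sheet(cfg)
        with pytest.raises(DesignError):
            simulate_paired_betas(cfg, sheet, "tissue")

    def test_pairing_correlation_recovered(self):
        """rho=0.8, 500 independent individuals: z-scale pair correlation ±0.05."""
        cfg = _pairs_config(500, 200, rho=0.8, seed=3)
        sheet = simulate_sample_sheet(cfg)
        A, B, _ = simulate_paired_betas(cfg, sheet, "longitudinal", batch_effects=False)
        la, lb = logit(A.beta.to_numpy()), logit(B.beta.to_numpy())
        cors = [np.corrcoef(la[j], lb[j])[0, 1] for j in range(200)]
        assert np.mean(cors) == pytest.approx(0.8, abs=0.05)

    def test_family_share_recovered(self):
        """f=0.5, many size-2 families: within-family trait correlation ±0.05.

        At rho=1 the measurement equals the latent trait, so the correlation
        between the two family members' logit values estimates f directly.
        """
        cfg = SimulationConfig(
            n_families=800,
            family_template=("MZ", "MZ"),
            n_probes=100,
            rho_distribution=RhoDistribution(point_masses={1.0: 1.0}, uniform_weight=0.0),
            family_share_f=0.5,
            design_pairs={"longitudinal": 1600},
            seed=5,
        )
        sheet = simulate_sample_sheet(cfg)
        A, _, _ = simulate_paired_betas(cfg, sheet, "longitudinal", batch_effects=False)
        la = logit(A.beta.to_numpy())
        # columns come in family pairs: members 0 and 1 of each family
        fam = (
            sheet[sheet["timepoint"] == 1]
            .set_index("sample_id")
            .loc[A.beta.columns, "family_id"]
            .to_numpy()
        )
        order = np.argsort(fam, kind="mergesort")
        m1, m2 = la[:, order[0::2]], la[:, order[1::2]]
        cors = [np.corrcoef(m1[j], m2[j])[0, 1] for j in range(100)]
        assert np.mean(cors) == pytest.approx(0.5, abs=0.05)

    def test_correlation_recovery_grid(self):
        """Empirical pair correlation tracks rho over {0,.25,.5,.75,1} at n=2000."""
        for rho0 in (0.0, 0.25, 0.5, 0.75, 1.0):
            cfg = _pairs_config(2000, 40, rho=rho0, seed=int(rho0 * 100) + 7)
            sheet = simulate_sample_sheet(cfg)
            A, B, _ = simulate_paired_betas(
                cfg, sheet, "longitudinal", batch_effects=False
            )
            la, lb = logit(A.beta.to_numpy()), logit(B.beta.to_numpy())
            cors = [np.corrcoef(la[j], lb[j])[0, 1] for j in range(40)]
            assert np.mean(cors) == pytest.approx(rho0, abs=0.03)

    def test_marginal_beta_means_match_mixture(self):
        """With batch effects off, probe means match Gauss–Hermite integrals."""
        cfg = _pairs_config(4000, 50, seed=9)
        sheet = simulate_sample_sheet(cfg)
        A, _, _ = simulate_paired_betas(cfg, sheet, "longitudinal", batch_effects=False)
        # recover each probe's (mu, s) from the same seeded draw
        rng = cfg.rng(salt=2)
        cfg.rho_distribution.sample(cfg.n_probes, rng)
        mu, s = cfg.beta_mixture.sample_probe_params(cfg.n_probes, rng)
        nodes, weights = np.polynomial.hermite_e.hermegauss(80)
        w = weights / weights.sum()
        analytic = np.array(
            [(w * expit(mu[j] + s[j] * nodes)).sum() for j in range(50)]
        )
        emp = A.beta.to_numpy().mean(axis=1)
        assert np.max(np.abs(emp - analytic)) < 0.03

    def test_determinism_and_seed_sensitivity(self):
        cfg = _pairs_config(30, 50, seed=21)
        sheet = simulate_sample_sheet(cfg)
        A1, B1, r1 = simulate_paired_betas(cfg, sheet, "longitudinal")
        A2, B2, r2 = simulate_paired_betas(cfg, sheet, "longitudinal")
        assert A1.beta.equals(A2.beta) and B1.beta.equals(B2.beta)
        assert (r1 == r2).all()
        cfg2 = _pairs_config(30, 50, seed=22)
        A3, _, _ = simulate_paired_betas(cfg2, sheet, "longitudinal")
        assert not A1.beta.equals(A3.beta)

    def test_batch_effects_shift_logits(self):
        """Plate/row shifts move the logit-scale sample means."""
        cfg = _pairs_config(100, 300, rho=0.5, seed=2, plate_effect_sd=1.0)
        sheet = simulate_sample_sheet(cfg)
        A_on, _, _ = simulate_paired_betas(cfg, sheet, "longitudinal", batch_effects=True)
        A_off, _, _ = simulate_paired_betas(cfg, sheet, "longitudinal", batch_effects=False)
        shift = logit(np.clip(A_on.beta, 1e-12, 1 - 1e-12)) - logit(
            np.clip(A_off.beta, 1e-12, 1 - 1e-12)
        )
        by_plate = (
            shift.mean(axis=0)
            .groupby(sheet.set_index("sample_id")["plate"])
            .mean()
        )
        assert by_plate.std() > 0.2


class TestQCInjection:
    def test_zero_rates_all_pass(self, small_paired, small_config):
        A = small_paired[0]
        cfg = SimulationConfig(
            n_families=small_config.n_families,
            n_probes=small_config.n_probes,
            detp_fail_rate=0.0,
            beadcount_fail_rate=0.0,
            zero_intensity_rate=0.0,
            seed=1,
        )
        m = inject_qc_failures(A, cfg)
        assert (m.detection_p.to_numpy() <= 0.01).all()
        assert (m.bead_count.to_numpy() >= 3).all()
        assert not m.intensity_zero.to_numpy().any()

    def test_saturated_detection_rate(self, small_paired, small_config):
        A = small_paired[0]
        cfg = SimulationConfig(
            n_families=small_config.n_families,
            n_probes=small_config.n_probes,
            detp_fail_rate=1.0,
            seed=1,
        )
        m = inject_qc_failures(A, cfg)
        assert (m.detection_p.to_numpy() > 0.01).all()

    def test_failure_counts_binomial(self):
        """Rate 0.05 on 1000×100: failing entries within 3 binomial SDs of 5000."""
        cfg = _pairs_config(
            50, 1000, seed=13, detp_fail_rate=0.05, beadcount_fail_rate=0.05
        )
        sheet = simulate_sample_sheet(cfg)
        A, _, _ = simulate_paired_betas(cfg, sheet, "longitudinal")
        m = inject_qc_failures(A, cfg)
        n = m.beta.size
        expected = 0.05 * n
        sd = np.sqrt(n * 0.05 * 0.95)
        assert abs((m.detection_p.to_numpy() > 0.01).sum() - expected) < 3 * sd
        assert abs((m.bead_count.to_numpy() < 3).sum() - expected) < 3 * sd


def test_rho_distribution_mixture_law():
    rng = np.random.default_rng(0)
    d = RhoDistribution(point_masses={0.0: 0.3, 0.9: 0.2}, uniform_weight=0.5)
    draws = d.sample(20_000, rng)
    assert np.mean(draws == 0.0) == pytest.approx(0.3, abs=0.02)
    assert np.mean(draws == 0.9) == pytest.approx(0.2, abs=0.02)
    assert draws.min() >= 0 and draws.max() <= 1


def test_invalid_rates_rejected():
    with pytest.raises(MethpairError):
        SimulationConfig(detp_fail_rate=1.5)
    with pytest.raises(MethpairError):
        SimulationConfig(family_share_f=-0.1)
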