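"""Residualization, standardization and PCA diagnostics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methpair.datatypes import BetaMatrix, MethpairError
from methpair.preprocess import (
    ProbeScaler,
    ResidualMatrix,
    TechnicalResidualizer,
    pca_covariate_diagnostics,
    residualize_technical,
    standardize_probes,
)
from methpair.simulate import SimulationConfig, simulate_paired_betas, simulate_sample_sheet


def _sheet(samples, plates, rows):
    return pd.DataFrame(
        {
            "sample_id": samples,
            "individual_id": samples,
            "family_id": ["F0"] * len(samples),
            "relationship": ["sibling"] * len(samples),
            "tissue": ["blood"] * len(samples),
            "platform": ["EPIC"] * len(samples),
            "timepoint": [1] * len(samples),
            "age": [30.0] * len(samples),
            "sex": ["F"] * len(samples),
            "plate": plates,
            "row": rows,
            "design": ["longitudinal"] * len(samples),
        }
    )


def _beta(values, samples):
    arr = np.asarray(values, dtype=float)
    return BetaMatrix(
        beta=pd.DataFrame(
            arr, index=[f"cg{i:04d}" for i in range(arr.shape[0])], columns=samples
        )
    )


class TestResidualize:
    def test_single_level_covariates_demean(self):
        """One plate, one row: residuals are beta minus the probe mean."""
        samples = ["s1", "s2", "s3", "s4"]
        m = _beta([[0.1, 0.2, 0.3, 0.4]], samples)
        sheet = _sheet(samples, ["P1"] * 4, ["R1"] * 4)
        r = residualize_technical(m, sheet)
        expected = np.array([0.1, 0.2, 0.3, 0.4]) - 0.25
        assert np.allclose(r.values.to_numpy()[0], expected, atol=1e-12)

    def test_exact_plate_offsets_removed(self):
        """Beta = baseline + per-plate offset: residuals identical across plates."""
        samples = [f"s{i}" for i in range(6)]
        plates = ["P1", "P1", "P2", "P2", "P3", "P3"]
        base = np.array([0.4, 0.5, 0.4, 0.5, 0.4, 0.5])
        offset = {"P1": 0.0, "P2": 0.05, "P3": -0.03}
        vals = base + np.array([offset[p] for p in plates])
        m = _beta([vals], samples)
        r = residualize_technical(m, _sheet(samples, plates, ["R1"] * 6), ["plate"])
        res = r.values.to_numpy()[0]
        assert np.allclose(res[[0, 2, 4]], res[0], atol=1e-10)
        assert np.allclose(res[[1, 3, 5]], res[1], atol=1e-10)

    def test_two_factor_toy_matches_normal_equations(self):
        """3 plates × 2 rows, 12 samples: residuals match a direct solve."""
        rng = np.random.default_rng(8)
        samples = [f"s{i}" for i in range(12)]
        plates = [f"P{1 + i % 3}" for i in range(12)]
        rows = [f"R{1 + i % 2}" for i in range(12)]
        vals = rng.uniform(0.2, 0.8, size=(5, 12))
        m = _beta(vals, samples)
        r = residualize_technical(m, _sheet(samples, plates, rows))
        # independent normal-equations oracle with explicit dummy design
        Z = np.column_stack(
            [
                np.ones(12),
                [p == "P2" for p in plates],
                [p == "P3" for p in plates],
                [w == "R2" for w in rows],
            ]
        ).astype(float)
        H = Z @ np.linalg.solve(Z.T @ Z, Z.T)
        expected = vals.T - H @ vals.T
        assert np.allclose(r.values.to_numpy(), expected.T, atol=1e-10)

    def test_covariate_missing_from_sheet_raises(self):
        samples = ["s1", "s2", "s3"]
        m = _beta([[0.1, 0.2, 0.3]], samples)
        with pytest.raises(MethpairError, match="covariate"):
            residualize_technical(m, _sheet(samples, ["P1"] * 3, ["R1"] * 3), ["chip"])

    def test_underdetermined_probe_flagged(self):
        """A probe observed in fewer samples than parameters is all-missing."""
        samples = [f"s{i}" for i in range(6)]
        vals = np.full((2, 6), 0.5)
        vals[0, :4] = np.nan  # 2 obs left, 4 params (1 + 2 plates + 1 row)
        m = _beta(vals, samples)
        sheet = _sheet(samples, ["P1", "P1", "P2", "P2", "P3", "P3"], ["R1", "R2"] * 3)
        r = residualize_technical(m, sheet)
        assert r.values.index[0] in r.flagged_probes
        assert r.values.iloc[0].isna().all()

    def test_orthogonality_to_dummies(self):
        """Residuals are orthogonal to every covariate dummy column."""
        rng = np.random.default_rng(2)
        samples = [f"s{i}" for i in range(20)]
        plates = [f"P{1 + i % 4}" for i in range(20)]
        rows = [f"R{1 + i % 3}" for i in range(20)]
        m = _beta(rng.uniform(size=(10, 20)), samples)
        r = residualize_technical(m, _sheet(samples, plates, rows))
        D = pd.get_dummies(pd.DataFrame({"plate": plates, "row": rows})).to_numpy(float)
        inner = r.values.to_numpy() @ D
        assert np.abs(inner).max() < 1e-8

    def test_invariance_to_plate_constant_shift(self):
        """Adding any plate-constant shift leaves standardized residuals unchanged."""
        rng = np.random.default_rng(4)
        samples = [f"s{i}" for i in range(12)]
        plates = [f"P{1 + i % 3}" for i in range(12)]
        rows = [f"R{1 + i % 2}" for i in range(12)]
        sheet = _sheet(samples, plates, rows)
        vals = rng.uniform(0.3, 0.6, size=(4, 12))
        shift = {"P1": 0.02, "P2": -0.04, "P3": 0.01}
        shifted = vals + np.array([shift[p] for p in plates])
        z1 = standardize_probes(residualize_technical(_beta(vals, samples), sheet))
        z2 = standardize_probes(residualize_technical(_beta(shifted, samples), sheet))
        assert np.allclose(z1.values.to_numpy(), z2.values.to_numpy(), atol=1e-8)


class TestStandardize:
    def test_closed_form_row(self):
        r = ResidualMatrix(
            values=pd.DataFrame([[1.0, 2.0, 3.0]], index=["cg1"], columns=list("abc"))
        )
        z = standardize_probes(r)
        assert np.allclose(z.values.to_numpy()[0], [-1, 0, 1])

    def test_constant_row_flagged(self):
        r = ResidualMatrix(
            values=pd.DataFrame([[0.5, 0.5, 0.5]], index=["cg1"], columns=list("abc"))
        )
        z = standardize_probes(r)
        assert z.values.iloc[0].isna().all()
        assert "cg1" in z.flagged_probes

    def test_output_moments(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(50, 30))
        vals[rng.random(size=vals.shape) < 0.1] = np.nan
        r = ResidualMatrix(
            values=pd.DataFrame(
                vals, index=[f"cg{i}" for i in range(50)], columns=[f"s{j}" for j in range(30)]
            )
        )
        z = standardize_probes(r)
        means = np.nanmean(z.values.to_numpy(), axis=1)
        sds = np.nanstd(z.values.to_numpy(), axis=1, ddof=1)
        assert np.abs(means).max() < 1e-10
        assert np.abs(sds - 1).max() < 1e-10

    def test_double_standardization_rejected(self):
        r = ResidualMatrix(
            values=pd.DataFrame([[1.0, 2.0, 4.0]], index=["cg1"], columns=list("abc"))
        )
        with pytest.raises(MethpairError):
            standardize_probes(standardize_probes(r))

    def test_scaler_estimator_api(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        sc = ProbeScaler().fit(X)
        out = sc.transform(X)
        assert np.allclose(out[:, 0], [-1, 0, 1])
        assert np.isnan(out[:, 1]).all()
        assert list(sc.flagged_features_) == [False, True]


class TestPCADiagnostics:
    def test_rank_one_matrix(self):
        """A rank-1 matrix loads all variance on PC1."""
        u = np.linspace(-1, 1, 12)
        v = np.linspace(0.2, 0.8, 9)
        vals = 0.5 + 0.2 * np.outer(v, u)
        samples = [f"s{i}" for i in range(12)]
        m = _beta(np.clip(vals, 0, 1), samples)
        sheet = _sheet(samples, ["P1"] * 12, ["R1"] * 12)
        diag = pca_covariate_diagnostics(m, sheet, n_pcs=3, covariates=["age"])
        assert diag.loc["PC1", "explained_variance"] == pytest.approx(1.0, abs=1e-9)

    def test_plate_shift_correlation_drops_after_residualization(self):
        """|corr(PC1..2, plate)| is larger before plate/row correction than after."""
        cfg = SimulationConfig(
            n_families=30,
            n_probes=300,
            design_pairs={"longitudinal": 100},
            plate_effect_sd=1.5,
            seed=6,
        )
        sheet = simulate_sample_sheet(cfg)
        A, _, _ = simulate_paired_betas(cfg, sheet, "longitudinal")
        before = pca_covariate_diagnostics(A, sheet, n_pcs=2, covariates=["plate"])
        resid = residualize_technical(A, sheet)
        after = pca_covariate_diagnostics(resid, sheet, n_pcs=2, covariates=["plate"])
        assert before["plate"].abs().max() > after["plate"].abs().max()
        assert before["plate"].abs().max() > 0.5

    def test_orthogonal_covariate_near_zero(self):
        """A covariate unrelated to the data by construction barely correlates."""
        rng = np.random.default_rng(12)
        samples = [f"s{i}" for i in range(60)]
        m = _beta(rng.uniform(0.2, 0.8, size=(200, 60)), samples)
        sheet = _sheet(samples, ["P1"] * 60, ["R1"] * 60)
        sheet["age"] = rng.normal(40, 5, size=60)  # independent of the data
        diag = pca_covariate_diagnostics(m, sheet, n_pcs=5, covariates=["age"])
        assert diag["age"].abs().max() < 0.45  # ~3.5/sqrt(60) Monte-Carlo bound

    def test_too_many_pcs_raises(self):
        samples = ["s1", "s2", "s3"]
        m = _beta(np.full((4, 3), 0.5), samples)
        with pytest.raises(MethpairError):
            pca_covariate_diagnostics(m, _sheet(samples, ["P1"] * 3, ["R1"] * 3), n_pcs=5)
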