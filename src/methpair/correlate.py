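"""Per-CpG paired-measurement correlation with family-clustered GEE.

For every probe, the two measurements of each individual (two timepoints, two
tissues, or two platforms) are assembled into paired vectors, re-standardized
within the analyzed subset, and the second measurement is regressed on the
first with a Gaussian GEE using an exchangeable working correlation over
families.  On z-scored inputs the GEE slope is a correlation coefficient; the
robust (sandwich) Wald statistic gives the p-value, since the family
clustering is the stated reason for using GEE in the first place.  Pearson's
r and a one-way intra-class correlation are computed on the same pairs as
comparators.

Probes are classified *significant* under a Bonferroni-corrected Wald test
(p < alpha / number of tests) and *strong* when the estimate exceeds 0.50
(strict inequality); both flags together define the reliably correlated set.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import ComparisonDesign, MethpairError
from .gee import ExchangeableGEE, ZeroVarianceError
from .preprocess import ResidualMatrix

__all__ = [
    "PairedCorrelationGEE",
    "estimate_cpg_correlation",
    "pearson_correlation",
    "icc_oneway",
    "classify_significant_strong",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = (
    "gee_estimate",
    "robust_se",
    "naive_se",
    "wald_z",
    "p_value",
    "p_value_naive",
    "pearson_r",
    "icc",
    "n_pairs",
    "sd_a",
    "sd_b",
    "significant",
    "strong",
)


def pearson_correlation(x, y) -> float:
    """Product-moment correlation over pairwise-complete entries.

    Returns NaN when fewer than two complete pairs remain or either vector
    has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def icc_oneway(x, y) -> float:
    """One-way random-effects intra-class correlation, ICC(1,1), for paired data.

    With pair means m_i and grand mean m over n complete pairs (k = 2
    measurements each):

        MS_between = 2·Σ(m_i − m)² / (n − 1)
        MS_within  = Σ[(x_i − m_i)² + (y_i − m_i)²] / n
        ICC        = (MS_between − MS_within) / (MS_between + MS_within)

    Returns NaN for degenerate variance (fewer than two pairs, or all values
    equal).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 2:
        return float("nan")
    m_i = (x + y) / 2.0
    m = m_i.mean()
    msb = 2.0 * np.sum((m_i - m) ** 2) / (n - 1)
    msw = np.sum((x - m_i) ** 2 + (y - m_i) ** 2) / n
    if msb + msw == 0:
        return float("nan")
    return float((msb - msw) / (msb + msw))


class PairedCorrelationGEE(BaseEstimator):
    """Per-probe paired-correlation estimator over a comparison design.

    Parameters
    ----------
    max_iter, tol : GEE iteration controls.
    min_pairs : int, default 10
        Probes analyzed in fewer individuals come back with missing estimates.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per probe (indexed by probe id) with columns
        ``gee_estimate, robust_se, naive_se, wald_z, p_value, p_value_naive,
        pearson_r, icc, n_pairs, sd_a, sd_b, significant, strong``.
        Classification flags are False until :meth:`classify` is called.
    design_ : ComparisonDesign
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-6, min_pairs: int = 10):
        self.max_iter = max_iter
        self.tol = tol
        self.min_pairs = min_pairs

    def fit(
        self,
        z_a: ResidualMatrix,
        z_b: ResidualMatrix,
        design: ComparisonDesign,
        beta_a: Optional[pd.DataFrame] = None,
        beta_b: Optional[pd.DataFrame] = None,
    ):
        """Estimate the per-probe pairing correlation.

        ``z_a``/``z_b`` hold standardized residuals (probes × samples);
        ``beta_a``/``beta_b`` optionally supply the original beta values from
        which the beta-scale standard deviations ``sd_a``/``sd_b`` are taken
        (otherwise the sds of the inputs are reported).
        """
        pairs = design.pairs
        for col, mat in (("sample_a", z_a), ("sample_b", z_b)):
            missing = set(pairs[col]) - set(mat.values.columns)
            if missing:
                raise MethpairError(
                    f"design references samples absent from matrices: "
                    f"{sorted(missing)[:5]}"
                )
        probes = z_a.values.index
        if not probes.equals(z_b.values.index):
            common = probes.intersection(z_b.values.index, sort=False)
            probes = common
        A = z_a.values.loc[probes, pairs["sample_a"]].to_numpy()
        B = z_b.values.loc[probes, pairs["sample_b"]].to_numpy()
        SA = None if beta_a is None else beta_a.loc[probes, pairs["sample_a"]].to_numpy()
        SB = None if beta_b is None else beta_b.loc[probes, pairs["sample_b"]].to_numpy()
        fam = pairs["family_id"].to_numpy()

        est = ExchangeableGEE(max_iter=self.max_iter, tol=self.tol)
        rows = np.full((len(probes), 11), np.nan)
        for j in range(len(probes)):
            x, y = A[j], B[j]
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            rows[j, 8] = n
            if n < self.min_pairs:
                continue
            xs, ys = x[ok], y[ok]
            sdx, sdy = xs.std(ddof=1), ys.std(ddof=1)
            rows[j, 9] = sdx if SA is None else np.nanstd(SA[j][ok], ddof=1)
            rows[j, 10] = sdy if SB is None else np.nanstd(SB[j][ok], ddof=1)
            if sdx == 0 or sdy == 0:
                continue
            # re-standardize within the analyzed subset so slope ≡ correlation
            xs = (xs - xs.mean()) / sdx
            ys = (ys - ys.mean()) / sdy
            try:
                est.fit(xs, ys, groups=fam[ok])
            except (ZeroVarianceError, np.linalg.LinAlgError):
                continue
            slope = float(est.coef_[0])
            rse = float(est.robust_se_[0])
            nse = float(est.naive_se_[0])
            z = slope / rse if rse > 0 else np.nan
            zn = slope / nse if nse > 0 else np.nan
            rows[j, 0:6] = (
                slope,
                rse,
                nse,
                z,
                2.0 * stats.norm.sf(abs(z)),
                2.0 * stats.norm.sf(abs(zn)),
            )
            rows[j, 6] = pearson_correlation(xs, ys)
            rows[j, 7] = icc_oneway(xs, ys)

        res = pd.DataFrame(
            rows,
            index=pd.Index(probes, name="probe_id"),
            columns=[
                "gee_estimate",
                "robust_se",
                "naive_se",
                "wald_z",
                "p_value",
                "p_value_naive",
                "pearson_r",
                "icc",
                "n_pairs",
                "sd_a",
                "sd_b",
            ],
        )
        res["n_pairs"] = res["n_pairs"].fillna(0).astype(int)
        res["significant"] = False
        res["strong"] = False
        self.results_ = res
        self.design_ = design
        return self

    def classify(
        self,
        alpha: float = 0.05,
        r_threshold: float = 0.50,
        n_tests: Optional[int] = None,
    ) -> pd.DataFrame:
        """Set the significance (Bonferroni) and strength flags in-place."""
        self.results_ = classify_significant_strong(
            self.results_, alpha=alpha, r_threshold=r_threshold, n_tests=n_tests
        )
        return self.results_


def estimate_cpg_correlation(
    z_a: ResidualMatrix,
    z_b: ResidualMatrix,
    design: ComparisonDesign,
    beta_a: Optional[pd.DataFrame] = None,
    beta_b: Optional[pd.DataFrame] = None,
    min_pairs: int = 10,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Functional wrapper over :class:`PairedCorrelationGEE`; returns results."""
    est = PairedCorrelationGEE(max_iter=max_iter, tol=tol, min_pairs=min_pairs)
    est.fit(z_a, z_b, design, beta_a=beta_a, beta_b=beta_b)
    return est.results_


def classify_significant_strong(
    results: pd.DataFrame,
    alpha: float = 0.05,
    r_threshold: float = 0.50,
    n_tests: Optional[int] = None,
) -> pd.DataFrame:
    """Bonferroni significance and strict strength classification.

    ``significant`` ⇔ p < alpha / n_tests; ``strong`` ⇔ estimate > threshold.
    ``n_tests`` defaults to the number of probes with a non-missing estimate
    and must be at least that number.
    """
    res = results.copy()
    n_valid = int(res["gee_estimate"].notna().sum())
    if n_tests is None:
        n_tests = n_valid
    if n_tests < n_valid:
        raise MethpairError(
            f"n_tests={n_tests} is below the {n_valid} non-missing results"
        )
    if n_tests == 0:
        res["significant"] = False
        res["strong"] = False
        return res
    cutoff = alpha / n_tests
    res["significant"] = (res["p_value"] < cutoff).fillna(False)
    res["strong"] = (res["gee_estimate"] > r_threshold).fillna(False)
    return res


def write_results_tsv(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index_label="probe_id")


def read_results_tsv(path) -> pd.DataFrame:
    res = pd.read_csv(path, sep="\t", index_col="probe_id")
    for col in ("significant", "strong"):
        res[col] = res[col].astype(bool)
    return res
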