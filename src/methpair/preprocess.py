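"""Technical-covariate residualization, per-probe z-scoring, PCA diagnostics.

Before per-CpG correlation estimation, beta values are corrected for the
technical covariates of the assay (sample plate and array row) by per-probe
ordinary least squares on dummy-coded covariates, and the residuals are
z-scored per probe.  On standardized inputs the slope of the pair-mate GEE
regression equals a correlation coefficient, which is the point of the
z-scoring.  Cell-composition covariates are deliberately not adjusted:
biological sources of (dis)similarity between the paired measurements are
part of what the correlation is meant to capture.

Residualization is applied within each measurement set separately (all
first-measurement samples of a design together, all second-measurement
samples together), since plate/row layouts differ between assay batches.

:func:`pca_covariate_diagnostics` reproduces the standard batch-effect check:
correlate the leading sample-space principal components with technical and
biological covariates, before and after correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .datatypes import BetaMatrix, MethpairError

__all__ = [
    "TechnicalResidualizer",
    "ProbeScaler",
    "ResidualMatrix",
    "residualize_technical",
    "standardize_probes",
    "pca_covariate_diagnostics",
]

DEFAULT_COVARIATES = ("plate", "row")


@dataclass
class ResidualMatrix:
    """Probes × samples residualized (optionally z-scored) methylation values."""

    values: pd.DataFrame
    standardized: bool = False
    flagged_probes: frozenset = frozenset()

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def _dummy_design(meta: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    """Intercept plus treatment-coded dummies for each covariate."""
    cols = [np.ones(len(meta))]
    for cov in covariates:
        if cov not in meta.columns:
            raise MethpairError(f"covariate {cov!r} absent from sample sheet")
        d = pd.get_dummies(meta[cov].astype("category"), drop_first=True)
        if d.shape[1]:
            cols.append(d.to_numpy(dtype=float))
    return np.column_stack(cols)


class TechnicalResidualizer(BaseEstimator, TransformerMixin):
    """Remove dummy-coded technical covariates from each probe by OLS.

    Operates on samples × probes arrays (scikit-learn orientation); the
    module-level :func:`residualize_technical` handles the probes × samples
    containers.  Fit and transform act on the same sample set: the design
    matrix is built from the covariate frame passed at fit time.

    Parameters
    ----------
    covariates : sequence of str, default ("plate", "row")
        Columns of the covariate frame to dummy-code.

    Attributes
    ----------
    design_ : ndarray of shape (n_samples, q)
    coef_ : ndarray of shape (q, n_features)
        Per-probe OLS coefficients (NaN-aware).
    flagged_features_ : ndarray of bool
        Probes with fewer non-missing samples than model parameters; their
        residuals are all-missing.
    """

    def __init__(self, covariates: Sequence[str] = DEFAULT_COVARIATES):
        self.covariates = covariates

    def fit(self, X, y=None, *, covariate_frame: pd.DataFrame):
        X = np.asarray(X, dtype=float)
        if len(covariate_frame) != X.shape[0]:
            raise MethpairError(
                "covariate frame rows must match the number of samples"
            )
        Z = _dummy_design(covariate_frame, self.covariates)
        n, q = Z.shape
        coef = np.full((q, X.shape[1]), np.nan)
        flagged = np.zeros(X.shape[1], dtype=bool)

        complete = ~np.isnan(X).any(axis=0)
        if complete.any():
            sol, *_ = np.linalg.lstsq(Z, X[:, complete], rcond=None)
            coef[:, complete] = sol
        for j in np.flatnonzero(~complete):
            obs = ~np.isnan(X[:, j])
            if obs.sum() < q:
                flagged[j] = True
                continue
            sol, *_ = np.linalg.lstsq(Z[obs], X[obs, j], rcond=None)
            coef[:, j] = sol
        self.design_ = Z
        self.coef_ = coef
        self.flagged_features_ = flagged
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        resid = X - self.design_ @ np.where(np.isnan(self.coef_), 0.0, self.coef_)
        resid[np.isnan(X)] = np.nan
        resid[:, self.flagged_features_] = np.nan
        return resid


class ProbeScaler(BaseEstimator, TransformerMixin):
    """Per-feature z-scoring with the n−1 denominator, NaN-aware.

    Zero-variance features (or features with fewer than two observed values)
    are flagged and set all-missing, rather than divided by zero.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        with np.errstate(invalid="ignore"):
            self.mean_ = np.nanmean(X, axis=0)
            n_obs = np.sum(~np.isnan(X), axis=0)
            self.scale_ = np.full(X.shape[1], np.nan)
            ok = n_obs >= 2
            self.scale_[ok] = np.nanstd(X[:, ok], axis=0, ddof=1)
        self.flagged_features_ = ~(self.scale_ > 0)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (X - self.mean_) / self.scale_
        out[:, self.flagged_features_] = np.nan
        return out


def residualize_technical(
    m: BetaMatrix | ResidualMatrix,
    sheet: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> ResidualMatrix:
    """Per-probe OLS residuals of beta on dummy-coded technical covariates.

    Every sample of ``m`` must appear in ``sheet``; probes with fewer
    non-missing samples than model parameters come back all-missing and
    flagged.
    """
    values = m.beta if isinstance(m, BetaMatrix) else m.values
    meta = sheet.set_index("sample_id")
    missing = values.columns.difference(meta.index)
    if len(missing):
        raise MethpairError(f"samples absent from sheet: {list(missing[:5])}")
    meta = meta.loc[values.columns]
    est = TechnicalResidualizer(covariates=covariates)
    resid = est.fit(values.to_numpy().T, covariate_frame=meta).transform(
        values.to_numpy().T
    )
    flagged = frozenset(values.index[est.flagged_features_])
    return ResidualMatrix(
        values=pd.DataFrame(resid.T, index=values.index, columns=values.columns),
        standardized=False,
        flagged_probes=flagged,
    )


def standardize_probes(r: ResidualMatrix) -> ResidualMatrix:
    """Z-score each probe row (n−1 denominator) over its non-missing entries."""
    if r.standardized:
        raise MethpairError("matrix is already standardized")
    est = ProbeScaler().fit(r.values.to_numpy().T)
    out = est.transform(r.values.to_numpy().T)
    flagged = frozenset(r.values.index[est.flagged_features_]) | r.flagged_probes
    return ResidualMatrix(
        values=pd.DataFrame(out.T, index=r.values.index, columns=r.values.columns),
        standardized=True,
        flagged_probes=flagged,
    )


def pca_covariate_diagnostics(
    m: BetaMatrix | ResidualMatrix,
    sheet: pd.DataFrame,
    n_pcs: int = 10,
    covariates: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Correlate the first ``n_pcs`` sample-space PCs with covariates.

    Missing entries are mean-imputed per probe for the decomposition only.
    Numeric covariates get a signed Pearson correlation; categorical ones the
    multiple correlation coefficient (square root of the R² from regressing
    the PC on the covariate's dummies).  Returns one row per PC with the
    covariate grid plus an ``explained_variance`` fraction column.
    """
    values = m.beta if isinstance(m, BetaMatrix) else m.values
    n_samples = values.shape[1]
    if n_pcs > n_samples:
        raise MethpairError(f"n_pcs={n_pcs} exceeds the {n_samples} samples")
    meta = sheet.set_index("sample_id").loc[values.columns]
    if covariates is None:
        covariates = [
            c for c in ("age", "sex", "plate", "row", "tissue", "platform", "timepoint")
            if c in meta.columns and meta[c].nunique() > 1
        ]

    X = values.to_numpy().T.copy()  # samples × probes
    col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    X = X[:, np.isfinite(X).all(axis=0)]  # drop all-missing probes

    pca = PCA(n_components=n_pcs)
    scores = pca.fit_transform(X)

    rows = []
    for k in range(n_pcs):
        pc = scores[:, k]
        row: dict[str, float] = {"explained_variance": float(pca.explained_variance_ratio_[k])}
        for cov in covariates:
            col = meta[cov]
            if pd.api.types.is_numeric_dtype(col):
                v = col.to_numpy(dtype=float)
                if np.std(v) == 0 or np.std(pc) == 0:
                    row[cov] = np.nan
                else:
                    row[cov] = float(np.corrcoef(pc, v)[0, 1])
            else:
                D = pd.get_dummies(col.astype("category")).to_numpy(dtype=float)
                row[cov] = _multiple_correlation(pc, D)
        rows.append(row)
    return pd.DataFrame(rows, index=[f"PC{k + 1}" for k in range(n_pcs)])


def _multiple_correlation(y: np.ndarray, D: np.ndarray) -> float:
    """sqrt(R²) of OLS of y on [1, D]; in [0, 1]."""
    Z = np.column_stack([np.ones(len(y)), D])
    coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
    fitted = Z @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return np.nan
    r2 = 1.0 - float(np.sum((y - fitted) ** 2)) / ss_tot
    return float(np.sqrt(max(r2, 0.0)))
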