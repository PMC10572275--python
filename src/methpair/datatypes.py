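"""Core data containers for paired methylation-array analysis.

The central object is the :class:`BetaMatrix`: a probes × samples matrix of
methylation beta values (fractions in [0, 1]) with optional aligned layers
carrying per-entry quality information (detection p-values, bead counts, and
zero-intensity flags).  Sample metadata lives in a plain :class:`pandas.DataFrame`
sample sheet; :class:`ComparisonDesign` pins down, for one of the three paired
designs (longitudinal, cross-tissue, cross-platform), which two samples belong
to each individual and which family each individual belongs to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

DESIGNS = ("longitudinal", "tissue", "platform")

#: Required columns of a sample sheet.
SHEET_COLUMNS = (
    "sample_id",
    "individual_id",
    "family_id",
    "relationship",
    "tissue",
    "platform",
    "timepoint",
    "age",
    "sex",
    "plate",
    "row",
    "design",
)

RELATIONSHIPS = ("MZ", "DZ", "sibling", "parent")


class MethpairError(ValueError):
    """Base class for named errors raised by this package."""


class LayerMismatchError(MethpairError):
    """An optional layer does not share the beta matrix's dimensions."""


class DesignError(MethpairError):
    """A comparison design is absent from, or inconsistent with, a sample sheet."""


class AnnotationError(MethpairError):
    """Probe annotation does not cover the probes it must describe."""


@dataclass
class BetaMatrix:
    """Probes × samples methylation beta values plus optional QC layers.

    Parameters
    ----------
    beta : pandas.DataFrame
        Rows indexed by probe id, columns by sample id; values in [0, 1],
        NaN for missing.
    detection_p, bead_count, intensity_zero : pandas.DataFrame, optional
        Layers aligned with ``beta`` (same index and columns).  ``bead_count``
        is numeric (float to allow NaN); ``intensity_zero`` is boolean.
    """

    beta: pd.DataFrame
    detection_p: Optional[pd.DataFrame] = None
    bead_count: Optional[pd.DataFrame] = None
    intensity_zero: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.beta = self.beta.astype(float)
        vals = self.beta.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise MethpairError("beta values must lie in [0, 1]")
        for name in ("detection_p", "bead_count", "intensity_zero"):
            layer = getattr(self, name)
            if layer is None:
                continue
            if layer.shape != self.beta.shape:
                raise LayerMismatchError(
                    f"layer {name!r} has shape {layer.shape}, beta has {self.beta.shape}"
                )
            if not (
                layer.index.equals(self.beta.index)
                and layer.columns.equals(self.beta.columns)
            ):
                raise LayerMismatchError(f"layer {name!r} is not aligned with beta")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.beta.shape

    def subset_probes(self, probes: Iterable[str]) -> "BetaMatrix":
        """Return a new matrix restricted to ``probes`` (order preserved)."""
        idx = self.beta.index.intersection(pd.Index(probes), sort=False)
        return BetaMatrix(
            beta=self.beta.loc[idx],
            detection_p=None if self.detection_p is None else self.detection_p.loc[idx],
            bead_count=None if self.bead_count is None else self.bead_count.loc[idx],
            intensity_zero=None
            if self.intensity_zero is None
            else self.intensity_zero.loc[idx],
        )

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(
            beta=self.beta.copy(),
            detection_p=None if self.detection_p is None else self.detection_p.copy(),
            bead_count=None if self.bead_count is None else self.bead_count.copy(),
            intensity_zero=None
            if self.intensity_zero is None
            else self.intensity_zero.copy(),
        )


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate required sheet columns and identifier consistency.

    Raises
    ------
    MethpairError
        On missing columns, duplicated sample ids, or an individual mapped
        to more than one family.
    """
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise MethpairError(f"sample sheet missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise MethpairError(f"duplicate sample ids: {dup[:5]}")
    fam_per_ind = sheet.groupby("individual_id")["family_id"].nunique()
    if (fam_per_ind > 1).any():
        bad = fam_per_ind[fam_per_ind > 1].index.tolist()
        raise MethpairError(f"individuals mapped to multiple families: {bad[:5]}")
    return sheet


# Per design: the sheet column that distinguishes the two samples of a pair,
# and the (first, second) level order defining measurement A and B.
_DESIGN_AXIS = {
    "longitudinal": ("timepoint", (1, 2)),
    "tissue": ("tissue", ("blood", "buccal")),
    "platform": ("platform", ("450K", "EPIC")),
}


@dataclass
class ComparisonDesign:
    """Per-individual pairing of two samples for one comparison design.

    ``pairs`` has one row per individual with columns ``individual_id``,
    ``family_id``, ``sample_a``, ``sample_b``.  Measurement A/B order is fixed
    per design: timepoint 1/2, blood/buccal, 450K/EPIC.
    """

    design: str
    pairs: pd.DataFrame = field(repr=False)

    @classmethod
    def from_sheet(cls, sheet: pd.DataFrame, design: str) -> "ComparisonDesign":
        if design not in DESIGNS:
            raise DesignError(f"unknown design {design!r}; expected one of {DESIGNS}")
        validate_sample_sheet(sheet)
        sub = sheet[sheet["design"] == design]
        if sub.empty:
            raise DesignError(f"design {design!r} absent from sample sheet")
        axis, (lvl_a, lvl_b) = _DESIGN_AXIS[design]
        rows = []
        for ind, grp in sub.groupby("individual_id", sort=True):
            if len(grp) != 2:
                raise DesignError(
                    f"individual {ind!r} has {len(grp)} samples in design {design!r}"
                )
            a = grp[grp[axis] == lvl_a]
            b = grp[grp[axis] == lvl_b]
            if len(a) != 1 or len(b) != 1:
                raise DesignError(
                    f"individual {ind!r} lacks the {axis} {lvl_a}/{lvl_b} pair"
                )
            rows.append(
                {
                    "individual_id": ind,
                    "family_id": a["family_id"].iloc[0],
                    "sample_a": a["sample_id"].iloc[0],
                    "sample_b": b["sample_id"].iloc[0],
                }
            )
        return cls(design=design, pairs=pd.DataFrame(rows))

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# Plain-text IO (TSV matrices, CSV sheets)
# ---------------------------------------------------------------------------

def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a probes × samples matrix as TSV with a probe_id index column."""
    df.to_csv(path, sep="\t", index_label="probe_id")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def write_beta_matrix(m: BetaMatrix, prefix: str | Path) -> list[Path]:
    """Write beta and present layers as ``<prefix>.<layer>.tsv`` files."""
    prefix = Path(prefix)
    written = []
    for name, df in (
        ("beta", m.beta),
        ("detection_p", m.detection_p),
        ("bead_count", m.bead_count),
        ("intensity_zero", m.intensity_zero),
    ):
        if df is None:
            continue
        out = prefix.with_suffix(f".{name}.tsv")
        if name == "intensity_zero":
            write_matrix_tsv(df.astype(int), out)
        else:
            write_matrix_tsv(df, out)
        written.append(out)
    return written


def read_beta_matrix(
    beta: str | Path,
    detection_p: str | Path | None = None,
    bead_count: str | Path | None = None,
    intensity_zero: str | Path | None = None,
) -> BetaMatrix:
    return BetaMatrix(
        beta=read_matrix_tsv(beta),
        detection_p=None if detection_p is None else read_matrix_tsv(detection_p),
        bead_count=None if bead_count is None else read_matrix_tsv(bead_count),
        intensity_zero=None
        if intensity_zero is None
        else read_matrix_tsv(intensity_zero).astype(bool),
    )


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    return validate_sample_sheet(sheet)


def read_probe_list(path: str | Path) -> list[str]:
    """Read a plain-text probe list, one id per line, blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_probe_list(probes: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f"{p}\n")
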