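"""Probe-level quality-control filters for beta matrices.

The filter chain, applied in a fixed order so stage counts are unambiguous:

1. value masking — entries with a zero intensity, detection p-value > 0.01,
   or bead count < 3 are set missing (boundary values pass);
2. success-rate filtering — probes observed in fewer than 95% of samples are
   removed (exactly 95% is kept);
3. mask-list removal — probes on a published exclusion list (polymorphic /
   cross-reactive probes) are removed;
4. sex-chromosome removal — probes on X or Y are removed, leaving autosomal
   probes only.

Stages 3 and 4 are disjointly accounted: a masked probe that also sits on a
sex chromosome is counted under the mask stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .datatypes import AnnotationError, BetaMatrix, MethpairError

__all__ = [
    "QCReport",
    "apply_value_filters",
    "filter_low_success_probes",
    "filter_masked_and_sex_probes",
    "run_probe_qc",
    "read_annotation",
]

DETECTION_P_MAX = 0.01
BEAD_COUNT_MIN = 3
SUCCESS_RATE_MIN = 0.95

AUTOSOMES = {str(i) for i in range(1, 23)}
SEX_CHROMOSOMES = {"X", "Y"}
ALLOWED_CHROMOSOMES = AUTOSOMES | SEX_CHROMOSOMES


@dataclass
class QCReport:
    """Disjoint accounting of the probe filter chain."""

    n_probes_in: int = 0
    n_entries_masked: int = 0
    n_probes_dropped_success: int = 0
    n_probes_dropped_mask: int = 0
    n_probes_dropped_sex: int = 0
    n_probes_out: int = 0

    def check(self) -> None:
        dropped = (
            self.n_probes_dropped_success
            + self.n_probes_dropped_mask
            + self.n_probes_dropped_sex
        )
        if self.n_probes_out != self.n_probes_in - dropped:
            raise MethpairError(
                "QCReport accounting identity violated: "
                f"{self.n_probes_out} != {self.n_probes_in} - {dropped}"
            )

    def to_text(self) -> str:
        return "".join(f"{k}\t{v}\n" for k, v in self.__dict__.items())

    @classmethod
    def from_text(cls, text: str) -> "QCReport":
        kv = dict(line.split("\t") for line in text.strip().splitlines())
        return cls(**{k: int(v) for k, v in kv.items()})

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())


def apply_value_filters(m: BetaMatrix) -> tuple[BetaMatrix, int]:
    """Set entries failing any per-entry rule to missing.

    An entry fails when its intensity is exactly zero, its detection p-value
    exceeds 0.01, or its bead count is below 3; absent layers skip their
    rule.  Returns the masked matrix and the count of newly masked entries
    (entries already missing are not recounted).
    """
    beta = m.beta.to_numpy().copy()
    fail = np.zeros(beta.shape, dtype=bool)
    if m.intensity_zero is not None:
        fail |= m.intensity_zero.to_numpy().astype(bool)
    if m.detection_p is not None:
        fail |= m.detection_p.to_numpy() > DETECTION_P_MAX
    if m.bead_count is not None:
        fail |= m.bead_count.to_numpy() < BEAD_COUNT_MIN
    newly = int(np.sum(fail & np.isfinite(beta)))
    beta[fail] = np.nan
    out = BetaMatrix(
        beta=pd.DataFrame(beta, index=m.beta.index, columns=m.beta.columns),
        detection_p=m.detection_p,
        bead_count=m.bead_count,
        intensity_zero=m.intensity_zero,
    )
    return out, newly


def filter_low_success_probes(
    m: BetaMatrix, threshold: float = SUCCESS_RATE_MIN
) -> tuple[BetaMatrix, set[str]]:
    """Remove probes whose fraction of non-missing entries is below ``threshold``.

    A success rate exactly at the threshold is kept.
    """
    if not 0.0 < threshold <= 1.0:
        raise MethpairError("success-rate threshold must lie in (0, 1]")
    if m.beta.size == 0:
        raise MethpairError("cannot filter an empty matrix")
    success = m.beta.notna().mean(axis=1)
    dropped = set(m.beta.index[success < threshold])
    kept = m.beta.index[~m.beta.index.isin(dropped)]
    return m.subset_probes(kept), dropped


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a probe annotation CSV with columns probe_id, chromosome, position[, gene]."""
    ann = pd.read_csv(path, dtype={"chromosome": str})
    return validate_annotation(ann)


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    for col in ("probe_id", "chromosome", "position"):
        if col not in ann.columns:
            raise AnnotationError(f"annotation missing column {col!r}")
    if ann["probe_id"].duplicated().any():
        raise AnnotationError("annotation has duplicated probe ids")
    chroms = set(ann["chromosome"].astype(str))
    bad = chroms - ALLOWED_CHROMOSOMES
    if bad:
        raise AnnotationError(f"annotation has unknown chromosomes: {sorted(bad)}")
    return ann


def filter_masked_and_sex_probes(
    m: BetaMatrix,
    mask: Iterable[str],
    ann: pd.DataFrame,
    report: Optional[QCReport] = None,
) -> tuple[BetaMatrix, QCReport]:
    """Remove mask-listed probes, then X/Y probes; tally each stage disjointly.

    ``ann`` must cover every probe of ``m``.  When an existing ``report`` is
    passed (carrying the earlier stages' tallies), its mask/sex/out fields
    are filled in; otherwise a fresh report covering only these stages is
    returned.
    """
    validate_annotation(ann)
    probe_ids = m.beta.index
    known = pd.Index(ann["probe_id"])
    missing = probe_ids.difference(known)
    if len(missing) > 0:
        raise AnnotationError(
            f"{len(missing)} probes missing from annotation, e.g. {list(missing[:5])}"
        )
    mask = set(mask)
    chrom = ann.set_index("probe_id")["chromosome"].astype(str)

    in_mask = probe_ids.isin(mask)
    on_sex = chrom.loc[probe_ids].isin(SEX_CHROMOSOMES).to_numpy()
    n_mask = int(in_mask.sum())
    n_sex = int((on_sex & ~in_mask).sum())  # masked probes counted once, under mask
    kept = probe_ids[~in_mask & ~on_sex]

    if report is None:
        report = QCReport(n_probes_in=len(probe_ids))
    report.n_probes_dropped_mask = n_mask
    report.n_probes_dropped_sex = n_sex
    report.n_probes_out = len(kept)
    report.check()
    return m.subset_probes(kept), report


def run_probe_qc(
    m: BetaMatrix,
    mask: Iterable[str] = (),
    ann: Optional[pd.DataFrame] = None,
    success_threshold: float = SUCCESS_RATE_MIN,
) -> tuple[BetaMatrix, QCReport]:
    """Full probe filter chain: value masking → success rate → mask list → sex.

    When ``ann`` is None the mask/sex stages are skipped (all probes treated
    as autosomal and unmasked).
    """
    report = QCReport(n_probes_in=m.shape[0])
    m, report.n_entries_masked = apply_value_filters(m)
    m, dropped = filter_low_success_probes(m, threshold=success_threshold)
    report.n_probes_dropped_success = len(dropped)
    if ann is None:
        report.n_probes_out = m.shape[0]
        report.check()
        return m, report
    return filter_masked_and_sex_probes(m, mask, ann, report=report)
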