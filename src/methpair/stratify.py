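"""Variability stratification, probe-set overlap, and summary statistics.

Stratification follows the convention of reporting results genome-wide and
within the 10% most variable CpGs (by beta-value standard deviation).  The
decile size is the fraction of the probe count rounded half-up to the nearest
integer, the only rule consistent with reporting both a 75,926-probe decile
out of 759,263 and a 38,681-probe decile out of 386,805.  Percentages are
reported to one decimal, round-half-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import BetaMatrix, MethpairError

__all__ = [
    "ProbeSet",
    "SetSummary",
    "round_half_up",
    "percent",
    "top_decile_by_sd",
    "set_overlap_summary",
    "triple_overlap_venn",
    "summarize_estimates",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero upward)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(n: int, denominator: int, ndigits: int = 1) -> float:
    """Percentage n/denominator, round-half-up to ``ndigits`` decimals."""
    if denominator == 0:
        raise MethpairError("percentage with zero denominator")
    return round_half_up(100.0 * n / denominator, ndigits)


@dataclass(frozen=True)
class ProbeSet:
    """A named set of probe ids."""

    name: str
    probes: frozenset

    def __init__(self, name: str, probes):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "probes", frozenset(probes))

    def __len__(self) -> int:
        return len(self.probes)

    def intersection(self, other: "ProbeSet", name: str | None = None) -> "ProbeSet":
        return ProbeSet(
            name or f"{self.name}&{other.name}", self.probes & other.probes
        )


@dataclass
class SetSummary:
    """Count, percentage and estimate summary over one probe set."""

    n: int
    denominator: int
    percent: float
    mean_estimate: float
    median_estimate: float
    n_strong_significant: int = 0
    percent_strong_significant: float = float("nan")


def top_decile_by_sd(m: BetaMatrix, fraction: float = 0.10) -> ProbeSet:
    """The round_half_up(fraction·M) probes with the largest beta-value sd.

    Standard deviation is the sample sd (n−1) over non-missing entries; ties
    at the boundary are broken by probe id lexicographic order so the set is
    invariant to row order.
    """
    if not 0.0 < fraction <= 1.0:
        raise MethpairError("fraction must lie in (0, 1]")
    if m.beta.size == 0:
        raise MethpairError("cannot stratify an empty matrix")
    sd = m.beta.std(axis=1, ddof=1)
    k = int(round_half_up(fraction * len(sd)))
    # tie rule: sort by (-sd, probe_id) so the cut is order-invariant
    df = pd.DataFrame({"probe_id": sd.index, "sd": sd.to_numpy()})
    df = df.sort_values(["sd", "probe_id"], ascending=[False, True], kind="mergesort")
    return ProbeSet(f"top{fraction:g}_by_sd", df["probe_id"].head(k))


def set_overlap_summary(
    a: ProbeSet,
    b: ProbeSet,
    results: pd.DataFrame | None = None,
    denominator: int | None = None,
) -> tuple[ProbeSet, SetSummary]:
    """Intersection of two probe sets with a configurable-denominator summary.

    The default denominator is min(|a|, |b|) — appropriate when both sets are
    same-sized strata (e.g. two top deciles); pass ``denominator`` explicitly
    otherwise.  When ``results`` is given, mean/median of ``gee_estimate``
    over the intersection members (and strong∧significant counts) are
    reported.
    """
    inter = a.intersection(b)
    denom = denominator if denominator is not None else min(len(a), len(b))
    mean_est = median_est = float("nan")
    n_ss = 0
    pct_ss = float("nan")
    if results is not None and len(inter):
        sub = results.loc[results.index.isin(inter.probes)]
        est = sub["gee_estimate"].dropna()
        if len(est):
            mean_est = float(est.mean())
            median_est = float(est.median())
        n_ss = int((sub["significant"] & sub["strong"]).sum())
        pct_ss = percent(n_ss, len(inter)) if len(inter) else float("nan")
    summary = SetSummary(
        n=len(inter),
        denominator=denom,
        percent=percent(len(inter), denom) if denom else float("nan"),
        mean_estimate=mean_est,
        median_estimate=median_est,
        n_strong_significant=n_ss,
        percent_strong_significant=pct_ss,
    )
    return inter, summary


def triple_overlap_venn(
    s1: ProbeSet, s2: ProbeSet, s3: ProbeSet
) -> tuple[dict[str, int], ProbeSet]:
    """Counts of the seven Venn regions of three probe sets.

    Region labels use binary membership flags in (s1, s2, s3) order, e.g.
    ``"110"`` is members of s1 and s2 but not s3.  Also returns the triple
    intersection as a probe set.
    """
    A, B, C = s1.probes, s2.probes, s3.probes
    regions = {
        "100": len(A - B - C),
        "010": len(B - A - C),
        "001": len(C - A - B),
        "110": len((A & B) - C),
        "101": len((A & C) - B),
        "011": len((B & C) - A),
        "111": len(A & B & C),
    }
    triple = ProbeSet(f"{s1.name}&{s2.name}&{s3.name}", A & B & C)
    return regions, triple


def summarize_estimates(
    results: pd.DataFrame, subset: ProbeSet | None = None
) -> SetSummary:
    """Mean/median estimate and strong∧significant tally over a probe subset.

    ``subset=None`` summarizes all probes with non-missing estimates.
    """
    res = results
    if subset is not None:
        res = results.loc[results.index.isin(subset.probes)]
    est = res["gee_estimate"].dropna()
    if len(est) == 0:
        raise MethpairError("empty subset: no probes with non-missing estimates")
    n_ss = int((res["significant"] & res["strong"]).sum())
    return SetSummary(
        n=len(est),
        denominator=len(est),
        percent=100.0,
        mean_estimate=float(est.mean()),
        median_estimate=float(est.median()),
        n_strong_significant=n_ss,
        percent_strong_significant=percent(n_ss, len(est)),
    )
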