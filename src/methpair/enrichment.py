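"""mQTL prevalence summaries and trait-enrichment odds ratios.

A methylation QTL (mQTL) table maps probe ids to counts of associated genetic
variants, split into cis (nearby) and trans (distant).  Prevalence summaries
report, for a query probe set, how many members carry at least one
association, the total association count, and per-associated-CpG means —
the arithmetic used to compare a reliably-correlated CpG set against the
genome-wide background.

Trait enrichment is a 2×2 test of a query set against a trait's CpG catalog
within a stated universe: odds ratio with a Woolf 95% CI (Haldane–Anscombe
0.5 correction when any cell is zero) and a one-sided hypergeometric tail
p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MethpairError
from .stratify import ProbeSet, percent, round_half_up

__all__ = [
    "PrevalenceSummary",
    "read_mqtl_table",
    "mqtl_prevalence_summary",
    "trait_enrichment_odds_ratio",
    "prevalence_comparison",
    "simulate_mqtl_table",
]


@dataclass
class PrevalenceSummary:
    """mQTL-association prevalence of one probe set.

    Percentages are one-decimal round-half-up of count ratios; the
    per-associated-CpG mean is the total association count over the number
    of associated CpGs, rounded the same way.
    """

    n_query: int
    n_with_assoc: int
    prevalence_percent: float
    total_assoc: int
    cis_assoc: int
    trans_assoc: int
    mean_per_assoc_cpg: float
    median_per_assoc_cpg: float
    n_cis_cpgs: int
    n_trans_cpgs: int
    percent_cis_cpgs: float
    percent_trans_cpgs: float

    def check(self) -> None:
        if self.n_with_assoc > self.n_query:
            raise MethpairError("n_with_assoc exceeds n_query")
        if self.total_assoc != self.cis_assoc + self.trans_assoc:
            raise MethpairError("total_assoc != cis_assoc + trans_assoc")


def read_mqtl_table(path: str | Path) -> pd.DataFrame:
    """Read an mQTL table CSV with columns probe_id, n_cis, n_trans."""
    t = pd.read_csv(path)
    return validate_mqtl_table(t)


def validate_mqtl_table(table: pd.DataFrame) -> pd.DataFrame:
    for col in ("probe_id", "n_cis", "n_trans"):
        if col not in table.columns:
            raise MethpairError(f"mQTL table missing column {col!r}")
    if table["probe_id"].duplicated().any():
        raise MethpairError("mQTL table has duplicated probe ids")
    if (table[["n_cis", "n_trans"]] < 0).any().any():
        raise MethpairError("mQTL counts must be non-negative")
    return table


def mqtl_prevalence_summary(query: ProbeSet, table: pd.DataFrame) -> PrevalenceSummary:
    """Prevalence summary of ``query`` against an mQTL table.

    Probes absent from the table count as unassociated.  A CpG is
    cis-associated when n_cis ≥ 1 and trans-associated when n_trans ≥ 1
    (it may be both).
    """
    if len(query) == 0:
        raise MethpairError("empty query set")
    validate_mqtl_table(table)
    sub = table[table["probe_id"].isin(query.probes)]
    total = sub["n_cis"] + sub["n_trans"]
    assoc = sub[total > 0]
    n_assoc = len(assoc)
    total_assoc = int(total[total > 0].sum())
    cis_assoc = int(assoc["n_cis"].sum())
    trans_assoc = int(assoc["n_trans"].sum())
    n_cis = int((assoc["n_cis"] >= 1).sum())
    n_trans = int((assoc["n_trans"] >= 1).sum())
    per_cpg = (assoc["n_cis"] + assoc["n_trans"]).to_numpy()
    summary = PrevalenceSummary(
        n_query=len(query),
        n_with_assoc=n_assoc,
        prevalence_percent=percent(n_assoc, len(query)),
        total_assoc=total_assoc,
        cis_assoc=cis_assoc,
        trans_assoc=trans_assoc,
        mean_per_assoc_cpg=round_half_up(total_assoc / n_assoc, 1)
        if n_assoc
        else float("nan"),
        median_per_assoc_cpg=float(np.median(per_cpg)) if n_assoc else float("nan"),
        n_cis_cpgs=n_cis,
        n_trans_cpgs=n_trans,
        percent_cis_cpgs=percent(n_cis, len(query)),
        percent_trans_cpgs=percent(n_trans, len(query)),
    )
    summary.check()
    return summary


def trait_enrichment_odds_ratio(
    a: int, query_size: int, background_hits: int, universe: int
) -> dict:
    """2×2 enrichment of a query set against a trait catalog.

    ``a`` query probes are in the catalog, out of ``query_size`` query probes
    and ``background_hits`` catalog probes within ``universe``.  Returns the
    odds ratio, the one-sided hypergeometric enrichment p-value
    P[X ≥ a], and a Woolf 95% CI on the log odds ratio; when any 2×2 cell is
    zero the Haldane–Anscombe 0.5 correction is applied to the OR and CI
    (the p-value uses the uncorrected table).
    """
    if a < 0 or a > min(query_size, background_hits):
        raise MethpairError("a must satisfy 0 <= a <= min(query, hits)")
    if background_hits > universe or query_size > universe:
        raise MethpairError("query and hits must fit inside the universe")
    b = query_size - a
    c = background_hits - a
    d = universe - query_size - background_hits + a
    if d < 0:
        raise MethpairError("inconsistent counts: universe too small")

    p = float(stats.hypergeom.sf(a - 1, universe, background_hits, query_size))

    cells = np.array([a, b, c, d], dtype=float)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    oddsr = (a_ * d_) / (b_ * c_)
    se_log = math.sqrt(1.0 / a_ + 1.0 / b_ + 1.0 / c_ + 1.0 / d_)
    lo = math.exp(math.log(oddsr) - 1.959963984540054 * se_log)
    hi = math.exp(math.log(oddsr) + 1.959963984540054 * se_log)
    return {
        "odds_ratio": float(oddsr),
        "p_value": p,
        "ci95": (float(lo), float(hi)),
        "corrected": corrected,
        "table": (int(a), int(query_size - a), int(background_hits - a), int(d)),
    }


def prevalence_comparison(
    query: PrevalenceSummary, baseline: PrevalenceSummary
) -> dict:
    """Compare two prevalence summaries: the percentage pair and their ratio."""
    pair = (query.prevalence_percent, baseline.prevalence_percent)
    if baseline.prevalence_percent == 0:
        return {"percent_pair": pair, "ratio": float("nan"), "ratio_defined": False}
    return {
        "percent_pair": pair,
        "ratio": query.prevalence_percent / baseline.prevalence_percent,
        "ratio_defined": True,
    }


def simulate_mqtl_table(
    probe_ids,
    prevalence: float = 0.36,
    mean_cis: float = 2.0,
    mean_trans: float = 0.2,
    reliability: pd.Series | None = None,
    reliability_boost: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic mQTL table with configurable prevalence.

    Each probe is associated with probability ``prevalence``; when a per-probe
    ``reliability`` score in [0, 1] is given, the probability is raised by
    ``reliability_boost``·score (clipped to [0, 1]) so reliably measured CpGs
    carry more genetic signal — the pattern prevalence comparisons exist to
    detect.  Associated probes draw 1 + Poisson counts for cis and trans.
    """
    rng = np.random.default_rng(seed)
    probe_ids = pd.Index(probe_ids)
    p = np.full(len(probe_ids), prevalence)
    if reliability is not None:
        boost = reliability.reindex(probe_ids).fillna(0.0).to_numpy()
        p = np.clip(p + reliability_boost * boost, 0.0, 1.0)
    assoc = rng.random(len(probe_ids)) < p
    n_cis = np.zeros(len(probe_ids), dtype=int)
    n_trans = np.zeros(len(probe_ids), dtype=int)
    k = int(assoc.sum())
    n_cis[assoc] = 1 + rng.poisson(mean_cis, size=k)
    n_trans[assoc] = rng.poisson(mean_trans, size=k)
    return pd.DataFrame({"probe_id": probe_ids, "n_cis": n_cis, "n_trans": n_trans})
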