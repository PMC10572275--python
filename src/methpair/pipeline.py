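"""End-to-end orchestration: simulate → QC → preprocess → correlate → overlap → enrich.

A single YAML config drives the whole chain on synthetic twin-family data.
Every stage writes its tabular outputs under the run directory, a log records
probe-count deltas after each filter, and a machine-readable manifest pins
the seed, thresholds and output checksums so a rerun at the same seed is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import (
    DESIGNS,
    BetaMatrix,
    ComparisonDesign,
    MethpairError,
    write_matrix_tsv,
    write_probe_list,
)
from .correlate import PairedCorrelationGEE, write_results_tsv
from .enrichment import (
    mqtl_prevalence_summary,
    prevalence_comparison,
    simulate_mqtl_table,
)
from .preprocess import residualize_technical, standardize_probes
from .qc import run_probe_qc
from .simulate import (
    SimulationConfig,
    config_to_dict,
    inject_qc_failures,
    simulate_paired_betas,
    simulate_sample_sheet,
)
from .stratify import ProbeSet, set_overlap_summary, summarize_estimates, top_decile_by_sd, triple_overlap_venn

__all__ = ["PipelineConfig", "run_pipeline", "probe_scatter_report"]

logger = logging.getLogger("methpair")


@dataclass
class Thresholds:
    alpha: float = 0.05
    r_threshold: float = 0.50
    success: float = 0.95
    detp: float = 0.01
    beads: int = 3
    variability_fraction: float = 0.10
    min_pairs: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise MethpairError("alpha must lie in [0, 1]")
        if not 0.0 < self.success <= 1.0:
            raise MethpairError("success threshold must lie in (0, 1]")
        if not 0.0 < self.variability_fraction <= 1.0:
            raise MethpairError("variability_fraction must lie in (0, 1]")


@dataclass
class PipelineConfig:
    """Run configuration; ``simulation`` holds the synthetic study conditions."""

    out_dir: str = "methpair_run"
    designs: tuple[str, ...] = DESIGNS
    covariates: tuple[str, ...] = ("plate", "row")
    thresholds: Thresholds = field(default_factory=Thresholds)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # synthetic annotation/mask structure
    mask_fraction: float = 0.03
    sex_fraction: float = 0.02
    mqtl_prevalence: float = 0.36
    seed: int = 0

    def __post_init__(self) -> None:
        bad = [d for d in self.designs if d not in DESIGNS]
        if bad:
            raise MethpairError(f"unknown designs: {bad}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        sim_raw = raw.pop("simulation", {})
        sim_raw.setdefault("seed", raw.get("seed", 0))
        if "family_template" in sim_raw:
            sim_raw["family_template"] = tuple(sim_raw["family_template"])
        sim = SimulationConfig(**sim_raw)
        if "designs" in raw:
            raw["designs"] = tuple(raw["designs"])
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(thresholds=thr, simulation=sim, **raw)


def _synthetic_annotation(
    probe_ids: pd.Index, sex_fraction: float, seed: int
) -> pd.DataFrame:
    """Synthetic probe annotation: mostly autosomal, a seeded fraction on X/Y."""
    rng = np.random.default_rng((seed, 101))
    chroms = np.array([str(1 + i % 22) for i in range(len(probe_ids))], dtype=object)
    n_sex = int(round(sex_fraction * len(probe_ids)))
    if n_sex:
        pick = rng.choice(len(probe_ids), size=n_sex, replace=False)
        half = n_sex // 2
        chroms[pick[:half]] = "X"
        chroms[pick[half:]] = "Y"
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chromosome": chroms,
            "position": np.arange(1, len(probe_ids) + 1) * 1000,
            "gene": "",
        }
    )


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages per design; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    thr = config.thresholds
    sim = config.simulation
    try:
        sheet = simulate_sample_sheet(sim)
        sheet.to_csv(out / "sample_sheet.csv", index=False)
        logger.info("sample sheet: %d samples", len(sheet))

        strong_sets: dict[str, ProbeSet] = {}
        all_results: dict[str, pd.DataFrame] = {}
        true_rho_by_design: dict[str, pd.Series] = {}
        summaries = []
        for design in config.designs:
            ddir = out / design
            ddir.mkdir(exist_ok=True)
            stage = f"{design}/simulate"
            try:
                A, B, true_rho = simulate_paired_betas(sim, sheet, design)
                A = inject_qc_failures(A, sim)
                B = inject_qc_failures(B, sim)
                true_rho.to_frame().to_csv(ddir / "true_rho.tsv", sep="\t")
                true_rho_by_design[design] = true_rho

                stage = f"{design}/qc"
                ann = _synthetic_annotation(
                    A.beta.index, config.sex_fraction, sim.seed
                )
                ann.to_csv(ddir / "annotation.csv", index=False)
                rng_mask = np.random.default_rng((sim.seed, 102))
                mask = set(
                    rng_mask.choice(
                        A.beta.index,
                        size=int(round(config.mask_fraction * len(A.beta.index))),
                        replace=False,
                    )
                )
                write_probe_list(sorted(mask), ddir / "mask.txt")
                qcA, repA = run_probe_qc(A, mask, ann, thr.success)
                qcB, repB = run_probe_qc(B, mask, ann, thr.success)
                repA.write(ddir / "qc_report_a.txt")
                repB.write(ddir / "qc_report_b.txt")
                common = qcA.beta.index.intersection(qcB.beta.index, sort=False)
                qcA, qcB = qcA.subset_probes(common), qcB.subset_probes(common)
                logger.info(
                    "%s qc: %d -> %d probes (A: %d masked entries, B: %d)",
                    design, sim.n_probes, len(common),
                    repA.n_entries_masked, repB.n_entries_masked,
                )

                stage = f"{design}/preprocess"
                za = standardize_probes(
                    residualize_technical(qcA, sheet, config.covariates)
                )
                zb = standardize_probes(
                    residualize_technical(qcB, sheet, config.covariates)
                )

                stage = f"{design}/correlate"
                cd = ComparisonDesign.from_sheet(sheet, design)
                est = PairedCorrelationGEE(min_pairs=thr.min_pairs)
                est.fit(za, zb, cd, beta_a=qcA.beta, beta_b=qcB.beta)
                n_tests = int(est.results_["gee_estimate"].notna().sum())
                results = est.classify(
                    alpha=thr.alpha, r_threshold=thr.r_threshold, n_tests=n_tests
                )
                write_results_tsv(results, ddir / "results.tsv")
                all_results[design] = results

                stage = f"{design}/overlap"
                dec_a = top_decile_by_sd(qcA, thr.variability_fraction)
                dec_b = top_decile_by_sd(qcB, thr.variability_fraction)
                inter, osum = set_overlap_summary(dec_a, dec_b, results)
                write_probe_list(sorted(inter.probes), ddir / "top_decile_shared.txt")
                gsum = summarize_estimates(results)
                strong = ProbeSet(
                    design,
                    results.index[results["significant"] & results["strong"]],
                )
                strong_sets[design] = strong
                write_probe_list(sorted(strong.probes), ddir / "strong_significant.txt")
                summaries.append(
                    {
                        "design": design,
                        "n_pairs": cd.n_pairs,
                        "n_probes_tested": n_tests,
                        "mean_estimate": gsum.mean_estimate,
                        "median_estimate": gsum.median_estimate,
                        "n_strong_significant": gsum.n_strong_significant,
                        "percent_strong_significant": gsum.percent_strong_significant,
                        "decile_overlap_n": osum.n,
                        "decile_overlap_percent": osum.percent,
                    }
                )
                logger.info(
                    "%s: %d pairs, mean r=%.3f, %d strong+significant",
                    design, cd.n_pairs, gsum.mean_estimate, gsum.n_strong_significant,
                )
            except MethpairError as err:
                raise MethpairError(f"stage {stage} failed: {err}") from err

        pd.DataFrame(summaries).to_csv(out / "design_summaries.csv", index=False)

        if len(strong_sets) == 3:
            regions, triple = triple_overlap_venn(*strong_sets.values())
            pd.DataFrame(
                {"region": list(regions), "count": list(regions.values())}
            ).to_csv(out / "venn_counts.csv", index=False)
            write_probe_list(sorted(triple.probes), out / "triple_overlap.txt")
        else:
            triple = None

        # enrichment against a synthetic mQTL catalog whose prevalence rises
        # with the true pairing correlation
        rho_ref = next(iter(true_rho_by_design.values()))
        mqtl = simulate_mqtl_table(
            rho_ref.index,
            prevalence=config.mqtl_prevalence,
            reliability=rho_ref,
            seed=sim.seed,
        )
        mqtl.to_csv(out / "mqtl_table.csv", index=False)
        background = ProbeSet("background", mqtl["probe_id"])
        base_summary = mqtl_prevalence_summary(background, mqtl)
        enrich_rows = [{"set": "background", **base_summary.__dict__}]
        for name, pset in strong_sets.items():
            if len(pset) == 0:
                continue
            s = mqtl_prevalence_summary(pset, mqtl)
            cmp_ = prevalence_comparison(s, base_summary)
            enrich_rows.append(
                {"set": name, **s.__dict__, "prevalence_ratio_vs_background": cmp_["ratio"]}
            )
        if triple is not None and len(triple):
            s = mqtl_prevalence_summary(triple, mqtl)
            cmp_ = prevalence_comparison(s, base_summary)
            enrich_rows.append(
                {"set": "overlap", **s.__dict__, "prevalence_ratio_vs_background": cmp_["ratio"]}
            )
        pd.DataFrame(enrich_rows).to_csv(out / "mqtl_prevalence.csv", index=False)

        manifest = {
            "package": "methpair",
            "version": __version__,
            "seed": config.seed,
            "designs": list(config.designs),
            "covariates": list(config.covariates),
            "thresholds": dict(thr.__dict__),
            "simulation": config_to_dict(sim),
            "outputs": {},
        }
        for path in sorted(out.rglob("*")):
            if path.is_file() and path.name not in ("manifest.json", "run.log"):
                manifest["outputs"][str(path.relative_to(out))] = _checksum(path)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        logger.info("run complete: %s", out)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def probe_scatter_report(
    probe_ids: Sequence[str],
    matrices: tuple[BetaMatrix, BetaMatrix],
    results: pd.DataFrame,
    design: ComparisonDesign,
    out_dir: str | Path,
    sheet: Optional[pd.DataFrame] = None,
    highlight: Optional[str] = None,
) -> list[Path]:
    """Scatter of paired beta values per probe, annotated with the estimate.

    Writes one PNG and one CSV of plotted values per probe.  ``highlight``
    names a sample-sheet column used to color points by the first member's
    value; if the column is absent a warning is logged and the plot is
    emitted uncolored.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    A, B = matrices
    written: list[Path] = []
    color_by = None
    if highlight is not None:
        if sheet is not None and highlight in sheet.columns:
            color_by = sheet.set_index("sample_id")[highlight]
        else:
            logger.warning("highlight column %r absent; plotting uncolored", highlight)

    for probe in probe_ids:
        if probe not in results.index:
            raise MethpairError(f"unknown probe {probe!r}")
        xa = A.beta.loc[probe, design.pairs["sample_a"]].to_numpy()
        xb = B.beta.loc[probe, design.pairs["sample_b"]].to_numpy()
        ok = np.isfinite(xa) & np.isfinite(xb)
        df = pd.DataFrame(
            {
                "individual_id": design.pairs["individual_id"].to_numpy()[ok],
                "beta_a": xa[ok],
                "beta_b": xb[ok],
            }
        )
        csv_path = out_dir / f"{probe}_{design.design}.csv"
        df.to_csv(csv_path, index=False)
        written.append(csv_path)

        fig, ax = plt.subplots(figsize=(4.2, 4))
        if color_by is not None:
            cvals = color_by.reindex(design.pairs["sample_a"]).to_numpy()[ok]
            codes = pd.Categorical(cvals).codes if cvals.dtype == object else cvals
            sc = ax.scatter(df["beta_a"], df["beta_b"], c=codes, s=16, cmap="coolwarm")
        else:
            ax.scatter(df["beta_a"], df["beta_b"], s=16, color="#336699")
        est = results.loc[probe, "gee_estimate"]
        ax.set_xlabel("beta, measurement A")
        ax.set_ylabel("beta, measurement B")
        ax.set_title(f"{probe} ({design.design}) r = {est:.2f}")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        fig.tight_layout()
        png_path = out_dir / f"{probe}_{design.design}.png"
        fig.savefig(png_path, dpi=110)
        plt.close(fig)
        written.append(png_path)
    return written
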