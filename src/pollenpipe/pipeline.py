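"""End-to-end orchestration: simulate (or load) inputs, run every analysis
stage in dependency order, and emit a machine-readable run report.

Stage order: counts -> QC -> genotyping -> clustering -> DE -> target-set
summaries, with the methylome/MPG, timecourse, and morphometry branches
independent. A stage failure marks the stage failed and skips dependents.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexp, morphometry, sc_expression, timecourse
from . import methylome as methylome_mod
from .genotyping import genotype_table, segregation_chi2
from .synthetic_data import (
    GENOTYPE_CLASSES,
    SimulationConfig,
    TruthBundle,
    simulate_methylome_and_tissue_tpm,
    simulate_pollen_experiment,
    simulate_sentinel_evidence,
    simulate_timecourse_and_areas,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Single configuration object for a full pipeline run."""

    outdir: str = "pollenpipe_run"
    seed: int = 0
    counts_path: str | None = None  # load instead of simulating when set
    run_expression: bool = True
    run_methylome: bool = True
    run_timecourse: bool = True
    run_morphometry: bool = True
    simulation: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)  # threshold, min_gap
    genotyping: dict = field(default_factory=dict)  # coverage_mean, recombination_prob, min_reads, majority
    clustering: dict = field(default_factory=dict)  # min_mean_tpm, linkage_method
    de: dict = field(default_factory=dict)  # alpha
    methylome: dict = field(default_factory=dict)  # n_genes, n_mpg, class_mix ...
    timecourse: dict = field(default_factory=dict)  # reference, bandwidth
    morphometry: dict = field(default_factory=dict)  # size_range, circ_range

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.counts_path is not None and not os.path.exists(self.counts_path):
            raise FileNotFoundError(f"counts file not found: {self.counts_path}")
        if not self.run_expression and self.counts_path is None and (
            self.genotyping or self.clustering or self.de
        ):
            # downstream expression stages need counts from somewhere
            raise ValueError("expression stages configured but no counts source enabled")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages; write report.json + report.txt to outdir.

    Returns the report dict. Identical config + seed => identical report.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "parameters": dataclasses.asdict(config),
        "stages": {},
        "summaries": {},
    }
    failed: set[str] = set()

    def stage(name: str, depends: tuple[str, ...] = ()):
        def deco(fn):
            if any(d in failed for d in depends):
                report["stages"][name] = {"status": "skipped", "reason": "upstream failure"}
                failed.add(name)
                return None
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as exc:  # noqa: BLE001 - report and continue
                report["stages"][name] = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
                failed.add(name)
                return None
            report["stages"][name] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
            }
            return out

        return deco

    counts = truth = None
    if config.run_expression or config.counts_path:

        @stage("counts")
        def _counts():
            if config.counts_path:
                return pd.read_csv(config.counts_path, sep="\t", index_col=0), TruthBundle()
            sim = SimulationConfig(**{"seed": config.seed, **config.simulation})
            c, t = simulate_pollen_experiment(sim)
            c.to_csv(outdir / "counts.tsv", sep="\t")
            t.to_json(outdir / "truth.json")
            return c, t

        if _counts is not None:
            counts, truth = _counts

        @stage("qc", depends=("counts",))
        def _qc():
            rep = sc_expression.filter_low_complexity(counts, **config.qc)
            rep.table.to_csv(outdir / "qc.tsv", sep="\t")
            report["summaries"]["qc"] = {
                "n_samples": int(counts.shape[1]),
                "n_kept": len(rep.kept),
                "n_excluded": len(rep.excluded),
            }
            return rep

        qc = _qc

        @stage("genotyping", depends=("qc",))
        def _genotyping():
            gt_cfg = dict(config.genotyping)
            call_kw = {
                k: gt_cfg.pop(k) for k in ("min_reads", "majority") if k in gt_cfg
            }
            kept_genotypes = {g: truth.genotypes[g] for g in qc.kept if g in truth.genotypes}
            if not kept_genotypes:
                raise ValueError("no truth genotypes available; genotyping needs simulated data")
            support, sent_cfg, _ = simulate_sentinel_evidence(
                kept_genotypes, seed=config.seed + 1, **gt_cfg
            )
            support.to_csv(outdir / "sentinel_support.tsv", sep="\t", index=False)
            table = genotype_table(support, sent_cfg, **call_kw)
            table.to_csv(outdir / "genotypes.tsv", sep="\t")
            called = table[table["genotype"] != "ambiguous"]["genotype"]
            counts_by_class = [int((called == c).sum()) for c in GENOTYPE_CLASSES]
            chi2 = df = p = None
            if sum(counts_by_class) > 0 and min(counts_by_class) >= 0:
                chi2, df, p = segregation_chi2(counts_by_class, [0.25] * 4)
            report["summaries"]["genotyping"] = {
                "class_counts": dict(zip(GENOTYPE_CLASSES, counts_by_class)),
                "n_ambiguous": int((table["genotype"] == "ambiguous").sum()),
                "segregation_chi2": chi2,
                "segregation_df": df,
                "segregation_p": p,
            }
            return table

        genotypes = _genotyping

        @stage("clustering", depends=("qc",))
        def _clustering():
            kept = counts[qc.kept]
            norm = sc_expression.normalize_tpm(kept)
            corr, Z, labels = sc_expression.correlate_and_cluster(norm, **config.clustering)
            corr.to_csv(outdir / "correlation.tsv", sep="\t")
            labels.to_csv(outdir / "clusters.tsv", sep="\t")
            truth_double = {g for g, c in truth.genotypes.items() if c == "double" and g in labels.index}
            separation = None
            if truth_double:
                double_labels = set(labels[list(truth_double)])
                other_labels = set(labels[[g for g in labels.index if g not in truth_double]])
                separation = bool(len(double_labels) == 1 and double_labels.isdisjoint(other_labels))
            report["summaries"]["clustering"] = {
                "cluster_sizes": labels.value_counts().sort_index().to_dict(),
                "double_mutant_separated": separation,
            }
            return labels

        @stage("de", depends=("qc", "genotyping"))
        def _de():
            kept = counts[qc.kept]
            geno = genotypes["genotype"].reindex(kept.columns)
            usable = geno[geno != "ambiguous"].index
            sub = kept[usable]
            is_double = (geno.loc[usable] == "double").to_numpy()
            res = diffexp.run_differential_expression(sub, is_double, **config.de)
            res.to_csv(outdir / "de_results.tsv", sep="\t")
            strong = res.index[res["class"] == "strong_DEG"]
            summary = diffexp.summarize_target_set(
                sub, list(strong) if len(strong) else truth.target_genes, geno.loc[usable]
            )
            report["summaries"]["differential_expression"] = {
                "n_strong_DEG": int((res["class"] == "strong_DEG").sum()),
                "n_weak_DEG": int((res["class"] == "weak_DEG").sum()),
                "target_set_fraction_by_group": summary["per_group_fraction"],
                "target_set_median_fold": summary["median_fold"],
            }
            return res

    if config.run_methylome:

        @stage("methylome")
        def _methylome():
            kw = {"seed": config.seed + 2, **config.methylome}
            sites, cds, te, tissue_expr, mtruth = simulate_methylome_and_tissue_tpm(**kw)
            summary = methylome_mod.summarize_gene_methylation(sites, cds)
            classes = methylome_mod.classify_epialleles(summary)
            overlap = methylome_mod.flag_cds_te_overlap(cds, te)
            mpgs = methylome_mod.select_mpgs(tissue_expr, classes, te_overlap=overlap)
            out = summary.assign(epiallele=classes, te_overlap=overlap)
            out.to_csv(outdir / "epialleles.tsv", sep="\t")
            report["summaries"]["methylome"] = {
                "class_counts": classes.value_counts().to_dict(),
                "n_te_overlap": int(overlap.sum()),
                "n_mpg": len(mpgs),
                "mpg_recovered_exactly": sorted(mpgs) == sorted(mtruth.mpg_genes),
            }
            return mpgs

    if config.run_timecourse:

        @stage("timecourse")
        def _timecourse():
            kw = dict(config.timecourse)
            reference = kw.pop("reference", "pollen")
            bandwidth = kw.pop("bandwidth", None)
            samples, _, ttruth = simulate_timecourse_and_areas(seed=config.seed + 3, **kw)
            samples.to_csv(outdir / "timecourse_samples.tsv", sep="\t")
            stage_means = samples.groupby("stage")["total_umis"].mean().to_dict()
            factors = timecourse.stage_scale_factors(stage_means, reference=reference)
            pt = samples["pseudotime"].to_numpy()
            h = bandwidth if bandwidth is not None else timecourse.silverman_bandwidth(pt)
            scaled_totals = samples["total_umis"].to_numpy(float) * samples["stage"].map(factors).to_numpy()
            grid, smoothed = timecourse.kernel_smooth(scaled_totals, pt, bandwidth=h)
            pd.DataFrame({"pseudotime": grid, "smoothed": smoothed}).to_csv(
                outdir / "timecourse_smoothed.tsv", sep="\t", index=False
            )
            report["summaries"]["timecourse"] = {
                "stage_scale_factors": {k: round(v, 6) for k, v in factors.items()},
                "bandwidth": float(h),
                "true_stage_means": ttruth.stage_means,
            }
            return factors

    if config.run_morphometry:

        @stage("morphometry")
        def _morphometry():
            kw = dict(config.morphometry)
            filt = {k: kw.pop(k) for k in ("size_range", "circ_range") if k in kw}
            _, particles, _ = simulate_timecourse_and_areas(seed=config.seed + 4, **kw)
            kept = morphometry.filter_particles(particles, **filt)
            fit = morphometry.fit_bimodal_areas(kept["area"].to_numpy())
            report["summaries"]["morphometry"] = {
                "n_particles": int(len(particles)),
                "n_kept": int(len(kept)),
                **{k: v for k, v in fit.to_dict().items() if k != "loglik_trace"},
            }
            return fit

    report["exit_ok"] = not failed
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
    with open(outdir / "report.txt", "w") as fh:
        fh.write(_render_text(report))
    return report


def _render_text(report: dict) -> str:
    lines = ["pollenpipe run report", "=" * 21, ""]
    for name, st in report["stages"].items():
        lines.append(f"[{st['status']}] {name}")
    lines.append("")
    for block, values in report["summaries"].items():
        lines.append(block)
        for k, v in values.items():
            lines.append(f"  {k}: {v}")
        lines.append("")
    return "\n".join(lines)
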