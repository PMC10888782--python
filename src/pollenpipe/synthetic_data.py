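"""Ground-truth simulator for every input the pipeline consumes.

Generates: a haploid single-grain UMI count matrix segregating four genotype
classes with a silenced target-gene set in the double mutant; sentinel-gene
allele-support tables with configurable recombination; a synthetic methylome
(per-site CDS calls, CDS/TE intervals, multi-tissue TPM) with teM/gbM/UM
epiallele classes and planted methylated pollen genes; a developmental
timecourse sample table with stage-dependent transcript totals; and a
two-component pollen-area particle table. Every observable carries a truth
label for recovery testing.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .celseq_ingest import ReadRecord
from .genotyping import AMBIGUOUS, MUTANT, WILDTYPE, SentinelConfig
from .methylome import Interval, TissueExpression

__all__ = [
    "GENOTYPE_CLASSES",
    "LOCI",
    "SimulationConfig",
    "TruthBundle",
    "simulate_pollen_experiment",
    "simulate_sentinel_evidence",
    "simulate_methylome_and_tissue_tpm",
    "simulate_timecourse_and_areas",
    "simulate_celseq_reads",
    "write_sentinel_support",
    "write_sites_tsv",
    "write_tissue_tpm",
    "write_timecourse_tsv",
    "write_particles_csv",
]

LOCI = ("locus1", "locus2")
GENOTYPE_CLASSES = ("WT", "single_locus1", "single_locus2", "double")

_MUTANT_AT = {
    "locus1": {"single_locus1", "double"},
    "locus2": {"single_locus2", "double"},
}


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the single-grain transcriptome simulation.

    Defaults mirror the reference experiment: 26 usable grains plus 21
    low-complexity ones, a 58-gene target set silenced ~124-fold in the
    double mutant and summing to ~11.1% of wild-type transcripts, and
    bimodal per-grain library sizes (~550k vs ~5.4k UMIs).
    """

    n_grains: int = 26
    n_low_complexity: int = 21
    n_genes: int = 5000
    n_target_genes: int = 58
    target_genes: list[str] | None = None
    n_target_clusters: int = 6
    silencing_fold: float = 124.1
    wt_target_fraction: float = 0.111
    depth_mean_high: float = 549_559.0
    depth_mean_low: float = 5_444.0
    depth_sigma: float = 0.35
    genotype_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    recombination_prob: float = 0.06
    dispersion: float = 0.05
    target_sigma: float = 0.6  # log-normal spread of target-gene abundances
    background_sigma: float = 1.2
    min_per_class: int = 2
    seed: int = 0

    def __post_init__(self):
        probs = np.asarray(self.genotype_probs, dtype=float)
        if len(probs) != 4 or (probs < 0).any() or (probs > 1).any():
            raise ConfigurationError("genotype_probs must be 4 proportions in [0,1]")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ConfigurationError("genotype_probs must sum to 1")
        if not self.silencing_fold > 1:
            raise ConfigurationError("silencing_fold must be > 1")
        for name in ("wt_target_fraction", "recombination_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0,1]")
        if self.n_grains < 0 or self.n_low_complexity < 0:
            raise ConfigurationError("grain counts must be non-negative")
        if self.n_target_genes > self.n_genes:
            raise ConfigurationError("more target genes than genes")


@dataclass
class TruthBundle:
    """Ground-truth labels attached to simulated observables."""

    genotypes: dict[str, str] = field(default_factory=dict)
    depth_class: dict[str, str] = field(default_factory=dict)
    target_genes: list[str] = field(default_factory=list)
    gene_clusters: dict[str, int] = field(default_factory=dict)
    sentinel_alleles: dict[str, dict[str, str]] = field(default_factory=dict)
    recombinant_flanks: dict[str, list[list[str]]] = field(default_factory=dict)
    expected_locus_calls: dict[str, dict[str, str]] = field(default_factory=dict)
    epialleles: dict[str, str] = field(default_factory=dict)
    mpg_genes: list[str] = field(default_factory=list)
    te_overlap_genes: list[str] = field(default_factory=list)
    particle_components: list[str] = field(default_factory=list)
    stage_means: dict[str, float] = field(default_factory=dict)

    def merge(self, other: "TruthBundle") -> "TruthBundle":
        merged = TruthBundle()
        for f in dataclasses.fields(TruthBundle):
            a = getattr(self, f.name)
            b = getattr(other, f.name)
            if isinstance(a, dict):
                setattr(merged, f.name, {**a, **b})
            else:
                setattr(merged, f.name, b if b else a)
        return merged

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _lognormal_with_mean(rng, mean: float, sigma: float, size: int) -> np.ndarray:
    mu = np.log(mean) - sigma**2 / 2.0
    return rng.lognormal(mu, sigma, size=size)


def _nb_counts(rng, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu)
    return rng.poisson(lam)


def _draw_genotypes(rng, n: int, probs, min_per_class: int) -> list[str]:
    """Multinomial genotype draw, redrawn until each class has at least
    min_per_class members (skipped when n is too small to allow it)."""
    probs = np.asarray(probs, dtype=float)
    enforce = min_per_class > 0 and n >= 4 * min_per_class and (probs > 0).all()
    for _ in range(10_000):
        idx = rng.choice(4, size=n, p=probs)
        if not enforce or np.bincount(idx, minlength=4).min() >= min_per_class:
            return [GENOTYPE_CLASSES[i] for i in idx]
    raise RuntimeError("could not draw genotypes satisfying min_per_class")


def simulate_pollen_experiment(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, TruthBundle]:
    """Simulate the gene x grain UMI count matrix plus truth labels.

    Counts are negative-binomial with per-grain depth drawn log-normally.
    Target genes' expected share is ``wt_target_fraction`` in non-double
    grains and is divided by ``silencing_fold`` (then renormalized) in
    double-mutant grains. Low-complexity grains are appended after the
    high-depth ones.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]

    if config.target_genes is not None:
        targets = list(config.target_genes)
        unknown = set(targets) - set(genes)
        if unknown:
            raise ConfigurationError(f"target genes outside gene universe: {sorted(unknown)}")
    else:
        targets = sorted(rng.choice(genes, size=config.n_target_genes, replace=False).tolist())

    # genomic-cluster metadata for half the targets (not used generatively)
    clusters: dict[str, int] = {}
    if targets and config.n_target_clusters > 0:
        clustered = targets[: len(targets) // 2]
        for i, g in enumerate(clustered):
            clusters[g] = i % config.n_target_clusters + 1

    n_total = config.n_grains + config.n_low_complexity
    grains = [f"pg{i + 1:02d}" for i in range(n_total)]
    if n_total == 0 or config.n_genes == 0:
        counts = pd.DataFrame(
            np.zeros((config.n_genes, 0), dtype=int), index=genes, columns=[]
        )
        counts.index.name = "gene"
        return counts, TruthBundle(target_genes=targets, gene_clusters=clusters)

    genotypes_hi = _draw_genotypes(
        rng, config.n_grains, config.genotype_probs, config.min_per_class
    )
    genotypes_lo = _draw_genotypes(rng, config.n_low_complexity, config.genotype_probs, 0)
    genotypes = genotypes_hi + genotypes_lo
    depth_class = ["high"] * config.n_grains + ["low"] * config.n_low_complexity

    is_target = np.isin(genes, targets)
    w = np.empty(config.n_genes)
    bg = rng.lognormal(0.0, config.background_sigma, size=int((~is_target).sum()))
    w[~is_target] = bg / bg.sum() * (1.0 - config.wt_target_fraction)
    if is_target.any():
        tg = rng.lognormal(0.0, config.target_sigma, size=int(is_target.sum()))
        w[is_target] = tg / tg.sum() * config.wt_target_fraction

    depths = np.concatenate(
        [
            _lognormal_with_mean(rng, config.depth_mean_high, config.depth_sigma, config.n_grains),
            _lognormal_with_mean(
                rng, config.depth_mean_low, config.depth_sigma, config.n_low_complexity
            ),
        ]
    )

    mat = np.zeros((config.n_genes, n_total), dtype=np.int64)
    for j, (gt, depth) in enumerate(zip(genotypes, depths)):
        p = w.copy()
        if gt == "double":
            p[is_target] /= config.silencing_fold
            p /= p.sum()
        mat[:, j] = _nb_counts(rng, depth * p, config.dispersion)

    counts = pd.DataFrame(mat, index=genes, columns=grains)
    counts.index.name = "gene"
    truth = TruthBundle(
        genotypes=dict(zip(grains, genotypes)),
        depth_class=dict(zip(grains, depth_class)),
        target_genes=targets,
        gene_clusters=clusters,
    )
    return counts, truth


def default_sentinel_config(n_per_side: int = 3) -> SentinelConfig:
    if n_per_side < 1:
        raise ConfigurationError("need at least 1 sentinel per side")
    loci = {
        locus: {
            "left": [f"{locus}_left{i + 1}" for i in range(n_per_side)],
            "right": [f"{locus}_right{i + 1}" for i in range(n_per_side)],
        }
        for locus in LOCI
    }
    return SentinelConfig(loci=loci)


def simulate_sentinel_evidence(
    genotypes: Mapping[str, str],
    n_sentinels_per_side: int = 3,
    coverage_mean: float = 8.0,
    recombination_prob: float | Mapping[str, float] = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SentinelConfig, TruthBundle]:
    """Simulate allele-diagnostic read support over sentinel genes.

    Per grain and locus, each flank independently recombines with
    ``recombination_prob`` (scalar, or a per-locus mapping), flipping every
    sentinel on that flank to the opposite haplotype. Per-sentinel coverage
    is Poisson, so zero-coverage (ambiguous) sentinels arise naturally; all
    reads support the flank's haplotype.
    """
    rng = np.random.default_rng(seed)
    config = default_sentinel_config(n_sentinels_per_side)
    if isinstance(recombination_prob, Mapping):
        rec = {locus: float(recombination_prob.get(locus, 0.0)) for locus in LOCI}
    else:
        rec = {locus: float(recombination_prob) for locus in LOCI}

    rows = []
    truth = TruthBundle()
    for grain, gt in genotypes.items():
        if gt not in GENOTYPE_CLASSES:
            raise ConfigurationError(f"unknown genotype class {gt!r} for grain {grain!r}")
        truth.sentinel_alleles[grain] = {}
        truth.recombinant_flanks[grain] = []
        truth.expected_locus_calls[grain] = {}
        for locus in LOCI:
            true_allele = MUTANT if gt in _MUTANT_AT[locus] else WILDTYPE
            flank_alleles = {}
            for side in ("left", "right"):
                flipped = rng.random() < rec[locus]
                allele = (
                    (WILDTYPE if true_allele == MUTANT else MUTANT) if flipped else true_allele
                )
                flank_alleles[side] = allele
                if flipped:
                    truth.recombinant_flanks[grain].append([locus, side])
                for sentinel in config.loci[locus][side]:
                    n_reads = int(rng.poisson(coverage_mean))
                    m = n_reads if allele == MUTANT else 0
                    wt = n_reads if allele == WILDTYPE else 0
                    truth.sentinel_alleles[grain][sentinel] = allele
                    rows.append(
                        {
                            "grain": grain,
                            "sentinel_gene": sentinel,
                            "mutant_reads": m,
                            "wt_reads": wt,
                        }
                    )
            if flank_alleles["left"] == flank_alleles["right"]:
                truth.expected_locus_calls[grain][locus] = flank_alleles["left"]
            else:
                truth.expected_locus_calls[grain][locus] = AMBIGUOUS
    support = pd.DataFrame(rows, columns=["grain", "sentinel_gene", "mutant_reads", "wt_reads"])
    return support, config, truth


def simulate_methylome_and_tissue_tpm(
    n_genes: int = 2000,
    class_mix: Mapping[str, float] | None = None,
    n_mpg: int = 56,
    insufficient_frac: float = 0.05,
    te_overlap_frac: float = 0.08,
    site_depth_mean: float = 6.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, list[Interval]], list[Interval], TissueExpression, TruthBundle]:
    """Simulate per-site CDS methylation calls, CDS/TE intervals, and a
    ten-tissue TPM matrix with ``n_mpg`` planted methylated pollen genes.

    ``class_mix`` gives teM/gbM/UM proportions (must sum to <= 1); the
    remainder are genes with intermediate (ambiguous) methylation. A
    further ``insufficient_frac`` of genes get fewer than 30 sites per
    context. MPGs are planted among clean teM genes that do not overlap TEs.
    """
    rng = np.random.default_rng(seed)
    if class_mix is None:
        class_mix = {"teM": 0.12, "gbM": 0.38, "UM": 0.40}
    mix = {k: float(class_mix.get(k, 0.0)) for k in ("teM", "gbM", "UM")}
    if any(v < 0 for v in mix.values()) or sum(mix.values()) > 1 + 1e-12:
        raise ConfigurationError("class_mix proportions must be >= 0 and sum to <= 1")

    genes = [f"mg{i:05d}" for i in range(n_genes)]
    probs = [mix["teM"], mix["gbM"], mix["UM"], max(0.0, 1.0 - sum(mix.values()))]
    classes = rng.choice(["teM", "gbM", "UM", "ambiguous"], size=n_genes, p=probs)
    insufficient = rng.random(n_genes) < insufficient_frac

    # clean-margin per-gene context levels
    level_cg = np.empty(n_genes)
    level_chg = np.empty(n_genes)
    for i, cls in enumerate(classes):
        if cls == "teM":
            level_cg[i] = rng.uniform(0.55, 0.90)
            level_chg[i] = rng.uniform(0.50, 0.85)
        elif cls == "gbM":
            level_cg[i] = rng.uniform(0.55, 0.90)
            level_chg[i] = rng.uniform(0.0, 0.02)
        elif cls == "UM":
            level_cg[i] = rng.uniform(0.0, 0.02)
            level_chg[i] = rng.uniform(0.0, 0.02)
        else:
            level_cg[i] = rng.uniform(0.15, 0.30)
            level_chg[i] = rng.uniform(0.10, 0.30)

    cds: dict[str, list[Interval]] = {}
    site_rows = []
    gene_span = 3000
    cds_len = 1500
    for i, gene in enumerate(genes):
        start = i * gene_span
        end = start + cds_len
        cds[gene] = [("chr1", start, end)]
        if insufficient[i]:
            n_cg = int(rng.integers(5, 26))
            n_chg = int(rng.integers(5, 26))
        else:
            n_cg = int(rng.integers(40, 121))
            n_chg = int(rng.integers(40, 121))
        for ctx, n_sites, lvl in (("CG", n_cg, level_cg[i]), ("CHG", n_chg, level_chg[i])):
            offset = 0 if ctx == "CG" else 1
            spacing = max(3, cds_len // max(n_sites, 1))
            for k in range(n_sites):
                pos = start + 1 + offset + k * spacing  # 1-based, inside CDS
                if pos > end:
                    break
                total = int(rng.poisson(site_depth_mean))
                meth = int(rng.binomial(total, lvl)) if total > 0 else 0
                site_rows.append(("chr1", pos, ctx, meth, total))
    sites = pd.DataFrame(
        site_rows, columns=["chrom", "pos", "context", "methylated_reads", "total_reads"]
    )

    te_hits = rng.random(n_genes) < te_overlap_frac
    te_intervals: list[Interval] = []
    for i, gene in enumerate(genes):
        if te_hits[i]:
            _, start, end = cds[gene][0]
            te_intervals.append(("chr1", end - 50, end + 200))
    te_intervals.append(("chr1", n_genes * gene_span + 100, n_genes * gene_span + 600))

    truth_class = np.where(insufficient, "insufficient", classes)
    mpg_pool = [
        genes[i]
        for i in range(n_genes)
        if truth_class[i] == "teM" and not te_hits[i]
    ]
    if len(mpg_pool) < n_mpg:
        raise ConfigurationError(
            f"only {len(mpg_pool)} clean teM genes available for {n_mpg} MPGs; "
            "raise n_genes or the teM share"
        )
    mpg = sorted(rng.choice(mpg_pool, size=n_mpg, replace=False).tolist())

    tissues = ["anther", "tassel"] + [f"veg{i + 1}" for i in range(8)]
    base = rng.lognormal(1.0, 1.0, size=n_genes)
    tpm = base[:, None] * rng.uniform(0.5, 2.0, size=(n_genes, len(tissues)))
    tpm_df = pd.DataFrame(tpm, index=genes, columns=tissues)
    tpm_df.loc[mpg, "anther"] = rng.uniform(300.0, 3000.0, size=n_mpg)
    tpm_df.loc[mpg, "tassel"] = rng.uniform(20.0, 500.0, size=n_mpg)
    for t in tissues[2:]:
        tpm_df.loc[mpg, t] = rng.uniform(0.0, 2.0, size=n_mpg)
    tpm_df.index.name = "gene"

    tissue_expr = TissueExpression(
        tpm=tpm_df, anther="anther", tassel="tassel", vegetative=tissues[2:]
    )
    truth = TruthBundle(
        epialleles=dict(zip(genes, truth_class.tolist())),
        mpg_genes=mpg,
        te_overlap_genes=[genes[i] for i in range(n_genes) if te_hits[i]],
    )
    return sites, cds, te_intervals, tissue_expr, truth


def simulate_timecourse_and_areas(
    stages: Sequence[tuple[str, float]] | None = None,
    n_samples_per_stage: int = 10,
    small_fraction: float = 0.25,
    area_reduction: float = 0.35,
    n_particles: int = 2000,
    large_area_mean: float = 7000.0,
    area_cv: float = 0.09,
    debris_frac: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthBundle]:
    """Simulate a staged timecourse sample table and a particle table.

    Sample totals are log-normal around each stage's mean, pseudotime
    increases with stage order, and particle areas come from a two-component
    normal mixture (small-component mean = (1 - area_reduction) x large
    mean, mixing weight ``small_fraction``) plus a little sub-window debris.
    """
    if stages is None:
        stages = [("meiosis", 60_000.0), ("UM", 90_000.0), ("BM", 133_905.0), ("pollen", 377_873.0)]
    if any(mean <= 0 for _, mean in stages):
        raise ConfigurationError("stage means must be positive")
    if not 0 <= small_fraction <= 1:
        raise ConfigurationError("small_fraction must lie in [0,1]")
    rng = np.random.default_rng(seed)

    rows = []
    for s_idx, (stage, mean_umis) in enumerate(stages):
        offsets = np.sort(rng.uniform(0.05, 0.95, size=n_samples_per_stage))
        totals = _lognormal_with_mean(rng, mean_umis, 0.15, n_samples_per_stage)
        for j in range(n_samples_per_stage):
            rows.append(
                {
                    "sample": f"{stage}_{j + 1:02d}",
                    "stage": stage,
                    "pseudotime": s_idx + offsets[j],
                    "total_umis": int(round(totals[j])),
                }
            )
    samples = pd.DataFrame(rows).set_index("sample")

    small_mean = (1.0 - area_reduction) * large_area_mean
    comp = np.where(rng.random(n_particles) < small_fraction, "small", "large").astype(object)
    n_debris = int(round(debris_frac * n_particles))
    if n_debris:
        comp[rng.choice(n_particles, size=n_debris, replace=False)] = "debris"
    area = np.empty(n_particles)
    for label, mean in (("small", small_mean), ("large", large_area_mean)):
        m = comp == label
        area[m] = rng.normal(mean, area_cv * mean, size=int(m.sum()))
    m = comp == "debris"
    area[m] = rng.uniform(200.0, 1900.0, size=int(m.sum()))
    area = np.maximum(area, 1.0)
    circ = rng.uniform(0.755, 0.995, size=n_particles)
    low_circ = rng.random(n_particles) < 0.05
    circ[low_circ] = rng.uniform(0.40, 0.745, size=int(low_circ.sum()))
    particles = pd.DataFrame({"area": area, "circularity": circ})

    truth = TruthBundle(
        particle_components=comp.tolist(),
        stage_means={stage: float(mean) for stage, mean in stages},
    )
    return samples, particles, truth


def simulate_celseq_reads(
    counts: pd.DataFrame,
    duplication_mean: float = 1.0,
    n_noise_reads: int = 0,
    seed: int = 0,
) -> tuple[list[ReadRecord], dict[str, str]]:
    """Emit CEL-seq read records realizing a molecule count matrix exactly.

    Each (gene, sample) molecule gets a UMI unique within that gene/sample
    (so exact-match deduplication recovers the matrix exactly) and
    ``1 + Poisson(duplication_mean)`` duplicate reads. Column names become
    samples; each is assigned a distinct 6-nt barcode. ``n_noise_reads``
    extra reads carry a barcode outside the whitelist.
    """
    rng = np.random.default_rng(seed)
    samples = list(counts.columns)
    if len(samples) + 1 > 4**6:
        raise ConfigurationError("too many samples for 6-nt barcodes")
    barcodes = {s: _int_to_seq(i, 6) for i, s in enumerate(samples)}
    noise_barcode = _int_to_seq(len(samples), 6)

    records: list[ReadRecord] = []
    rid = 0
    for sample in samples:
        bc = barcodes[sample]
        col = counts[sample]
        for gene, n_mol in col[col > 0].items():
            for j in range(int(n_mol)):
                umi = _int_to_seq(j, 10)
                n_reads = 1 + int(rng.poisson(duplication_mean))
                for _ in range(n_reads):
                    records.append(
                        ReadRecord(
                            read_id=f"r{rid:08d}",
                            read1_seq=f"{gene}",
                            read2_seq=umi + bc + "T" * 8,
                            gene=str(gene),
                        )
                    )
                    rid += 1
    for _ in range(n_noise_reads):
        records.append(
            ReadRecord(
                read_id=f"r{rid:08d}",
                read1_seq="",
                read2_seq=_int_to_seq(int(rng.integers(0, 4**10)), 10) + noise_barcode + "T" * 8,
                gene=None,
            )
        )
        rid += 1
    order = rng.permutation(len(records))
    return [records[i] for i in order], barcodes


def _int_to_seq(value: int, length: int) -> str:
    alphabet = "ACGT"
    out = []
    for _ in range(length):
        out.append(alphabet[value % 4])
        value //= 4
    return "".join(reversed(out))


# ---------------------------------------------------------------------------
# plain-text writers


def write_sentinel_support(support: pd.DataFrame, path) -> None:
    support.to_csv(path, sep="\t", index=False)


def write_sites_tsv(sites: pd.DataFrame, path) -> None:
    sites.to_csv(path, sep="\t", index=False)


def write_tissue_tpm(tissue_expr: TissueExpression, path) -> None:
    tissue_expr.tpm.to_csv(path, sep="\t", index_label="gene")


def write_timecourse_tsv(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample")


def write_particles_csv(particles: pd.DataFrame, path) -> None:
    particles.to_csv(path, index=False)
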