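"""Gene-body methylation epiallele classification and methylated-pollen-gene
(MPG) selection.

Only cytosines inside annotated CDS count. A site is informative when at
least one read covers it; per-gene context levels are read-weighted means.
Classes: teM (CG and CHG both >= 40%), gbM (high CG, near-zero CHG), UM
(near-zero both), ambiguous (anything else), insufficient (< 30 informative
sites in either context). Genes whose CDS touches a TE annotation by even a
single base are flagged and excluded from expression summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EpialleleThresholds",
    "TissueExpression",
    "summarize_gene_methylation",
    "classify_epiallele",
    "classify_epialleles",
    "flag_cds_te_overlap",
    "count_expressed_by_threshold",
    "select_mpgs",
    "read_bed",
    "write_bed",
]

VALID_CONTEXTS = {"CG", "CHG", "CHH"}

Interval = tuple[str, int, int]  # chrom, start, end — 0-based half-open


@dataclass(frozen=True)
class EpialleleThresholds:
    min_sites: int = 30
    tem_cg_min: float = 0.40
    tem_chg_min: float = 0.40
    gbm_cg_min: float = 0.40
    chg_low_max: float = 0.05
    cg_low_max: float = 0.05


@dataclass
class TissueExpression:
    """gene x tissue TPM with tissue roles tagged."""

    tpm: pd.DataFrame
    anther: str
    tassel: str
    vegetative: list[str]

    def __post_init__(self):
        cols = set(self.tpm.columns)
        missing = ({self.anther, self.tassel} | set(self.vegetative)) - cols
        if missing:
            raise ValueError(f"tissue columns missing from TPM matrix: {sorted(missing)}")
        if (self.tpm.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")


def _validate_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    out = []
    for chrom, start, end in intervals:
        if end <= start:
            raise ValueError(f"malformed interval {chrom}:{start}-{end} (end <= start)")
        out.append((str(chrom), int(start), int(end)))
    return out


def summarize_gene_methylation(
    sites: pd.DataFrame,
    cds_intervals: Mapping[str, Sequence[Interval]],
) -> pd.DataFrame:
    """Per-gene informative-site counts and CG/CHG levels over CDS.

    ``sites`` columns: chrom, pos (1-based), context, methylated_reads,
    total_reads. Sites falling outside every CDS interval are rejected with
    a warning; CHH sites are carried through the containment check but
    ignored for levels. Level = sum(methylated) / sum(total) over
    informative (total >= 1) sites, i.e. read-weighted.
    """
    required = {"chrom", "pos", "context", "methylated_reads", "total_reads"}
    missing = required - set(sites.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    bad_ctx = set(sites["context"]) - VALID_CONTEXTS
    if bad_ctx:
        raise ValueError(f"invalid methylation context(s): {sorted(bad_ctx)}")
    if (sites["methylated_reads"] > sites["total_reads"]).any():
        raise ValueError("methylated_reads exceeds total_reads for some site")

    # gene lookup by containment (1-based pos inside 0-based half-open interval)
    gene_index: dict[str, list[tuple[int, int, str]]] = {}
    for gene, ivals in cds_intervals.items():
        for chrom, start, end in _validate_intervals(ivals):
            gene_index.setdefault(chrom, []).append((start, end, gene))

    assigned_parts = []
    n_outside = 0
    for chrom, sub in sites.groupby(sites["chrom"].astype(str)):
        ivals = sorted(gene_index.get(chrom, []))
        if not ivals:
            n_outside += len(sub)
            continue
        starts = np.array([s for s, _, _ in ivals])
        ends = np.array([e for _, e, _ in ivals])
        names = np.array([g for _, _, g in ivals], dtype=object)
        max_end = np.maximum.accumulate(ends)
        c = sub["pos"].to_numpy() - 1  # 0-based coordinate of the cytosine
        idx = np.searchsorted(starts, c, side="right") - 1
        idx_safe = np.clip(idx, 0, len(starts) - 1)
        hit = (idx >= 0) & (starts[idx_safe] <= c) & (c < ends[idx_safe])
        gene_for = np.where(hit, names[idx_safe], None)
        # overlapping intervals: walk back while an earlier interval can still span
        for k in np.nonzero(~hit & (idx >= 0))[0]:
            j = idx[k]
            while j >= 0 and max_end[j] > c[k]:
                if starts[j] <= c[k] < ends[j]:
                    gene_for[k] = names[j]
                    break
                j -= 1
        found = gene_for != None  # noqa: E711 - elementwise on object array
        n_outside += int((~found).sum())
        part = sub.loc[found, ["context", "methylated_reads", "total_reads"]].copy()
        part["gene"] = gene_for[found]
        assigned_parts.append(part)
    if n_outside:
        warnings.warn(f"{n_outside} site(s) outside all CDS intervals were rejected")

    out = pd.DataFrame(
        0,
        index=pd.Index(list(cds_intervals), name="gene"),
        columns=["informative_cg", "informative_chg", "cg_meth", "cg_total", "chg_meth", "chg_total"],
    )
    if assigned_parts:
        assigned = pd.concat(assigned_parts, ignore_index=True)
        informative = assigned[(assigned["context"] != "CHH") & (assigned["total_reads"] >= 1)]
        agg = informative.groupby(["gene", "context"]).agg(
            n_sites=("total_reads", "size"),
            meth=("methylated_reads", "sum"),
            total=("total_reads", "sum"),
        )
        for ctx, key in (("CG", "cg"), ("CHG", "chg")):
            if ctx in agg.index.get_level_values("context"):
                sub_agg = agg.xs(ctx, level="context")
                out.loc[sub_agg.index, f"informative_{key}"] = sub_agg["n_sites"]
                out.loc[sub_agg.index, f"{key}_meth"] = sub_agg["meth"]
                out.loc[sub_agg.index, f"{key}_total"] = sub_agg["total"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["cg_level"] = np.where(out["cg_total"] > 0, out["cg_meth"] / out["cg_total"], np.nan)
        out["chg_level"] = np.where(out["chg_total"] > 0, out["chg_meth"] / out["chg_total"], np.nan)
    return out[["informative_cg", "informative_chg", "cg_level", "chg_level"]]


def classify_epiallele(
    cg_level: float,
    chg_level: float,
    informative_cg: int,
    informative_chg: int,
    thresholds: EpialleleThresholds = EpialleleThresholds(),
) -> str:
    """Classify one gene. All threshold comparisons are inclusive."""
    t = thresholds
    if informative_cg < t.min_sites or informative_chg < t.min_sites:
        return "insufficient"
    if cg_level >= t.tem_cg_min and chg_level >= t.tem_chg_min:
        return "teM"
    if cg_level >= t.gbm_cg_min and chg_level <= t.chg_low_max:
        return "gbM"
    if cg_level <= t.cg_low_max and chg_level <= t.chg_low_max:
        return "UM"
    return "ambiguous"


def classify_epialleles(
    summary: pd.DataFrame,
    thresholds: EpialleleThresholds = EpialleleThresholds(),
) -> pd.Series:
    """Vectorized classification of a summarize_gene_methylation() table."""
    labels = [
        classify_epiallele(
            r.cg_level, r.chg_level, int(r.informative_cg), int(r.informative_chg), thresholds
        )
        for r in summary.itertuples()
    ]
    return pd.Series(labels, index=summary.index, name="epiallele")


def flag_cds_te_overlap(
    cds_intervals: Mapping[str, Sequence[Interval]],
    te_intervals: Iterable[Interval],
) -> pd.Series:
    """True per gene iff any CDS interval intersects any TE by >= 1 base.

    Coordinates are 0-based half-open, so an adjacent TE ([200,300) next to
    a CDS ending at 200) does not overlap.
    """
    tes: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in _validate_intervals(te_intervals):
        tes.setdefault(chrom, []).append((start, end))
    starts = {}
    ends = {}
    for chrom, ivals in tes.items():
        ivals.sort()
        starts[chrom] = np.array([s for s, _ in ivals])
        # running max of ends supports nested/overlapping TEs
        ends[chrom] = np.maximum.accumulate(np.array([e for _, e in ivals]))

    flags = {}
    for gene, ivals in cds_intervals.items():
        hit = False
        for chrom, start, end in _validate_intervals(ivals):
            if chrom not in starts:
                continue
            i = np.searchsorted(starts[chrom], end, side="left")  # TEs starting before CDS end
            if i > 0 and ends[chrom][i - 1] > start:
                hit = True
                break
        flags[gene] = hit
    return pd.Series(flags, name="te_overlap")


def count_expressed_by_threshold(
    tissue_tpm: pd.DataFrame,
    genes: Iterable[str],
    thresholds: Iterable[int] = range(1, 101),
) -> pd.DataFrame:
    """Counts of ``genes`` with TPM >= threshold, per tissue per threshold.

    Callers should pass only genes passing the core / TE-overlap filters.
    Rows = thresholds, columns = tissues; counts are monotone non-increasing
    down each column's threshold axis by construction.
    """
    genes = [g for g in genes if g in tissue_tpm.index]
    sub = tissue_tpm.loc[genes]
    th = list(thresholds)
    data = {t: (sub >= t).sum(axis=0) for t in th}
    out = pd.DataFrame(data).T
    out.index.name = "tpm_threshold"
    return out


def select_mpgs(
    tissue_expr: TissueExpression,
    epialleles: pd.Series,
    fold: float = 10.0,
    pseudocount: float = 0.01,
    te_overlap: pd.Series | None = None,
) -> list[str]:
    """Select methylated pollen genes.

    A gene qualifies iff it is teM (and not TE-overlapping when that flag is
    supplied) and its anther TPM is at least ``fold`` times each of the 8
    vegetative tissues' TPM (+ ``pseudocount``); tassel, which contains
    pollen, is excluded from the comparison set.
    """
    if len(tissue_expr.vegetative) < 1:
        raise ValueError("no vegetative tissues configured")
    tpm = tissue_expr.tpm
    tem = epialleles[epialleles == "teM"].index
    tem = [g for g in tem if g in tpm.index]
    if te_overlap is not None:
        tem = [g for g in tem if not bool(te_overlap.get(g, False))]
    anther = tpm.loc[tem, tissue_expr.anther]
    veg = tpm.loc[tem, tissue_expr.vegetative]
    ok = (anther.to_numpy()[:, None] >= fold * (veg.to_numpy() + pseudocount)).all(axis=1)
    return sorted(np.asarray(tem)[ok].tolist())


# ---------------------------------------------------------------------------
# BED I/O (0-based half-open; name column = gene id)


def read_bed(path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            out.append((chrom, start, end, name))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
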