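"""Haploid genotype inference from allele-diagnostic sentinel genes.

Each locus of interest is flanked by "sentinel" genes whose expressed SNPs
distinguish the mutant-linked haplotype from the wild-type-linked one. A
grain's locus genotype is called only when every informative sentinel on
both flanks agrees; anything less (no coverage, biallelic evidence, or
discordant flanks, e.g. from recombination) is ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MUTANT",
    "WILDTYPE",
    "AMBIGUOUS",
    "AlleleCall",
    "SentinelConfig",
    "GrainGenotype",
    "call_sentinel_allele",
    "genotype_grain",
    "genotype_table",
    "segregation_chi2",
]

MUTANT = "mutant"
WILDTYPE = "wildtype"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class AlleleCall:
    """Allele call for one sentinel gene in one grain."""

    call: str  # one of MUTANT / WILDTYPE / AMBIGUOUS
    mutant_reads: int
    wt_reads: int

    def __post_init__(self):
        if self.call not in (MUTANT, WILDTYPE, AMBIGUOUS):
            raise ValueError(f"invalid allele call {self.call!r}")

    @property
    def informative(self) -> bool:
        return self.call != AMBIGUOUS


@dataclass
class SentinelConfig:
    """Sentinel layout: per locus, ordered left/right flank gene lists."""

    loci: dict[str, dict[str, list[str]]]

    def __post_init__(self):
        seen: dict[str, str] = {}
        for locus, flanks in self.loci.items():
            for side in ("left", "right"):
                genes = flanks.get(side, [])
                if len(genes) < 1:
                    raise ValueError(f"locus {locus!r} needs >=1 sentinel on {side} flank")
                for g in genes:
                    if g in seen:
                        raise ValueError(f"sentinel {g!r} assigned to both {seen[g]!r} and {locus!r}")
                    seen[g] = locus

    @property
    def locus_names(self) -> list[str]:
        return list(self.loci)

    @property
    def sentinel_genes(self) -> list[str]:
        return [g for flanks in self.loci.values() for side in ("left", "right") for g in flanks[side]]

    def locus_of(self, sentinel: str) -> str:
        for locus, flanks in self.loci.items():
            if sentinel in flanks["left"] or sentinel in flanks["right"]:
                return locus
        raise KeyError(f"sentinel {sentinel!r} not in config")


@dataclass
class GrainGenotype:
    """Per-grain locus calls plus the derived 4-class (+ ambiguous) label."""

    grain: str
    locus_calls: dict[str, str]
    grain_class: str = field(init=False)

    def __post_init__(self):
        calls = list(self.locus_calls.values())
        loci = list(self.locus_calls)
        if any(c == AMBIGUOUS for c in calls):
            self.grain_class = AMBIGUOUS
        elif all(c == MUTANT for c in calls):
            self.grain_class = "double"
        elif all(c == WILDTYPE for c in calls):
            self.grain_class = "WT"
        else:
            mutant_locus = loci[calls.index(MUTANT)]
            self.grain_class = f"single_{mutant_locus}"


def call_sentinel_allele(
    mutant_reads: int,
    wt_reads: int,
    min_reads: int = 2,
    majority: float = 0.8,
) -> AlleleCall:
    """Call one sentinel from allele-supporting read counts.

    The call is ``mutant`` (resp. ``wildtype``) when total coverage reaches
    ``min_reads`` and that allele carries at least the ``majority`` fraction
    of reads; otherwise ``ambiguous``. Biallelic evidence (neither allele at
    majority) is ambiguous, not an error.
    """
    if mutant_reads < 0 or wt_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = mutant_reads + wt_reads
    if total >= min_reads:
        if mutant_reads / total >= majority:
            return AlleleCall(MUTANT, mutant_reads, wt_reads)
        if wt_reads / total >= majority:
            return AlleleCall(WILDTYPE, mutant_reads, wt_reads)
    return AlleleCall(AMBIGUOUS, mutant_reads, wt_reads)


def _call_locus(calls: Mapping[str, AlleleCall], flanks: Mapping[str, list[str]]) -> str:
    informative: dict[str, list[str]] = {"left": [], "right": []}
    for side in ("left", "right"):
        for gene in flanks[side]:
            c = calls.get(gene)
            if c is not None and c.informative:
                informative[side].append(c.call)
    if not informative["left"] or not informative["right"]:
        return AMBIGUOUS
    alleles = set(informative["left"]) | set(informative["right"])
    if len(alleles) == 1:
        return alleles.pop()
    return AMBIGUOUS


def genotype_grain(
    sentinel_calls: Mapping[str, AlleleCall],
    config: SentinelConfig,
    grain: str = "",
) -> GrainGenotype:
    """Combine per-sentinel calls into a per-grain genotype.

    A locus is called only when each flank carries at least one informative
    sentinel and all informative sentinels across both flanks agree; any
    disagreement (recombination between the linked genes) or one-sided
    evidence yields an ambiguous locus.
    """
    known = set(config.sentinel_genes)
    unknown = set(sentinel_calls) - known
    if unknown:
        raise ValueError(f"sentinel ids not in config: {sorted(unknown)}")
    locus_calls = {
        locus: _call_locus(sentinel_calls, flanks) for locus, flanks in config.loci.items()
    }
    return GrainGenotype(grain=grain, locus_calls=locus_calls)


def genotype_table(
    support: pd.DataFrame,
    config: SentinelConfig,
    min_reads: int = 2,
    majority: float = 0.8,
) -> pd.DataFrame:
    """Genotype every grain in a long-format support table.

    ``support`` columns: grain, sentinel_gene, mutant_reads, wt_reads.
    Returns one row per grain with per-locus calls and the derived class.
    """
    required = {"grain", "sentinel_gene", "mutant_reads", "wt_reads"}
    missing = required - set(support.columns)
    if missing:
        raise ValueError(f"support table missing columns: {sorted(missing)}")
    rows = []
    for grain, sub in support.groupby("grain", sort=True):
        calls = {
            r.sentinel_gene: call_sentinel_allele(
                int(r.mutant_reads), int(r.wt_reads), min_reads=min_reads, majority=majority
            )
            for r in sub.itertuples()
        }
        gt = genotype_grain(calls, config, grain=str(grain))
        row = {"grain": gt.grain, **{f"locus_{k}": v for k, v in gt.locus_calls.items()}}
        row["genotype"] = gt.grain_class
        rows.append(row)
    return pd.DataFrame(rows).set_index("grain")


def segregation_chi2(
    class_counts: Sequence[int] | Iterable[int],
    expected_probs: Sequence[float],
) -> tuple[float, int, float]:
    """Pearson goodness-of-fit test of class counts against expected ratios.

    Returns ``(chi2, df, p)`` with ``df = k - 1`` and the upper-tail
    chi-squared p-value.
    """
    obs = np.asarray(list(class_counts), dtype=float)
    probs = np.asarray(list(expected_probs), dtype=float)
    if obs.shape != probs.shape:
        raise ValueError("counts and probabilities must have equal length")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("expected probabilities must sum to 1")
    expected = total * probs
    if (expected == 0).any():
        raise ValueError("expected count of zero; drop impossible classes first")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p
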