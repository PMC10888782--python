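"""Single-grain transcriptome QC, TPM normalization, and correlation
clustering.

QC has two layers: a library-complexity split (the bimodal UMI-total
populations seen when some grains fail to lyse) and per-sample anomaly
flags (low correlation with every other grain, or biallelic sentinel
expression suggesting a doublet).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._mixture import fit_gmm1d
from .genotyping import SentinelConfig

__all__ = [
    "NormalizedMatrix",
    "QcReport",
    "normalize_tpm",
    "filter_low_complexity",
    "flag_anomalous",
    "correlate_and_cluster",
]


@dataclass
class NormalizedMatrix:
    """genes x samples expression matrix on TPM scale.

    ``log_transformed`` records whether values are log1p(TPM) rather than
    raw TPM.
    """

    values: pd.DataFrame
    log_transformed: bool = False


@dataclass
class QcReport:
    """Per-sample QC table and the kept/excluded partition."""

    table: pd.DataFrame  # index=sample; total_umis, detected_genes, complexity, kept
    kept: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)


def normalize_tpm(counts: pd.DataFrame, log: bool = False) -> NormalizedMatrix:
    """Scale each sample to transcripts-per-million; optionally log1p.

    Raises on zero-total columns, naming the offending sample(s).
    """
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    tpm = counts.div(totals, axis=1) * 1e6
    if log:
        return NormalizedMatrix(values=np.log1p(tpm), log_transformed=True)
    return NormalizedMatrix(values=tpm, log_transformed=False)


def filter_low_complexity(
    counts: pd.DataFrame,
    threshold: float | None = None,
    min_gap: float = 0.5,
) -> QcReport:
    """Split samples into high/low library-complexity groups.

    By default a 2-component Gaussian mixture is fit to log10 total UMIs and
    samples assigned to the low-mean component are excluded; if the component
    means are closer than ``min_gap`` (log10 units) nothing is excluded.
    With ``threshold`` set, samples with total UMIs below it are excluded
    instead.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    totals = counts.sum(axis=0)
    detected = (counts > 0).sum(axis=0)
    if (totals <= 0).any():
        raise ValueError(f"zero-total sample(s): {list(totals[totals <= 0].index)}")

    if threshold is not None:
        low = totals < threshold
    else:
        logt = np.log10(totals.to_numpy(float))
        fit = fit_gmm1d(logt, n_components=2)
        if fit.means[1] - fit.means[0] < min_gap:
            low = pd.Series(False, index=totals.index)
        else:
            resp = fit.responsibilities(logt)
            low = pd.Series(resp[:, 0] > 0.5, index=totals.index)

    table = pd.DataFrame(
        {
            "total_umis": totals.astype(int),
            "detected_genes": detected.astype(int),
            "complexity": np.where(low, "low", "high"),
            "kept": ~low,
        }
    )
    table.index.name = "sample"
    return QcReport(
        table=table,
        kept=list(table.index[~low]),
        excluded=list(table.index[low]),
    )


def flag_anomalous(
    corr_matrix: pd.DataFrame,
    sentinel_support: pd.DataFrame | None = None,
    sentinel_config: SentinelConfig | None = None,
    k_sd: float = 3.0,
    min_reads: int = 2,
    majority: float = 0.8,
    min_biallelic_sentinels: int = 2,
) -> pd.DataFrame:
    """Flag outlier samples by correlation and biallelic sentinel evidence.

    A sample is flagged ``low_correlation`` when its mean off-diagonal
    correlation falls more than ``k_sd`` SDs below the group mean of those
    means. It is flagged ``biallelic`` when any locus flank shows at least
    ``min_biallelic_sentinels`` covered sentinels failing the majority rule
    with reads on both alleles — the signature of a doublet at that locus.
    """
    if corr_matrix.shape[0] != corr_matrix.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr_matrix.to_numpy(), corr_matrix.to_numpy().T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")

    c = corr_matrix.to_numpy(float).copy()
    np.fill_diagonal(c, np.nan)
    mean_off = np.nanmean(c, axis=1)
    # leave-one-out mean/SD so an outlier cannot mask itself
    n = len(mean_off)
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        rest = np.delete(mean_off, i)
        flags[i] = mean_off[i] < rest.mean() - k_sd * rest.std(ddof=0)
    low_corr = pd.Series(flags, index=corr_matrix.index)

    biallelic = pd.Series(False, index=corr_matrix.index)
    biallelic_locus = pd.Series("", index=corr_matrix.index)
    if sentinel_support is not None:
        if sentinel_config is None:
            raise ValueError("sentinel_support requires sentinel_config")
        for grain, sub in sentinel_support.groupby("grain"):
            if grain not in biallelic.index:
                continue
            hits = []
            for locus, flanks in sentinel_config.loci.items():
                for side in ("left", "right"):
                    n_bad = 0
                    for r in sub[sub["sentinel_gene"].isin(flanks[side])].itertuples():
                        m, w = int(r.mutant_reads), int(r.wt_reads)
                        total = m + w
                        if total >= min_reads and m > 0 and w > 0 and max(m, w) / total < majority:
                            n_bad += 1
                    if n_bad >= min_biallelic_sentinels:
                        hits.append(locus)
            if hits:
                biallelic.loc[grain] = True
                biallelic_locus.loc[grain] = ",".join(sorted(set(hits)))

    out = pd.DataFrame(
        {
            "mean_off_diag_corr": mean_off,
            "low_correlation": low_corr,
            "biallelic": biallelic,
            "biallelic_locus": biallelic_locus,
        },
        index=corr_matrix.index,
    )
    out.index.name = "sample"
    return out


def correlate_and_cluster(
    norm: NormalizedMatrix,
    min_mean_tpm: float = 500.0,
    linkage_method: str = "average",
) -> tuple[pd.DataFrame, np.ndarray, pd.Series]:
    """Pearson-correlate samples on highly expressed genes and cut into 2 groups.

    Genes whose mean raw TPM (across the input samples) is below
    ``min_mean_tpm`` are removed (boundary inclusive: mean >= threshold is
    kept), the surviving matrix is log1p-transformed, pairwise Pearson
    correlation computed, and average-linkage hierarchical clustering on
    distance 1 - r is cut at 2 groups.

    Returns (correlation matrix, linkage matrix, 2-group labels).
    """
    if norm.log_transformed:
        raise ValueError("pass a raw-TPM NormalizedMatrix; the gene filter is on raw TPM")
    tpm = norm.values
    if tpm.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    keep = tpm.mean(axis=1) >= min_mean_tpm
    if keep.sum() < 2:
        raise ValueError(
            f"only {int(keep.sum())} gene(s) with mean TPM >= {min_mean_tpm}; need >= 2"
        )
    logexpr = np.log1p(tpm.loc[keep])
    corr = logexpr.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    return corr, Z, pd.Series(labels, index=corr.index, name="cluster")
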