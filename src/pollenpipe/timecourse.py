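"""Developmental-timecourse normalization and pseudotime smoothing.

TPM hides stage-to-stage changes in total transcript abundance, so stage
TPM is rescaled by the ratio of that stage's mean total UMIs to the
reference stage's (mature pollen). Gene trajectories are then smoothed with
a Gaussian kernel over per-sample pseudotime.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "stage_scale_factors",
    "scale_abundance",
    "kernel_smooth",
    "filter_min_pollen_expression",
    "silverman_bandwidth",
]


def stage_scale_factors(
    stage_mean_umis: Mapping[str, float],
    reference: str,
) -> dict[str, float]:
    """factor(stage) = mean UMIs(stage) / mean UMIs(reference)."""
    if reference not in stage_mean_umis:
        raise ValueError(f"reference stage {reference!r} not in stage means")
    ref = float(stage_mean_umis[reference])
    if ref <= 0 or any(v <= 0 for v in stage_mean_umis.values()):
        raise ValueError("stage mean UMIs must be positive")
    return {stage: float(v) / ref for stage, v in stage_mean_umis.items()}


def scale_abundance(
    expr: pd.DataFrame,
    sample_stages: pd.Series,
    factors: Mapping[str, float],
) -> pd.DataFrame:
    """Multiply each sample's TPM column by its stage's scale factor."""
    stages = sample_stages.reindex(expr.columns)
    unknown = set(stages.dropna()) - set(factors)
    if unknown or stages.isna().any():
        missing = sorted(unknown | set(expr.columns[stages.isna()]))
        raise ValueError(f"no scale factor / stage for: {missing}")
    col_factors = stages.map(factors).to_numpy(float)
    return expr * col_factors[None, :]


def kernel_smooth(
    values,
    pseudotimes,
    bandwidth: float,
    query: Iterable[float] | None = None,
    n_grid: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel weighted average of values over pseudotime.

    smoothed(t) = sum_i w_i v_i / sum_i w_i with
    w_i = exp(-(t - pt_i)^2 / (2 h^2)). ``query`` defaults to ``n_grid``
    evenly spaced points spanning the sample pseudotimes. Returns
    (query points, smoothed values).
    """
    v = np.asarray(values, dtype=float)
    pt = np.asarray(pseudotimes, dtype=float)
    if v.shape != pt.shape:
        raise ValueError("values and pseudotimes must have equal length")
    if v.size < 2:
        raise ValueError("need at least 2 samples")
    if not bandwidth > 0:
        raise ValueError("bandwidth must be > 0")
    if query is None:
        q = np.linspace(pt.min(), pt.max(), n_grid)
    else:
        q = np.asarray(list(query), dtype=float)
    # log-space weights avoid spurious all-zero underflow
    logw = -((q[:, None] - pt[None, :]) ** 2) / (2.0 * bandwidth**2)
    logw_max = logw.max(axis=1, keepdims=True)
    if not np.isfinite(logw_max).all():
        raise ValueError("all kernel weights underflow; increase the bandwidth")
    w = np.exp(logw - logw_max)
    smoothed = (w * v[None, :]).sum(axis=1) / w.sum(axis=1)
    return q, smoothed


def silverman_bandwidth(pseudotimes) -> float:
    """Silverman's rule-of-thumb bandwidth on the pseudotime axis."""
    pt = np.asarray(pseudotimes, dtype=float)
    n = pt.size
    sd = pt.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(pt, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 0:
        scale = max(abs(pt).max(), 1.0)
    return float(0.9 * scale * n ** (-0.2))


def filter_min_pollen_expression(
    genes: Iterable[str],
    pollen_tpm: Mapping[str, float] | pd.Series,
    min_tpm: float = 10.0,
) -> list[str]:
    """Keep genes whose pollen TPM is >= min_tpm (strict-< exclusion)."""
    kept = []
    for g in genes:
        tpm = pollen_tpm.get(g) if hasattr(pollen_tpm, "get") else pollen_tpm[g]
        if tpm is None or (isinstance(tpm, float) and np.isnan(tpm)):
            raise KeyError(f"no pollen TPM for gene {g!r}")
        if float(tpm) >= min_tpm:
            kept.append(g)
    return kept
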