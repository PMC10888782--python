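"""Pollen particle filtering and two-component area mixture analysis.

Particles from the imaging pipeline are filtered on area and circularity
windows, then grain areas are fit with a 2-component Gaussian mixture to
quantify a small-pollen subpopulation: its mixing weight, the small/large
mean-area ratio, and the implied volume reduction assuming spherical grains
(volume proportional to area^1.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._mixture import Mixture1DFit, fit_gmm1d

__all__ = ["MixtureFit", "filter_particles", "fit_bimodal_areas"]


@dataclass
class MixtureFit:
    mean_small: float
    mean_large: float
    sd_small: float
    sd_large: float
    weight_small: float
    log_likelihood: float
    converged: bool
    verdict: str  # "bimodal" or "unimodal"
    bic_one: float
    bic_two: float
    loglik_trace: list[float]

    @property
    def area_ratio(self) -> float:
        return self.mean_small / self.mean_large

    @property
    def volume_ratio(self) -> float:
        # spherical grains: volume ~ area^(3/2)
        return self.area_ratio**1.5

    @property
    def volume_reduction(self) -> float:
        return 1.0 - self.volume_ratio

    def to_dict(self) -> dict:
        return {
            "mean_small": self.mean_small,
            "mean_large": self.mean_large,
            "sd_small": self.sd_small,
            "sd_large": self.sd_large,
            "weight_small": self.weight_small,
            "area_ratio": self.area_ratio,
            "volume_reduction": self.volume_reduction,
            "verdict": self.verdict,
            "converged": self.converged,
            "log_likelihood": self.log_likelihood,
            "bic_one": self.bic_one,
            "bic_two": self.bic_two,
            "volume_model": "sphere: volume ~ area^1.5",
        }


def filter_particles(
    particles: pd.DataFrame,
    size_range: tuple[float, float] = (2000.0, 14000.0),
    circ_range: tuple[float, float] = (0.75, 1.00),
) -> pd.DataFrame:
    """Keep particles inside the inclusive area and circularity windows."""
    if size_range[0] > size_range[1] or circ_range[0] > circ_range[1]:
        raise ValueError("invalid filter ranges")
    keep = (
        particles["area"].between(*size_range)
        & particles["circularity"].between(*circ_range)
    )
    return particles.loc[keep]


def fit_bimodal_areas(areas, min_weight: float = 0.05, min_n: int = 50) -> MixtureFit:
    """EM-fit a 2-component Gaussian mixture to particle areas.

    The verdict is "unimodal" when a single Gaussian has the lower BIC or
    when the minor component's weight falls below ``min_weight``. Components
    are labeled small/large by mean, making the fit invariant to
    initialization order.
    """
    x = np.asarray(areas, dtype=float).ravel()
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} areas, got {x.size}")
    one: Mixture1DFit = fit_gmm1d(x, n_components=1)
    two: Mixture1DFit = fit_gmm1d(x, n_components=2)
    weight_small = float(two.weights[0])
    unimodal = one.bic <= two.bic or min(two.weights) < min_weight
    return MixtureFit(
        mean_small=float(two.means[0]),
        mean_large=float(two.means[1]),
        sd_small=float(two.sds[0]),
        sd_large=float(two.sds[1]),
        weight_small=weight_small,
        log_likelihood=two.log_likelihood,
        converged=two.converged,
        verdict="unimodal" if unimodal else "bimodal",
        bic_one=one.bic,
        bic_two=two.bic,
        loglik_trace=two.loglik_trace,
    )
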