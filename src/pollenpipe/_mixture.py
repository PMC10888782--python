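"""One-dimensional Gaussian mixture fitting by EM.

Deterministic quantile-based initialization (no RNG) so that fits are
reproducible without threading a seed through callers. The EM trace is kept
so callers can assert the monotone log-likelihood property.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = ["Mixture1DFit", "fit_gmm1d"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class Mixture1DFit:
    """Result of a 1-D Gaussian mixture EM fit, components sorted by mean."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list, repr=False)
    n_obs: int = 0

    @property
    def n_components(self) -> int:
        return len(self.means)

    @property
    def n_parameters(self) -> int:
        # k means + k variances + (k-1) free weights
        return 3 * self.n_components - 1

    @property
    def bic(self) -> float:
        return -2.0 * self.log_likelihood + self.n_parameters * np.log(self.n_obs)

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        lp = _component_logpdf(np.asarray(x, float), self.means, self.sds, self.weights)
        return np.exp(lp - logsumexp(lp, axis=1, keepdims=True))


def _component_logpdf(x, means, sds, weights):
    z = (x[:, None] - means[None, :]) / sds[None, :]
    return np.log(weights)[None, :] - np.log(sds)[None, :] - 0.5 * (z * z + _LOG_2PI)


def fit_gmm1d(
    x,
    n_components: int = 2,
    max_iter: int = 500,
    tol: float = 1e-9,
    var_floor_frac: float = 1e-6,
) -> Mixture1DFit:
    """Fit a ``n_components`` Gaussian mixture to 1-D data by EM.

    Components are initialized at evenly spaced sample quantiles with the
    pooled SD; a variance floor (``var_floor_frac`` of the data variance)
    prevents degenerate spikes. Components in the returned fit are ordered
    by ascending mean.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < n_components:
        raise ValueError(f"need at least {n_components} observations, got {n}")
    k = int(n_components)

    if k == 1:
        mu = float(x.mean())
        var = max(float(x.var()), 1e-300)
        ll = float(-0.5 * n * (_LOG_2PI + np.log(var) + 1.0))
        return Mixture1DFit(
            means=np.array([mu]),
            sds=np.array([np.sqrt(var)]),
            weights=np.array([1.0]),
            log_likelihood=ll,
            n_iter=0,
            converged=True,
            loglik_trace=[ll],
            n_obs=n,
        )

    var_floor = max(var_floor_frac * float(x.var()), 1e-12)
    qs = (np.arange(k) + 0.5) / k
    means = np.quantile(x, qs)
    sds = np.full(k, max(float(x.std()), np.sqrt(var_floor)))
    weights = np.full(k, 1.0 / k)

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lp = _component_logpdf(x, means, sds, weights)
        row_ll = logsumexp(lp, axis=1)
        ll = float(row_ll.sum())
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (1.0 + abs(ll)):
            converged = True
            break
        resp = np.exp(lp - row_ll[:, None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = resp.T @ x / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, var_floor))

    order = np.argsort(means)
    return Mixture1DFit(
        means=means[order],
        sds=sds[order],
        weights=weights[order],
        log_likelihood=trace[-1],
        n_iter=it,
        converged=converged,
        loglik_trace=trace,
        n_obs=n,
    )
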