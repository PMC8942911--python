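"""Unequal-variance signal-detection model for pooled confidence-rating data.

The model places new-item memory strength at N(0, 1) and old-item strength at
N(mu, sigma^2) with its own standard deviation; three criteria c1 < c2 < c3
partition the strength axis into the four rating responses.  Sensitivity is
summarised by

    d_a = mu * sqrt(2 / (1 + sigma^2)),

which reduces to d' when sigma = 1, and bias by x_c = c2, the middle
criterion separating "new" from "old" responses on the new-distribution axis.

Fitting is by maximum likelihood on pooled counts (one multinomial per item
class).  Standard errors come from the observed information matrix, with the
standard error of d_a obtained by the delta method.  Two independent fits are
compared with a two-sample Wald z test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm
from statsmodels.tools.numdiff import approx_hess1

from .design import RatingCounts

__all__ = [
    "UVSDTParams",
    "UVSDTFit",
    "WaldTest",
    "uvsdt_negloglik",
    "da_from_params",
    "fit_uvsdt",
    "wald_z",
]

log = logging.getLogger(__name__)

_PROB_FLOOR = 1e-12

#: deterministic start grid: mu x sigma (criteria start spread around 0)
_START_GRID = [(mu0, s0) for mu0 in (0.5, 1.5, 2.5) for s0 in (1.0, 1.5)]


@dataclass(frozen=True)
class UVSDTParams:
    """Model parameters: old-item mean and SD plus the three rating criteria."""

    mu: float
    sigma: float
    criteria: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        c = self.criteria
        if len(c) != 3 or not (c[0] < c[1] < c[2]):
            raise ValueError(f"criteria must satisfy c1 < c2 < c3, got {c}")

    def response_probabilities(self, old: bool) -> np.ndarray:
        """P(rating = 1..4) for the old or the new item class."""
        m, s = (self.mu, self.sigma) if old else (0.0, 1.0)
        cdf = norm.cdf((np.asarray(self.criteria) - m) / s)
        return np.diff(np.concatenate(([0.0], cdf, [1.0])))


@dataclass(frozen=True)
class WaldTest:
    """Two-sample Wald z test of independent estimates."""

    z: float
    p_value: float


@dataclass(frozen=True)
class UVSDTFit:
    """Maximum-likelihood fit with derived sensitivity and bias indices."""

    params: UVSDTParams
    d_a: float
    x_c: float
    se_d_a: float
    se_x_c: float
    loglik: float
    converged: bool
    #: covariance of (mu, sigma, c1, c2, c3) from the observed information
    cov: np.ndarray
    n_old: int
    n_new: int

    def __post_init__(self) -> None:
        if self.converged and (self.se_d_a <= 0 or self.se_x_c <= 0):
            raise ValueError("standard errors must be positive")


def da_from_params(mu: float, sigma: float) -> float:
    """Sensitivity index d_a = mu * sqrt(2 / (1 + sigma^2))."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return mu * math.sqrt(2.0 / (1.0 + sigma**2))


def _as_counts(x) -> np.ndarray:
    if isinstance(x, RatingCounts):
        return x.as_array()
    arr = np.asarray(x, dtype=float)
    if arr.shape != (4,) or (arr < 0).any():
        raise ValueError(f"expected 4 non-negative rating counts, got {x}")
    return arr


def uvsdt_negloglik(params: UVSDTParams, old, new) -> float:
    """Negative multinomial log-likelihood of pooled old/new rating counts.

    Cell probabilities below ``1e-12`` are floored (and logged) so that a
    positive count in a vanishing cell yields a large finite penalty rather
    than a non-finite objective.
    """
    old_c, new_c = _as_counts(old), _as_counts(new)
    nll = 0.0
    for counts, is_old in ((old_c, True), (new_c, False)):
        p = params.response_probabilities(is_old)
        if (p < _PROB_FLOOR).any() and (counts[p < _PROB_FLOOR] > 0).any():
            log.debug("probability floor hit for %s class at %s", "old" if is_old else "new", params)
        nll -= float(counts @ np.log(np.clip(p, _PROB_FLOOR, 1.0)))
    return nll


def _unpack(theta: np.ndarray) -> UVSDTParams:
    mu, log_sigma, c1, log_d2, log_d3 = theta
    c2 = c1 + math.exp(log_d2)
    c3 = c2 + math.exp(log_d3)
    return UVSDTParams(mu=mu, sigma=math.exp(log_sigma), criteria=(c1, c2, c3))


def fit_uvsdt(old, new) -> UVSDTFit:
    """Fit the unequal-variance model to pooled old vs. new rating counts.

    Optimisation runs in an unconstrained space (free mu; log sigma; c1 plus
    log-increments for c2 and c3, so criterion ordering holds by
    construction) from a deterministic grid of starts; the best likelihood is
    kept.  Raises ``RuntimeError`` if no start converges.
    """
    old_c, new_c = _as_counts(old), _as_counts(new)
    for label, c in (("old", old_c), ("new", new_c)):
        if (c > 0).sum() < 2:
            raise ValueError(f"{label} class needs nonzero counts beyond a single rating: {c}")

    def objective(theta: np.ndarray) -> float:
        return uvsdt_negloglik(_unpack(theta), old_c, new_c)

    best = None
    for mu0, s0 in _START_GRID:
        x0 = np.array([mu0, math.log(s0), 0.0, math.log(0.8), math.log(0.8)])
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"maxiter": 20000, "maxfev": 20000, "xatol": 1e-10, "fatol": 1e-12},
        )
        log.debug("uvsdt start (mu=%.1f, sigma=%.1f): nll=%.6f success=%s", mu0, s0, res.fun, res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("UVSDT fit failed to converge from every start")

    params = _unpack(best.x)
    if params.sigma < 1e-3 or params.sigma > 1e3:
        log.warning("boundary sigma estimate: %g", params.sigma)

    # observed information in the natural parameterisation (mu, sigma, c1, c2, c3)
    def nll_natural(theta: np.ndarray) -> float:
        mu, sigma, c1, c2, c3 = theta
        return uvsdt_negloglik(UVSDTParams(mu, sigma, (c1, c2, c3)), old_c, new_c)

    theta_hat = np.array([params.mu, params.sigma, *params.criteria])
    hess = approx_hess1(theta_hat, nll_natural)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError as err:
        raise RuntimeError("singular observed information; cannot compute SEs") from err

    d_a = da_from_params(params.mu, params.sigma)
    # delta method: gradient of d_a w.r.t. (mu, sigma, c1, c2, c3)
    grad = np.array(
        [
            math.sqrt(2.0 / (1.0 + params.sigma**2)),
            -params.mu * math.sqrt(2.0) * params.sigma * (1.0 + params.sigma**2) ** -1.5,
            0.0,
            0.0,
            0.0,
        ]
    )
    se_d_a = float(np.sqrt(grad @ cov @ grad))
    se_x_c = float(np.sqrt(cov[3, 3]))

    return UVSDTFit(
        params=params,
        d_a=float(d_a),
        x_c=float(params.criteria[1]),
        se_d_a=se_d_a,
        se_x_c=se_x_c,
        loglik=-float(best.fun),
        converged=bool(best.success),
        cov=cov,
        n_old=int(old_c.sum()),
        n_new=int(new_c.sum()),
    )


def wald_z(est1: float, se1: float, est2: float, se2: float) -> WaldTest:
    """Two-sided z test of est1 - est2 for independent samples."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (est1 - est2) / math.sqrt(se1**2 + se2**2)
    return WaldTest(z=float(z), p_value=float(2.0 * norm.sf(abs(z))))
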