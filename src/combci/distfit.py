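"""Fit parametric distributions to reported confidence intervals.

Published estimates usually arrive as a point estimate with a confidence
interval, not as raw data.  To propagate their uncertainty through a
downstream calculation we invert the interval: find the member of a chosen
parametric family whose quantiles at the interval's tail probabilities
reproduce the reported bounds.  For two-parameter continuous families
(beta, normal, gamma) the two bounds determine the two parameters and the
match is exact to numerical precision; for one-parameter families
(exponential, Poisson) the two constraints are reconciled in the
least-squares sense; for discrete families (Poisson, negative binomial)
the cumulative distribution function is matched at the bounds because the
step-shaped quantile function is not invertible.  The achieved discrepancy
is always reported as ``fit_residual``.

Only the interval bounds and the confidence level enter the fit; a point
estimate, when present, is carried through for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import DomainError, FitError

__all__ = [
    "FAMILIES",
    "EstimateCI",
    "FittedDist",
    "fit_from_ci",
    "normal_from_ci_closed_form",
    "quantile_match_objective",
]

FAMILIES = (
    "beta",
    "normal",
    "exponential",
    "gamma",
    "poisson",
    "negative_binomial",
)

_DISCRETE = frozenset({"poisson", "negative_binomial"})

#: Large finite penalty returned by the objective where the family's
#: quantile/CDF is undefined, so derivative-free searches never see NaN.
_PENALTY = 1e18


@dataclass(frozen=True)
class EstimateCI:
    """A reported point estimate with a two-sided confidence interval.

    Parameters
    ----------
    lower, upper : float
        Interval bounds, in the units of the estimated parameter.
    level : float
        Confidence level in (0, 1); 0.95 for the usual 95% interval.
    point : float, optional
        The reported point estimate.  Not used when fitting a
        distribution, only carried through for reporting.
    """

    lower: float
    upper: float
    level: float = 0.95
    point: float | None = None

    def __post_init__(self):
        if not (0.0 < self.level < 1.0):
            raise DomainError(f"confidence level must lie in (0, 1), got {self.level}")
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise DomainError("interval bounds must be finite")
        if self.lower == self.upper:
            raise DomainError(f"degenerate interval: lower == upper == {self.lower}")
        if self.lower > self.upper:
            raise DomainError(f"lower bound {self.lower} exceeds upper bound {self.upper}")
        if self.point is not None and not (self.lower <= self.point <= self.upper):
            raise DomainError(
                f"point estimate {self.point} outside interval "
                f"[{self.lower}, {self.upper}]"
            )

    @property
    def tail_probs(self) -> tuple[float, float]:
        """The two tail probabilities ((1-level)/2, 1-(1-level)/2)."""
        a = (1.0 - self.level) / 2.0
        return a, 1.0 - a


def _frozen(family: str, params: Sequence[float]):
    """scipy frozen distribution for a family/parameter vector."""
    if family == "beta":
        return stats.beta(params[0], params[1])
    if family == "normal":
        return stats.norm(loc=params[0], scale=params[1])
    if family == "exponential":
        return stats.expon(scale=1.0 / params[0])
    if family == "gamma":
        return stats.gamma(params[0], scale=1.0 / params[1])
    if family == "poisson":
        return stats.poisson(params[0])
    if family == "negative_binomial":
        return stats.nbinom(params[0], params[1])
    raise DomainError(f"unknown distribution family {family!r}; choose from {FAMILIES}")


def _params_legal(family: str, params: Sequence[float]) -> bool:
    p = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(p)):
        return False
    if family == "normal":
        return p[1] > 0
    if family == "negative_binomial":
        return p[0] > 0 and 0 < p[1] < 1
    return bool(np.all(p > 0))


@dataclass
class FittedDist:
    """A parametric distribution fitted to a reported confidence interval.

    ``quantile``, ``cdf`` and ``sample`` delegate to the corresponding
    scipy.stats frozen distribution; ``fit_residual`` is the achieved
    value of :func:`quantile_match_objective` at the fitted parameters.
    """

    family: str
    params: tuple[float, ...]
    fit_residual: float
    source: EstimateCI | None = None
    _dist: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise DomainError(f"unknown distribution family {self.family!r}")
        if not _params_legal(self.family, self.params):
            raise DomainError(
                f"illegal parameters {self.params} for family {self.family!r}"
            )
        self._dist = _frozen(self.family, self.params)

    def quantile(self, p):
        return self._dist.ppf(p)

    def cdf(self, x):
        return self._dist.cdf(x)

    def sample(self, n: int, random_state=None) -> np.ndarray:
        """Draw ``n`` independent variates.

        ``random_state`` may be an int seed, a numpy Generator/SeedSequence,
        or None for fresh OS entropy.
        """
        rng = np.random.default_rng(random_state)
        return np.asarray(self._dist.rvs(size=n, random_state=rng), dtype=float)

    @property
    def sampler(self) -> Callable[[int, object], np.ndarray]:
        """Sampler contract ``(n, rng) -> draws`` for the bootstrap engine."""
        return self.sample


def quantile_match_objective(
    params: Sequence[float],
    family: str,
    targets: tuple[float, float, float],
) -> float:
    """Sum-of-squares discrepancy between achieved and target interval.

    For continuous families this is the squared difference between the
    family's quantiles at the interval's tail probabilities and the target
    bounds; for discrete families the CDF evaluated at the bounds is
    compared with the tail probabilities instead.  Returns a large finite
    penalty (never NaN/inf) for illegal parameters, so the function is
    defined over the whole search space.
    """
    lower, upper, level = targets
    if family not in FAMILIES:
        raise DomainError(f"unknown distribution family {family!r}")
    if not _params_legal(family, params):
        return _PENALTY
    a = (1.0 - level) / 2.0
    probs = np.array([a, 1.0 - a])
    dist = _frozen(family, params)
    if family in _DISCRETE:
        achieved = dist.cdf(np.floor([lower, upper]))
        resid = achieved - probs
    else:
        achieved = dist.ppf(probs)
        resid = achieved - np.array([lower, upper])
    if not np.all(np.isfinite(resid)):
        return _PENALTY
    return float(np.sum(resid**2))


def _check_support(est: EstimateCI, family: str) -> None:
    if family == "beta":
        if not (0.0 < est.lower and est.upper < 1.0):
            bad = est.lower if est.lower <= 0 else est.upper
            raise DomainError(
                f"beta fit requires bounds strictly inside (0, 1); got {bad}"
            )
    elif family in ("gamma", "exponential"):
        if est.lower < 0:
            raise DomainError(
                f"{family} fit requires non-negative bounds; got lower={est.lower}"
            )
    elif family in _DISCRETE:
        if est.lower < 0:
            raise DomainError(
                f"{family} fit requires non-negative bounds; got lower={est.lower}"
            )
    # normal: whole real line, nothing to check


def _pseudo_moments(est: EstimateCI) -> tuple[float, float]:
    """Normal-approximation mean and sd implied by the interval."""
    z = stats.norm.ppf(est.tail_probs[1])
    m = 0.5 * (est.lower + est.upper)
    s = (est.upper - est.lower) / (2.0 * z)
    return m, s


def normal_from_ci_closed_form(est: EstimateCI) -> FittedDist:
    """Exact normal fit: mean is the interval midpoint, sd its half-width
    divided by the standard-normal quantile at 1-(1-level)/2."""
    m, s = _pseudo_moments(est)
    resid = quantile_match_objective((m, s), "normal", (est.lower, est.upper, est.level))
    return FittedDist("normal", (m, s), resid, source=est)


def _fit_two_param_continuous(est: EstimateCI, family: str) -> FittedDist:
    """Root-find the two quantile equations in log-parameter space."""
    m, s = _pseudo_moments(est)
    if family == "beta":
        # method-of-moments start
        k = max(m * (1.0 - m) / (s * s) - 1.0, 1e-6)
        x0 = np.log([max(m * k, 1e-8), max((1.0 - m) * k, 1e-8)])
    else:  # gamma(shape, rate)
        x0 = np.log([max(m * m / (s * s), 1e-8), max(m / (s * s), 1e-8)])

    a, b = est.tail_probs
    probs = np.array([a, b])
    target = np.array([est.lower, est.upper])

    def equations(t):
        q = _frozen(family, np.exp(t)).ppf(probs)
        out = q - target
        return np.where(np.isfinite(out), out, 1e6)

    sol = optimize.root(equations, x0, method="hybr")
    params = tuple(np.exp(sol.x))
    resid = quantile_match_objective(params, family, (est.lower, est.upper, est.level))

    tol = 1e-10 * (est.upper - est.lower) ** 2
    if not sol.success or resid > tol:
        # derivative-free fallback from the same start
        nm = optimize.minimize(
            lambda t: quantile_match_objective(
                np.exp(t), family, (est.lower, est.upper, est.level)
            ),
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-13, "fatol": 1e-26, "maxiter": 10_000},
        )
        nm_params = tuple(np.exp(nm.x))
        nm_resid = quantile_match_objective(
            nm_params, family, (est.lower, est.upper, est.level)
        )
        if nm_resid < resid:
            params, resid = nm_params, nm_resid
    if resid > tol:
        raise FitError(
            f"{family} quantile-matching fit did not converge for interval "
            f"[{est.lower}, {est.upper}] at level {est.level}: "
            f"residual {resid:.3e} exceeds tolerance {tol:.3e}",
            residual=resid,
        )
    return FittedDist(family, params, resid, source=est)


def _fit_exponential(est: EstimateCI) -> FittedDist:
    # quantiles are linear in 1/rate: q_p = -ln(1-p)/rate, so the
    # least-squares rate over both targets has a closed form
    a, b = est.tail_probs
    c = -np.log1p(-np.array([a, b]))
    t = np.array([est.lower, est.upper])
    u = float(np.dot(c, t) / np.dot(c, c))  # u = 1/rate
    if u <= 0:
        raise FitError("exponential fit produced a non-positive scale", residual=None)
    rate = 1.0 / u
    resid = quantile_match_objective((rate,), "exponential", (est.lower, est.upper, est.level))
    return FittedDist("exponential", (rate,), resid, source=est)


def _fit_poisson(est: EstimateCI) -> FittedDist:
    targets = (est.lower, est.upper, est.level)

    def obj(log_mu):
        return quantile_match_objective((math.exp(log_mu),), "poisson", targets)

    # the objective is flat (saturated CDF) away from a narrow dip near
    # the interval midpoint; locate the dip with a coarse grid in log-mu,
    # then refine with a bounded scalar search inside the winning cell
    m = max(0.5 * (est.lower + est.upper), 1e-8)
    grid = np.linspace(math.log(m) - 4.0, math.log(m) + 4.0, 401)
    values = [obj(g) for g in grid]
    i = int(np.argmin(values))
    res = optimize.minimize_scalar(
        obj,
        bounds=(grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]),
        method="bounded",
        options={"xatol": 1e-12},
    )
    mu = math.exp(res.x)
    resid = quantile_match_objective((mu,), "poisson", targets)
    return FittedDist("poisson", (mu,), resid, source=est)


def _fit_negative_binomial(est: EstimateCI) -> FittedDist:
    targets = (est.lower, est.upper, est.level)
    m, s = _pseudo_moments(est)
    m = max(m, 1e-6)
    v = max(s * s, 1.25 * m)  # enforce overdispersion for the start
    p0 = min(max(m / v, 1e-6), 1.0 - 1e-6)
    size0 = max(m * p0 / (1.0 - p0), 1e-6)
    x0 = np.array([math.log(size0), math.log(p0 / (1.0 - p0))])

    def obj(t):
        size = math.exp(t[0])
        prob = 1.0 / (1.0 + math.exp(-t[1]))
        return quantile_match_objective((size, prob), "negative_binomial", targets)

    res = optimize.minimize(
        obj, x0, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-20, "maxiter": 10_000},
    )
    size = math.exp(res.x[0])
    prob = 1.0 / (1.0 + math.exp(-res.x[1]))
    resid = quantile_match_objective((size, prob), "negative_binomial", targets)
    return FittedDist("negative_binomial", (size, prob), resid, source=est)


def fit_from_ci(est: EstimateCI, family: str) -> FittedDist:
    """Fit a distribution of the given family to a reported interval.

    The fitted distribution's quantiles at the interval's tail
    probabilities reproduce (lower, upper): exactly, within numerical
    tolerance, for the two-parameter continuous families (beta, normal,
    gamma); in the least-squares sense for one-parameter and discrete
    families, where ``fit_residual`` reports the remaining discrepancy.

    Raises
    ------
    DomainError
        If the bounds lie outside the family's support or the interval
        is degenerate.
    FitError
        If a two-parameter continuous fit does not reach residual
        <= 1e-10 * (upper - lower)**2.
    """
    if family not in FAMILIES:
        raise DomainError(f"unknown distribution family {family!r}; choose from {FAMILIES}")
    _check_support(est, family)
    if family == "normal":
        return normal_from_ci_closed_form(est)
    if family in ("beta", "gamma"):
        return _fit_two_param_continuous(est, family)
    if family == "exponential":
        return _fit_exponential(est)
    if family == "poisson":
        return _fit_poisson(est)
    return _fit_negative_binomial(est)
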