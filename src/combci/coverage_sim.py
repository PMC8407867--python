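"""Monte-Carlo validation of interval coverage.

Each scenario repeatedly simulates a complete study — binomial counts are
drawn at known true parameter values, exact Clopper-Pearson intervals are
computed from the counts, and the full fit-and-bootstrap pipeline is run
on those intervals exactly as a user would run it on published numbers.
The fraction of simulations whose interval contains the true combined
parameter estimates the procedure's actual coverage, reported with its
own exact binomial confidence interval.

The sensitivity/specificity scenario exposes ``assume_sens_spec_exact``
to quantify how badly the interval under-covers when the uncertainty in
the test's operating characteristics is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binom_exact import BinomCount, clopper_pearson
from .prevalence import (
    SensSpecAdjustInput,
    adjust_prev_sens_spec_ci,
    product_prevalences_ci,
)
from .errors import CombciError, DomainError

__all__ = ["CoverageResult", "sim_product_two_prevs", "sim_prev_sens_spec"]


@dataclass
class CoverageResult:
    """Empirical coverage of an interval procedure over repeated studies."""

    n_sims: int
    n_covered: int
    coverage_ci: tuple[float, float]
    scenario_params: dict
    seed: object = None
    n_excluded: int = 0  #: simulations skipped because no interval was computable

    @property
    def coverage(self) -> float:
        return self.n_covered / self.n_sims

    def to_row(self) -> dict:
        """Flat one-row record for CSV export."""
        row = dict(self.scenario_params)
        row.update(
            n_sims=self.n_sims,
            n_covered=self.n_covered,
            n_excluded=self.n_excluded,
            coverage=self.coverage,
            coverage_ci_lower=self.coverage_ci[0],
            coverage_ci_upper=self.coverage_ci[1],
            seed=self.seed,
        )
        return row


def _coverage_result(n_covered, n_eval, params, seed, n_excluded) -> CoverageResult:
    ci = clopper_pearson(BinomCount(n_covered, n_eval, 0.95))
    return CoverageResult(
        n_sims=n_eval,
        n_covered=n_covered,
        coverage_ci=(ci.lower, ci.upper),
        scenario_params=params,
        seed=seed,
        n_excluded=n_excluded,
    )


def sim_product_two_prevs(
    p1: float,
    p2: float,
    n_exp1: int,
    n_exp2: int,
    n_sims: int = 1000,
    level: float = 0.95,
    n_boot: int = 10_000,
    method: str = "percentile",
    seed: object = None,
) -> CoverageResult:
    """Coverage of the bootstrap interval for a product of two prevalences.

    Per simulation: draw x1 ~ Bin(n_exp1, p1) and x2 ~ Bin(n_exp2, p2),
    form their exact binomial intervals, run the beta-fit product
    bootstrap, and record whether p1*p2 lies inside the interval.  Any
    fit or bootstrap failure aborts the run, reporting the failing
    simulation index.
    """
    if not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
        raise DomainError("p1 and p2 must lie in (0, 1)")
    if n_exp1 < 1 or n_exp2 < 1:
        raise DomainError("sample sizes must be >= 1")
    truth = p1 * p2
    children = np.random.SeedSequence(seed).spawn(n_sims)
    n_covered = 0
    for i in range(n_sims):
        rng = np.random.default_rng(children[i])
        x1 = int(rng.binomial(n_exp1, p1))
        x2 = int(rng.binomial(n_exp2, p2))
        try:
            ci1 = clopper_pearson(BinomCount(x1, n_exp1, level))
            ci2 = clopper_pearson(BinomCount(x2, n_exp2, level))
            res = product_prevalences_ci(
                ci1, ci2, method=method, n_boot=n_boot, seed=rng
            )
        except CombciError as exc:
            raise CombciError(f"simulation {i} failed: {exc}") from exc
        if res.lower <= truth <= res.upper:
            n_covered += 1
    params = dict(
        scenario="product_two_prevs", p1=p1, p2=p2, n_exp1=n_exp1, n_exp2=n_exp2,
        level=level, n_boot=n_boot, method=method,
    )
    return _coverage_result(n_covered, n_sims, params, seed, 0)


def sim_prev_sens_spec(
    p: float,
    sens: float,
    spec: float,
    n_exp: int,
    n_exp_sens: int,
    n_exp_spec: int,
    n_sims: int = 1000,
    level: float = 0.95,
    n_boot: int = 10_000,
    assume_sens_spec_exact: bool = False,
    method: str = "percentile",
    seed: object = None,
) -> CoverageResult:
    """Coverage of the sensitivity/specificity-adjusted prevalence interval.

    The apparent prevalence follows from the true values as
    p_raw = p * sens + (1 - p) * (1 - spec); per simulation the three
    binomial counts (positives, sensitivity panel, specificity panel) are
    drawn at their stated sample sizes, exact intervals computed, and the
    adjustment bootstrap run — either with full three-way propagation or,
    with ``assume_sens_spec_exact``, holding sensitivity and specificity
    fixed at their simulated point estimates.

    Simulations where no interval is computable are counted, excluded and
    reported via ``n_excluded``: estimated sensitivity + specificity <= 1
    (test no better than chance in that replicate), or a simulated count
    hitting 0 or its maximum so that an exact-interval endpoint lands on
    the support boundary and no beta distribution can be fitted.
    """
    if not (0.0 < p < 1.0):
        raise DomainError(f"p must lie in (0, 1), got {p}")
    for name, v in (("sens", sens), ("spec", spec)):
        if not (0.0 < v <= 1.0):  # a perfect test is a legal limiting case
            raise DomainError(f"{name} must lie in (0, 1], got {v}")
    if sens + spec <= 1.0:
        raise DomainError("sens + spec must exceed 1")
    p_raw = p * sens + (1.0 - p) * (1.0 - spec)
    children = np.random.SeedSequence(seed).spawn(n_sims)
    n_covered = 0
    n_excluded = 0
    for i in range(n_sims):
        rng = np.random.default_rng(children[i])
        x = int(rng.binomial(n_exp, p_raw))
        x_s = int(rng.binomial(n_exp_sens, sens))
        x_sp = int(rng.binomial(n_exp_spec, spec))
        if x_s / n_exp_sens + x_sp / n_exp_spec <= 1.0:
            n_excluded += 1
            continue
        try:
            inp = SensSpecAdjustInput(
                prev_ci=clopper_pearson(BinomCount(x, n_exp, level)),
                sens_ci=clopper_pearson(BinomCount(x_s, n_exp_sens, level)),
                spec_ci=clopper_pearson(BinomCount(x_sp, n_exp_spec, level)),
                method=method,
                n_boot=n_boot,
                seed=rng,
                sens_spec_exact=assume_sens_spec_exact,
            )
            res = adjust_prev_sens_spec_ci(inp)
        except DomainError:
            # exact-interval endpoint on the support boundary: no beta fit
            n_excluded += 1
            continue
        if res.lower <= p <= res.upper:
            n_covered += 1
    n_eval = n_sims - n_excluded
    if n_eval == 0:
        raise CombciError("every simulation was excluded; check the scenario values")
    params = dict(
        scenario="prev_sens_spec", p=p, sens=sens, spec=spec, n_exp=n_exp,
        n_exp_sens=n_exp_sens, n_exp_spec=n_exp_spec, level=level,
        n_boot=n_boot, method=method,
        assume_sens_spec_exact=assume_sens_spec_exact,
    )
    return _coverage_result(n_covered, n_eval, params, seed, n_excluded)
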