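"""Clopper-Pearson exact binomial confidence intervals.

The exact interval for x successes in n trials comes from the duality
between binomial tail sums and the beta distribution: the lower bound is
the (alpha/2) quantile of Beta(x, n - x + 1) and the upper bound the
(1 - alpha/2) quantile of Beta(x + 1, n - x), with the conventions
lower = 0 at x = 0 and upper = 1 at x = n.  The interval is conservative:
its true coverage is at least the nominal level for every (n, p).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .distfit import EstimateCI
from .errors import DomainError

__all__ = ["BinomCount", "clopper_pearson"]


@dataclass(frozen=True)
class BinomCount:
    """x successes out of n trials, with a requested confidence level."""

    successes: int
    trials: int
    level: float = 0.95

    def __post_init__(self):
        if self.trials < 1:
            raise DomainError(f"trials must be >= 1, got {self.trials}")
        if not (0 <= self.successes <= self.trials):
            raise DomainError(
                f"successes must lie in [0, trials], got {self.successes}/{self.trials}"
            )
        if not (0.0 < self.level < 1.0):
            raise DomainError(f"level must lie in (0, 1), got {self.level}")

    @property
    def proportion(self) -> float:
        return self.successes / self.trials


def clopper_pearson(count: BinomCount | int, trials: int | None = None,
                    level: float = 0.95) -> EstimateCI:
    """Exact binomial confidence interval via the beta-quantile formulation.

    Accepts either a :class:`BinomCount` or ``(successes, trials[, level])``
    directly.  Returns an :class:`EstimateCI` whose point estimate is the
    observed proportion.
    """
    if not isinstance(count, BinomCount):
        if trials is None:
            raise DomainError("trials must be given when successes is an integer")
        count = BinomCount(int(count), int(trials), level)
    x, n = count.successes, count.trials
    a = (1.0 - count.level) / 2.0
    lower = 0.0 if x == 0 else float(stats.beta.ppf(a, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1.0 - a, x + 1, n - x))
    return EstimateCI(lower=lower, upper=upper, level=count.level, point=x / n)
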