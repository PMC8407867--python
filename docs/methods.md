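# Methods

## Model

A parameter of interest φ is a function g of k parameters θ₁…θₖ that were
estimated independently, each published as a point estimate with a
(1−α)·100% confidence interval. The estimator Θⱼ of each θⱼ is modelled
as following a parametric distribution Fⱼ; the reported interval is
treated as a pair of quantiles of Fⱼ, from which F̂ⱼ is recovered. A
parametric bootstrap then simulates the joint sampling variability:
θ⁽ᵇ⁾ ~ (F̂₁,…,F̂ₖ) independently for b = 1…B, φ⁽ᵇ⁾ = g(θ⁽ᵇ⁾), and the
interval for φ is an interval of the empirical distribution of
{φ⁽ᵇ⁾}.

Assumptions worth stating explicitly:

* **Independence.** Replicates are drawn independently per parameter.
  If the input estimates share data or design, the resulting interval is
  wrong in an unquantified direction. Nothing in the code can detect
  this.
* **Distributional adequacy.** The interval is assumed to be a central
  two-sided quantile pair of a distribution in the chosen family. A
  profile-likelihood or otherwise asymmetric interval from a family with
  a different shape will be distorted by the fit.
* **The reported bounds are exact.** Rounding in the published bounds
  propagates directly into the fitted parameters.

## Quantile-matching fits

For a family with CDF F(·; ψ) the fit minimises

    h(ψ) = (F⁻¹(α/2; ψ) − l)² + (F⁻¹(1−α/2; ψ) − u)²

over legal ψ. Implementation choices:

* **Search space.** All positivity/interval constraints are removed by
  log (shapes, rates, σ) and logit (probabilities) transforms, so the
  optimisers work unconstrained and can never leave the legal domain.
  Outside-domain evaluations return a large finite penalty, never NaN.
* **Two-parameter continuous families (beta, gamma).** The two quantile
  equations are solved directly with a hybrid Powell root finder started
  from method-of-moments values (pseudo-mean m = (l+u)/2, pseudo-sd
  s = (u−l)/(2z), z the normal quantile at 1−α/2). A Nelder–Mead
  polish is used as fallback. The fit is declared failed if the residual
  exceeds 1e-10·(u−l)²; for well-posed inputs the achieved residual is
  at machine-precision level (≤1e-20), i.e. the match is exact for all
  practical purposes.
* **Normal.** Closed form: μ = (l+u)/2, σ = (u−l)/(2z).
* **Exponential.** The two constraints over-determine the single rate.
  Because the quantiles are linear in 1/rate, the least-squares
  compromise has the closed form rate = Σc² / Σc·t with
  c = −ln(1−p) at the two tail probabilities and t = (l, u). The
  residual is reported — a user fitting an exponential to an interval an
  exponential cannot produce will see a large `fit_residual`.
* **Discrete families (Poisson, negative binomial).** The step-shaped
  quantile function is not invertible, so the CDF is matched at the
  bounds instead: (F(⌊l⌋;ψ) − α/2)² + (F(⌊u⌋;ψ) − (1−α/2))². For the
  Poisson the objective in log-mean is a narrow dip between two flat
  plateaus where the CDF saturates at 0 or 1; a 401-point grid scan
  locates the dip before a bounded scalar search refines it. The
  negative binomial uses Nelder–Mead on (log size, logit prob).
* **The point estimate never enters the fit** — only the bounds and the
  level. It is carried through for reporting so that the combined point
  estimate g(θ̂₁,…,θ̂ₖ) can be printed alongside the interval.

A note on published reference values for this fit: quantile matching at
double precision pins the beta parameters to far more digits than
optimisers with loose stopping rules report. Values computed with an
early-stopping simplex search can differ from the converged optimum by
a few tenths of a percent while matching the quantiles only to ~1e-5;
this package always reports the converged optimum and the achieved
residual, so such discrepancies are visible rather than silent.

## Interval extraction

* **Percentile method** (default): the empirical α/2 and 1−α/2 quantiles
  with linear interpolation of order statistics (numpy's default, the
  classic "type 7" convention). Fixed and documented so that order-
  statistic oracles in the tests are well defined.
* **HDI**: over the sorted sample, the narrowest window of
  m = ⌈(1−α)·B⌉ consecutive order statistics; ties broken toward the
  lowest window, so output is deterministic. The HDI is never wider than
  the percentile interval and is preferable for skewed unimodal
  samples, but it is a *single* interval: for multimodal bootstrap
  distributions it can cover low-density valleys. The package does not
  try to detect multimodality — it provides the histogram summary
  (`sample_histogram_summary`, exported by the CLI as CSV/plot) and the
  CLI logs an advisory whenever the HDI method is selected; inspection
  is the user's job.
* HDI endpoints carry more Monte-Carlo noise than central quantiles and
  the minimal-width statistic is biased short at small B; published HDI
  endpoints obtained from single runs at modest B can therefore sit
  several of this package's large-B standard errors away from the
  population value.

Non-finite combined draws (possible when a sampler's support edge makes
g undefined, e.g. a non-positive Rogan–Gladen denominator) are dropped
with a warning when rarer than 0.1% and raise an error above that,
since a high rate signals a mis-specified g.

Default B is 10⁶ for one-shot interval calls — enough that the 2.5%
quantile of a smooth unimodal sample is stable to ~3 decimal places —
and 10⁴ inside coverage simulations, where interval noise averages out
across replicates and runtime matters.

## Prevalence applications

Probability parameters are always fitted with the beta family in the
convenience routines (`product_prevalences_ci`,
`adjust_prev_sens_spec_ci`); other families make little sense for
parameters confined to (0,1), and power users can assemble any
combination through `boot_comb` directly.

The Rogan–Gladen adjustment (π̂_raw + spec − 1)/(sens + spec − 1) can
produce draws below 0 (when a raw-prevalence draw falls below the
false-positive rate draw) — about 1% of draws in the worked example.
They are legitimate realizations of the estimator and are **retained by
default** so the interval reflects the estimator's true sampling
distribution; `truncate_to_unit=True` clips draws into [0,1] first, for
users who need a proper probability. The fraction outside [0,1] is
always reported (`out_of_unit_fraction`).

`sens_spec_exact=True` replaces the sensitivity and specificity samplers
with point masses at their point estimates. This reproduces the common
shortcut of treating the assay's operating characteristics as known —
and the coverage simulations quantify its cost.

## Coverage simulations

Each scenario regenerates complete studies at known truth: binomial
counts at the stated sample sizes, Clopper–Pearson intervals from the
counts, the full fit-and-bootstrap pipeline on those intervals, and a
hit/miss against the true combined value. Coverage is reported with its
own Clopper–Pearson 95% interval. Per-simulation RNG streams are spawned
from one master `SeedSequence`, so runs replay exactly and an excluded
simulation cannot shift the stream of later ones.

The sensitivity/specificity scenario generates the apparent prevalence
from the truth via π_raw = π·sens + (1−π)·(1−spec). Two kinds of
replicate are counted and excluded rather than aborting the run
(`n_excluded`): estimated sens + spec ≤ 1 (the adjustment is undefined),
and a count hitting 0 or its maximum, which puts a Clopper–Pearson
endpoint exactly on 0 or 1 where no beta distribution can match it. At
the default scenario (spec = 0.932, n_spec = 88) the boundary case
occurs in ≈0.2% of replicates, so the exclusion shifts coverage by well
under a percentage point. The interval method inside simulations is the
percentile method, the package default.

Simulation sizes used by the shipped reproduction script and acceptance
tests — 1000 simulated studies with B = 10⁴ each — were chosen so that
the binomial standard error of a coverage estimate (~0.7pp at 95%) is
the dominant uncertainty, with bootstrap noise per replicate an order
of magnitude smaller.

What the simulations do **not** emulate: real studies whose published
intervals are not exact binomial intervals, dependence between the
estimates, model misspecification of the beta family, and rounding of
published bounds. Passing coverage here validates the propagation
machinery under its own assumptions, not the assumptions themselves.

## CLI design

The combination function in config files is a restricted arithmetic
expression (+ − * / **, unary sign, parentheses, exp/log/log2/log10/
sqrt/abs) compiled by walking Python's `ast` against a whitelist —
configs cannot execute arbitrary code. The library API accepts arbitrary
callables. Every stage logs fitted parameters, residuals and seeds, so
any reported interval can be replayed from the log alone.

## Known limitations

* No joint/dependent parameter modelling; independence is assumed, not
  checked.
* Single-interval HDI only; no multi-interval output for multimodal
  samples.
* No BCa/studentized bootstrap variants — the percentile and HDI methods
  are the only extraction rules.
* One-parameter families cannot honour both bounds; the least-squares
  compromise is flagged through `fit_residual` but it is still the
  user's responsibility to check it before trusting the interval.
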