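# combci

Confidence intervals for a parameter that is an arbitrary function of
several *independently* estimated quantities, each known only through a
published point estimate and confidence interval.

A typical user is an epidemiologist combining numbers from different
studies: the population prevalence of a co-infection as
p(co-infection | carrier) × p(carrier), or a seroprevalence corrected for
the sensitivity and specificity of the antibody assay, where each input
has its own reported 95% CI and the naive interval arithmetic
(g applied to the endpoints) is far too wide.

## Method

For each input parameter θⱼ with reported interval [lⱼ, uⱼ] at level 1−α,
fit a parametric distribution F̂ⱼ by **quantile matching**: choose the
family's parameters so that the α/2 and 1−α/2 quantiles equal lⱼ and uⱼ.
Six families are supported — beta, normal, gamma (exact two-parameter
matches), exponential, Poisson, negative binomial (least-squares
compromise with the achieved residual reported). Then propagate by
**parametric bootstrap**: draw B independent replicates
θ⁽ᵇ⁾ ~ (F̂₁, …, F̂ₖ), compute φ⁽ᵇ⁾ = g(θ⁽ᵇ⁾), and read the interval for
φ off the sample {φ⁽ᵇ⁾} — the central percentile interval or the
highest-density interval (HDI), the shortest window containing a
fraction 1−α of the draws.

Built-in applications:

* **Product of two prevalences** — beta fits, g = product.
* **Rogan–Gladen adjustment** π̂ = (π̂_raw + spec − 1)/(sens + spec − 1),
  with the uncertainty of all three inputs propagated jointly.
* **Coverage simulations** that repeatedly regenerate binomial counts at
  known truth, rerun the whole pipeline, and measure how often the
  interval covers — demonstrating, for example, that ignoring
  sensitivity/specificity uncertainty collapses coverage from ≈95% to
  ≈75%.
* **Clopper–Pearson exact binomial intervals** to turn raw counts into
  the intervals the fitters consume.

Everything assumes the input estimates are independent; correlated
estimates need a joint model and are out of scope.

## Worked example

Population prevalence of a rare co-infection, combining an HBsAg carrier
prevalence of 3.5% (95% CI 2.7–5.0%) with a conditional prevalence of
4.5% (95% CI 3.6–5.7%):

```python
from combci import EstimateCI, fit_from_ci, product_prevalences_ci

carrier = EstimateCI(lower=0.027, upper=0.050, point=0.035)
conditional = EstimateCI(lower=0.036, upper=0.057, point=0.045)

fit = fit_from_ci(carrier, "beta")
print(fit.params)        # (39.45, 1007.85) — beta whose 2.5/97.5% quantiles
                         # are exactly 0.027 and 0.050

res = product_prevalences_ci(conditional, carrier, n_boot=10**6, seed=1)
print(res.estimate)                              # 0.001575
print(round(res.lower, 6), round(res.upper, 6))  # 0.001145 0.002467
```

The combined prevalence is 0.16% with 95% CI (0.11%, 0.25%): far
narrower than the naive endpoint product (0.027 × 0.036, 0.050 × 0.057) =
(0.097%, 0.29%).

Seroprevalence adjusted for an imperfect assay, straight from counts
(84/500 positive, sensitivity panel 238/270, specificity panel 82/88):

```python
from combci import (clopper_pearson, SensSpecAdjustInput,
                    adjust_prev_sens_spec_ci)

adj = adjust_prev_sens_spec_ci(SensSpecAdjustInput(
    prev_ci=clopper_pearson(84, 500),
    sens_ci=clopper_pearson(238, 270),
    spec_ci=clopper_pearson(82, 88),
    method="hdi", n_boot=10**6, seed=1))
print(round(adj.estimate, 7))                    # 0.1227324
print(round(adj.lower, 4), round(adj.upper, 4))  # 0.0357 0.1927
print(adj.out_of_unit_fraction)  # 0.009079 — share of draws < 0 (kept, not clipped)
```

The same runs are available from the shell:

```sh
combci fit-dist --family beta --lower 0.027 --upper 0.050
combci binom-ci 84 500
combci adjust-prev --prev-counts 84 500 --sens-counts 238 270 \
    --spec-counts 82 88 --method hdi --seed 1
combci combine --config my_run.yaml --seed 1   # arbitrary expressions, plots
combci sim-coverage prev-sens-spec --p 0.1227 --sens 0.881 --spec 0.932 \
    --n 500 --n-sens 270 --n-spec 88 --seed 1
```

`combine` reads a YAML config listing named parameters (family, lower,
upper, optional point/level), an arithmetic `expression` over those names
(`"pHBsAg * pHDVgivenHBsAg"`), and optional output paths for the JSON
report, the bootstrap sample CSV, the histogram CSV and diagnostic plots
(fitted densities, bootstrap histogram with the interval overlaid).

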