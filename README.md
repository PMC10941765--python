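# ndoikit

Toolkit for the **index of notifiable disease outbreaks (NDOI)** — a composite
monthly indicator of how intensely a register of notifiable infectious
diseases is flaring up — together with the surrounding surveillance
analytics: transmission-route-stratified case tables, a synthetic
surveillance-data generator, pre/post-pandemic change reports, univariate
screening statistics, and linear constrained ordination (RDA) with a Monte
Carlo permutation test.

It is written for epidemiologists and public-health analysts who work with
monthly notifiable-disease report tables (months × diseases counts, each
disease assigned to one of four transmission routes: direct-contact,
water-and-food, airborne, vector-borne) and panels of monthly environmental
or socioeconomic covariates.

## The index

For period *i* within a stratum (all diseases or one route), let *n_i* be the
total confirmed cases and *t_i* the number of distinct diseases with at least
one case. Both are min–max normalized over the analysis window,

    N_i = (n_i − min n) / (max n − min n),     T_i analogous,

and combined as a convex combination

    NDOI_i = α·N_i + β·T_i,     α + β = 1,

so NDOI ∈ [0, 1]: 1 in a month attaining both window maxima, 0 at both
minima. The weights are derived from the data by the **entropy weight
method** (the indicator with lower Shannon entropy across months — more
dispersion, more signal — gets more weight), or fixed to the published
Shanghai 2017–2020 calibration α = 0.51, β = 0.49 for replication.

Around the index the package provides:

* `rate_of_change(pre, post)` — signed percent change of a post-period value
  against the mean of pre-period annual values, the summary used for
  pandemic-impact tables;
* `rda(species, env)` / `RDA` — redundancy analysis (multivariate least
  squares of the disease matrix on covariates, then PCA of the fitted
  values), with rare-disease filtering, per-covariate marginal explained
  variance, and a permutation test (p = (1 + exceedances)/(1 + permutations));
* `simulate_surveillance(config)` — negative-binomial seasonal counts with a
  step "pandemic" intervention and planted covariate–disease effects, so the
  whole pipeline is testable without restricted surveillance data;
* a packaged fixture with the published Shanghai 2017–2020 annual summary
  (32 diseases, four routes, annual case totals and NDOI values).

## Worked example

```python
from ndoikit import (default_shanghai_like_config, simulate_surveillance,
                     compute_ndoi, annual_ndoi_means, rare_filter, rda)

config = default_shanghai_like_config(seed=42)   # 32 diseases, 48 months
cases, covariates = simulate_surveillance(config)

series = compute_ndoi(cases, stratum="all", weights="auto")
print("entropy weights: alpha=%.3f beta=%.3f" % (series.weights.alpha, series.weights.beta))
print(annual_ndoi_means(series).round(3))

result = rda(rare_filter(cases, 0.05).counts, covariates.values,
             n_permutations=499, random_state=42)
print("constrained fraction: %.1f%%" % (100 * result.constrained_fraction))
print("overall permutation p: %.3f" % result.permutation_p["overall"])
```

prints

```
entropy weights: alpha=0.664 beta=0.336
2017    0.529
2018    0.576
2019    0.622
2020    0.179
Name: ndoi, dtype: float64
constrained fraction: 47.1%
overall permutation p: 0.002
```

The simulated register behaves like the real one: the index is roughly
stable over the three pre-pandemic years, then collapses in the intervention
year (here 0.62 → 0.18, a 71% drop, driven by the per-route case
multipliers in the config); the covariate panel explains about half of the
disease variance and the association is significant at the smallest
attainable p (1/500 with 499 permutations).

The same steps are available from the shell:

```sh
ndoikit simulate --seed 42 --out sim/
ndoikit run sim/cases.csv --covariates sim/covariates.csv --out results/
ndoikit replicate-table2
```

`replicate-table2` recomputes every rate of change in the packaged Shanghai
annual summary from its annual totals and confirms each disease-level rate
agrees with the printed value to 0.1 percentage points (e.g. all-disease
cases −47.1%, NDOI −52.6%, hand-foot-and-mouth disease −83.5%).

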