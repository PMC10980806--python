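# finwhale

Line-transect distance sampling and Monte-Carlo krill-consumption
estimation for Southern Ocean fin whale (*Balaenoptera physalus*)
shipboard surveys, built around the design of the 2019 multi-vessel
Scotia Sea krill survey (CCAMLR Area 48; strata AP, SS and ESS).

It is aimed at cetacean survey analysts and ecosystem modellers who
need a fully scripted, testable pipeline from raw observation logs to
stratified abundance estimates and population-level prey-consumption
figures.

## What it computes

**Detection function.** Perpendicular distances x of detected groups
are modelled with the half-normal key g(x) = exp(−x²/2σ²) or the
hazard-rate key g(x) = 1 − exp(−(x/σ)^−b), with observation-level
covariates (observer, ln group size, wind speed, vessel) entering the
scale on the log link, σ(z) = exp(β₀ + Σβⱼzⱼ). Fitting maximises the
conditional likelihood Π g(xᵢ|zᵢ)/μ(zᵢ) with μ(z) = ∫₀ʷ g(u|z) du the
effective strip width (ESW), truncated at w = 7,000 m. Models are
ranked by AIC; absolute fit is screened with a Cramér–von Mises test.

**Abundance.** Per stratum, the Horvitz–Thompson estimator
D̂ = Σᵢ sᵢ/μᵢ / (2L) (sᵢ group size, L effort) gives density, N̂ = D̂·A
abundance. CVs combine the between-transect ("R2") encounter-rate
variance, var(P̂ₐ) by the delta method and var(Ē_s); 95% CIs are
lognormal. Strata combine by summing abundances and variances.

**Consumption.** Per-capita daily krill rations come from four
published allometric sets C = αM^β and from an energetic budget
(Kleiber BMR = 3.39·M^0.75 W plus cost of transport
(λ/2ε_Aε_P)·ρSC_dV³ over a prolate-spheroid body surface), propagated
through lognormal abundance draws and normal body-mass draws
(60 t, CV 0.2) over a 180-day feeding season.

**Synthetic surveys.** Because the 2019 field data are not publicly
deposited, the `synthetic_data` module generates surveys with known
truth at the real survey's scale (3 strata, 11,341 km of effort in 272
transects, hazard-rate detectability varying by observer and wind,
mean group size 1.77) so that every estimator can be validated by
parameter recovery and CI coverage.

## Worked example

```python
import numpy as np
from finwhale import detection, abundance, synthetic_data, consumption

# a survey at the 2019 survey's scale, with known truth
ds, truth = synthetic_data.scenario_paperlike(seed=7)
print(len(ds.sightings), round(truth["true_abundance_total"]))
# 440 26119

fit = detection.fit_detection(
    ds.sightings, "hazard_rate", ("obs", "wind_speed"), ds.truncation_m
)
print(round(fit.pa, 3), round(fit.cvm_p, 3), round(np.exp(fit.params[0]), 3))
# 0.379 0.971 1.721          (average detectability, CvM p, shape b)

print(abundance.abundance_table(fit, ds).round(3).to_string())
```

```
stratum  n_groups  er_groups  density_individuals  abundance  cv_abundance  ci_lower  ci_upper
     AP        99      0.038                0.011    5907.1         0.154    4374.3    7976.8
     SS       313      0.046                0.016   19339.9         0.105   15766.1   23723.7
    ESS        28      0.015                0.005    1814.5         0.209    1209.7    2721.7
    All       440      0.039                0.013   27061.4         0.083   22999.6   31840.6
```

The combined estimate (27,061; CV 0.083) covers the generating truth
of 26,119 whales. Consumption at the published survey estimate
(N = 53,873, CV 0.149):

```python
cfg = consumption.ConsumptionConfig(n_sim=10_000, seed=1)
for r in consumption.run_consumption(cfg):
    print(r.method, r.alpha, r.individual_daily, r.population_annual)
```

```
allometric 0.177  0.972 t/day   9,529,953 t/season
allometric 1.660  0.774 t/day   7,589,247 t/season
allometric 0.420  0.665 t/day   6,515,699 t/season
allometric 0.123  0.815 t/day   7,986,232 t/season
energetic   —     0.885 t/day   8,679,422 t/season
```

giving a five-method mean of ≈8.06 million tonnes of krill per season
for the combined survey area — roughly 20× the commercial krill catch
taken in Area 48 in the same season
(`consumption.consumption_ratio(8.06e6, 390_168)` ≈ 20.7).

The same chain is available from the shell:

```sh
finwhale simulate --seed 7 --out survey/
finwhale preprocess survey/ --out clean/
finwhale fit clean/ --out fits/
finwhale estimate clean/ --out estimates/
finwhale consume --seed 1 --out consumption/
finwhale project 5500 0.04 25      # -> 14662
```

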