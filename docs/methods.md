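# Methods

This note documents the statistical models, numerical choices and
design decisions behind `finwhale`, and what the synthetic-data tests
do and do not demonstrate about real survey data.

## Survey preprocessing

Raw sighting logs carry radial distance r and sighting angle α
relative to the bow (signed, port negative). The analysis distance is
the perpendicular distance x = r·|sin α|; the absolute value folds
port-side sightings onto a single-sided axis, which is the convention
the single-observer detection model requires. Preprocessing applies,
in order:

1. **Species filter** — only certain ("fin") and likely ("like_fin")
   identifications are retained, weighted identically thereafter.
2. **Primary-quadrant filter** — each vessel's dedicated observers
   covered particular forward quadrants (KPH port, CDH starboard, DIS
   both); sightings outside them are incidental and removed. Interval
   bounds are closed.
3. **Truncation** — sightings with x strictly greater than
   w = 7,000 m are removed (the boundary value is kept); distant
   sightings have unreliable species identification and degrade
   detection-function fits.
4. **Transect splitting** — contiguous on-effort legs form one
   transect; a new transect starts at any off-effort gap, stratum
   change, or circular heading change ≥ 35°. The ≥ (closed) threshold
   is a documented choice; the circular difference avoids spurious
   splits across north (350° → 5° is a 15° turn). Total on-effort
   length is conserved exactly.
5. **Covariate fill** — missing sighting-level wind speeds take the
   temporally nearest weather record of the same vessel, prior or
   subsequent; an exact tie goes to the prior record.

Internal units are metres for detection distances, kilometres for
effort and km² for areas; nautical-mile effort input is converted on
read (1 nm = 1.852 km). Legs connecting main transects are retained.

## Detection function

Two keys are supported: half-normal g(x) = exp(−x²/2σ²) and
hazard-rate g(x) = 1 − exp(−(x/σ)^−b) (g(0) := 1, its limit). The
hazard-rate shape b > 0 controls the shoulder. Covariates enter only
the scale, on the log link σ(z) = exp(β₀ + Σβⱼzⱼ): this is the
standard multiple-covariate distance sampling (MCDS) conditional
formulation, and it makes the likelihood invariant to affine recoding
of a covariate. Observer and vessel are categorical with treatment
coding (reference = alphabetically first level); group size enters as
its natural log, the conventional MCDS practice; wind speed enters
raw in m/s. A categorical covariate with a single observed level is
dropped with a warning.

The log-likelihood is Σᵢ [log g(xᵢ|zᵢ) − log μ(zᵢ)], with
μ(z) = ∫₀ʷ g the effective strip width. Cosine series adjustments
(null models only) multiply the key by
(1 + Σ aₘ cos(mπx/w)) / (1 + Σ aₘ), so g(0) = 1 is preserved;
parameter vectors producing a negative g anywhere on [0, w] (checked
on a 201-point grid) are rejected inside the optimiser.

**Numerics.** μ is computed by 64-node Gauss–Legendre quadrature on
[0, w], validated in the tests against a 10⁵-point trapezoid oracle to
1e−6 relative; the integrand is smooth so this is far inside tolerance.
Optimisation is L-BFGS-B on (log b, β, a) from a heuristic start
(σ₀ = RMS distance for half-normal, median distance with b₀ = 2 for
hazard-rate) plus five jittered restarts with a fixed jitter seed —
fits are deterministic given the data. Invalid regions return a large
finite penalty (1e10) so finite-difference gradients stay clean.
Convergence: ftol 1e−12, gtol 1e−9, 500 iterations. A fitted baseline
scale above 2w triggers a "no decline" warning (the likelihood is flat
there; the data carry no distance signal). The covariance matrix is
the pseudo-inverse of a central-difference Hessian of the negative
log-likelihood.

**Derived quantities.** Average detectability is the
Horvitz–Thompson-consistent P̂ₐ = n / Σᵢ(1/pᵢ) with pᵢ = μᵢ/w; its
standard error comes from the delta method. With no covariates P̂ₐ
equals μ/w exactly. Model selection is by AIC (= 2k − 2ℓ). Goodness
of fit uses the Cramér–von Mises statistic on the probability-integral
transforms uᵢ = Fᵢ(xᵢ) of each observation under its own conditional
fitted CDF, with the classical asymptotic p-value and no
parameter-estimation correction — the test is used only as a screen at
p > 0.05, and the uncorrected p-value is conservative in that
direction (estimated parameters shift p-values upward, never toward
spurious rejection).

## Abundance estimation

Within a stratum of area A with effort L, individual density is the
Horvitz–Thompson sum over detected groups, D̂ = Σᵢ sᵢ/μᵢ / (2L) (μᵢ in
km); group density uses sᵢ = 1, and N̂ = D̂·A. With constant
detectability p this reduces exactly to n·Ē_s·A/(2wLp), an identity
the tests verify to 1e−9.

Variance components, combined as cv² sums by the delta method:

* **Encounter rate** — the between-transect "R2" estimator
  var(n/L) = k/(L²(k−1)) Σⱼ lⱼ²(nⱼ/lⱼ − n/L)², the default in
  standard distance-sampling software; a stratum with one transect has
  no variance estimate and is flagged.
* **Detectability** — cv(P̂ₐ) from the fit.
* **Group size** — cv of the unweighted mean of observed sizes. No
  size-bias regression is applied: detection in the model does not
  depend on size, and the survey's published per-stratum expected
  group sizes equal simple means of the observed sizes.

95% intervals are the standard lognormal form (N/C, N·C),
C = exp(q√(ln(1+cv²))) with q the normal 0.975 quantile; a Student-t
quantile with user-supplied df is available and reproduces slightly
wider published-style bounds. Strata combine by summing N̂ and
variances (independence by design); combined density is N̂_all/ΣA.
Where a survey's published pooled row differs from the sum of its
strata, this package always reports the sum.

## Krill consumption

Per-capita daily rations (kg/day, M in kg):

* **Allometric** — C = αM^β for the four published parameter sets
  (0.177, 0.783), (1.660, 0.559), (0.420, 0.670), (0.123, 0.800).
* **Energetic** — annual energy = (BMR + P_COT)·86,400·365 J with
  Kleiber BMR = 292.9·M^0.75 kJ/day ≡ 3.39·M^0.75 W and
  P_COT = (λ/2ε_Aε_P)·ρSC_dV³, S the surface of a prolate spheroid
  with semi-axes a = length/2, b = circumference/2π
  (S = 2πb²(1 + (a/be)·asin e)). The ration converts the seasonal
  fraction (0.8) of the annual budget over the season length at the
  krill energy density (4,400 J/g) and assimilation efficiency (0.9).

Defaults: body mass 60 t (CV 0.2), length 20 m, circumference 2.7π m,
λ = 0.7, ρ = 1027 kg/m³, C_d = 0.003, season 180 days. The published
analysis states a 120-day residence assumption in its methods but its
tabulated annual values are daily × 180 and its results text uses 180
days; the default here is 180 to be consistent with the tabulated
rates, and 120 is selectable by config. The efficiencies ε_A = 0.25,
ε_P = 0.75 and speed V = 2.5 m/s are not printed in the source
analysis; these defaults are a calibration chosen so the 60-t
energetic ration (0.887 t/day) matches the published simulated mean
(0.882 t/day) within 1%, and all three are overridable. The BMR
expression is implemented in Kleiber's units (kJ/day, equivalently W
after the correct 86.4·10³ scaling); the printed "×86.4" conversion is
dimensionally inconsistent as stated and reproducing it literally
would misstate the ration by orders of magnitude.

**Simulation design.** Each of n_sim draws takes one abundance
Nⱼ ~ exp(Normal(ln N̂, √ln(1+cv²))) — the log-scale location is ln of
the estimate, so back-transformed draws average ≈ cv²/2 (+1.1% at
cv 0.149) above N̂; this follows the source's log-transform wording
and the small bias is documented rather than corrected — and a cohort
of body masses (default 256) from Normal(60 t, 12 t), resampling
non-positive values. Individual-level results use the first mass of
each cohort (one mass per draw), so their 5–95% quantiles reflect
between-individual mass variation. Population-level results multiply
Nⱼ by the cohort-mean ration: with one mass per individual in a
population of ~5·10⁴, mass variation contributes cv ≈ 0.157/√N ≈ 0.001
to the population total, so a 256-mass cohort (cv ≈ 0.01) reproduces
the per-individual design's population quantiles at a small fraction
of its cost. Quantiles are empirical (type 7). All randomness flows
from a single seed in the config.

Projections are geometric, N₀(1+r)^t, and consumption ratios are
simple quotients against a reference tonnage (fishery catch or krill
standing stock).

## Synthetic surveys

The generator emulates the 2019 survey design: strata AP/SS/ESS with
areas 527/1,231/368 ×10³ km², efforts 2,633/6,839/1,869 km in
60/170/42 transects, three vessels with their quadrant conventions,
and seven observers. Groups are placed by a Poisson process (optional
Neyman–Scott hotspot clustering with configurable mean cluster size)
in the 2w strip, sized by a zero-truncated Poisson with mean 1.77
(λ ≈ 1.283), and thinned by a hazard-rate model with σ = 1,200 m,
b = 1.555, per-observer log-scale effects fixed at the septile
midpoints of Normal(0.129, 0.5), and a wind coefficient of −0.0125
per m/s acting on a bounded per-vessel random walk (mean 5 m/s,
clipped to [0, 12]). Observer effects and the transect plan are
deterministic (seed-free) so expected counts are computable in closed
form; stratum densities in `scenario_paperlike` are calibrated once so
the expected detected group counts (wind at its mean) equal the real
survey's realised counts (96/311/24). Angles are drawn uniformly over
[5°, 90°] magnitude in each vessel's primary quadrant and radial
distance is back-computed from x, so the preprocessing path is
exercised end to end.

What passing tests show: the estimators are consistent and their CIs
approximately calibrated *under the generating model* — independent
uniform placement (or mild clustering), scale-only covariate effects,
exact covariate recording, g(0) = 1, no responsive movement. What they
do not show: robustness to availability/perception bias, distance or
angle measurement error, strong spatial aggregation matched to real
whale behaviour, or duplicate sightings — none of which the estimator
corrects for in real data either (the published estimates are likewise
uncorrected, hence conservative).

## Problem sizes used in validation

Parameter-recovery checks use n = 10,000 distances (recovery of σ and
b within 5%); CI-coverage and bias checks use 50 independent
survey-scale replicates (coverage required within [88%, 99%], mean
relative bias within 3%); sign-recovery and AIC-selection simulation
checks use 15–20 replicates at n = 1,000–2,500 with thresholds set
where the detectable effect is near-certain; distributional checks
(PIT uniformity, KS against f = g/μ, Poisson dispersion) use 40–120
seeds at the sizes stated in each test. The consumption engine's
published-value checks use 10,000 draws.

## Known limitations

* Hazard-rate fits on small strata can sit on flat likelihood ridges
  (σ–b trade-off); multi-start optimisation mitigates but a global
  optimum is not guaranteed.
* The delta-method cv treats encounter rate, detectability and group
  size as independent; with covariate models sharing data across
  strata this is the standard approximation, not exact.
* The Cramér–von Mises p-value ignores parameter estimation (see
  above).
* No bootstrap variance, no mark–recapture (dual-platform) options,
  no left truncation or binned distances, no density surface
  modelling.
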