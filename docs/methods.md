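# Methods

## Gravimetric water flux

Each pot is weighed every third day and re-irrigated to a fixed target
weight immediately after weighing. For consecutive weighings at DAS
t₁ < t₂ the evapotranspiration rate is

    ET = (W(t₁) + irrigation − W(t₂)) / (t₂ − t₁)   [ml d⁻¹, 1 g ≡ 1 ml]

assigned to the interval midpoint. This telescopes exactly: per pot,
Σ irrigation − ΔW = Σ ET·Δt identically, so water-balance closure holds
to machine precision whatever the noise on individual weighings (the
closure test asserts 1e-9). Rates more negative than −2 ml d⁻¹ are
flagged as probable weighing errors and retained.

Leaf area is interpolated linearly from the imaging series (three
times a week) to the interval midpoints. Analysis starts at DAS 18 by
default (`das_start`): earlier data mix establishment at field
capacity with the dry-down and are evaporation-dominated.

## Partitioning and transpiration traits

Per watering regime, OLS of ET on leaf area over all pot × interval
points yields soil evaporation as the intercept and canopy
transpiration per unit leaf area as the slope. Using pot-level points
rather than genotype means is deliberate (the relation is a point
cloud over growth); a genotype-mean variant exists behind
`genotype_means=True` for sensitivity. Transpiration of any point is
ET minus the regime's intercept, floored at 0 (flooring events are
logged). Cumulative transpiration converts ml to mm of water depth via
the pot surface area; the default `pot_area_m2 = 0.0391` reads the pot
footprint "23 × 17 cm" as a rectangle — the geometry is ambiguous
(a 23 cm diameter circle would give 0.0415 m²), so it is a config knob
and the transpiration-efficiency check uses a bracket [3.4, 4.2]
rather than a point value.

Residual analysis regresses transpiration on leaf area per regime and
tests the genotype × regime structure of the residuals with a
fixed-effects two-way ANOVA plus Tukey–Kramer letters; genotypes whose
stomata are wider open than their canopy predicts sit systematically
above the line.

## Atmospheric demand

Reference evapotranspiration follows the FAO-56 daily standard.
Greenhouse wind is not measured; u₂ defaults to 0.5 m s⁻¹ (still-air
greenhouse). Net radiation defaults to 0.77 × global radiation at
plant level; soil heat flux G = 0 at the daily step. The demand check
regresses the residuals of (regime-averaged ET ~ DAS) on ET₀ averaged
over each weighing interval — the gravimetric rates are interval means,
so a midpoint-interpolated daily ET₀ would cap the attainable R² near
0.67 for day-to-day weather noise and understate the demand signal.

## Substrate hydrology

Water content follows the van Genuchten closed form with suction head
in cm; matric potentials are accepted in MPa and converted in exactly
one place (1 MPa = 10 197.16 cm H₂O). Field capacity is taken at
−0.01 MPa (not the common −0.033 MPa) and wilting point at −1.5 MPa,
both configurable. The default parameters (θr 0.05, θs 0.55,
α 0.02 cm⁻¹, n 1.6) are assumed typical for a peat–sand–pumice potting
mix, not a laboratory fit — any real study should substitute its own
measured curve. Irrigation target weight = tare + dry substrate +
water at θ(pwp) + level·PAW (+ plant fresh weight if supplied).

## Typology

Standardization: x_rel(g) = mean over regimes of x(g,t) / meanᴳ x(·,t)
(the average of the two within-regime ratios; the alternative — ratio
of cross-regime means — is available via `pooled_means=True`). The
mean of x_rel over genotypes is exactly 1, standardization is
idempotent, and the regime main effect on standardized values is zero
by construction. Ties at exactly 1.0 classify to the "high" side — a
measure-zero case that must be deterministic. Type summaries pool
genotype × regime records with equal weight.

Printed reference values for the relative trait means were evidently
computed from unrounded replicate data: recomputing them from the
rounded trait table reproduces six of eight within 0.05 but the
conductance SC_rel (1.217 vs 1.26) and spender LAD_rel (1.131 vs 1.19)
only within 0.1; tests assert at those documented tolerances. The same
applies to the control dry-matter CV (recomputed 18.46 vs printed
18.4).

## Statistics

OLS and the factorial ANOVAs are statsmodels under the hood (type-II
sums of squares; effects with numerically zero sum of squares report
F = 0, p = 1 instead of 0/0). The slope-equality test between two
simple regressions is the pooled-residual t test
(t = (b₁−b₂)/√(s²(1/Sxx₁+1/Sxx₂)), df = n₁+n₂−4). Tukey–Kramer
pairwise p-values come from the studentized range distribution; the
compact letter display uses the insert-and-absorb algorithm, so chain
patterns (a~b, b~c, a≁c) receive a bridging letter. Forward stepwise
selection adds the predictor with the largest R² gain while its
coefficient p ≤ p_enter (default 0.15, the classical threshold). All
tests are two-sided at α = 0.05 unless configured. Repeated-measures
mixed models with unstructured covariance are deliberately out of
scope: group means, contrasts and regressions do not depend on the
covariance model, and endpoint traits are analyzed with the
fixed-effects two-way ANOVA instead.

## Synthetic experiment generator

The generator emulates the study conditions: 15 genotypes (2 savers,
5 area types, 5 conductance types including the 3 cultivars,
3 spenders) × 2 regimes (75%/25% PAW) × 5 pots, DAS 0–47, weighing
every 3rd day, imaging 3×/week, gas exchange at DAS 36 (3 replicates),
harvest at DAS 47 (5 replicates).

* Climate: mild deterministic cycles plus daily weather noise;
  amplitudes chosen so evaporative demand is not confounded with the
  growth trend (a large within-month seasonal ramp would bias the
  partition intercepts).
* Leaf area: logistic, rate 0.15 d⁻¹, midpoint DAS 30; archetype
  asymptotes 325/435 cm² (×0.68 under drought), 4% genotype jitter.
* Transpiration of day t: k·A(t+½)·(ET₀/ET₀̄)·√(SC_g/SC_ref) with
  k = 0.185 ml d⁻¹ cm⁻². The mid-day area matters: using the
  start-of-day snapshot would make every interval's flux half a day
  stale relative to the interpolated midpoint covariate and bias the
  recovered intercepts by ≈ −1 ml d⁻¹. The square root reflects
  canopy–atmosphere decoupling (canopy flux responds sublinearly to
  leaf-level conductance); drought acts on canopy water loss only
  through leaf area, so ET~area slopes are common across regimes,
  while the −16% leaf-level SC reduction appears in the gas-exchange
  readings.
* Evaporation: constant per regime, defaults 39.4 / 18.6 ml d⁻¹.
* Weights follow the balance exactly; noise (SD 5 g) applies only to
  recorded values. Plant fresh weight (a few g against a ~2–3 kg pot)
  is ignored in the balance.
* Gas exchange: SC with −16% under drought and 8% multiplicative
  noise; assimilation saturates in SC (PR = 40·SC/(SC+200)), so
  drought reduces conductance several-fold more than assimilation.
* Harvest: dry matter = (TE_true·cum_transp + 30 g m⁻²)·pot_area +
  genotype effect + noise, TE_true = 3.8 g m⁻² mm⁻¹. The cumulative
  transpiration used here covers whole days [18, 47) — exactly the
  span the interval-based flux analysis can observe — so TE recovery
  compares like with like.

Randomness is one `SeedSequence` stream per concern (climate,
genotypes, each pot, each gas-exchange unit): identical seeds give
byte-identical output and adding pots never perturbs existing ones.
Reference modes for identifiability studies: `constant_climate=True`
(flat demand), `uniform_conductance=True` (common canopy slope), and
`.noise_free()`; with all three, the pipeline recovers the generating
evaporation and TE to 0.1% (tested at ±1%, the remaining slack being
interpolation of the logistic onto the weighing grid).

What the generator does **not** emulate: soil-water feedback on
stomata within an interval, diurnal dynamics, spatial greenhouse
gradients, imaging occlusion/overlap errors, or genotype × regime
interactions (the study found none in most traits). Passing recovery
tests therefore show the pipeline is correct and well-calibrated under
the stated structure, not that real data meet that structure.

## Problem sizes and tolerances

Recovery studies average estimates over replicate simulated
experiments: 10 seeds in the test suite, 20 in the acceptance script.
A single experiment's partition intercept scatters by ±3 ml d⁻¹
(SD) because one 29-day window realizes one demand series whose chance
correlation with the growth trend tilts the fit — averaging over
experiments removes it, which is why recovery is defined as a
replicated study. Tolerances: evaporation intercepts ±10%, TE slope
±5%, archetype classification accuracy ≥ 90% (observed ≈ 100%),
demand-residual R² ≥ 0.6 (observed ≈ 0.77 mean). Null calibrations
(ANOVA p uniform) use 200 cheap replicates and a KS test at α = 0.01.
Fixture-derived published values are asserted to ±0.05 where they are
means printed to one decimal, and ±0.1 where the printed value derives
from unrounded replicate data (the CVs and relative trait means noted
above).
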