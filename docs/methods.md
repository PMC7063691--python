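# Methods

This note documents the models implemented in `wheatgap`, their assumptions,
the parameters that matter, and what the synthetic experiments do and do not
show.  All empirical statements below refer to quantities the test suite or
`scripts/acceptance.py` actually compute.

## 1. Synthetic weather

The generator (`wheatgap.weather`) is a classic WGEN-style scheme, chosen
because the analysis uses weather only as a *climate sampler*: what matters
is inter-annual variability, dry spells and heat spells with realistic
persistence, not distributional fidelity to any particular station.

* **Calendar**: 365-day years, no leap days.  Simplifies phenology
  bookkeeping; the bias is negligible for multi-decadal yield statistics.
* **Rainfall occurrence**: a two-state Markov chain with monthly transition
  probabilities `p_wet_given_wet`, `p_wet_given_dry`.  Presets parameterize
  these from a stationary wet probability π and a persistence r = 0.3 via
  p₁₁ = π + (1−π)r, p₀₁ = π(1−r), which leaves π invariant.
* **Rainfall amounts**: exponential with the configured monthly wet-day
  mean.  A single-parameter skewed positive distribution is sufficient for
  a bucket-soil water balance.
* **Temperature**: daily mean = single annual harmonic through the twelve
  monthly means (the fitted intercept preserves the annual mean) plus an
  AR(1) residual (lag-1 autocorrelation 0.65) scaled by the monthly SD.
  tmin/tmax = mean ∓ half the (harmonic) diurnal range; the range shrinks by
  20% on wet days.  tmax ≥ tmin holds by construction.
* **Radiation**: harmonic through monthly means, ×0.75 on wet (cloudy)
  days, with 15% multiplicative noise, floored at positive values.

**Moment recovery** (verified by tests): 100 generated years reproduce the
configured annual precipitation within 5%, mean annual temperature within
0.5 °C, and monthly wet-day frequency and wet-day mean amounts within 10%
relative.

**Site presets** are synthetic archetypes, not reconstructions of real
stations: `cool_wet_NW` (coolest, wettest), `temperate_CW`,
`continental_CE`, `cold_NE` (lowest radiation), `hot_dry_SW` (hottest,
driest, sunniest; winter-peaked rainfall; autumn sowing; the largest daily
temperature variability, SD 4 °C, so that spring heat spikes above grain-
number damage thresholds actually occur).  Their configured annual means
bracket the European gradient of ≈ 7.1–19.2 °C, 344–801 mm yr⁻¹ and
9.7–17.0 MJ m⁻² day⁻¹.

## 2. Crop model

A deliberately minimal daily radiation-use-efficiency wheat model
(`wheatgap.crop`).  Each mechanism is the simplest form consistent with the
process it represents; every functional form below is a design choice of
this package.  Internal units: biomass in g m⁻², water in mm, thermal time
in °C d.

### Phenology

Daily thermal time `tt = max(0, (tmin+tmax)/2 − t_base)` with t_base = 0 °C.
Pre-anthesis accumulation is multiplied by a photoperiod factor

    f(d) = clamp(1 − P_p · (15 − d)/(15 − 8), 0.25, 1)

(day length d in hours from standard solar-declination geometry), so short
days slow development in photoperiod-sensitive cultivars.  Anthesis occurs
when modified thermal time reaches `(N_leaf + 2) · P_h` with a fixed final
leaf number N_leaf = 9 and a booting-to-flowering allowance of two
phyllochrons.  This preserves the causal chain — larger P_h or P_p delays
anthesis — without a full leaf-number model.  Vernalization is out of scope;
consequently very insensitive, short-phyllochron genotypes can flower
unrealistically early, which is visible as the "escape" strategy the
optimizer discovers in hot climates (see section 5).  Maturity is reached when
grain-fill thermal time reaches G_f, or at complete canopy senescence,
whichever is first.

### Canopy and growth

LAI rises linearly with modified thermal time to a maximum
`LAI_max = 2.0 + A_max` (a basal canopy plus the flag-leaf contribution) at
flag-leaf completion (9 · P_h).  After anthesis LAI declines linearly over a
thermal duration `600 · (1 + S_G)` °C d, the decline multiplied by the water
stress acceleration `1 + (W_ss − 1)(1 − stress)`.  Daily intercepted PAR is
`IPAR = 0.5 · rad · (1 − exp(−k·LAI))` (k = 0.6), and biomass gain is
`RUE · lue_multiplier · IPAR · stress` with RUE = 2.3 g MJ⁻¹ PAR.
Ideotypes carry `lue_multiplier = 1.10`; under full water supply and no sink
limitation this scales biomass and yield by exactly 1.10 (asserted in
tests).  No temperature limitation of RUE is applied beyond thermal-time
control (documented extension point).  CO₂ is held at 364 ppm with no
response function; the single-level optimal-Rubisco argument enters only
through the 1.10 multiplier.

### Soil water

A single bucket of capacity AWC = 177 mm (a common medium profile), refilled
to 90% at each sowing; seasons are simulated independently with no
carry-over.  Daily: rain infiltrates, storage above capacity drains, uptake
is `min(demand, R_u · storage)` with demand proportional to IPAR
(0.45 mm MJ⁻¹), and the stress index is uptake/demand (1 when demand is
zero).  Mass balance is exact (closure ≤ 10⁻⁶ mm per season over 1000
random seasons, asserted).  R_u embodies the root-system trade-off: fast
uptake avoids mid-season stress but can exhaust the profile before grain
filling under terminal drought.

### Grain number, flowering stress and grain filling

Potential grain number is `grains_per_g · biomass` at anthesis
(16 grains g⁻¹).  Within a flowering window of anthesis ± 4 days ("a short
spell around flowering"), grain number is reduced by

* heat: `Σ_days HSGNR · max(0, tmax − HSGNT)`, capped at 1;
* drought: `Σ_days DSGNS · max(0, DSGNT − stress)`, capped at DSGNRMax.

The sensitive (iS) set is HSGNT = 27 °C, HSGNR = 0.05, DSGNT = 0.6,
DSGNS = 0.3, DSGNRMax = 0.9; the tolerant (iT) set is HSGNT = 32 °C,
HSGNR = 0.01, DSGNT = 0.4, DSGNS = 0.1, DSGNRMax = 0.3.  These are
calibration defaults expressing "sensitive" vs "tolerant", not measured
values, and are overridable in cultivar files.  The current-cultivar
baseline uses the sensitive set (modern cultivars are stress-sensitive
around flowering).

Grain filling runs for G_f °C d from anthesis.  The grain pool receives the
current day's biomass gain plus a labile pre-anthesis reserve
(22% of anthesis biomass) delivered in proportion to fill progress, and is
capped by the sink `grain_number × max_grain_wt` (50 mg).  Grain-size stress
is represented only through this source/sink limitation during filling — a
deliberate simplification; there is no separate grain-size damage pathway.
The calibration (16 grains g⁻¹ × 50 mg = 0.8 g sink per g anthesis biomass)
makes wheat mildly sink-limited, as observed in the field: grain-number
damage then translates into yield loss, and anthesis date becomes a genuine
source/sink trade-off.

Harvest index is yield/biomass at maturity and is ≤ 1 structurally; yields
are reported in t ha⁻¹ (1 g m⁻² = 0.01 t ha⁻¹).

### Multi-year statistics

A weather series of N calendar years hosts N − 1 complete 365-day seasons
(each sown at the site's sowing day-of-year); the pipeline therefore
generates `years + 1` calendar years when `years` harvests are requested.
The yield CV uses the **sample** standard deviation (divisor n − 1),
documented here because the 10% stability filter depends on the convention.

## 3. Evolutionary search

`wheatgap.optimize` implements a multi-start (1+λ) evolution strategy with
λ = 16 candidates per generation and log-normal step-size self-adaptation:
each per-trait step size is multiplied by `exp(τ·N(0,1))` with
τ = 1/√(2·7), each trait is then perturbed by its own Gaussian and reflected
back into bounds.  Initial step sizes are 10% of each trait's range width.

* **Feasibility**: candidates with yield CV > 10% or mean HI > 0.64 are
  removed from selection.  The HI filter uses the across-year *mean* HI.
* **Selection**: the best feasible candidate replaces the parent only if it
  strictly improves mean yield (ties keep the parent).  An infeasible
  initial parent is displaced by any feasible candidate, so the cultivar
  parent is never silently dropped but cannot trap a start.
* **Convergence**: a start stops after 20 generations without an
  improvement above 10⁻³ t ha⁻¹, or at the generation cap (200 by default).
* **Multi-start**: 25 initial parents by default — one at the cultivar's
  own trait values, the rest uniform in the search ranges.  The best final
  parent across starts is the optimal ideotype.
* **Common random numbers**: all candidates and starts are evaluated on the
  identical weather series, so selection is free of Monte-Carlo noise.
* All random streams derive from one seed via `numpy` `SeedSequence`
  spawning; per-site seeds come from `SeedSequence([seed, crc32(site_id)])`
  so adding a site never perturbs another site's results.

Default trait ranges (stand-ins expressing plausible germplasm variation):
A_max ∈ [1.75, 7] LAI units (0.5–2× the reference flag-leaf contribution of
3.5), S_G ∈ [0, 2], P_h ∈ [70, 140] °C d, P_p ∈ [0, 1],
G_f ∈ [400, 900] °C d, R_u ∈ [0.02, 0.12] day⁻¹, W_ss ∈ [1, 4].

Correctness of the search is checked against a coarse grid-search oracle on
separable quadratic stub fitness functions (the separability makes the 21⁷
grid factorize into per-trait maxima): the recovered optimum lies within one
grid spacing of the grid argmax on every trait for multiple seeds.  The
quadratic's curvature is scaled so near-optimum fitness differences are of
the same order as yield differences (t ha⁻¹), the scale the 10⁻³
improvement threshold is designed for.

## 4. Gap analysis

`wheatgap.gaps` computes, per site and ideotype mode,
`Y_iG = Y_iW − Y_W` and `Y_iG(%) = 100·Y_iG/Y_iW`, where Y_W is the
baseline cultivar (LUE multiplier 1.0) and Y_iW the optimized ideotype, all
three evaluated on the same weather series.  Negative gaps are reported and
flagged rather than clipped — they diagnose an under-converged optimizer
run.  Aggregation takes arithmetic means across sites per mode and the
iT−iS contrast (absolute, and as % of the iS gap).  Percentages are carried
at full precision and rounded half-up to integers only in the
printed-precision layer.

## 5. What the synthetic experiments show — and what they do not

The weather archetypes emulate the *statistical structure* of European
climates, not any real station; consequently site-level yields are
illustrative magnitudes (baseline cultivar yields of roughly 6–10 t ha⁻¹
across the gradient at the shipped calibration), not predictions for named
locations.  Properties that are meaningful and tested:

* the constraint filters hold for every candidate accepted during
  optimization (max accepted CV ≤ 10%, max accepted mean HI ≤ 0.64);
* optimized yield never falls below the cultivar-started parent, and parent
  fitness is non-decreasing through each start's trace;
* the tolerance mechanism is directional: on the hot-dry archetype the
  optimized iT ideotype out-yields the optimized iS ideotype on matched
  weather and optimizer seeds, the iS optimum flowering earlier (stress
  escape) than the iT optimum (stress tolerance), while on the cool-wet
  archetype — where the flowering window is essentially stress-free — the
  iT−iS difference shrinks toward zero.

Reduced-scale problem sizes are used throughout the automated suite — 10
weather seasons, 3–4 optimizer starts and a generation cap of 50 for full
optimizations; miniature (4-season, 2-start) runs for pipeline plumbing —
chosen as the smallest sizes at which the above properties are stable.
Full-scale (100 seasons, 25 starts) runs are available through the CLI and
configuration files.

## 6. Known limitations

* No vernalization, frost kill, nitrogen dynamics, pests/disease,
  multi-layer soil, separate soil evaporation, or CO₂ response curve.
* The photoperiod floor (0.25) plus the absence of vernalization permits
  unrealistically early flowering for insensitive genotypes in warm
  climates; the resulting escape strategies are internally consistent but
  stronger than in more complete phenology models.
* The flowering window (±4 days) and the damage forms (linear in threshold
  exceedance) are structural choices; only their monotone directions, not
  their magnitudes, should be interpreted.
* Monotonicity of yield in W_ss (faster stress senescence never helps) is
  asserted empirically across simulated seasons; in deeply supply-limited
  corners of parameter space the water-saving feedback of a smaller canopy
  could in principle offset senescence losses.
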