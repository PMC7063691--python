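# wheatgap

Process-based wheat simulation, *in-silico* ideotype design and **genetic
yield gap** analysis under synthetic stochastic weather.

## The scientific problem

How much additional wheat yield is still available through *breeding alone*?
For a given location, the **genetic yield potential** Y<sub>iW</sub> is the
water-limited yield of an *ideotype* — a virtual cultivar whose trait values
are optimal for that environment, constrained to the range of variation found
in real wheat germplasm.  The **genetic yield gap** is the shortfall of the
current, well-adapted cultivar (yield Y<sub>W</sub> under optimal
management):

    Y_iG (t ha⁻¹) = Y_iW − Y_W
    Y_iG (%)      = 100 × Y_iG / Y_iW

`wheatgap` implements the full pipeline needed to estimate these quantities
at desk scale:

1. **`wheatgap.weather`** — a seeded WGEN-style stochastic weather generator
   (monthly two-state Markov rainfall occurrence, exponential wet-day
   amounts, AR(1) temperature residuals around an annual harmonic,
   cloud-reduced radiation) with five synthetic site archetypes spanning the
   European climate gradient (annual mean temperature ≈ 7–19 °C,
   precipitation ≈ 340–810 mm yr⁻¹, radiation ≈ 9.6–17.1 MJ m⁻² day⁻¹).
2. **`wheatgap.crop`** — a daily radiation-use-efficiency wheat model:
   photoperiod-modified thermal-time phenology paced by the phyllochron,
   Beer's-law light interception, a single-bucket soil water balance with an
   extractable-fraction root uptake rule, heat/drought grain-number damage in
   a ±4-day flowering window, stress-accelerated canopy senescence, and
   thermal-duration grain filling fed by current assimilate plus a labile
   pre-anthesis reserve.
3. **`wheatgap.optimize`** — a multi-start (1+16) evolution strategy with
   log-normal step-size self-adaptation over seven traits (flag-leaf area
   A_max, stay-green S_G, phyllochron P_h, photoperiod sensitivity P_p,
   grain-fill duration G_f, root water uptake R_u, senescence acceleration
   W_ss).  Candidates with a yield CV above 10% (stability) or a mean harvest
   index above 0.64 (biological ceiling) are removed from selection.
   Ideotypes additionally carry a +10% light-use-efficiency multiplier
   (optimal-Rubisco assumption) and one of two flowering-stress
   parameterizations: sensitive (**iS**) or tolerant (**iT**).
4. **`wheatgap.gaps`** — the gap arithmetic and multi-site aggregation.
5. **`wheatgap.config` / `wheatgap.pipeline` / `wheatgap.cli`** — YAML
   configuration, a seeded end-to-end driver, and a command-line interface.

See `docs/methods.md` for model equations, parameter meanings, defaults and
limitations.

## Worked example

Simulate the reference cultivar at the temperate archetype over 30 seasons:

```
$ wheatgap simulate --site temperate_CW --years 30 --seed 1
temperate_CW / reference: mean yield 8.95 t/ha, CV 4.6%, mean HI 0.466 (30 seasons)
```

The mean water-limited yield of the current cultivar is 8.95 t ha⁻¹, its
inter-annual coefficient of variation 4.6% (sample-SD convention) and its
mean harvest index 0.466.  Now design ideotypes and compute the gap at
reduced scale (10 seasons, 3 optimizer starts — minutes on one CPU):

```
$ wheatgap gap-report --sites temperate_CW --reduced --seed 1 --out results
        site mode  y_w  y_iw  y_ig_abs  y_ig_pct
temperate_CW   iS 8.78 13.41      4.63     34.51
temperate_CW   iT 8.78 13.47      4.69     34.82
```

Reading the iS row: the optimal heat/drought-sensitive ideotype would yield
13.41 t ha⁻¹ (the genetic yield potential), 4.63 t ha⁻¹ more than the current
cultivar's 8.78 t ha⁻¹ — a genetic yield gap of 34.5% of the potential.  In
this benign temperate climate the tolerant ideotype (iT) gains little over
the sensitive one; on the `hot_dry_SW` archetype the iT−iS difference is
systematically larger, because flowering-window stress is what separates the
two parameterizations.

Full-scale runs (100 seasons, 25 starts, per-site configuration) use a YAML
config:

```yaml
# run.yaml
sites: [cool_wet_NW, temperate_CW, continental_CE, cold_NE, hot_dry_SW]
years: 100
n_starts: 25
seed: 1
outdir: results
```

```bash
wheatgap gap-report --config run.yaml
```

Reports are CSVs (`gap_report.csv`, `gap_summary.csv`, per-site optimization
traces, and re-simulatable ideotype YAML files).

## Configuration file formats

* **Run config** (`load_config`): keys `sites`, `cultivar`, `trait_ranges`,
  `years`, `n_starts`, `n_candidates`, `patience`, `max_gen`, `seed`,
  `outdir`, `reduced`.
* **Site YAML** (`load_site`): `latitude`, `sowing_doy`, and twelve monthly
  values each of `monthly_tmin_mean`, `monthly_tmax_mean` (°C),
  `monthly_t_sd` (°C), `monthly_rad_mean` (MJ m⁻² day⁻¹), `p_wet_given_wet`,
  `p_wet_given_dry` (probabilities), `wet_day_precip_mean` (mm).
* **Cultivar YAML** (`load_cultivar` / `save_cultivar`): blocks `traits`
  (a_max, s_g, p_h, p_p, g_f, r_u, w_ss), `stress` (hsgnt, hsgnr, dsgnt,
  dsgns, dsgnr_max) and `physiology` (rue, k_ext, t_base, grains_per_g,
  max_grain_wt, labile_frac).
* **Trait ranges YAML** (`load_trait_ranges`): each trait name mapped to
  `[lower, upper]`.
* **Weather CSV**: columns `day,tmin,tmax,precip,rad` (°C, °C, mm,
  MJ m⁻² day⁻¹), one row per day, 365-day years.
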