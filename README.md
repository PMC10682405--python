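# otofmr — otolith-isotope inference of temperature and field metabolic rate

Fish otoliths ("ear stones") grow throughout life and archive the stable
isotope composition of the water and the fish's own metabolism. `otofmr`
turns per-fish otolith δ¹³C / δ¹⁸O measurements into two physiological
quantities, propagates every source of uncertainty, and summarises the
population-level thermal biology that emerges:

* **Experienced temperature** from oxygen isotopes, via linear aragonite
  thermometry
  `δ¹⁸O_oto − δ¹⁸O_water = a + b·T` with `a = 5.193 ‰`, `b = −0.27 ‰/°C`,
  so `T = (5.193 − Δ)/0.27`.
* **C_resp**, the proportion of respiratory (diet-derived) carbon in the
  otolith carbonate — a proxy for field metabolic rate (FMR) — from a
  two-end-member carbon mass balance between diet and dissolved inorganic
  carbon (DIC):
  `C_resp = 1 − (δ¹³C_diet − δ¹³C_oto) / (δ¹³C_diet − δ¹³C_DIC)`.
  Measured δ¹³C_oto values are first standardised to a reference year with
  a Suess-effect correction of −0.025 ‰ yr⁻¹.

Built for marine ecophysiologists working with otolith isotope archives
(the defaults describe juvenile Atlantic bluefin tuna), the package covers
the full chain:

1. **Monte-Carlo uncertainty propagation** (`otofmr.montecarlo`) — every
   uncertain input (thermometry coefficients, diet/DIC end-members, water
   δ¹⁸O, measurement error) is redrawn from independent normals with
   sd = (95% width)/3.92; thermometry coefficients are shared across fish
   within a replicate; replicate 0 is the noise-free central pass.
2. **Thermal performance** (`otofmr.tpc`) — scikit-learn-style
   `QuadraticThermalModel` and `SegmentedThermalModel` estimators fit
   C_resp against temperature; the quadratic vertex and the segmented
   breakpoint ψ both estimate the limiting temperature T_lim; the Davies
   bound tests whether a breakpoint model beats a straight line; a kernel
   density mode gives the preferred temperature T_pref; the per-degree
   inter-quartile range of C_resp traces a field analogue of aerobic scope.
3. **Synthetic cohorts** (`otofmr.cohort`) — cohorts with known true
   temperatures and a known piecewise-linear performance curve,
   inverse-mapped to δ values, for end-to-end recovery testing.
4. **Climate thresholds** (`otofmr.climate`) — seasonal (July–September)
   SST means, anomaly bias correction of model ensembles against an
   observed reference year, ensemble statistics with outlier screening,
   and per-cell first-year-above-28 °C crossing maps.

## Worked example

Simulate a 2000-fish cohort, estimate physiology with 100 Monte-Carlo
replicates, and summarise its thermal performance:

```sh
otofmr simulate --n-fish 2000 --seed 42 --out .
otofmr estimate --config run.yaml     # records_path: cohort.csv, mc: {n_replicates: 100, seed: 7}
otofmr tpc --config run.yaml
```

The CI-width summary and the pooled row of `tpc_summary.csv` read:

```
sample_id  temperature_width  c_resp_width
 __mean__           1.657556      0.033475

age_group    n  t_pref  t_pref_sd  t_iqr_max  vertex_T  breakpoint_T  breakpoint_T_sd  slope_low  slope_high  davies_p
      all 2000 25.3787     0.4059       28.0   29.4026        28.007           0.4855     0.0069     -0.0088       0.0
```

Reading the numbers: each fish's 95% confidence interval is ~1.66 °C wide
in temperature and ~0.033 in C_resp once all parameter and measurement
uncertainty is propagated. The population prefers ~25.4 °C (KDE mode), but
its FMR proxy keeps rising with temperature until the segmented-regression
breakpoint at 28.0 °C (±0.49 across replicates) — the limiting temperature
T_lim — above which the slope turns negative (+0.0069 to −0.0088 C_resp
per °C). A Davies p-value at numerical zero says the two-segment model
clearly beats a straight line; the C_resp inter-quartile range (the field
aerobic-scope analogue) is widest at 28 °C, between T_pref and T_lim.

The same API is available programmatically
(`generate_cohort`, `run_monte_carlo`, `fit_segmented`, `davies_test`,
`modal_temperature`, `iqr_curve`, `crossing_year`, …), and
`otofmr climate --model m1.nc --model m2.nc --obs obs.nc --out clim/`
produces bias-corrected 28 °C crossing-year maps and regional warming
trajectories from gridded SST inputs.

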