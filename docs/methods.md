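# Methods

## The inference chain

Otolith aragonite is precipitated near isotopic equilibrium with the blood,
which itself tracks ambient water and metabolism. Two linear relationships
carry all the physiology:

**Thermometry.** The oxygen-isotope offset between otolith and ambient
water is linear in temperature,

    δ¹⁸O_oto − δ¹⁸O_water = a + b·T,    a = 5.193 ‰, b = −0.27 ‰ °C⁻¹,

inverted as `T = ((δ¹⁸O_oto − δ¹⁸O_water) − a)/b`. The coefficients come
from a bluefin-tuna calibration; their 95% confidence ranges (0.12 ‰ and
0.016 ‰ °C⁻¹ full widths) are carried through the uncertainty analysis.
The relationship assumes body temperature equals otolith growth
temperature, which holds for fish in their first year of life before
regional endothermy develops.

**Carbon mass balance.** Otolith carbon is a two-source mixture of
dissolved inorganic carbon (DIC) and respiratory (diet-derived) carbon:

    C_resp = 1 − (δ¹³C_diet − δ¹³C_oto) / (δ¹³C_diet − δ¹³C_DIC).

C_resp rises as the otolith carbon becomes more diet-like (more negative),
and is used as a proxy for field metabolic rate. A total diet→otolith
fractionation ε is exposed as a parameter but defaults to 0; because any
fixed ε shifts all fish equally, it does not change the shape of the
temperature–C_resp relationship. Measured δ¹³C_oto values are standardised
to 2019 before the mass balance by the Suess-effect correction
`δ + r·(2019 − birth_year)` with `r = −0.025 ‰ yr⁻¹`, compensating the
secular decline of seawater DIC δ¹³C.

### Default parameters

| quantity | central | 95% full width | unit |
|---|---|---|---|
| thermometry intercept a | 5.193 | 0.12 | ‰ |
| thermometry slope b | −0.27 | 0.016 | ‰ °C⁻¹ |
| δ¹³C_diet | −18.5 | 1.0 | ‰ |
| δ¹³C_DIC | +1.0 | 0.5 | ‰ |
| δ¹⁸O_water (west / Mediterranean) | 1.0 / 1.2 | 0.2 | ‰ |
| δ¹³C_oto measurement | — | 0.4 | ‰ |
| δ¹⁸O_oto measurement | — | 0.1 | ‰ |
| Suess rate | −0.025 | — | ‰ yr⁻¹ |

All confidence values are interpreted as full 95% widths and converted to
normal standard deviations with the divisor 3.92 (= 2 × 1.96), exposed as
`McConfig.width_to_sd`. This convention, propagated first-order through
both equations, predicts per-fish sds of ≈0.0089 for C_resp and
≈0.45–0.51 °C for temperature over the 24–30 °C range — i.e. 95% interval
widths of ≈0.035 and ≈1.8–2.0 °C — which the Monte-Carlo machinery
reproduces empirically (`delta_method_sd` is kept as an independent
analytic oracle in the tests).

The sign of δ¹³C_DIC deserves a note: marine surface-ocean DIC δ¹³C is
positive, and only a positive value is consistent with the observed
C_resp ≈ 0.48 at δ¹³C_oto ≈ −8.4 ‰; the package default is +1.0 ‰.

## Monte-Carlo propagation

For `n_replicates` replicates (default 100): one thermometry pair (a, b)
is drawn per replicate and shared by all fish — coefficient error is a
systematic, not per-fish, error source — while δ¹³C_DIC, δ¹³C_diet,
δ¹³C_oto, δ¹⁸O_oto and δ¹⁸O_water are redrawn per fish per replicate. All
draws are independent normals (no correlation structure is assumed).
Replicate 0 always holds the central, noise-free pass, so downstream
summaries can separate the central estimate from the Monte-Carlo spread.
Both granularities are switchable (`shared_coefficients`,
`per_fish_sources`); the reported mean CI widths are insensitive to the
choice at the printed precision.

Per-fish 95% confidence intervals are empirical quantile ranges (linear
interpolation) across the noisy replicates — not normal approximations —
and out-of-[0,1] C_resp values are flagged, never clipped, since clipping
would bias the ensemble summaries. Seeding uses one root
`numpy.random.SeedSequence` whose per-replicate substreams make every
replicate reproducible in isolation.

## Thermal performance

* **Quadratic model** `C_resp = c0 + c1·T + c2·T²` by ordinary least
  squares; the vertex `−c1/(2c2)` estimates T_lim and is flagged interior
  only when `c2 < 0` and the vertex falls inside the data range.
* **Segmented model** `C_resp = β0 + β1·T + β2·(T − ψ)₊` — continuous at
  the breakpoint. ψ is estimated by profiling the RSS on a 0.05 °C grid
  spanning the [5th, 95th] temperature percentiles (each candidate must
  leave ≥3 distinct temperatures on both sides), then refined by bounded
  scalar minimisation between the neighbouring grid points. This is
  deterministic and, on desk-scale data, equivalent to exhaustive search
  over data-interval midpoints (tested). If the profile has no interior
  minimum, or the best breakpoint improves the RSS by less than a 1e-10
  relative margin, the fit collapses to the simple line and the breakpoint
  is reported absent.
* **Davies' test.** With the breakpoint unidentified under the null, the
  Wald statistic for β₂ is evaluated at k = 10 equally spaced candidate
  breakpoints between the 10th and 90th temperature percentiles
  (mirroring common segmented-regression defaults), and the upper bound
  p ≤ 2[Φ(−M) + V·exp(−M²/2)/√(8π)] is reported, where M is the largest
  |statistic| and V the total variation of the statistic sequence. The
  bound is conservative: simulated straight-line data reject at ≤ α. Very
  strong breaks can drive the bound to exact numerical zero; it is
  reported as computed.
* **T_pref** is the mode of a Gaussian KDE (Silverman bandwidth) of
  experienced temperatures on a 0.1 °C grid; at least 30 observations are
  required, smaller samples should use a histogram mode.
* **IQR curve.** Temperatures are binned to the nearest integer °C
  (half-away-from-zero); bins with strictly more than 15 observations
  contribute the inter-quartile range of their C_resp values — a robust
  spread measure standing in for field aerobic scope. The maximising bin
  breaks ties toward the lower temperature, which is conservative for
  claims about limiting temperatures.
* **Across-replicate summaries** report the central-fit value together
  with the Monte-Carlo mean and sd of each metric, plus z-scored curves on
  a common grid for visual comparison of density, C_resp and IQR profiles.

## Synthetic cohorts

The generator draws true temperatures from a normal with mean
`t_pref_true` and sd `t_sd`, truncated to (18, 34) °C; true C_resp follows
the continuous piecewise-linear performance curve (peak `c_resp_at_tlim`
at ψ, slopes `slope_low_true`/`slope_high_true`) plus normal biological
scatter on the C_resp scale (not the δ scale — this keeps the IQR
structure tunable), clipped to (0.05, 0.95). The pairs are inverse-mapped
through the two equations with origin-specific water values and central
constants, the Suess standardisation is inverted by birth year, and
measurement noise (width/3.92) is added to the δ values.

Defaults describe the juvenile-bluefin study system: T_pref 25.5 °C,
t_sd 1.7 °C, ψ = 28 °C, slopes +0.007/−0.012 C_resp °C⁻¹, peak 0.50
(giving a cohort median C_resp ≈ 0.48), biological scatter 0.03 (pooled
C_resp IQR ≈ 0.045), 25% western origin, birth years 1994–2012.

What the generator does **not** emulate: the real data are a two-origin
mixture with different temperature distributions (Mediterranean fish
24–27 °C, western fish 26–30 °C), skewed rather than normal; spatial
capture structure; ontogenetic trends in C_resp; and non-normal
measurement error. Recovery tests therefore demonstrate that the
estimation machinery is unbiased and well-calibrated under its own
assumptions — not that those assumptions exhaust the structure of real
otolith datasets.

Problem sizes used in the test-suite recovery studies: 50 cohorts of
n = 2000 with measurement noise (breakpoint bias and spread, Davies power),
500 straight-line datasets of n = 200 (null calibration), cohorts of
1000 fish × 1000 replicates (CI widths). With biological scatter at its
realistic default (0.03) rather than measurement noise alone, breakpoint
recovery remains unbiased (mean ψ̂ ≈ 28.0, sd ≈ 0.21) but Davies' p falls
below 1e-6 in only ~70% of cohorts, because few fish experience
temperatures above ψ when the cohort mode sits at 25.5 °C.

## Climate thresholds

Monthly SST cubes are reduced to July–September (JAS) seasonal means per
cell-year; each model is bias-corrected by the anomaly method — subtract
its own 2016 field, add the observed 2016 field — so corrected series are
exact at the reference year and retain each model's projected change. The
ensemble mean and inter-model sd are cell-wise; per-model regional-mean
z-scores are reported for outlier screening but no model is excluded
automatically. The crossing map records the first year within the
projection window whose seasonal mean is ≥ the threshold (single-year
criterion; no persistence requirement — a deliberate, stated choice).
Regional trajectories are cosine-latitude-weighted means per model, then
ensemble mean ± sd.

Inputs must share a grid (no regridding); netCDF I/O uses the classic
netCDF-3 format via xarray's scipy engine, with automatic `tos`/`sst`
detection and Kelvin→Celsius conversion. The synthetic grid generator
produces aligned cubes with prescribed trend, bias and seasonal cycle for
testing; it makes no attempt to emulate real climate-model output.

## Known limitations

* Elevated body temperature from developing endothermy would bias inferred
  temperatures warm in older fish; the thermometry assumes ectothermy.
* The C_resp→oxygen-consumption calibration is species-specific and not
  bundled; `c_resp_to_mo2` refuses to run without explicit coefficients.
* All parameter draws are independent; correlated errors (e.g. between
  water δ¹⁸O and temperature climatology) are not modelled.
* The Davies bound is conservative; with small effects it under-rejects
  relative to exact resampling tests.
* Unweighted pooling is used when combining origins or age groups.
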