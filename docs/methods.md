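# Methods

## Model structure

Daily GPP is the product of absorbed PAR, a maximum light-use efficiency
(LUE), and three multiplicative regulation scalars, computed separately
for sunlit and shaded leaves and summed. The two canopy fractions matter
because shaded leaves, lit only by diffuse radiation, operate closer to
their light-saturation point and therefore convert absorbed energy to
carbon more efficiently — ε_msh is several times ε_msu for most forest
types. All per-vegetation-type parameters (ε_msh, ε_msu, T_opt, albedo,
clumping index Ω; VPD limits fixed at 0.93 / 4.1 kPa for all types) ship
as a delimited table in `tllue/data/pft_parameters.csv`; the tabulated
standard deviations are across-site spread metadata and never enter the
computation. Deciduous needleleaf forests alias the deciduous broadleaf
parameter set.

### Canopy radiation

Above-canopy PAR is split into diffuse and direct streams by a quartic
polynomial in the sky clearness index R = S/(1367 cos θ), clipped to
[0, 1]. Sunlit leaf area is LAI_su = 2 cos θ (1 − e^(−LAI Ω/(2 cos θ))),
shaded area the remainder. Absorption terms follow the standard two-leaf
formulation with leaf angle β = 60° (cos β = 0.5), a multiple-scattering
term C = 0.07 Ω PAR_dir (1.1 − 0.1 LAI) e^(−cos θ) and diffuse
transmission PAR_dif,u = PAR_dif e^(−0.5 Ω LAI / cos θ̄) with
cos θ̄ = 0.537 + 0.025 LAI.

Degenerate-input policy (the formulas are silent in each case):

* C is floored at 0 — its linear LAI term goes negative past LAI = 11,
  but scattered radiation cannot be negative.
* LAI_su is capped at LAI so the shaded remainder is never negative (the
  exponential expression can marginally exceed LAI at very small LAI
  with large cos θ).
* At LAI = 0 both absorbed-PAR terms are defined as 0, bypassing the
  0/0 in the per-LAI diffuse term.
* Clearness is clipped to [0, 1]; daytime-mean geometry can push the raw
  ratio slightly above 1, outside the polynomial's fitted domain.

### Time basis and units

The LUEs are in g C MJ⁻¹, so APAR must be an energy. The model runs at a
daily step on 24-h mean fluxes (W m⁻²); internally these are converted to
daytime-mean fluxes by dividing the daily energy by the astronomical
daylength, the radiation partition and clearness index are evaluated on
that basis (consistent with the daytime-mean cos θ), and absorbed PAR is
integrated back over the daylength into MJ m⁻² d⁻¹. Integrating over
daylight rather than 24 h is the physically coherent choice: PAR is zero
at night, and pairing a 24-h mean flux with a daytime zenith cosine would
bias the clearness index low.

Solar geometry uses Cooper's declination approximation and the analytic
daytime mean of cos θ over the sunlit hour-angle range; polar night gives
zero daylength and zero GPP. The daytime-mean convention (vs. noon value
or weighted integral) is a design choice; tests pin it to a fine-grid
quadrature oracle at 1e-6 absolute.

### Regulation scalars

T_s uses fixed limits 273.15 / 313.15 K and the per-type optimum; outside
the open interval the rational form misbehaves, so T_s = 0 there (no
photosynthesis beyond the thermal limits). W_s is clamped to [0, 1]
outside the VPD ramp. The CO₂ chain evaluates, in order: K_c and K_o
(Arrhenius forms with coefficients 39.97 and 27480 at 298.15 K,
activation terms 79.43 and 36.38 with R = 8.314), K = K_c(1 + 21/K_o),
ξ = √(356.51 K / (1.6 · 0.8903)), χ = ξ/(ξ + √VPD) with VPD in kPa,
C_i = χ C_a, and C_s = (C_i − Γ\*)/(C_i + 2Γ\*) with
Γ\* = 4.22 e^(37830 (T−298.15)/(298.15 R T)). C_s is floored at 0 when
C_i ≤ Γ\*.

A unit caveat: the published coefficient set mixes C_i in ppm with a
compensation point whose 4.22 magnitude matches Pa-scale literature
values. The default mode evaluates the chain exactly as the coefficients
print (ppm throughout), which is what the calibrated LUEs absorb; a
`units="pa"` option converts C_i to partial pressure at standard surface
pressure for a dimensionally homogeneous variant. The two differ
noticeably in C_s level but similarly in shape; the printed-form default
is the faithful choice and the calibration target.

Air temperature is used in every Arrhenius form (a single temperature
symbol; no leaf energy balance).

## Calibration

Only ε_msh and ε_msu are optimized; everything else stays at table
values. The objective is the Willmott agreement index over all pooled
calibration days of a vegetation type (not per-site averages), maximized
by SCE-UA within (0.01, 10) g C MJ⁻¹ bounds — a generous cover of the
tabulated 0.65–4.80 range. The site split is 75/25 by site, seeded, and
recorded in the result. The SCE-UA implementation follows the standard
sizing for n parameters (complexes of 2n+1 points, simplexes of n+1,
2n+1 evolution steps per complex per shuffle; 4 complexes by default),
with reflection/contraction/random-replacement competitive evolution,
convergence on relative objective improvement below 1e-6 over 5 shuffling
loops, and a 10 000-evaluation budget. Runs are bit-reproducible per
seed.

Daily modeled GPP is linear in the two LUEs at fixed forcing, so the
per-day unit-LUE bases are precomputed once per site and each objective
evaluation reduces to a dot product; calibration of a multi-site,
multi-year task takes well under a second.

Validation reports the agreement index over pooled held-out days and a
per-site R² of daily values (squared Pearson correlation), labelled as
such.

## Synthetic data

`make_site` builds daily forcing from sinusoidal seasonal cycles
(temperature, VPD, LAI peaking at a configurable day of year) plus
lag-1 autocorrelated noise (coefficient 0.7, chosen to mimic synoptic
persistence) and a clearness series clipped to [0.05, 0.95]; shortwave
is reconstructed from clearness and solar geometry, so the generator and
the model share no shortcut — "observed" GPP is produced by the forward
model with known true LUEs, then perturbed by multiplicative lognormal
noise (mean 1, CV configurable) and punched with seeded random gaps.
Defaults describe a plausible mid-latitude deciduous site (3 years,
LAI 0.3–5, T̄ = 283 K ± 12 K seasonal, VPD 0.9 ± 0.6 kPa, CO₂ 370 ppm
+2 ppm a⁻¹). Monte-Carlo repetition over seeds puts noise-free parameter
recovery within 1 % and 20 %-noise recovery within 10 % — the tolerances
the acceptance tests assert.

What the generator does **not** emulate: weather regimes beyond AR(1)
persistence, covariance between clearness and VPD, instrument drift,
u*-filtering artifacts or the energy-balance-closure biases of real
towers, realistic LAI retrieval noise. Passing recovery tests therefore
demonstrates the correctness of the estimation machinery under the
stated error model, not expected accuracy on real towers.

`make_grid` produces a small (default 20×20, 0.05°) driver stack with
latitudinal gradients and a matching truth GPP stack computed by the
forward model, for product-pipeline round trips.

## Gridded products

Pixel-center registration, longitude −180→180 and latitude 90→−90 row
order. 8-day aggregation follows the MODIS day-of-year convention
(periods start DOY 1, 9, …; the last period of a year is short), so
annual = Σ monthly = Σ 8-day exactly before encoding. Sub-annual
products are stored as int16 after dividing by the scale factor (0.01
for 8-day, 0.1 for monthly) and rounding half away from zero — round
trips are within half a quantum; annual products are doubles. Nodata is
−32768 (int16) or NaN (double). Files are single-band GeoTIFFs with
WGS-84 geokeys written through tifffile, named
`<Var>_v21_<year>[_<period>].tif`, with a SHA-256 manifest per run.
Non-vegetated pixels yield NaN, distinguishing "no vegetation" from
"zero flux". Unknown land-cover codes map to nodata; the UN-LCCS→IGBP
crosswalk is a shipped table and can be overridden.

Trend maps use per-pixel unweighted OLS of annual GPP on year with a
two-sided t-test on the slope; pixels with p > 0.05 are masked.
Exact-fit pixels (zero residual, nonzero slope) are retained with p = 0;
constant series are masked. The type-I error rate on null simulations is
tested at 5 % ± 1 % over 10⁴ pixels.

## Forcing layer

VPD comes from specific humidity, pressure and temperature via the
mixing-ratio relation and a Buck-type saturation formula
(0.61121 kPa at 0 °C), floored at 0 for supersaturated input. The
shortwave→PAR factor defaults to 0.43 and is configurable (literature
range 0.39–0.53). Six-hourly aggregation expects exactly four steps per
day (sum of shortwave energy, mean of temperature and VPD); other
cadences must be resampled upstream. Site-year screening requires every
required variable (temperature, VPD, CO₂, shortwave/PAR, observed GPP)
to miss fewer than 60 days per calendar year; accepted years are
gap-filled by 1-D linear interpolation in time without extrapolation.
No correction of reanalysis shortwave against tower measurements is
implemented; drivers are used as read.

## Known limitations

* Daily time step only; no sub-daily radiation or temperature dynamics.
* Water stress is VPD-only; no soil moisture.
* No C3/C4 crop distinction.
* The ppm/Pa ambiguity in the CO₂ chain is resolved by fidelity to the
  printed coefficients, not by dimensional analysis (see above).
* Test problem sizes (3-year sites, 20×20 grids, 10⁴ null pixels) are
  chosen to exercise every code path at desk scale; continental-scale
  runs would use the same code paths over chunked inputs.
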