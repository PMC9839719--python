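# Methods

## Problem and scope

The package quantifies how county crop yields respond to *dry* versus
*humid* extreme-heat exposure measured at weather stations. Exposure is
counted in days: a season day is an extreme-`Tmax` day when its daily
maximum dry-bulb temperature exceeds the station's local percentile
threshold; it is a **humid-heat day (HHD)** when the daily maximum
wet-bulb temperature `Twmax` exceeds its own threshold, and a **dry-heat
day (DHD)** when only the `Tmax` threshold is exceeded. Days exceeding
both count as humid, never dry, so for every station-year

    DHD + overlap = extreme-Tmax days

holds by construction and is enforced as an invariant.

Because real station archives and county yield databases are external
inputs, the package ships a synthetic generator that emulates their
relevant statistical structure with *known planted effects*; every claim
the test suite makes is therefore a claim about the method's behaviour
under those generated conditions, not about any real-world dataset.

## Wet-bulb temperature

`Tw` is defined as the root of

    θ_E(Tw, r_sat(Tw, p), p) = θ_E(T, r, p),      Tw ∈ [dew point, T]

with `θ_E` Bolton's pseudoequivalent potential temperature (saturation
vapor pressure `e_s = 6.112·exp(17.67·T/(T+243.5))` hPa; LCL temperature
from Bolton's closed form; exponent `0.2854·(1−0.28·r)`). The left side is
strictly increasing in `Tw`, so the root is unique. The solver uses a
piecewise first guess in the normalized equivalent temperature
`x = (273.15/T_e)^3.504` — polynomial branches for moderate `x` and a
series expansion around the equivalent temperature for hot/moist cases —
followed by Newton iteration with a finite-difference derivative.

Numerical choices: convergence tolerance 0.001 K on the θ_E residual; at
most 10 Newton iterations; a bracketed Brent fallback on
`[max(T−80, −59.9), T]` whenever Newton strays or stalls. Super-saturated
inputs are clipped to saturation (warned above float-noise level); with
clipping the saturation identity `Tw = T` is exact. The independent check
in the tests is a pure 60-step bisection on the same defining equation;
across a 500-point grid over T ∈ [10, 45] °C, RH ∈ [5, 100] %,
p ∈ [850, 1020] hPa the two agree to better than 0.001 °C (the acceptance
bound is 0.02 °C).

Station pressure is reduced from sea-level pressure with the ICAO
standard-atmosphere relation `p = slp·(1 − 0.0065·z/288.15)^5.25588`; the
source data's own reduction method is unknown, so this is a documented
package choice (any smooth monotone reduction changes thresholds, which
are station-local percentiles, only negligibly).

The hourly → daily reduction takes the maximum of hourly dry-bulb and of
hourly wet-bulb values separately (the two maxima may occur at different
hours). A day needs ≥ 18 of 24 hours to count; incomplete days are
missing, never zero. Timestamps are taken to be local civil time.

## Thresholds, classification, exposure

Station screening follows a coverage rule: a month is good when ≥ 90 % of
its days are present, a station passes when ≥ 90 % of months are good.
For season-only records the rule is evaluated over the season months.

Thresholds are empirical percentiles (linear interpolation between order
statistics) of all non-missing season-day values pooled across the base
period (default 1981–2010), one threshold per station per variable; at
least 80 % of the possible base-period season days are required.
Exceedance is strict `>`: ties have probability zero for continuous
temperatures, and strictness keeps the degenerate-distribution case
well-defined. Missing days inside a season count as non-events and the
missing fraction is reported, keeping counts comparable across years.
Season windows are configurable (May–September default, with May–June and
July–September sub-season splits).

The annual-frequency trend is an OLS slope of counts against year with a
plain t-test; the "total change" is slope × (years − 1).

## Yield regressions

Yields and heat-day counts are linearly detrended in year (OLS line
removed) before the per-county regression

    yield*_t = β₀ + β₁·DHD*_t + β₂·HHD*_t ,

fitted by OLS with plain (non-robust) standard errors and two-sided
Student-t p-values at df = n − 3. Note a subtlety kept deliberately: the
inputs are detrended, which by Frisch–Waugh makes the fit equivalent to a
regression that also includes year, whose residual df is n − 4; using
n − 3 makes the test very slightly anti-conservative (≈ 5.3 % nominal 5 %
size at n = 40). This matches the stated procedure and the calibration
test band accounts for it. When a county has several stations the model
is fitted once per station against the county yield series, and "area
averages" weight stations equally.

The fixed-effects panel model on *non-detrended* yields,

    yield_{i,t} = C_i + T_t + β₁·DHD_{i,t} + β₂·HHD_{i,t} + ε_{i,t} ,

is estimated as OLS with explicit county and year indicator columns, one
of each dropped (reference categories), so effects are reported as
contrasts; the tests verify equality with a hand-built dummy-matrix
least-squares oracle to 1e−8. Non-irrigated rows only by default,
mirroring the headline comparison. Unbalanced panels are allowed.

Multicollinearity between the two exposure series is summarized as
`VIF = 1/(1−R²)` with `R` their Pearson correlation; under the default
generator the VIF stays well below 2, so β₁ and β₂ are separately
identified.

`percent_yield_impact` converts β (Bu/acre per day) to percent of mean
yield: per-day percent rounded to one decimal, cumulative percent (per-day
× average seasonal exposure) rounded to the nearest whole percent, both
half-away-from-zero, matching the conventional printed precision.

## Composites

For each event class, rainfall is averaged over the day-offset windows
before = {−3,−2,−1}, on = {0}, after = {+1,+2,+3}. Offsets are calendar
days on the record's date index, so windows never bridge gaps; events near
a record edge contribute only their in-range days, and an event with no
in-range day for a window drops out of that window's denominator. The
headline mean pools all (event, window-day) pairs. The dry-vs-humid
contrast uses a pooled-variance two-sample Student t-test whose sampling
unit is the **per-event window mean**: the unit choice was open, and
per-event means avoid pseudo-replication from the 3 days within a window.
Consecutive event days are separate events (the unit of analysis is the
day). Windows of nearby events may share days, which leaves a small
positive dependence between sampling units; the measured type-I error of
the before-window test under the uncoupled generator (≈ 5–6 %) shows the
effect is minor at these event densities.

## Synthetic generator

Per station (stream `default_rng(seed XOR station_index)`, so stations are
independently generatable yet reproducible; draw order fixed):

- `Tmax = mean + amplitude·cos(2π(doy−196)/365.25) + AR(1) anomaly`, with
  mean 29 °C, amplitude 5 °C (peak mid-July), lag-1 autocorrelation 0.7
  and stationary anomaly SD 3 °C — realistic midsummer persistence and
  variability for a continental interior station. The AR(1) chain runs
  across the concatenated season blocks; the (unphysical) carry-over
  across the September→May gap is harmless for a test surface.
- Rain occurrence is a two-state chain with P(wet|wet) = P(wet|dry) = 0.3
  by default and exponential amounts with mean 8 mm. The chain supports
  persistence (and is tested with it), but the default is memoryless **by
  design**: the wet-bulb elevation is planted on the 3 *prior* days only,
  and a persistent chain would smear rain past the event day, blurring the
  lead/lag asymmetry the composites are meant to isolate.
- `Twmax = Tmax − max(0, 6 + 1.5·N(0,1) − 0.25·rain₃)` °C with `rain₃` the
  rain sum over the 3 prior days (within the year). The 0.25 °C/mm
  coupling places the generator in the regime where humid-heat days see
  more than double the prior-window rainfall of dry-heat days; the floor
  at 0 guarantees `Twmax ≤ Tmax`.
- County yields: `intercept 120 + county offset N(0,10) + 1.5·(t−t₀)
  − 2·DHD + 0·HHD + N(0,8)` Bu/acre, floored at 0 (flooring logged;
  essentially never triggered at these levels). Irrigated counties
  (⌊0.2·n⌋ of them) use their own sensitivities, zero by default,
  emulating the insensitivity of irrigated yields. Station i serves county
  i mod n_counties (one per county at the default equal counts; wrapping
  gives the many-stations mode, where a county's yield is generated from
  its lowest-index station).

Default network: 50 stations/counties, 1980–2019 (40 years), base period
1981–2010, MJJAS. At the 95th-percentile level this yields ≈ 7.6
extreme-`Tmax` days per season (5 % of 153 days), of which ≈ 4.2 are dry
and ≈ 3.4 overlap — mean seasonal dry-heat exposures of a few days, the
right order for sensitivity estimation over 40 years.

What the generator does **not** emulate: spatial correlation between
stations, instrument-level artifacts, real geography beyond an assignable
lat/lon box (36–46° N), crop-specific phenology, or any feedback of crops
on local climate. Passing tests therefore demonstrate the statistical
machinery — threshold self-consistency, unbiased recovery of planted
sensitivities by both regression routes, calibrated significance tests,
correct lead/lag attribution — under idealized independence, not the
magnitude of real-world yield sensitivities.

## Monte-Carlo test design

Parameter recovery runs 200 replicates of the default conditions; the
area-average β₁ over non-irrigated stations must lie within 2 Monte-Carlo
SEs of −2, the fixed-effects estimate must agree with the area average
within 2 SEs of their paired difference, and the β₂ = 0 test (one
designated per-station test per replicate, making the replicate the
Bernoulli unit) must reject at 5 % within 2 binomial SEs of 5 %.
Composite structure uses 60 single-station replicates with the coupling on
(before-window ratio, after-window null) and 200 with the coupling off
(type-I calibration). These problem sizes keep the full suite to a few
minutes while leaving the Monte-Carlo bands tight enough to detect
percent-level biases.

## Known limitations

- The detrended-input/df = n − 3 convention mildly inflates the
  per-station test size (see above); it is retained as the reference
  procedure rather than corrected.
- No multiple-testing correction is applied across stations; per-station
  5 % significance maps are descriptive.
- The wet-bulb solver is scalar; for bulk hourly archives a vectorized
  front-end (`wet_bulb_many`) simply loops.
- Whether area averages should weight stations equally or by production
  is an open choice; equal station weights are used.
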