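# heatyield

Dry heat and humid heat are not the same stress for a crop. A day whose
daily-maximum dry-bulb temperature `Tmax` is extreme *without* a
correspondingly extreme daily-maximum wet-bulb temperature `Twmax` (a
**dry-heat day**) signals high atmospheric moisture demand and, typically,
little recent rain; a day whose `Twmax` is extreme (a **humid-heat day**)
is hot *and* moist, and tends to follow rain. Panel analyses of US county
corn and soybean yields show that separating the two matters: yields fall
steeply with dry-heat exposure while humid-heat exposure has little effect,
so conflating them understates the dry-heat sensitivity.

`heatyield` is a tested, reusable implementation of that analysis chain
for station weather and county yield panels, exercised end-to-end on a
synthetic generator with *known planted effects* so every stage has a
ground-truth test surface:

1. **Wet-bulb temperature** from dry-bulb temperature, specific humidity
   and pressure, by inverting Bolton's pseudoequivalent potential
   temperature `θ_E` (Davies-Jones-style first guess + Newton refinement),
   and hourly → daily-maximum reduction (`heatyield.wetbulb`).
2. **Event classification**: station percentile thresholds (90th/95th) of
   `Tmax` and `Twmax` over a fixed base period, pooled across season days;
   a day is humid-heat iff `Twmax` exceeds its threshold, dry-heat iff
   `Tmax` exceeds its threshold but `Twmax` does not, so
   `DHD + overlap = extreme-Tmax days` exactly (`heatyield.heat_events`).
3. **Yield statistics** (`heatyield.yield_stats`):
   - per-county regression on detrended series
     `yield*_t = β₀ + β₁·DHD*_t + β₂·HHD*_t`, plain Student-t significance;
   - national fixed-effects panel on non-detrended yields
     `yield_{i,t} = C_i + T_t + β₁·DHD_{i,t} + β₂·HHD_{i,t}`;
   - `VIF = 1/(1−R²)` between the two exposure series;
   - latitude-band and irrigation-group coefficient summaries and the
     percent-of-mean-yield impact conversion.
4. **Event-relative composites**: rainfall averaged over the 3 days
   before / the day of / the 3 days after each event class, with
   two-sample t-tests on the dry-vs-humid contrast (`heatyield.composites`).
5. **Synthetic data** (`heatyield.synthetic`): AR(1) temperature with a
   seasonal cycle, two-state rainfall occurrence with exponential amounts,
   rain-coupled wet-bulb depression, and county yield panels with planted
   sensitivities (default β₁ = −2, β₂ = 0 Bu/acre per day).

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic conditions (50 stations, 1980–2019, 95th-percentile thresholds,
MJJAS season, seed 42) and print what they find:

```sh
python analysis/01_simulate.py
python analysis/02_classify_heat_events.py
python analysis/03_fit_yield_models.py
python analysis/04_composites.py
python analysis/05_parameter_recovery.py
```

`03_fit_yield_models.py` prints (β in Bu/acre per heat day):

```
area-average vs fixed-effects sensitivities (Bu/acre per day):
                            method crop  beta1_bu_acre_day  beta2_bu_acre_day
per_county_regression_area_average corn             -1.998             -0.068
               fixed_effects_panel corn             -1.954             -0.068

VIF between DHD and HHD: median 1.13 (max 1.77) — multicollinearity is low
```

Both regression routes recover the planted dry-heat sensitivity of
−2 Bu/acre/day and the null humid-heat sensitivity, and the exposure
predictors are nearly orthogonal (VIF well below 2). `04_composites.py`
shows the planted lead/lag asymmetry — humid-heat days see ~8× the rainfall
of dry-heat days over the 3 prior days, while the 3 days after are
indistinguishable:

```
network-mean rainfall (mm/day) around events:
window       before    on  after
DRY_HEAT       0.80  2.39   2.40
HUMID_HEAT     6.51  2.42   2.37
```

The same machinery is available as a one-shot CLI:

```sh
heatyield --seed 42 --level 0.95 --season MJJAS --outdir run/
```

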