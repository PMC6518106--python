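# Methods

## Model overview

`iaqsim` simulates one year (8760 h, non-leap, local-time hourly intervals)
of PM2.5 in a 30 m² four-room apartment (bedroom 9, living room 12, kitchen
6, bathroom 3 m²; default ceiling height 2.5 m, total volume 75 m³). Each
room is a well-mixed zone in a linear mass balance with infiltration,
exfiltration, exhaust fans, doorway mixing, indoor sources, first-order
deposition and an optional clean-air-delivery filter sink. The core
simplification relative to a full pressure-network contaminant model is that
**airflows are prescribed, not solved**: the whole-dwelling air exchange
rate a(t) is an input schedule, calibrated to the dwelling's summary
statistics (annual mean 1.5/h, daily values ≈ 0.3–4.5/h), rather than derived
from wind pressure coefficients and leakage areas. This keeps the model
linear, exactly solvable hour by hour, and auditable.

## Airflow bookkeeping

Envelope exchange a(t)·V_total is apportioned to zones by volume, entering
and leaving each zone symmetrically. Every exhaust fan (bathroom 120 m³/h,
6:00–7:00; kitchen 170 m³/h during cooking) induces matching make-up
infiltration, which enters through the non-fan zones in proportion to volume
and is routed to the fan zone through the doorway graph by a potential flow
(graph-Laplacian solve), so inflow equals outflow in every zone at every
hour. Doorways additionally carry a symmetric mixing flow, default
150 m³/h per doorway — rooms are near, but not exactly, well-mixed. Because
no measured interzonal flows exist for this dwelling, runs that target
whole-dwelling summary numbers use **single-zone mode** (all zones merged at
total volume); multi-zone mode is structural fidelity for room-resolved
questions, and the two agree to better than 1% when the mixing flow is made
large.

## Sources, sinks, filter

* Cooking: 0.14 mg/min (LPG stove) on 7:00–7:30, 12:00–12:30, 17:00–18:00
  (2 h/day), in the kitchen. Half-hour events enter as fractional duty in the
  hourly schedule.
* Smoking (scenario option): 0.33 mg/min, 8 cigarettes/day, one per hour from
  9:00, living room. The cigarette duration is not specified by the source
  material; the default is 10 min/cigarette (26.4 mg/day). The published
  smoker-present results are mutually inconsistent under any single-zone or
  multi-zone well-mixed balance — the no-filter smoker/non-smoker gap implies
  roughly an order of magnitude more emitted mass than the all-day-HEPA gap —
  so no duration choice reproduces all of them; 10 min keeps the filtered
  scenarios faithful and understates the unfiltered smoker baseline. The
  duration is a parameter.
* Deposition: 0.19/h in every zone. Envelope penetration P = 1.0
  (no penetration loss is listed among the sinks of the source model).
* Filter: CADR 200 cfm, taken at the printed conversion 5.66 m³/min
  (339.6 m³/h), with single-pass efficiency 0.30 (MERV 8), 0.65 (MERV 12) or
  0.99 (HEPA). Removal is the standard first-order clean-air-delivery sink
  η·CADR·C in the filter's zone. The default placement policy follows the
  occupant (bedroom 22:00–06:00, living room otherwise); a fixed zone is
  selectable. Use schedules: 24 h; 15 h = 17:00–08:00 (evening and night,
  covering occupancy); 8 h = 22:00–06:00 (sleep). The 8-h window nests inside
  the 15-h window, which gives the use-hours monotonicity its meaning.

## Numerical scheme

All coefficients are constant within an hour, so each hourly step uses the
exact solution of dC/dt = A·C + b: a scalar exponential in single-zone mode
and a Van Loan block matrix exponential (state, constant forcing, running
integral) in multi-zone mode. Reported hourly values are within-hour time
averages, not endpoint samples. Consequences: unconditional stability,
non-negativity for any admissible forcing, and a mass budget (emitted +
infiltrated = deposited + exfiltrated + filtered + storage change) that
closes to floating-point round-off — the 0.5% accounting check in the tests
passes with enormous margin. The `dt` argument is validated (must divide
60 min) for interface compatibility but does not alter results. The initial
condition is the steady state of hour 0, which removes spin-up transients.

## Synthetic environment generator

The generator supplies the forcing the analysis assumes, with no downloads.

**Ambient PM2.5** is lognormal: log-concentration = annual cosine (amplitude
0.82, peaking ≈ 5 January) + mean-centred diurnal profile + AR(1) hourly
residual (ρ = 0.95, stationary sd 0.35). After exponentiation the series is
rescaled so the annual mean of daily means equals the target (123 µg/m³)
exactly, for any seed. The diurnal profile is two circular Gaussian bumps —
morning (07:30, width 2 h, amplitude 0.55) and late night (22:30, width 4 h,
amplitude 0.90) — with a mid-afternoon trough, and its amplitude is modulated
seasonally (factor 1 ± 0.6 over the year, strongest in winter when the
shallow nocturnal boundary layer amplifies the day/night contrast). The
seasonal amplitude is set so the standard deviation of daily means lands near
78 µg/m³, the value whose normal-approximation 95% CI half-width reproduces
the ±8 µg/m³ interval reported for the Delhi-2017 annual mean; the diurnal
amplitudes are set so the day/night concentration contrast matches the
observed Delhi pattern that makes night-time filter operation meaningfully
different from daytime operation. Winters come out ≈ 4–5× summer levels
(well above the tested 1.5× threshold).

**AER** is a deterministic step profile — windows open 7:00–18:00 at
2.682/h, closed at 0.5/h, giving a daily mean of exactly 1.5/h — times an
annual cosine (amplitude 0.25, peak mid-June) and mean-one lognormal
day-to-day jitter (log-sd 0.45), rescaled so the annual mean of daily means
is exactly the deterministic baseline. The 5th–95th percentile of daily
means stays inside the reported 0.3–4.5/h envelope, and the open-hours >
closed-hours contrast survives on every day because the jitter is common to
all hours of a day. Exhaust-fan air exchange is *not* folded into a(t); fans
are explicit volumetric flows in the simulator, avoiding double counting.
The `windows_open_24h` sensitivity preset holds 3.3/h around the clock with
calmer jitter (a constantly open 1 m² window dominates the exchange),
spanning daily means ≈ 0.5–11/h.

**What the generator does not emulate:** synoptic multi-day pollution
episodes beyond AR(1) persistence, meteorology-driven covariance between
ambient PM2.5 and ventilation behaviour, monsoon washout asymmetry, and
station-to-station spatial heterogeneity. Passing tests therefore show that
the pipeline reproduces the published results *given forcing with the
calibrated summary statistics*, not that it forecasts any particular real
year.

## Occupant and exposure statistics

The single occupant is indoors 24 h in the base case: bedroom 22:00–06:00,
bathroom 06:00–07:00, kitchen during cooking (shared half-hours are
time-weighted mixes), living room otherwise. The `outdoors_2h` preset moves
14:00–16:00 outdoors, where exposure equals the ambient series. "Annual mean
exposure" is the mean of 365 daily means (identical to the plain hourly mean
for complete years); the 95% CI is mean ± 1.96·sd(daily means)/√365, i.e.
across days — day-to-day variability of one simulated year, not uncertainty
across replicate years.

## Scenario orchestration

The factorial is 3 filter grades × 3 use schedules × 2 smoking states plus
two no-filter baselines (20 runs). One environment realization per seed is
shared by all 20 scenarios so contrasts are paired; percent reductions and
averted mortality compare each scenario to the no-filter baseline of
matching smoking status. A full factorial takes ≈ 2 s in single-zone mode;
the acceptance checks average the headline scenarios over five seeds.

## Health impact

Averted deaths follow the IER chain RR → PAF → attributable rate per cause,
with the child-ALRI term scaled by the under-five population fraction, and
"percent of avoidable" defined as total averted over total pre-intervention
attributable burden. The bundled coefficient and Delhi background-rate
tables are **synthetic, order-of-magnitude illustrations** (the actual GBD
draws and sub-national rates are not published in the source material);
absolute mortality counts from the defaults are therefore indicative only,
while the closed-form RR/PAF arithmetic, monotonicity, additivity and
full-abatement limits are exact and tested. CSV loaders accept real GBD
coefficient/rate tables.

## Design choices where the ground truth is open

* Ceiling height 2.5 m: only the floor area is fixed by the dwelling
  template; 2.5 m makes the all-day HEPA clean-air removal ≈ 4.5/h, which a
  steady-state analysis shows is what reproduces the published all-day-HEPA
  exposure level. Configurable.
* Zone area split 9/12/6/3 m² is invented (only the 30 m² total is given).
* Filter use windows (15 h and 8 h) and follow-occupant placement are
  explicit, overridable choices; the defining appendix is not available.
* The smoking schedule ("8 per day, one per hour from 9:00–14:00") spans
  fewer slots than cigarettes; events simply continue hourly past 14:00.
* CIs are computed across days (whether the published intervals are across
  days or replicates is unstated).

## Known limitations

Single occupant; no breathing-rate dose weighting; no particle-size
resolution, coagulation or resuspension; no humidity dependence of
deposition; prescribed airflows preclude floor-level and wind-direction
effects; the smoker-present absolute levels depend on an unreported
per-cigarette emission mass (see above); leap years are unsupported by
design.
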