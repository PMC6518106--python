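# iaqsim

Yearlong simulation of indoor PM2.5 and personal exposure in a naturally
ventilated urban-Delhi apartment, with averted-mortality estimates for
portable air-filter interventions.

Delhi's ambient PM2.5 (annual mean ≈ 123 µg/m³) infiltrates homes through
windows and envelope leakage; indoor cooking and smoking add more. This
package answers a practical question for exposure scientists and
environmental-health researchers: **how much personal exposure and how much
PM2.5-attributable mortality can a portable air filter avert** under
realistic use patterns, filter grades and household smoking status?

## The model

Each room *i* is a well-mixed zone obeying a linear mass balance
(concentrations C in µg/m³, flows Q in m³/h):

```
V_i dC_i/dt = P·Q_inf,i·C_out + Σ_j Q_ji·C_j
              − (Q_exf,i + Q_fan,i + Σ_j Q_ij)·C_i
              + S_i(t) − k_dep·V_i·C_i − η·CADR·C_i·[filter in zone i, on]
```

* air exchange follows a prescribed hourly schedule `a(t)` (windows open
  7:00–18:00; annual mean 1.5/h, daily values spanning ≈ 0.3–4.5/h), with
  exhaust fans adding matching make-up infiltration;
* sources: LPG cooking (0.14 mg/min, 2 h/day) and optionally a smoker
  (0.33 mg/min, 8 cigarettes/day, one per hour from 9:00);
* sinks: deposition k_dep = 0.19/h, exfiltration, and a portable filter with
  CADR 200 cfm (≈ 339.6 m³/h) at single-pass efficiency η ∈ {0.30, 0.65, 0.99}.

All coefficients are hourly-constant, so each hour is advanced with the exact
solution of the linear system (matrix exponential); outputs are true
within-hour averages, non-negative by construction, and the mass budget
closes to floating point.

Personal exposure weights zone concentrations by the occupant's
time-activity schedule; the annual summary is the mean of 365 daily means
with a 95% CI of `mean ± 1.96·sd/√365`. Exposure reductions feed integrated
exposure-response (IER) curves,

```
RR(z) = 1 + α·(1 − exp(−γ·(z − z_cf)^δ)),    PAF = (RR − 1)/RR,
```

for five causes (COPD, IHD, stroke, lung cancer, child ALRI) to estimate
attributable and averted deaths. The bundled IER/background-rate tables are
synthetic illustrations; real GBD tables load from CSV.

A seeded synthetic environment generator reproduces the statistical
structure of Delhi-2017 forcing (lognormal ambient series with winter
elevation, morning/late-night peaks and AR(1) hourly residuals, calibrated to
an annual mean of 123 µg/m³; an AER schedule calibrated to 1.5/h), so the
entire analysis runs with no downloads. Optional readers ingest real CPCB
station CSV exports and EnergyPlus EPW weather files.

## Worked example

```python
from iaqsim import RunConfig, run_all

report = run_all(RunConfig(seed=1))
cols = ["scenario_id", "annual_mean_ugm3", "pct_reduction", "pct_of_avoidable"]
print(report[cols].to_string(index=False, float_format=lambda v: f"{v:.1f}"))
```

prints (abridged):

```
       scenario_id  annual_mean_ugm3  pct_reduction  pct_of_avoidable
none-none-nosmoker             100.3            NaN               NaN
  none-none-smoker             105.9            NaN               NaN
  8h-hepa-nosmoker              67.7           32.5              11.0
 15h-hepa-nosmoker              44.1           56.0              23.5
  24h-mid-nosmoker              32.7           67.4              32.5
 24h-hepa-nosmoker              25.1           75.0              40.6
```

Reading: without a filter the occupant's annual mean exposure is
≈ 100 µg/m³ — below the ambient 123 µg/m³ because closed windows at night
attenuate the nocturnal peaks. Running a HEPA filter all day cuts exposure by
75% to ≈ 25 µg/m³ (under the WHO interim target of 35 µg/m³); the same filter
used only during sleep (8 h) achieves 33%. The mortality column is the share
of the PM2.5-attributable death burden (under the bundled illustrative
exposure-response tables) removed by each intervention.

The same factorial runs from the shell:

```
iaqsim run --seed 1 --out out/          # 20 scenarios, writes out/report.csv
iaqsim generate-env --seed 1 --out env/ # just the synthetic year
iaqsim report --run-dir out/
```

## Scope notes

Airflows are prescribed (calibrated AER schedules), not solved from wind and
stack pressures; floor-level effects and DALY/cost-effectiveness outputs are
out of scope. See `docs/methods.md` for model assumptions, parameter
rationale and known limitations.
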