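# afburden

**AF-burden estimation from intermittent patient-operated ECGs, and its
relation to cardiovascular outcomes — as a fully synthetic, testable
pipeline.**

Atrial fibrillation (AF) is diagnosed from a single ECG, but its clinical
impact tracks the *burden* — the fraction of monitored time spent in AF.
When patients transmit short (30-s) single-lead ECGs once or twice a week,
burden can be estimated as

```
B̂ = (# ECGs classified AF) / (# ECGs classified AF or sinus rhythm)
```

after a two-stage classifier removes unreadable records (a 1-D CNN noise
detector) and labels the rest SR / AF / other from 13 RR-interval features
(moments, pNN50, RMSSD, COSEn, fuzzy measure entropy, a local heart-rate
deviation, and Lomb–Scargle LF/HF indices) with a cross-validated SVM. A
sensitivity definition interpolates rhythms to days (gaps filled only when
both neighbouring ECGs agree) and reports days in sinus rhythm per
monitoring day. Patients are then grouped by burden quartile (exact zeros
tied into Q1) and, after a 12-month landmark, outcome incidence per 100
patient-years is compared across quartiles with Aalen–Johansen cumulative
incidence under competing risks and a Cox model of hazard against burden
(per percentage point).

Because the underlying trial ECGs are not public, the package ships a
first-class synthetic-data module that emulates the study's statistical
structure — rhythm classes, a cohort burden distribution with a ~29.5% zero
point-mass and median ≈ 6% (IQR ≈ 0–22%), episode patterns from
short-paroxysmal to persistent, weekly transmission schedules with
symptom-triggered extras, and event hazards increasing with burden — so
every stage is exercisable and testable end to end. See
[docs/methods.md](docs/methods.md) for the models and their limitations.

## Who this is for

Biostatisticians and digital-cardiology researchers who want a worked,
tested reference implementation of: short-ECG rhythm-feature engineering
(COSEn, fuzzy measure entropy, recurrence-plot irregularity), AF-burden
estimation from intermittent sampling, monitoring-schedule design
(how many ECGs per week does a burden quartile need?), and landmark
competing-risks analysis.

## Worked example

```python
import numpy as np
from afburden import synthetic as syn, simulation as sim, outcomes as oc

# monitoring-schedule simulation on a study-matched cohort
scenario = sim.SimulationScenario(
    schedule=syn.MonitoringSchedule(regular_per_week=1.0,
                                    symptom_trigger_prob=0.1),
    n_patients=1000, n_replicates=20, seed=1)
report = sim.run_scenario(scenario)
print(f"quartile agreement: {report.quartile_agreement:.1%}")
# quartile agreement: 87.6%

# landmark analysis of a synthetic cohort with HR 1.01 per percent burden
cohort = syn.generate_cohort(5000, outcome_beta=np.log(1.01), seed=42,
                             baseline_hazard_py=0.04,
                             censor_hazard_py=0.01, competing_hazard_py=0.01)
df = cohort.patients.assign(
    event=lambda d: (d.event_type == "primary").astype(int),
    burden_pct=lambda d: 100 * d.burden_true)
fit = oc.cox_ph(df, ["burden_pct"], time_col="event_time_days")
print(fit[["covariate", "hr", "ci_lower", "ci_upper"]].round(4).to_string(index=False))
#  covariate     hr  ci_lower  ci_upper
# burden_pct 1.0104     1.007    1.0138
```

The 87.6% means that under weekly transmissions plus symptom-triggered
extras, about 7 of 8 synthetic patients land in the same burden quartile
whether quartiles are computed from the sampled estimate or from the true
per-day burden; disagreements concentrate between Q1 and Q2 (patients whose
few AF days were never sampled). The Cox fit recovers the generating hazard
ratio of 1.01 per percentage point of burden.

The numbered scripts under `analysis/` run the pipeline as a narrative —
`01_simulate_cohort.py` through `06_landmark_outcomes.py` (cohort → features
→ classifier → burden → schedules → landmark) — writing their tables under
`results/`. A thin CLI mirrors them (`afburden simulate`,
`afburden features`, `afburden simulate-monitoring`, `afburden burden`,
`afburden landmark`).

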