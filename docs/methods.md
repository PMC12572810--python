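# Methods

`afburden` reimplements, end to end on synthetic data, the computational
chain of an AF-burden study built on patient-operated telemetric 30-s ECGs:
rhythm classification of individual transmissions, patient-level AF-burden
estimation from intermittent recordings, simulation of monitoring schedules
against known true burden, and a 12-month landmark analysis of cardiovascular
outcomes by burden quartile. This note documents the models, the parameters
that matter, the numerical choices, and what the synthetic data can and
cannot establish.

## Synthetic data model

**RR processes.** Sinus rhythm is a low-variability renewal process around
the target mean interval with a 0.25-Hz respiratory modulation (amplitude 4%
of the mean RR) plus 2% white jitter, giving a coefficient of variation of
~3.5% (contract: ≤ 8%). AF intervals are i.i.d. gamma draws with CV 0.24
(contract: CV ≥ 0.15, lag-1 autocorrelation ≈ 0) — serial independence of
AF intervals is the standard modelling idealisation and is exactly the
property the entropy features exploit. "Other rhythm" is a regular base
rhythm with premature complexes every 4–8 beats (coupling interval 0.55·RR,
compensatory pause 1.45·RR). All intervals are clipped to (210, 2900) ms.

**ECG waveforms.** Each beat is a sum of five Gaussians (P, Q, R, S, T) with
fixed amplitudes/offsets/widths; R amplitude 1 mV. AF traces omit the P wave
and add a 5–7 Hz fibrillatory baseline oscillation (0.05 mV). Noise is
additive white noise plus 0.33-Hz baseline wander scaled by `noise_level`
(mV); at `noise_level ≥ 1.5` the QRS is no longer recoverable and the record
is labelled NOISE. This generator is deliberately minimal: it gives exact
beat-time ground truth and controllable P-wave presence, which is all the
feature chain and the two-stage classifier need. It does **not** model
electrode artefacts, muscle noise spectra, ectopy morphology or
inter-patient template variability, so classifier performance on it bounds
nothing about real ECGs; it demonstrates that the pipeline is correct and
that the features separate the rhythm classes they are designed to separate.

**Rhythm trajectories.** Per-day SR/AF state over follow-up from an
alternating two-state semi-Markov process. AF episode durations are
log-normal with pattern-specific medians — short 1.5 d (σ=0.7), medium 14 d
(σ=0.6), persistent 180 d (σ=0.4) — spanning paroxysmal to persistent
phenotypes; SR gap durations are log-normal (σ=0.8) with mean chosen so the
expected AF fraction equals the target burden. Because a 180-day episode
scale cannot freely realise, say, a 6% burden inside 365 days, realized
burdens are repaired to within ±2 percentage points of target by growing or
shrinking episodes one day at a time at their boundaries (contiguity
preserved); any positive target keeps at least one AF day so that exact
zeros arise only from the explicit zero point-mass. Day resolution is a
stated simplification: sub-day episodes are out of scope.

**Cohort burden distribution.** Burden targets are drawn from a zero-inflated
Beta mixture: point mass 348/1178 ≈ 0.295 at zero plus Beta(0.695, 2.843).
The Beta parameters were solved once so the mixture quantiles are
(q25, q50, q75) ≈ (0, 5.8%, 21.9%), the distribution observed in the study
population this package models. A 2000-patient draw lands the empirical
median in [4%, 8%] with q25 = 0.

**Monitoring.** Regular transmissions fall on an evenly spaced grid
(14/7/3.5-day spacing for 0.5/1/2 per week) with a uniformly random phase;
on each AF day an extra symptom-triggered transmission occurs with
probability `symptom_trigger_prob` (symptoms are assumed specific to AF,
mirroring a protocol that requests transmission on symptoms); any
transmission is unreadable with probability `noise_prob`. Note the symptom
channel oversamples AF days and biases the ECG-fraction estimate upward at
intermediate burdens; because quartile edges are recomputed on the estimated
burdens, quartile assignment is largely insensitive to this monotone bias.

**Outcomes.** Post-landmark event times are exponential with hazard
`baseline_hazard_py · exp(β · burden_pct)`; defaults β = ln(1.01) per
percentage point and baseline 0.02/patient-year, so that the low-burden
quartiles see ~2 events/100 patient-years. Competing death (0.012/py) and
censoring (0.03/py, administrative cut at 4.1 years) are independent.
Covariates (age, sex, BMI, diastolic blood pressure, heart failure, centre)
are drawn with weak burden links for DBP and heart failure.

## Feature extraction

**QRS detection** is an energy-based detector in the spirit of the
band-pass/threshold family: 5–25 Hz Butterworth band-pass, squaring, 150-ms
moving-window integration, adaptive threshold `max(0.08·max, 2·median)` of
the integrated energy, 200-ms refractory period, and refinement of each
detection to the local energy maximum. On noise-free synthetic records it
reaches sensitivity and positive predictivity 1.0 across 45–150 bpm with
beat-time error under 20 ms. A flat or energy-free trace returns an empty
beat list rather than raising.

**The 13 RR features**: mean, median, SD, max, min of the RR intervals;
pNN50 and RMSSD on successive differences; COSEn; fuzzy measure entropy; the
median absolute deviation of 3-beat local heart rate from the record mean
(over runs of three adjacent intervals whose spread is < 10% of the run
mean; 0 if no run qualifies); and normalised LF (0.04–0.15 Hz) and HF
(0.15–0.40 Hz) power of the RR tachogram with their ratio. pNN50 uses the
standard successive-difference definition. Spectral powers come from a
Lomb–Scargle periodogram evaluated on the irregular beat times (avoiding
resampling artefacts on 30-s records) and are normalised by LF+HF.

**Entropies.** COSEn = SampEn(m=1, r=30 ms) + ln(2r) − ln(mean RR), the
AF-detection convention in which the match-radius and heart-rate corrections
make short-series entropy comparable across records. Fuzzy measure entropy
is the sum of a local (template-mean-removed) and a global
(series-mean-removed) fuzzy entropy with exponential membership
exp(−(d/r)^2) on Chebyshev distances, m = 2. The fuzzy radii are **absolute**
(30 ms, matching the COSEn radius) rather than the common 0.2·SD(RR): a
radius proportional to the series' own SD makes the measure scale-invariant
and therefore nearly blind to the high absolute RR variability that
distinguishes AF (single-feature AUC collapses from 1.0 to ~0.6 on the
synthetic benchmark). Both radii are parameters. A constant series returns 0;
series without template matches return an infinite sentinel (capped at 10 in
the assembled feature vector so classifiers see finite inputs). Minimum
series length for the full vector is 5 intervals; shorter records are routed
to NOISE/unclassifiable.

**Irregularity index.** The trace is cut into non-overlapping 0.5-s
segments, each mean-removed (so baseline offsets do not dominate), and
cosine similarity is computed for all unordered pairs. A pair is a
recurrence when the cosine **distance** is ≤ 0.15 — i.e. recurrences are
highly similar segments; the literal reading (similarity ≤ 0.15) is also
selectable (`mode="similarity"`) since the two conventions circulate. The
index is 1 − recurrences/pairs, scale-invariant by construction.

**Annotation bins.** The joint (heart rate, irregularity) distribution is
discretised into a 10×10 equally spaced grid over the observed ranges; bins
with ≥ 500 records are eligible. Per patient, two records are drawn from two
randomly chosen eligible bins (uniform over bins), with a uniform fallback
for patients without any record in an eligible bin, and a disjoint test
record per patient.

## Two-stage classifier

Stage 1 is a 1-D CNN noise detector: three blocks of [convolution, 64
filters of width 16 → ReLU → batch normalisation → max pooling stride 2
(width 2)], then dense layers of width 64 and 32 and a 2-way softmax, on
0.5–40 Hz band-passed, per-record standardised traces, trained with Adam on
cross-entropy. The network is implemented directly on numpy (float32,
im2col/tap-accumulation convolutions); weight init and batch order are
seeded, so training is bit-for-bit reproducible. Batch-norm inference
statistics are the cumulative average of the batch statistics seen during
training, which stays well-calibrated even for the short training runs this
problem needs (an exponential moving average barely leaves its initial value
after a handful of updates). Pooling width, threshold (0.5), epochs (30),
learning rate (1e-3) and batch size (32) are parameters; the pooling width
of 2 is a choice where only the stride is pinned down.

Stage 2 is an SVM over the 13 features with the kernel (linear, polynomial,
RBF) chosen by rhythm-stratified 5-fold cross-validated accuracy and
refitted on all data; inverse-frequency class weights handle the rarity of
"other rhythm". Records flagged by stage 1, or whose QRS/RR extraction fails
the feature preconditions, are labelled NOISE and excluded from everything
downstream — no NOISE record ever enters a burden estimate.

On the 2000-record synthetic benchmark (40% SR, 40% AF, 10% other, 10%
noise; stage 1 trained on 100+100 records for 3 epochs, stage 2 on 400
feature vectors) the pipeline's AF F1 exceeds 0.9. This is a property check
of the implemented procedure under clean class structure, not a claim about
performance on trial ECGs.

## Burden estimation

Primary definition: AF ECGs / analysable ECGs, where analysable means
classified SR or AF (noise and other-rhythm excluded from numerator and
denominator). Patients with fewer than two analysable ECGs are flagged
ineligible. Sensitivity definition: each gap between consecutive analysable
observations is filled with their shared label iff both endpoints agree;
otherwise the days stay unassigned, as do days before the first and after
the last observation. Days in sinus rhythm are reported per monitoring day
(first to last assigned day, inclusive — the denominator had to be fixed by
choice, and unassigned interior days stay in it but never in the numerator)
and per total follow-up day. A day with any AF observation is an AF day.
Therapy-change events act as AF-equivalent endpoints in the interpolation
but are not ECGs: by default they do not enter the ECG-fraction tally
(`include_therapy_changes` flips this, since the convention is genuinely
ambiguous). Adherence is the percentage of follow-up weeks containing a
transmission; motivation is days from randomization to the first ECG.

## Monitoring simulation

For a scenario (schedule, episode-pattern mix, cohort size, replicates,
seed) the simulator draws target burdens from the study-matched mixture,
realises a timeline per patient, samples the monitoring stream, estimates
burden as above, and compares to the true per-day burden: stratified
mean/SD/mean-absolute error (true-burden bands 0–20 / 20–50 / 50–100%,
matching the ranges in which precision claims are usually made, crossed with
pattern), the fraction of patients assigned to the same burden quartile
under estimated and true burden (quartiles computed separately on each
array, zeros tied into Q1), and the share of disagreements in the Q1↔Q2
cells. True burden is defined at day resolution, consistent with the
timeline generator.

Under the study-matched cohort with weekly sampling plus symptom triggers
(p = 0.1), quartile agreement is ~88% (bound checked: ≥ 75%), the error is
smaller at twice-weekly than weekly sampling, and the largest single
confusion cell is Q1↔Q2 — low-burden patients whose few AF days are missed
entirely.

## Landmark analysis

The landmark cohort keeps patients alive and primary-event-free at day 365
with ≥ 2 analysable first-year ECGs; the clock restarts at the landmark.
Quartile edges are the empirical quartiles of first-year burden with ties at
an edge resolved downward, so all exact-zero burdens sit in Q1 and Q1 is
larger than Q2 whenever the zero mass exceeds a quarter. Incidence rates are
100·events/person-years, printed to one decimal (two below 0.5, the
precision needed for rare components). Cumulative incidence under competing
risks uses the product-sum estimator CIF(t) = Σ S(t⁻)·d/n with the all-cause
Kaplan–Meier survivor S; survivor plus all CIFs sum to 1 at every step to
1e-12 by construction, and the estimator is cross-checked against an
independent library implementation.

The Cox proportional-hazards fit maximises the Breslow partial likelihood
(the simplest defensible tie convention; ties are rare at day resolution) by
Newton–Raphson with step-halving on internally standardised covariates,
Wald 95% CIs from the inverse observed information, and two-sided normal
p-values. Divergence of any standardised coefficient beyond |β| > 10 raises
a separation error (the partial likelihood approaches a finite supremum
under separation, so a gradient criterion alone would "converge"). The fit
is verified against an exhaustive grid search of a hand-written partial
likelihood on toy data and against an independent library on tie-free data.
The centre frailty term of the original model is replaced by an optional
per-centre stratification/covariate at this scale; frailty estimation is
ancillary to the burden question and no frailty diagnostics exist to match.
Multiple imputation for secondary endpoints is out of scope (complete-case
only). LOESS curves of event probability against burden use a tricube local
linear smoother with robustness iterations disabled — robust reweighting
treats the minority class of a 0/1 indicator as outliers and biases the
estimated probability.

## Problem sizes and reproducibility

Every stochastic component takes an integer seed and is bit-for-bit
reproducible. The shipped analyses use 1000-patient cohorts, 20-replicate
monitoring scenarios, a 2000-record classifier benchmark (stage-1 training:
200 records × 3 epochs) and an n = 5000 Cox recovery experiment (~850
events; the recovered per-percent log-HR sits within ±0.003 of ln(1.01)).
These sizes were chosen so the full pipeline, including the numpy CNN, runs
comfortably on a single CPU core.

## Known limitations

- The ECG generator's noise model is white + baseline wander only; the noise
  CNN's task here is far easier than on device recordings.
- Day-resolution timelines cannot represent sub-day paroxysms; short-pattern
  burdens are therefore slightly coarser than reality.
- The symptom-trigger model (probability per AF day, AF-specific) is a
  stand-in; the real dependence of transmission behaviour on symptoms is
  unknown and the episode-duration parameters are documented choices, not
  fitted values.
- The per-component censoring scheme for outcome components treats each
  component with first-event censoring; published per-component person-years
  conventions vary.
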