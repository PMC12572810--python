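"""Synthetic ECGs, RR processes, rhythm trajectories, monitoring and outcomes.

Everything downstream (feature extraction, classification, burden estimation,
monitoring simulation, landmark analysis) is exercised on data from this
module.  The generator emulates the statistical structure of a telemetric
AF-monitoring study: patient-operated 30-s single-lead ECGs at 200 Hz,
per-day SR/AF rhythm trajectories with episode patterns from short-paroxysmal
to persistent, 1-2 regular transmissions per week plus symptom-triggered
extras, a cohort burden distribution with a point mass at zero (median ~6%,
IQR ~0-22%), and event hazards increasing with burden.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

RHYTHMS = ("SR", "AF", "OTHER", "NOISE")
PATTERNS = ("short", "medium", "persistent")

#: median AF-episode duration (days) per episode pattern
EPISODE_MEDIAN_DAYS = {"short": 1.5, "medium": 14.0, "persistent": 180.0}
#: log-normal sigma of episode durations per pattern
EPISODE_SIGMA = {"short": 0.7, "medium": 0.6, "persistent": 0.4}

#: noise amplitude (mV) at and above which a synthesized record is labelled NOISE
NOISE_LABEL_THRESHOLD = 1.5

#: cohort burden mixture calibrated to a zero point-mass of 348/1178 patients
#: and overall quantiles (q25, q50, q75) ~ (0, 0.058, 0.219)
DEFAULT_BURDEN_MIXTURE = {"zero_mass": 348 / 1178, "beta_a": 0.695, "beta_b": 2.843}
DEFAULT_PATTERN_MIX = {"short": 1 / 3, "medium": 1 / 3, "persistent": 1 / 3}


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #


@dataclass
class RRSeries:
    """Beat-to-beat intervals in milliseconds; all in (200, 3000) ms."""

    intervals_ms: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)

    def __len__(self) -> int:
        return len(self.intervals_ms)

    @property
    def mean_hr_bpm(self) -> float:
        return 60000.0 / float(np.mean(self.intervals_ms))

    def beat_times_s(self) -> np.ndarray:
        """Beat instants in seconds, first beat at t0."""
        return self.t0 + np.concatenate(([0.0], np.cumsum(self.intervals_ms) / 1000.0))


@dataclass
class ECGRecord:
    """One 30-s single-lead trace (mV) with its provenance."""

    samples: np.ndarray
    fs: float = 200.0
    duration_s: float = 30.0
    patient_id: str = ""
    recorded_at: int = 0          # day index from randomization
    true_label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")


@dataclass
class PatientTimeline:
    """Ground-truth per-day rhythm state (0 = SR, 1 = AF) over follow-up."""

    patient_id: str
    day_state: np.ndarray
    episode_pattern: str
    true_burden: float
    therapy_change_days: list = field(default_factory=list)

    @property
    def followup_days(self) -> int:
        return len(self.day_state)


@dataclass
class MonitoringSchedule:
    regular_per_week: float = 1.0
    symptom_trigger_prob: float = 0.0
    noise_prob: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.symptom_trigger_prob <= 1.0):
            raise ValueError("symptom_trigger_prob must be in [0, 1]")
        if not (0.0 <= self.noise_prob <= 1.0):
            raise ValueError("noise_prob must be in [0, 1]")
        if self.regular_per_week <= 0:
            raise ValueError("regular_per_week must be positive")


@dataclass
class RhythmObservation:
    """(day, classified rhythm) pair — the unit of burden estimation."""

    patient_id: str
    day: int
    label: str
    source: str = "regular"  # regular | symptom | therapy_change


@dataclass
class SyntheticCohort:
    timelines: list
    patients: pd.DataFrame
    burden_mixture: dict
    pattern_mix: dict
    outcome_beta: float
    seed: int

    def to_csv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(out / "patients.csv", index=False)
        rows = []
        for tl in self.timelines:
            rows.append(
                pd.DataFrame(
                    {
                        "patient_id": tl.patient_id,
                        "day": np.arange(tl.followup_days),
                        "state": np.where(tl.day_state == 1, "AF", "SR"),
                    }
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(out / "timelines.csv", index=False)
        cfg = {
            "burden_mixture": self.burden_mixture,
            "pattern_mix": self.pattern_mix,
            "outcome_beta": self.outcome_beta,
            "seed": self.seed,
        }
        (out / "config.json").write_text(json.dumps(cfg, indent=2))


# --------------------------------------------------------------------------- #
# RR-interval processes
# --------------------------------------------------------------------------- #


def generate_rr_series(
    rhythm: str,
    duration_s: float,
    hr_mean_bpm: float,
    seed: int,
    variability: float | None = None,
) -> RRSeries:
    """Generate a beat-interval series of one rhythm class.

    SR: low-variability intervals with smooth respiratory modulation
    (CV <= 0.08).  AF: serially uncorrelated high-variability intervals
    (CV >= 0.15, lag-1 autocorrelation ~ 0).  OTHER: regular base rhythm with
    inserted premature beats (short coupling interval followed by a
    compensatory pause).

    ``variability`` scales the rhythm's default dispersion; 0 gives a
    perfectly regular series.
    """
    if rhythm not in ("SR", "AF", "OTHER"):
        raise ValueError(f"unknown rhythm {rhythm!r}")
    if duration_s <= 0 or hr_mean_bpm <= 0:
        raise ValueError("duration_s and hr_mean_bpm must be positive")
    rng = np.random.default_rng(seed)
    mean_rr = 60000.0 / hr_mean_bpm
    n = max(2, int(np.ceil(duration_s * 1000.0 / mean_rr)) + 3)
    v = 1.0 if variability is None else float(variability)

    if rhythm == "SR":
        # respiratory sinus modulation (~0.25 Hz) + small white jitter
        t = np.cumsum(np.full(n, mean_rr)) / 1000.0
        resp = 0.04 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
        jitter = 0.02 * rng.standard_normal(n)
        intervals = mean_rr * (1.0 + v * (resp + jitter))
    elif rhythm == "AF":
        cv = 0.24 * v
        if cv <= 0:
            intervals = np.full(n, mean_rr)
        else:
            shape = 1.0 / cv**2
            intervals = rng.gamma(shape, mean_rr / shape, size=n)
    else:  # OTHER: premature beats on a regular base rhythm
        intervals = mean_rr * (1.0 + 0.02 * v * rng.standard_normal(n))
        step = max(3, int(rng.integers(4, 8)))
        for i in range(1, n - 1, step):
            intervals[i] = 0.55 * mean_rr
            intervals[i + 1] = 1.45 * mean_rr

    intervals = np.clip(intervals, 210.0, 2900.0)
    # keep beats inside the record duration
    keep = np.cumsum(intervals) <= duration_s * 1000.0
    if keep.sum() >= 2:
        intervals = intervals[keep]
    else:
        intervals = intervals[:2]
    return RRSeries(intervals_ms=intervals)


# --------------------------------------------------------------------------- #
# ECG waveform synthesis
# --------------------------------------------------------------------------- #

# sum-of-Gaussians P-QRS-T template: (amplitude mV, offset s from R, width s)
_PQRST = {
    "P": (0.15, -0.17, 0.025),
    "Q": (-0.10, -0.035, 0.010),
    "R": (1.00, 0.0, 0.012),
    "S": (-0.20, 0.035, 0.010),
    "T": (0.30, 0.22, 0.050),
}


def synthesize_ecg(
    rr: RRSeries,
    rhythm: str,
    noise_level: float,
    fs: float = 200.0,
    seed: int = 0,
    duration_s: float = 30.0,
    patient_id: str = "",
    recorded_at: int = 0,
) -> ECGRecord:
    """Render an RR series as a single-lead trace.

    Beat complexes are placed at cumulative RR times using a sum-of-Gaussians
    P-QRS-T template.  AF traces omit P waves and carry a small-amplitude
    fibrillatory baseline oscillation.  ``noise_level`` (mV) adds white noise
    plus baseline wander; at ``noise_level >= NOISE_LABEL_THRESHOLD`` the QRS
    complexes are obscured and the record is labelled NOISE.
    """
    if len(rr) == 0:
        raise ValueError("empty RRSeries")
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    if rhythm not in ("SR", "AF", "OTHER"):
        raise ValueError(f"unknown rhythm {rhythm!r}")
    rng = np.random.default_rng(seed)
    n = int(round(fs * duration_s))
    t = np.arange(n) / fs
    x = np.zeros(n)

    beats = rr.beat_times_s() + 0.3  # leave room for the first P wave
    beats = beats[beats < duration_s - 0.05]
    waves = dict(_PQRST)
    if rhythm == "AF":
        waves.pop("P")
    for tb in beats:
        for amp, off, width in waves.values():
            c = tb + off
            lo = max(0, int((c - 5 * width) * fs))
            hi = min(n, int((c + 5 * width) * fs) + 1)
            if hi > lo:
                x[lo:hi] += amp * np.exp(-((t[lo:hi] - c) ** 2) / (2 * width**2))

    if rhythm == "AF":
        # fibrillatory waves: irregular 5-7 Hz baseline oscillation
        f1 = rng.uniform(5.0, 7.0)
        x += 0.05 * np.sin(2 * np.pi * f1 * t + rng.uniform(0, 2 * np.pi))
        x += 0.03 * np.sin(2 * np.pi * 1.7 * f1 * t + rng.uniform(0, 2 * np.pi))

    if noise_level > 0:
        x += noise_level * rng.standard_normal(n)
        x += 0.5 * noise_level * np.sin(2 * np.pi * 0.33 * t + rng.uniform(0, 2 * np.pi))

    label = "NOISE" if noise_level >= NOISE_LABEL_THRESHOLD else rhythm
    return ECGRecord(
        samples=x,
        fs=fs,
        duration_s=duration_s,
        patient_id=patient_id,
        recorded_at=recorded_at,
        true_label=label,
    )


def ecg_to_csv(record: ECGRecord, path: str | Path) -> None:
    """One sample column; header carries fs, patient id, date and label."""
    header = (
        f"# fs={record.fs} patient_id={record.patient_id} "
        f"recorded_at={record.recorded_at} label={record.true_label}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        fh.write("sample_mv\n")
        np.savetxt(fh, record.samples, fmt="%.6f")


def ecg_from_csv(path: str | Path) -> ECGRecord:
    with open(path) as fh:
        meta = dict(kv.split("=") for kv in fh.readline().lstrip("# ").split())
    samples = np.loadtxt(path, skiprows=2)
    label = meta.get("label")
    return ECGRecord(
        samples=samples,
        fs=float(meta["fs"]),
        duration_s=len(samples) / float(meta["fs"]),
        patient_id=meta.get("patient_id", ""),
        recorded_at=int(meta.get("recorded_at", 0)),
        true_label=None if label in (None, "None") else label,
    )


# --------------------------------------------------------------------------- #
# rhythm trajectories
# --------------------------------------------------------------------------- #


def generate_timeline(
    pattern: str,
    target_burden: float,
    followup_days: int,
    seed: int,
    patient_id: str = "",
    tolerance: float = 0.02,
    therapy_change_rate: float = 0.0,
) -> PatientTimeline:
    """Alternating SR/AF two-state semi-Markov trajectory at day resolution.

    AF-episode durations are log-normal with pattern-specific medians
    (short ~1.5 d, medium ~14 d, persistent ~180 d); SR gaps are log-normal
    with their mean set so the expected burden equals ``target_burden``.
    Whole-day boundary adjustments then repair the realized burden to within
    ``tolerance`` of the target (necessary for patterns whose episode scale
    is large relative to follow-up).  The exact realized fraction is stored.
    """
    if not (0.0 <= target_burden <= 1.0):
        raise ValueError("target_burden must be in [0, 1]")
    if followup_days < 1:
        raise ValueError("followup_days must be >= 1")
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}")
    rng = np.random.default_rng(seed)
    F = followup_days

    if target_burden <= 0.0:
        state = np.zeros(F, dtype=np.int8)
    elif target_burden >= 1.0:
        state = np.ones(F, dtype=np.int8)
    else:
        med_af = EPISODE_MEDIAN_DAYS[pattern]
        sig_af = EPISODE_SIGMA[pattern]
        mean_af = med_af * np.exp(sig_af**2 / 2)
        sig_sr = 0.8
        mean_sr = mean_af * (1.0 - target_burden) / target_burden
        med_sr = max(mean_sr / np.exp(sig_sr**2 / 2), 0.25)

        state = np.zeros(F, dtype=np.int8)
        pos = 0
        in_af = False
        first = True
        while pos < F:
            if in_af:
                dur = rng.lognormal(np.log(med_af), sig_af)
            else:
                dur = rng.lognormal(np.log(med_sr), sig_sr)
                if first:
                    dur *= rng.uniform(0.0, 1.0)  # random phase
            first = False
            d = max(1, int(round(dur)))
            if in_af:
                state[pos : pos + d] = 1
            pos += d
            in_af = not in_af
        _repair_burden(state, target_burden, tolerance, rng)
        if state.sum() == 0:
            # zero burdens must come only from the explicit point mass
            state[rng.integers(F)] = 1

    af_days = int(state.sum())
    therapy_days: list[int] = []
    if therapy_change_rate > 0 and af_days > 0:
        af_idx = np.flatnonzero(state == 1)
        hit = rng.random(af_days) < therapy_change_rate
        therapy_days = [int(d) for d in af_idx[hit]]

    return PatientTimeline(
        patient_id=patient_id,
        day_state=state,
        episode_pattern=pattern,
        true_burden=af_days / F,
        therapy_change_days=therapy_days,
    )


def _repair_burden(
    state: np.ndarray, target: float, tol: float, rng: np.random.Generator
) -> None:
    """Grow/shrink episodes at their boundaries, one day at a time, until the
    realized AF fraction is within ``tol`` of ``target``."""
    F = len(state)
    for _ in range(2 * F):
        burden = state.sum() / F
        if abs(burden - target) <= tol:
            return
        if burden < target:
            if state.sum() == 0:
                state[rng.integers(F)] = 1
                continue
            # SR days adjacent to an AF day
            cand = np.flatnonzero(
                (state == 0)
                & (np.concatenate(([0], state[:-1])) | np.concatenate((state[1:], [0])))
            )
            if len(cand) == 0:
                cand = np.flatnonzero(state == 0)
            state[rng.choice(cand)] = 1
        else:
            cand = np.flatnonzero(
                (state == 1)
                & (
                    (np.concatenate(([1], state[:-1])) == 0)
                    | (np.concatenate((state[1:], [1])) == 0)
                )
            )
            if len(cand) == 0:
                cand = np.flatnonzero(state == 1)
            state[rng.choice(cand)] = 0


# --------------------------------------------------------------------------- #
# monitoring
# --------------------------------------------------------------------------- #


def sample_monitoring(
    timeline: PatientTimeline,
    schedule: MonitoringSchedule,
    seed: int,
) -> list[RhythmObservation]:
    """Draw the transmissions a patient would produce under a schedule.

    Regular transmissions fall on an evenly spaced day grid with a random
    phase; on AF days an extra symptom-triggered transmission occurs with
    ``symptom_trigger_prob``.  Each observation carries the timeline's state
    that day unless flipped to NOISE with ``noise_prob``.
    """
    F = timeline.followup_days
    if F == 0:
        raise ValueError("empty timeline")
    rng = np.random.default_rng(seed)
    period = 7.0 / schedule.regular_per_week
    phase = rng.uniform(0.0, period)
    grid = np.floor(phase + period * np.arange(int(np.ceil(F / period)) + 1))
    days = np.unique(grid[grid < F].astype(int))

    obs: list[RhythmObservation] = []
    for d in days:
        label = "AF" if timeline.day_state[d] == 1 else "SR"
        if schedule.noise_prob > 0 and rng.random() < schedule.noise_prob:
            label = "NOISE"
        obs.append(RhythmObservation(timeline.patient_id, int(d), label, "regular"))

    if schedule.symptom_trigger_prob > 0:
        af_days = np.flatnonzero(timeline.day_state == 1)
        hit = rng.random(len(af_days)) < schedule.symptom_trigger_prob
        for d in af_days[hit]:
            label = "AF"
            if schedule.noise_prob > 0 and rng.random() < schedule.noise_prob:
                label = "NOISE"
            obs.append(RhythmObservation(timeline.patient_id, int(d), label, "symptom"))

    obs.sort(key=lambda o: o.day)
    return obs


def observations_to_frame(obs: Sequence[RhythmObservation]) -> pd.DataFrame:
    return pd.DataFrame([asdict(o) for o in obs])


# --------------------------------------------------------------------------- #
# cohorts
# --------------------------------------------------------------------------- #


def draw_burdens(n: int, mixture: dict, rng: np.random.Generator) -> np.ndarray:
    """Zero point-mass plus right-skewed Beta continuous part."""
    p0 = mixture["zero_mass"]
    a, b = mixture["beta_a"], mixture["beta_b"]
    if not (0.0 <= p0 <= 1.0) or a <= 0 or b <= 0:
        raise ValueError("invalid burden mixture parameters")
    burdens = rng.beta(a, b, size=n)
    burdens[rng.random(n) < p0] = 0.0
    return burdens


def generate_cohort(
    n: int,
    burden_mixture: dict | None = None,
    pattern_mix: dict | None = None,
    outcome_beta: float = float(np.log(1.01)),
    followup_years: float = 4.1,
    seed: int = 0,
    baseline_hazard_py: float = 0.02,
    competing_hazard_py: float = 0.012,
    censor_hazard_py: float = 0.03,
    followup_days: int = 365,
    therapy_change_rate: float = 0.0,
) -> SyntheticCohort:
    """Full synthetic cohort: first-year timelines plus post-landmark outcomes.

    Burdens come from the zero-inflated Beta mixture; each patient gets a
    rhythm trajectory realizing their burden.  Post-landmark event times are
    exponential with hazard ``baseline_hazard_py * exp(outcome_beta *
    burden_percent)`` (``outcome_beta`` is the per-percentage-point log hazard
    ratio), an independent competing-death hazard, and independent censoring
    plus an administrative cut at ``followup_years``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mixture = dict(DEFAULT_BURDEN_MIXTURE if burden_mixture is None else burden_mixture)
    mix = dict(DEFAULT_PATTERN_MIX if pattern_mix is None else pattern_mix)
    w = np.array([mix.get(p, 0.0) for p in PATTERNS], dtype=float)
    if w.sum() <= 0:
        raise ValueError("pattern_mix weights must sum to a positive value")
    w = w / w.sum()

    rng = np.random.default_rng(seed)
    burdens = draw_burdens(n, mixture, rng)
    patterns = rng.choice(PATTERNS, size=n, p=w)
    timeline_seeds = rng.integers(0, 2**31 - 1, size=n)

    timelines = []
    rows = []
    admin_days = followup_years * 365.0
    for i in range(n):
        pid = f"P{i:05d}"
        tl = generate_timeline(
            patterns[i],
            float(burdens[i]),
            followup_days,
            int(timeline_seeds[i]),
            patient_id=pid,
            therapy_change_rate=therapy_change_rate,
        )
        timelines.append(tl)
        pct = 100.0 * tl.true_burden

        rate_primary = baseline_hazard_py * np.exp(outcome_beta * pct) / 365.0
        t_primary = rng.exponential(1.0 / rate_primary)
        t_death = rng.exponential(365.0 / competing_hazard_py)
        t_cens = min(rng.exponential(365.0 / censor_hazard_py), admin_days)
        t = min(t_primary, t_death, t_cens)
        if t == t_primary:
            event = "primary"
        elif t == t_death:
            event = "competing_death"
        else:
            event = "censored"

        rows.append(
            {
                "patient_id": pid,
                "pattern": tl.episode_pattern,
                "burden_true": tl.true_burden,
                "event_time_days": float(max(t, 0.5)),
                "event_type": event,
                "age": float(np.clip(rng.normal(70, 8), 40, 95)),
                "sex_female": int(rng.random() < 0.45),
                "bmi": float(np.clip(rng.normal(29.3, 5.4), 16, 55)),
                "dbp": float(rng.normal(79 + 4 * tl.true_burden, 12)),
                "heart_failure": int(rng.random() < 0.23 + 0.10 * tl.true_burden),
                "centre": int(rng.integers(0, 20)),
            }
        )

    return SyntheticCohort(
        timelines=timelines,
        patients=pd.DataFrame(rows),
        burden_mixture=mixture,
        pattern_mix=mix,
        outcome_beta=outcome_beta,
        seed=seed,
    )
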