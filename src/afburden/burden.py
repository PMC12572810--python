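"""Patient-level AF-burden estimates from per-record rhythm labels.

The primary definition is the fraction of analysable ECGs (SR or AF only)
classified as AF. A sensitivity definition assigns a rhythm to every day of
the monitoring period by filling gaps between transmissions whose endpoint
rhythms agree, and reports days in sinus rhythm per monitoring day and per
follow-up day. Therapy-change events enter the interpolation as AF-equivalent
endpoints but are not ECGs and never enter the ECG-fraction tally (a config
flag can include them). Adherence and motivation summarise transmission
behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from afburden.synthetic import RhythmObservation

# per-day assignment codes
SR, AF, UNASSIGNED = 0, 1, -1

#: minimum analysable (SR/AF) ECGs for a patient to receive a burden estimate
MIN_ANALYSABLE = 2


class IneligiblePatientError(ValueError):
    """Patient does not meet the minimum-data requirement for an estimate."""


@dataclass
class BurdenEstimate:
    patient_id: str
    burden_ecg_fraction: float
    days_in_sr_fraction: float
    days_in_sr_total_fu: float
    n_ecgs_analysable: int
    monitoring_days: int


def _is_ecg(o: RhythmObservation) -> bool:
    return o.source != "therapy_change"


def estimate_burden(
    observations: Sequence[RhythmObservation],
    include_therapy_changes: bool = False,
) -> float:
    """AF ECGs / analysable ECGs. NOISE and OTHER labels are excluded from
    numerator and denominator; fewer than 2 analysable ECGs raises
    :class:`IneligiblePatientError`."""
    n_af = n_sr = 0
    for o in observations:
        if not include_therapy_changes and not _is_ecg(o):
            continue
        if o.label == "AF":
            n_af += 1
        elif o.label == "SR":
            n_sr += 1
    if n_af + n_sr < MIN_ANALYSABLE:
        raise IneligiblePatientError(
            f"only {n_af + n_sr} analysable ECG(s); need {MIN_ANALYSABLE}"
        )
    return n_af / (n_af + n_sr)


def interpolate_days(
    observations: Sequence[RhythmObservation], followup_days: int
) -> np.ndarray:
    """Per-day assignment over ``followup_days``: SR (0), AF (1) or
    UNASSIGNED (-1).

    NOISE/OTHER observations are discarded first; therapy-change events count
    as AF endpoints. A day with any AF observation is an AF day. Days in a
    gap between consecutive analysable observations get the shared label iff
    both endpoints agree; days before the first and after the last
    observation stay UNASSIGNED.
    """
    days: dict[int, int] = {}
    for o in observations:
        label = "AF" if o.source == "therapy_change" else o.label
        if label not in ("SR", "AF"):
            continue
        if not (0 <= o.day < followup_days):
            continue
        code = AF if label == "AF" else SR
        days[o.day] = max(days.get(o.day, SR), code)  # any AF makes the day AF

    out = np.full(followup_days, UNASSIGNED, dtype=np.int8)
    obs_days = sorted(days)
    for d in obs_days:
        out[d] = days[d]
    for d0, d1 in zip(obs_days[:-1], obs_days[1:]):
        if days[d0] == days[d1]:
            out[d0 + 1 : d1] = days[d0]
    return out


def days_in_sr(
    interpolated: np.ndarray, total_followup_days: int
) -> tuple[float, float]:
    """(SR days / monitoring days, SR days / total follow-up days).

    The monitoring period runs from the first to the last assigned day,
    inclusive; interior UNASSIGNED days stay in the denominator but never the
    numerator.
    """
    assigned = np.flatnonzero(interpolated != UNASSIGNED)
    if len(assigned) == 0:
        raise IneligiblePatientError("no assigned days: zero monitoring days")
    first, last = int(assigned[0]), int(assigned[-1])
    monitoring_days = last - first + 1
    sr_days = int(np.count_nonzero(interpolated[first : last + 1] == SR))
    return sr_days / monitoring_days, sr_days / total_followup_days


def adherence(
    observations: Sequence[RhythmObservation], followup_weeks: int
) -> float:
    """Percentage of follow-up weeks with at least one transmission of any
    label."""
    if followup_weeks < 1:
        raise ValueError("followup_weeks must be >= 1")
    weeks = {o.day // 7 for o in observations if _is_ecg(o) and o.day // 7 < followup_weeks}
    return 100.0 * len(weeks) / followup_weeks


def motivation(randomization_day: int, first_ecg_day: int) -> int:
    """Days between randomization and the first patient-operated ECG."""
    if first_ecg_day < randomization_day:
        raise ValueError("first ECG precedes randomization")
    return int(first_ecg_day - randomization_day)


def burden_table(
    labels: pd.DataFrame,
    events: pd.DataFrame | None = None,
    followup_days: int = 365,
) -> pd.DataFrame:
    """Per-patient burden estimates from a classifier label table.

    ``labels`` needs columns patient_id, day, label (and optionally source);
    ``events`` may add therapy-change rows (patient_id, day). Ineligible
    patients (fewer than 2 analysable ECGs) are flagged, not dropped.
    """
    if "source" not in labels.columns:
        labels = labels.assign(source="regular")
    frames = [labels[["patient_id", "day", "label", "source"]]]
    if events is not None and len(events):
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": events["patient_id"],
                    "day": events["day"],
                    "label": "AF",
                    "source": "therapy_change",
                }
            )
        )
    allobs = pd.concat(frames, ignore_index=True)

    rows = []
    for pid, grp in allobs.groupby("patient_id", sort=True):
        obs = [
            RhythmObservation(str(pid), int(r.day), str(r.label), str(r.source))
            for r in grp.itertuples()
        ]
        obs.sort(key=lambda o: o.day)
        try:
            frac = estimate_burden(obs)
            interp = interpolate_days(obs, followup_days)
            sr_mon, sr_fu = days_in_sr(interp, followup_days)
            assigned = np.flatnonzero(interp != UNASSIGNED)
            rows.append(
                {
                    "patient_id": pid,
                    "eligible": True,
                    "burden_ecg_fraction": frac,
                    "days_in_sr_fraction": sr_mon,
                    "days_in_sr_total_fu": sr_fu,
                    "n_ecgs_analysable": sum(
                        1 for o in obs if _is_ecg(o) and o.label in ("SR", "AF")
                    ),
                    "monitoring_days": int(assigned[-1] - assigned[0] + 1),
                }
            )
        except IneligiblePatientError:
            rows.append(
                {
                    "patient_id": pid,
                    "eligible": False,
                    "burden_ecg_fraction": np.nan,
                    "days_in_sr_fraction": np.nan,
                    "days_in_sr_total_fu": np.nan,
                    "n_ecgs_analysable": sum(
                        1 for o in obs if _is_ecg(o) and o.label in ("SR", "AF")
                    ),
                    "monitoring_days": 0,
                }
            )
    return pd.DataFrame(rows)
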