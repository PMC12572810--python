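"""Beat detection and RR-interval features for short single-lead ECGs.

Implements the feature chain of the rhythm classifier: an energy-based QRS
detector (band-pass, squaring, windowed integration, adaptive threshold with
a 200-ms refractory period), the 13 RR-interval features commonly used for
AF detection (moments, pNN50, RMSSD, COSEn, fuzzy measure entropy, a local
heart-rate deviation measure, and Lomb-Scargle LF/HF spectral indices), the
recurrence-plot irregularity index over 0.5-s segments, and the heart-rate x
irregularity annotation-sampling bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from afburden.synthetic import ECGRecord, RRSeries

RR_MIN_MS = 200.0
RR_MAX_MS = 3000.0
#: minimum number of intervals for the full feature vector
MIN_INTERVALS = 5

FEATURE_NAMES = (
    "rr_mean",
    "rr_median",
    "rr_sd",
    "rr_max",
    "rr_min",
    "pnn50",
    "rmssd",
    "cosen",
    "fuzzy_mentropy",
    "mad_hr3",
    "lf_norm",
    "hf_norm",
    "lf_hf_ratio",
)


class UnclassifiableRecordError(ValueError):
    """Record yields no usable RR series (too few beats / all intervals invalid)."""


class SeriesTooShortError(ValueError):
    """RR series shorter than the minimum required for a feature."""


@dataclass
class FeatureVector:
    rr_mean: float
    rr_median: float
    rr_sd: float
    rr_max: float
    rr_min: float
    pnn50: float
    rmssd: float
    cosen: float
    fuzzy_mentropy: float
    mad_hr3: float
    lf_norm: float
    hf_norm: float
    lf_hf_ratio: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_NAMES], dtype=float)


@dataclass
class IrregularityResult:
    irregularity: float
    n_segments: int
    n_recurrences: int
    similarity_threshold: float = 0.15


# --------------------------------------------------------------------------- #
# QRS detection
# --------------------------------------------------------------------------- #


def detect_qrs(ecg: ECGRecord, refractory_s: float = 0.2) -> np.ndarray:
    """Energy-based QRS detector; returns strictly increasing sample indices.

    Band-pass filter (5-25 Hz), squaring, 150-ms moving-window integration,
    adaptive thresholding against the integrated-energy distribution, and
    refinement of each detection to the local energy maximum. A flat or
    energy-free signal yields an empty result rather than an exception.
    """
    x = np.asarray(ecg.samples, dtype=float)
    fs = ecg.fs
    if len(x) < 5 * fs:
        raise ValueError("record must be at least 5 s long")
    x = x - np.mean(x)
    if np.max(np.abs(x)) < 1e-9:
        return np.array([], dtype=int)

    nyq = fs / 2.0
    b, a = signal.butter(2, [5.0 / nyq, min(25.0, 0.9 * nyq) / nyq], btype="band")
    xf = signal.filtfilt(b, a, x)
    energy = xf**2
    win = max(1, int(round(0.15 * fs)))
    integ = np.convolve(energy, np.ones(win) / win, mode="same")

    # adaptive threshold: robust against isolated artefacts
    thr = max(0.08 * np.max(integ), 2.0 * np.median(integ))
    dist = max(1, int(round(refractory_s * fs)))
    peaks, _ = signal.find_peaks(integ, height=thr, distance=dist)
    if len(peaks) == 0:
        return np.array([], dtype=int)

    # refine to the local maximum of the squared filtered signal (R wave)
    half = int(round(0.08 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        refined.append(lo + int(np.argmax(energy[lo:hi])))
    refined = np.array(sorted(set(refined)), dtype=int)
    # enforce refractory after refinement
    keep = [0]
    for i in range(1, len(refined)):
        if refined[i] - refined[keep[-1]] >= dist:
            keep.append(i)
    return refined[keep]


def rr_from_beats(beats: np.ndarray, fs: float) -> RRSeries:
    """Intervals in ms from beat sample indices; intervals outside
    [200, 3000] ms are dropped (logged as a warning)."""
    beats = np.asarray(beats)
    if len(beats) < 2:
        raise UnclassifiableRecordError("fewer than 2 beats")
    iv = np.diff(beats) / fs * 1000.0
    valid = (iv >= RR_MIN_MS) & (iv <= RR_MAX_MS)
    if not valid.all():
        warnings.warn(
            f"dropped {int((~valid).sum())} RR interval(s) outside "
            f"[{RR_MIN_MS:.0f}, {RR_MAX_MS:.0f}] ms",
            stacklevel=2,
        )
    iv = iv[valid]
    if len(iv) == 0:
        raise UnclassifiableRecordError("no valid RR intervals")
    return RRSeries(intervals_ms=iv, t0=beats[0] / fs)


# --------------------------------------------------------------------------- #
# entropies
# --------------------------------------------------------------------------- #


def _sampen_counts(u: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Unordered template-match counts (B at length m, A at length m+1),
    Chebyshev distance, self-matches excluded."""
    n = len(u)

    def count(mm: int) -> int:
        nt = n - mm + 1
        if nt < 2:
            return 0
        tpl = np.lib.stride_tricks.sliding_window_view(u, mm)
        d = np.max(np.abs(tpl[:, None, :] - tpl[None, :, :]), axis=2)
        iu = np.triu_indices(nt, k=1)
        return int(np.count_nonzero(d[iu] <= r))

    return count(m + 1), count(m)


def sample_entropy(rr: RRSeries | np.ndarray, m: int = 1, r: float = 30.0) -> float:
    """SampEn(m, r) on the RR series (ms). +inf when no matches exist."""
    u = rr.intervals_ms if isinstance(rr, RRSeries) else np.asarray(rr, dtype=float)
    if r <= 0:
        raise ValueError("r must be positive")
    if len(u) < m + 2:
        raise SeriesTooShortError(f"need at least {m + 2} intervals")
    a, b = _sampen_counts(u, m, r)
    if a == 0 or b == 0:
        warnings.warn("no template matches; sample entropy is infinite", stacklevel=2)
        return np.inf
    return -np.log(a / b)


def cosen(rr: RRSeries | np.ndarray, m: int = 1, r: float = 30.0) -> float:
    """Coefficient of sample entropy: SampEn(m, r) + ln(2r) - ln(mean RR).

    The match radius correction makes short-series entropy comparable across
    radii; the mean-RR correction removes the heart-rate dependence.  All
    quantities in ms; the AF-detection convention is m = 1, r = 30 ms.
    """
    u = rr.intervals_ms if isinstance(rr, RRSeries) else np.asarray(rr, dtype=float)
    se = sample_entropy(u, m, r)
    return se + np.log(2 * r) - np.log(float(np.mean(u)))


def fuzzy_measure_entropy(
    rr: RRSeries | np.ndarray,
    m: int = 2,
    r_local: float = 30.0,
    r_global: float = 30.0,
    n_fuzzy: float = 2.0,
) -> float:
    """Fuzzy measure entropy: sum of local and global fuzzy entropies.

    Local templates are mean-removed per template (shape information); global
    templates are baseline-removed (series mean subtracted). Membership is the
    exponential kernel exp(-(d/r)^n_fuzzy) on Chebyshev distances. Radii are
    absolute (ms); the 30-ms default mirrors the COSEn match radius so that
    the absolute beat-to-beat variability of AF is retained (a radius relative
    to SD(RR) would make the measure scale-invariant and nearly rhythm-blind).
    A constant series returns 0.
    """
    u = rr.intervals_ms if isinstance(rr, RRSeries) else np.asarray(rr, dtype=float)
    if len(u) < m + 2:
        raise SeriesTooShortError(f"need at least {m + 2} intervals")
    if r_local <= 0 or r_global <= 0:
        raise ValueError("fuzzy radii must be positive")
    if float(np.std(u)) == 0.0:
        return 0.0  # all distances are zero: fully regular

    def phi(mm: int, removal: str, r: float) -> float:
        tpl = np.lib.stride_tricks.sliding_window_view(u, mm).astype(float)
        if removal == "local":
            tpl = tpl - tpl.mean(axis=1, keepdims=True)
        else:
            tpl = tpl - float(np.mean(u))
        d = np.max(np.abs(tpl[:, None, :] - tpl[None, :, :]), axis=2)
        iu = np.triu_indices(len(tpl), k=1)
        return float(np.mean(np.exp(-((d[iu] / r) ** n_fuzzy))))

    local = np.log(phi(m, "local", r_local)) - np.log(phi(m + 1, "local", r_local))
    glob = np.log(phi(m, "global", r_global)) - np.log(phi(m + 1, "global", r_global))
    return local + glob


# --------------------------------------------------------------------------- #
# the 13-feature vector
# --------------------------------------------------------------------------- #


def _mad_hr3(iv: np.ndarray, similar_tol: float = 0.10) -> float:
    """Median absolute deviation of 3-beat local heart rate from the record
    mean heart rate, over runs of three adjacent similar-length intervals
    (max pairwise difference < 10% of the run mean). 0 when no run qualifies."""
    hr_record = 60000.0 / np.mean(iv)
    devs = []
    for i in range(len(iv) - 2):
        run = iv[i : i + 3]
        if (run.max() - run.min()) < similar_tol * run.mean():
            devs.append(abs(60000.0 / run.mean() - hr_record))
    return float(np.median(devs)) if devs else 0.0


def _spectral_powers(iv: np.ndarray) -> tuple[float, float, float]:
    """Normalised LF (0.04-0.15 Hz) and HF (0.15-0.40 Hz) power of the RR
    tachogram via Lomb-Scargle on beat times, and their ratio."""
    t = np.cumsum(iv) / 1000.0
    y = iv - np.mean(iv)
    if np.allclose(y, 0.0):
        return 0.0, 0.0, 0.0
    freqs = np.linspace(0.04, 0.40, 73)
    pgram = signal.lombscargle(t, y, 2 * np.pi * freqs, normalize=False)
    lf_band = freqs <= 0.15
    lf = float(np.trapezoid(pgram[lf_band], freqs[lf_band]))
    hf = float(np.trapezoid(pgram[~lf_band], freqs[~lf_band]))
    tot = lf + hf
    if tot <= 0:
        return 0.0, 0.0, 0.0
    ratio = lf / hf if hf > 0 else np.inf
    return lf / tot, hf / tot, ratio


def compute_features(rr: RRSeries) -> FeatureVector:
    """The 13 RR-interval features used for rhythm classification."""
    iv = np.asarray(rr.intervals_ms, dtype=float)
    if len(iv) < MIN_INTERVALS:
        raise SeriesTooShortError(
            f"need at least {MIN_INTERVALS} intervals, got {len(iv)}"
        )
    diffs = np.diff(iv)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # infinite-entropy sentinels are handled below
        cos = cosen(iv)
        fme = fuzzy_measure_entropy(iv)
    # cap the no-match sentinel to keep the vector finite for classifiers
    if not np.isfinite(cos):
        cos = 10.0
    lf_norm, hf_norm, lf_hf = _spectral_powers(iv)
    if not np.isfinite(lf_hf):
        lf_hf = 1e6
    return FeatureVector(
        rr_mean=float(np.mean(iv)),
        rr_median=float(np.median(iv)),
        rr_sd=float(np.std(iv, ddof=0)),
        rr_max=float(np.max(iv)),
        rr_min=float(np.min(iv)),
        pnn50=float(100.0 * np.mean(np.abs(diffs) > 50.0)) if len(diffs) else 0.0,
        rmssd=float(np.sqrt(np.mean(diffs**2))) if len(diffs) else 0.0,
        cosen=float(cos),
        fuzzy_mentropy=float(fme),
        mad_hr3=_mad_hr3(iv),
        lf_norm=lf_norm,
        hf_norm=hf_norm,
        lf_hf_ratio=float(lf_hf),
    )


def heart_rate_bpm(rr: RRSeries) -> float:
    return 60000.0 / float(np.mean(rr.intervals_ms))


# --------------------------------------------------------------------------- #
# recurrence-plot irregularity
# --------------------------------------------------------------------------- #


def irregularity_index(
    ecg: ECGRecord,
    threshold: float = 0.15,
    segment_s: float = 0.5,
    mode: str = "distance",
) -> IrregularityResult:
    """One minus the relative number of recurrences among 0.5-s segments.

    The trace is cut into non-overlapping 0.5-s segments (mean-removed); for
    every unordered segment pair the cosine similarity is computed. With
    ``mode="distance"`` a pair is a recurrence when the cosine distance
    (1 - similarity) is <= ``threshold``, i.e. highly similar segments recur;
    ``mode="similarity"`` applies the threshold to the similarity itself.
    """
    if mode not in ("distance", "similarity"):
        raise ValueError("mode must be 'distance' or 'similarity'")
    x = np.asarray(ecg.samples, dtype=float)
    seg_len = int(round(segment_s * ecg.fs))
    n_seg = len(x) // seg_len
    if n_seg < 2:
        raise ValueError("need at least 2 segments (record >= 1 s)")
    segs = x[: n_seg * seg_len].reshape(n_seg, seg_len)
    segs = segs - segs.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(segs, axis=1)
    zero = norms < 1e-12
    safe = np.where(zero, 1.0, norms)
    unit = segs / safe[:, None]
    sim = unit @ unit.T
    # two all-flat segments are identical; flat vs non-flat are dissimilar
    if zero.any():
        sim[zero, :] = 0.0
        sim[:, zero] = 0.0
        zz = np.outer(zero, zero)
        sim[zz] = 1.0
    iu = np.triu_indices(n_seg, k=1)
    if mode == "distance":
        rec = np.count_nonzero((1.0 - sim[iu]) <= threshold)
    else:
        rec = np.count_nonzero(sim[iu] <= threshold)
    n_pairs = len(iu[0])
    return IrregularityResult(
        irregularity=1.0 - rec / n_pairs,
        n_segments=n_seg,
        n_recurrences=int(rec),
        similarity_threshold=threshold,
    )


# --------------------------------------------------------------------------- #
# annotation-sampling bins
# --------------------------------------------------------------------------- #


@dataclass
class AnnotationBins:
    hr_edges: np.ndarray
    irr_edges: np.ndarray
    counts: np.ndarray
    eligible: np.ndarray

    @property
    def n_eligible(self) -> int:
        return int(self.eligible.sum())


@dataclass
class AnnotationSample:
    bins: AnnotationBins
    train_ids: list
    test_ids: list


def build_annotation_bins(
    df: pd.DataFrame,
    n_bins: int = 10,
    min_count: int = 500,
    per_patient: int = 2,
    seed: int = 0,
) -> AnnotationSample:
    """Discretise the joint (heart rate, irregularity) distribution into an
    ``n_bins`` x ``n_bins`` equally spaced grid and sample annotation sets.

    Bins with at least ``min_count`` records are eligible. Per patient, up to
    ``per_patient`` records are drawn from randomly chosen eligible bins
    (uniform over the patient's occupied eligible bins); patients with no
    record in any eligible bin contribute records sampled uniformly at
    random. A disjoint test set takes one further random record per patient.

    ``df`` needs columns record_id, patient_id, heart_rate, irregularity.
    """
    if len(df) == 0:
        raise ValueError("empty input")
    rng = np.random.default_rng(seed)
    hr = df["heart_rate"].to_numpy(dtype=float)
    irr = df["irregularity"].to_numpy(dtype=float)

    def edges(v: np.ndarray) -> np.ndarray:
        lo, hi = float(np.min(v)), float(np.max(v))
        if hi <= lo:
            hi = lo + 1e-9
        return np.linspace(lo, hi, n_bins + 1)

    hr_edges, irr_edges = edges(hr), edges(irr)
    counts, _, _ = np.histogram2d(hr, irr, bins=[hr_edges, irr_edges])
    counts = counts.astype(int)
    eligible = counts >= min_count

    ix = np.clip(np.searchsorted(hr_edges, hr, side="right") - 1, 0, n_bins - 1)
    iy = np.clip(np.searchsorted(irr_edges, irr, side="right") - 1, 0, n_bins - 1)
    df = df.reset_index(drop=True)
    bin_flat = ix * n_bins + iy
    elig_flat = eligible.flatten()

    train_ids: list = []
    for _, grp in df.groupby("patient_id", sort=True):
        idx = grp.index.to_numpy()
        in_elig = elig_flat[bin_flat[idx]]
        chosen: list = []
        if in_elig.any():
            occupied = np.unique(bin_flat[idx][in_elig])
            n_take = min(per_patient, int(in_elig.sum()))
            pick_bins = rng.choice(
                occupied, size=n_take, replace=len(occupied) < n_take
            )
            used: set = set()
            for b in pick_bins:
                pool = [j for j in idx[bin_flat[idx] == b] if j not in used]
                if pool:
                    j = int(rng.choice(pool))
                    chosen.append(j)
                    used.add(j)
        else:
            n_take = min(per_patient, len(idx))
            chosen = [int(j) for j in rng.choice(idx, size=n_take, replace=False)]
        train_ids.extend(df.loc[chosen, "record_id"].tolist())

    train_set = set(train_ids)
    test_ids: list = []
    for _, grp in df.groupby("patient_id", sort=True):
        pool = [r for r in grp["record_id"] if r not in train_set]
        if pool:
            test_ids.append(rng.choice(pool))

    return AnnotationSample(
        bins=AnnotationBins(hr_edges, irr_edges, counts, eligible),
        train_ids=train_ids,
        test_ids=[str(t) for t in test_ids],
    )


def feature_table(
    ecgs: list[ECGRecord], record_ids: list[str] | None = None
) -> pd.DataFrame:
    """Feature rows (13 features + heart rate + irregularity) for a batch of
    records; unclassifiable records get NaN features and ok=False."""
    rows = []
    for i, ecg in enumerate(ecgs):
        rid = record_ids[i] if record_ids else f"R{i:06d}"
        row: dict = {"record_id": rid, "patient_id": ecg.patient_id}
        try:
            beats = detect_qrs(ecg)
            rr = rr_from_beats(beats, ecg.fs)
            fv = compute_features(rr)
            row.update(dict(zip(FEATURE_NAMES, fv.as_array())))
            row["heart_rate"] = heart_rate_bpm(rr)
            row["ok"] = True
        except (UnclassifiableRecordError, SeriesTooShortError):
            row.update({f: np.nan for f in FEATURE_NAMES})
            row["heart_rate"] = np.nan
            row["ok"] = False
        row["irregularity"] = irregularity_index(ecg).irregularity
        row["true_label"] = ecg.true_label
        rows.append(row)
    return pd.DataFrame(rows)
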