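"""Feature extraction against independent brute-force oracles and closed-form
cases."""

import numpy as np
import pandas as pd
import pytest

from afburden import features as feat
from afburden import synthetic as syn
from conftest import make_record


# --------------------------------------------------------------------------- #
# brute-force oracles (independent implementations)
# --------------------------------------------------------------------------- #


def sampen_bruteforce(u, m, r):
    """Exhaustive template-pair enumeration."""
    n = len(u)

    def matches(mm):
        c = 0
        for i in range(n - mm + 1):
            for j in range(i + 1, n - mm + 1):
                if max(abs(u[i + k] - u[j + k]) for k in range(mm)) <= r:
                    c += 1
        return c

    a, b = matches(m + 1), matches(m)
    if a == 0 or b == 0:
        return np.inf
    return -np.log(a / b)


def cosen_bruteforce(u, m=1, r=30.0):
    return sampen_bruteforce(u, m, r) + np.log(2 * r) - np.log(np.mean(u))


def fuzzy_mentropy_bruteforce(u, m=2, r_local=30.0, r_global=30.0, n_fuzzy=2.0):
    """Direct double-loop local + global fuzzy entropy."""
    u = np.asarray(u, dtype=float)
    gmean = u.mean()

    def phi(mm, removal, r):
        tpls = []
        for i in range(len(u) - mm + 1):
            t = u[i : i + mm].astype(float)
            tpls.append(t - t.mean() if removal == "local" else t - gmean)
        vals = []
        for i in range(len(tpls)):
            for j in range(i + 1, len(tpls)):
                d = max(abs(a - b) for a, b in zip(tpls[i], tpls[j]))
                vals.append(np.exp(-((d / r) ** n_fuzzy)))
        return float(np.mean(vals))

    return (
        np.log(phi(m, "local", r_local)) - np.log(phi(m + 1, "local", r_local))
        + np.log(phi(m, "global", r_global)) - np.log(phi(m + 1, "global", r_global))
    )


def recurrences_bruteforce(x, fs, threshold=0.15):
    seg_len = int(round(0.5 * fs))
    n_seg = len(x) // seg_len
    segs = [x[i * seg_len : (i + 1) * seg_len] for i in range(n_seg)]
    segs = [s - np.mean(s) for s in segs]
    count = 0
    for i in range(n_seg):
        for j in range(i + 1, n_seg):
            ni, nj = np.linalg.norm(segs[i]), np.linalg.norm(segs[j])
            if ni < 1e-12 and nj < 1e-12:
                sim = 1.0
            elif ni < 1e-12 or nj < 1e-12:
                sim = 0.0
            else:
                sim = float(np.dot(segs[i], segs[j]) / (ni * nj))
            if 1.0 - sim <= threshold:
                count += 1
    return count


# --------------------------------------------------------------------------- #
# QRS detection
# --------------------------------------------------------------------------- #


class TestDetectQRS:
    @pytest.mark.parametrize("hr", [45, 60, 90, 120, 150])
    def test_sensitivity_and_ppv_on_clean_records(self, hr):
        tp = n_true = n_det = 0
        for seed in range(10):
            rr = syn.generate_rr_series("SR", 30.0, hr, seed=seed)
            ecg = syn.synthesize_ecg(rr, "SR", 0.0, fs=200.0, seed=seed)
            truth = rr.beat_times_s() + 0.3
            truth = truth[truth < 29.95]
            det = feat.detect_qrs(ecg) / ecg.fs
            for t in truth:
                if len(det) and np.min(np.abs(det - t)) <= 0.020:
                    tp += 1
            n_true += len(truth)
            n_det += len(det)
        assert tp / n_true >= 0.98
        assert tp / n_det >= 0.98

    def test_zero_signal_returns_empty(self):
        ecg = syn.ECGRecord(samples=np.zeros(6000), fs=200.0)
        assert len(feat.detect_qrs(ecg)) == 0

    def test_short_record_raises(self):
        with pytest.raises(ValueError):
            feat.detect_qrs(syn.ECGRecord(samples=np.zeros(400), fs=200.0))

    def test_premature_beat_produces_one_short_interval(self):
        mean_rr = 1000.0
        iv = np.full(28, mean_rr)
        iv[13] = 0.55 * mean_rr
        iv[14] = 1.45 * mean_rr
        rr = syn.RRSeries(iv)
        ecg = syn.synthesize_ecg(rr, "SR", 0.0, fs=200.0, seed=0)
        det = feat.rr_from_beats(feat.detect_qrs(ecg), 200.0)
        mode = np.median(det.intervals_ms)
        assert np.count_nonzero(det.intervals_ms < 0.8 * mode) == 1


class TestRRFromBeats:
    def test_interval_arithmetic(self):
        rr = feat.rr_from_beats(np.array([0, 200, 400]), 200.0)
        np.testing.assert_allclose(rr.intervals_ms, [1000.0, 1000.0])
        rr = feat.rr_from_beats(np.array([0, 200, 440, 640]), 200.0)
        np.testing.assert_allclose(rr.intervals_ms, [1000.0, 1200.0, 1000.0])

    def test_out_of_range_interval_dropped_then_error(self):
        with pytest.raises(feat.UnclassifiableRecordError), pytest.warns(UserWarning):
            feat.rr_from_beats(np.array([0, 30]), 200.0)  # 150 ms -> dropped

    def test_single_beat_raises(self):
        with pytest.raises(feat.UnclassifiableRecordError):
            feat.rr_from_beats(np.array([100]), 200.0)


# --------------------------------------------------------------------------- #
# the 13 features
# --------------------------------------------------------------------------- #


class TestComputeFeatures:
    def test_constant_series(self):
        fv = feat.compute_features(syn.RRSeries(np.full(20, 1000.0)))
        assert fv.rr_sd == 0 and fv.rmssd == 0 and fv.pnn50 == 0
        assert fv.rr_mean == fv.rr_median == 1000.0
        assert fv.fuzzy_mentropy == 0.0

    def test_alternating_series(self):
        iv = np.tile([800.0, 900.0], 10)
        fv = feat.compute_features(syn.RRSeries(iv))
        assert fv.rmssd == pytest.approx(100.0)
        assert fv.pnn50 == pytest.approx(100.0)
        assert fv.rr_min <= fv.rr_median <= fv.rr_max

    def test_vector_has_13_finite_entries(self, sr_af_rr_series):
        for rr in sr_af_rr_series["SR"][:20] + sr_af_rr_series["AF"][:20]:
            arr = feat.compute_features(rr).as_array()
            assert arr.shape == (13,)
            assert np.isfinite(arr).all()
            fv = feat.compute_features(rr)
            assert fv.lf_norm + fv.hf_norm <= 1.0 + 1e-9

    def test_too_short_series_raises_distinct_error(self):
        with pytest.raises(feat.SeriesTooShortError):
            feat.compute_features(syn.RRSeries(np.array([800.0, 810, 790, 805])))

    def test_moment_features_match_numpy_oracle(self, rng):
        for _ in range(100):
            iv = rng.uniform(400, 1500, size=rng.integers(6, 40))
            fv = feat.compute_features(syn.RRSeries(iv))
            assert fv.rr_mean == pytest.approx(iv.mean(), abs=1e-9)
            assert fv.rr_median == pytest.approx(np.median(iv), abs=1e-9)
            assert fv.rr_sd == pytest.approx(iv.std(), abs=1e-9)
            assert fv.rr_max == iv.max() and fv.rr_min == iv.min()


class TestCOSEn:
    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(100):
            iv = rng.uniform(500, 1300, size=int(rng.integers(8, 30)))
            got = feat.cosen(iv)
            if np.isfinite(got):
                assert got == pytest.approx(cosen_bruteforce(iv), abs=1e-9)
            else:
                assert cosen_bruteforce(iv) == np.inf

    def test_random_exceeds_regular(self, rng):
        rand = rng.uniform(500, 1300, size=30)
        regular = 1000.0 + 0.5 * rng.standard_normal(30)
        assert feat.cosen(rand) > feat.cosen(regular)

    def test_too_short_raises(self):
        with pytest.raises(feat.SeriesTooShortError):
            feat.sample_entropy(np.array([800.0, 900.0]), m=1)

    def test_nonpositive_radius_raises(self):
        with pytest.raises(ValueError):
            feat.cosen(np.full(10, 1000.0), r=0.0)


class TestFuzzyMeasureEntropy:
    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(100):
            iv = rng.uniform(500, 1300, size=25)
            assert feat.fuzzy_measure_entropy(iv) == pytest.approx(
                fuzzy_mentropy_bruteforce(iv), abs=1e-9
            )

    def test_af_exceeds_sr_in_seeded_draws(self):
        wins = 0
        for seed in range(200):
            sr = syn.generate_rr_series("SR", 30.0, 75.0, seed=seed).intervals_ms[:20]
            af = syn.generate_rr_series("AF", 30.0, 75.0, seed=seed).intervals_ms[:20]
            if feat.fuzzy_measure_entropy(af) > feat.fuzzy_measure_entropy(sr):
                wins += 1
        assert wins >= 190

    def test_nonpositive_radius_raises(self):
        with pytest.raises(ValueError):
            feat.fuzzy_measure_entropy(np.arange(10.0) + 800, r_local=-1.0)


class TestIrregularity:
    def test_periodic_signal_is_fully_recurrent(self):
        t = np.arange(6000) / 200.0
        ecg = syn.ECGRecord(samples=np.sin(2 * np.pi * 2.0 * t), fs=200.0)
        assert feat.irregularity_index(ecg).irregularity == 0.0

    def test_orthogonal_segments_never_recur(self):
        # alternating sine frequencies phase-locked to 0.5-s segments
        fs, seg = 200, 100
        x = np.zeros(1000)
        for i in range(10):
            f = 2.0 * (i + 1)  # integer cycles per segment -> orthogonal
            tt = np.arange(seg) / fs
            x[i * seg : (i + 1) * seg] = np.sin(2 * np.pi * f * tt)
        ecg = syn.ECGRecord(samples=x, fs=float(fs))
        assert feat.irregularity_index(ecg).irregularity == 1.0

    def test_matches_bruteforce_recurrence_count(self, rng):
        for _ in range(100):
            x = rng.standard_normal(rng.integers(400, 2000)).cumsum()
            ecg = syn.ECGRecord(samples=x, fs=200.0)
            res = feat.irregularity_index(ecg)
            assert res.n_recurrences == recurrences_bruteforce(x, 200.0)
            n_pairs = res.n_segments * (res.n_segments - 1) // 2
            assert res.irregularity == pytest.approx(
                1.0 - res.n_recurrences / n_pairs, abs=1e-12
            )

    def test_amplitude_scale_invariance(self):
        ecg = make_record("AF", seed=2)
        a = feat.irregularity_index(ecg)
        scaled = syn.ECGRecord(samples=3.7 * ecg.samples, fs=ecg.fs)
        b = feat.irregularity_index(scaled)
        assert a.n_recurrences == b.n_recurrences

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            feat.irregularity_index(syn.ECGRecord(samples=np.zeros(80), fs=200.0))


class TestFeatureSeparability:
    def test_entropy_and_rmssd_separate_af_from_sr(self, sr_af_rr_series):
        from sklearn.metrics import roc_auc_score

        names = ("rmssd", "cosen", "fuzzy_mentropy")
        vals = {n: [] for n in names}
        y = []
        for rhythm in ("SR", "AF"):
            for rr in sr_af_rr_series[rhythm]:
                fv = feat.compute_features(rr)
                for n in names:
                    vals[n].append(getattr(fv, n))
                y.append(rhythm == "AF")
        for n in names:
            assert roc_auc_score(y, vals[n]) >= 0.9, n


# --------------------------------------------------------------------------- #
# annotation bins
# --------------------------------------------------------------------------- #


def _bin_frame(n, rng, n_patients=200):
    return pd.DataFrame(
        {
            "record_id": [f"R{i}" for i in range(n)],
            "patient_id": [f"P{i % n_patients}" for i in range(n)],
            "heart_rate": rng.uniform(40, 160, n),
            "irregularity": rng.uniform(0, 1, n),
        }
    )


class TestAnnotationBins:
    def test_uniform_grid_all_bins_eligible(self):
        rng = np.random.default_rng(0)
        sample = feat.build_annotation_bins(_bin_frame(60_000, rng), seed=1)
        assert sample.bins.n_eligible == 100
        assert sample.bins.counts.sum() == 60_000

    def test_identical_records_single_bin(self):
        df = pd.DataFrame(
            {
                "record_id": [f"R{i}" for i in range(30)],
                "patient_id": [f"P{i % 5}" for i in range(30)],
                "heart_rate": 70.0,
                "irregularity": 0.4,
            }
        )
        sample = feat.build_annotation_bins(df, min_count=10, seed=2)
        assert (sample.bins.counts > 0).sum() == 1
        counts = pd.Series(sample.train_ids).map(
            df.set_index("record_id")["patient_id"]
        ).value_counts()
        assert counts.max() <= 2

    def test_patient_without_eligible_bins_falls_back_to_random(self):
        rng = np.random.default_rng(3)
        df = _bin_frame(5000, rng, n_patients=50)
        # one extra patient far outside every populated bin region
        outlier = pd.DataFrame(
            {
                "record_id": ["X1", "X2", "X3"],
                "patient_id": "OUT",
                "heart_rate": [500.0, 510.0, 505.0],
                "irregularity": [0.5, 0.5, 0.5],
            }
        )
        sample = feat.build_annotation_bins(
            pd.concat([df, outlier], ignore_index=True), min_count=40, seed=4
        )
        got = [r for r in sample.train_ids if r.startswith("X")]
        assert len(got) == 2  # sampled uniformly from the patient's own records

    def test_train_test_disjoint(self):
        rng = np.random.default_rng(5)
        sample = feat.build_annotation_bins(_bin_frame(3000, rng), min_count=20,
                                            seed=6)
        assert not set(sample.train_ids) & set(sample.test_ids)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            feat.build_annotation_bins(pd.DataFrame(columns=["record_id"]))
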