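"""Two-stage rhythm classification for 30-s single-lead ECGs.

Stage 1 is a small 1-D CNN that flags unreadable (noise) records: three
blocks of [conv 64 filters x width 16, ReLU, batch norm, max pool stride 2],
two dense layers (64, 32) and a 2-way softmax, trained with Adam on
band-passed (0.5-40 Hz), per-record standardised traces. Stage 2 classifies
the remaining records as SR / AF / other from the 13 RR-interval features
with a support vector machine whose kernel is chosen by rhythm-stratified
5-fold cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from afburden import features as feat
from afburden import nnet
from afburden.synthetic import ECGRecord

RHYTHM_CLASSES = ("SR", "AF", "OTHER")
ALL_LABELS = ("SR", "AF", "OTHER", "NOISE")


def preprocess_for_cnn(ecgs: list[ECGRecord]) -> np.ndarray:
    """Band-pass 0.5-40 Hz and standardise each record to zero mean / unit
    variance; returns (n, 1, L) float32."""
    out = []
    for ecg in ecgs:
        nyq = ecg.fs / 2.0
        b, a = signal.butter(2, [0.5 / nyq, min(40.0, 0.95 * nyq) / nyq], btype="band")
        x = signal.filtfilt(b, a, np.asarray(ecg.samples, dtype=float))
        sd = x.std()
        x = (x - x.mean()) / (sd if sd > 1e-9 else 1.0)
        out.append(x.astype(np.float32))
    return np.stack(out)[:, None, :]


def _build_cnn(input_len: int, rng: np.random.Generator) -> nnet.SoftmaxClassifierNet:
    layers = []
    c_in, L = 1, input_len
    for _ in range(3):
        layers += [
            nnet.Conv1D(c_in, 64, 16, rng),
            nnet.ReLU(),
            nnet.BatchNorm1D(64),
            nnet.MaxPool1D(),
        ]
        L = (L - 16 + 1) // 2
        c_in = 64
    layers += [
        nnet.Flatten(),
        nnet.Dense(64 * L, 64, rng),
        nnet.ReLU(),
        nnet.Dense(64, 32, rng),
        nnet.ReLU(),
        nnet.Dense(32, 2, rng),
    ]
    return nnet.SoftmaxClassifierNet(layers)


@dataclass
class NoiseDetector:
    net: nnet.SoftmaxClassifierNet
    input_len: int
    threshold: float = 0.5
    loss_trace: list = field(default_factory=list)

    def noise_proba(self, ecgs: list[ECGRecord]) -> np.ndarray:
        x = preprocess_for_cnn(ecgs)
        if x.shape[2] != self.input_len:
            raise ValueError(
                f"record length {x.shape[2]} != trained input length {self.input_len}"
            )
        return self.net.predict_proba(x)[:, 1]

    def is_noise(self, ecgs: list[ECGRecord]) -> np.ndarray:
        return self.noise_proba(ecgs) >= self.threshold


def train_noise_detector(
    ecgs: list[ECGRecord],
    is_noise: np.ndarray,
    epochs: int = 30,
    lr: float = 1e-3,
    batch_size: int = 32,
    seed: int = 0,
    threshold: float = 0.5,
) -> NoiseDetector:
    """Train the stage-1 noise CNN (binary cross-entropy, Adam).

    Deterministic given ``seed``. Raises on single-class input; warns when
    the training set is small.
    """
    y = np.asarray(is_noise).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both clean and noise records")
    if len(ecgs) < 32:
        warnings.warn(
            f"small training set ({len(ecgs)} records); noise detector may be unreliable",
            stacklevel=2,
        )
    x = preprocess_for_cnn(ecgs)
    rng = np.random.default_rng(seed)
    net = _build_cnn(x.shape[2], rng)
    losses = net.fit(x, y, epochs=epochs, lr=lr, batch_size=batch_size, rng=rng)
    return NoiseDetector(net=net, input_len=x.shape[2], threshold=threshold,
                         loss_trace=losses)


@dataclass
class RhythmModel:
    kernel: str
    pipeline: object
    classes: tuple
    cv_table: pd.DataFrame

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.pipeline.predict(X)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return self.pipeline.decision_function(X)


def select_kernel_and_train(
    X: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    kernels: tuple = ("linear", "poly", "rbf"),
) -> RhythmModel:
    """Choose the SVM kernel by rhythm-stratified 5-fold CV, refit on all data.

    Class imbalance is handled with inverse-frequency class weights. Requires
    all three rhythm classes with at least 5 samples each.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 3:
        raise ValueError("need at least 3 rhythm classes represented")
    for cls, cnt in zip(classes, counts):
        if cnt < 5:
            raise ValueError(f"class {cls!r} has only {cnt} samples (< 5)")

    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    rows = []
    for kernel in kernels:
        pipe = make_pipeline(
            StandardScaler(),
            SVC(kernel=kernel, class_weight="balanced", random_state=seed),
        )
        scores = cross_val_score(pipe, X, labels, cv=cv, scoring="accuracy")
        rows.append({"kernel": kernel, "cv_accuracy": scores.mean(),
                     "cv_sd": scores.std()})
    table = pd.DataFrame(rows)
    best = table.loc[table["cv_accuracy"].idxmax(), "kernel"]
    final = make_pipeline(
        StandardScaler(),
        SVC(kernel=best, class_weight="balanced", random_state=seed),
    )
    final.fit(X, labels)
    return RhythmModel(kernel=str(best), pipeline=final,
                       classes=tuple(classes), cv_table=table)


def _features_or_none(ecg: ECGRecord) -> np.ndarray | None:
    try:
        beats = feat.detect_qrs(ecg)
        rr = feat.rr_from_beats(beats, ecg.fs)
        return feat.compute_features(rr).as_array()
    except (feat.UnclassifiableRecordError, feat.SeriesTooShortError):
        return None


def classify_record(
    ecg: ECGRecord, noise_model: NoiseDetector, rhythm_model: RhythmModel
) -> str:
    """Two-stage label for one record: NOISE, or the stage-2 rhythm class."""
    return classify_records([ecg], noise_model, rhythm_model)[0]


def classify_records(
    ecgs: list[ECGRecord], noise_model: NoiseDetector, rhythm_model: RhythmModel
) -> list[str]:
    """Vectorised two-stage classification.

    Stage 1 excludes noise records; records whose QRS/RR extraction fails the
    feature preconditions are also labelled NOISE. Every record receives
    exactly one label.
    """
    labels = ["NOISE"] * len(ecgs)
    noise = noise_model.is_noise(ecgs)
    feats, keep = [], []
    for i, ecg in enumerate(ecgs):
        if noise[i]:
            continue
        fv = _features_or_none(ecg)
        if fv is None:
            continue
        feats.append(fv)
        keep.append(i)
    if keep:
        preds = rhythm_model.predict(np.asarray(feats))
        for i, p in zip(keep, preds):
            labels[i] = str(p)
    return labels


# ---------------------------------------------------------------------------#
# model persistence
# ---------------------------------------------------------------------------#

MODEL_FORMAT_VERSION = 1


def save_models(
    noise_model: NoiseDetector, rhythm_model: RhythmModel, model_dir
) -> None:
    """Serialize both stages with a version header (JSON + npz + pickle)."""
    import json
    import pickle
    from pathlib import Path

    out = Path(model_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, layer in enumerate(noise_model.net.layers):
        for name, obj in layer.params():
            arrays[f"layer{i}_{name}"] = getattr(obj, name)
        if isinstance(layer, nnet.BatchNorm1D):
            arrays[f"layer{i}_run_mean"] = layer.run_mean
            arrays[f"layer{i}_run_var"] = layer.run_var
    np.savez(out / "noise_cnn.npz", **arrays)
    with open(out / "rhythm_svm.pkl", "wb") as fh:
        pickle.dump(
            {"pipeline": rhythm_model.pipeline, "classes": rhythm_model.classes,
             "cv_table": rhythm_model.cv_table}, fh,
        )
    header = {
        "format_version": MODEL_FORMAT_VERSION,
        "input_len": noise_model.input_len,
        "noise_threshold": noise_model.threshold,
        "svm_kernel": rhythm_model.kernel,
    }
    (out / "header.json").write_text(json.dumps(header, indent=2))


def load_models(model_dir) -> tuple[NoiseDetector, RhythmModel]:
    import json
    import pickle
    from pathlib import Path

    src = Path(model_dir)
    header = json.loads((src / "header.json").read_text())
    if header["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format {header['format_version']}"
        )
    net = _build_cnn(header["input_len"], np.random.default_rng(0))
    arrays = np.load(src / "noise_cnn.npz")
    for i, layer in enumerate(net.layers):
        for name, obj in layer.params():
            setattr(obj, name, arrays[f"layer{i}_{name}"])
        if isinstance(layer, nnet.BatchNorm1D):
            layer.run_mean = arrays[f"layer{i}_run_mean"]
            layer.run_var = arrays[f"layer{i}_run_var"]
    noise_model = NoiseDetector(
        net=net, input_len=header["input_len"],
        threshold=header["noise_threshold"],
    )
    with open(src / "rhythm_svm.pkl", "rb") as fh:
        payload = pickle.load(fh)
    rhythm_model = RhythmModel(
        kernel=header["svm_kernel"], pipeline=payload["pipeline"],
        classes=tuple(payload["classes"]), cv_table=payload["cv_table"],
    )
    return noise_model, rhythm_model


@dataclass
class ClassifierMetrics:
    accuracy: float
    auc: dict
    f1: dict
    confusion: pd.DataFrame


def evaluate(
    truth: np.ndarray,
    predictions: np.ndarray,
    scores: dict | None = None,
) -> ClassifierMetrics:
    """Accuracy, per-class F1, and (when per-class scores are given)
    one-vs-rest AUC, from aligned label sequences."""
    truth = np.asarray(truth)
    predictions = np.asarray(predictions)
    if len(truth) != len(predictions):
        raise ValueError("length mismatch")
    observed = set(truth) | set(predictions)
    if not observed & set(ALL_LABELS):
        raise ValueError(f"labels {sorted(observed)} share nothing with {ALL_LABELS}")
    if not observed <= set(ALL_LABELS):
        raise ValueError(f"unexpected labels: {sorted(observed - set(ALL_LABELS))}")
    present = [c for c in ALL_LABELS if c in observed]
    cm = confusion_matrix(truth, predictions, labels=present)
    f1 = {
        c: float(v)
        for c, v in zip(
            present, f1_score(truth, predictions, labels=present, average=None,
                              zero_division=0)
        )
    }
    auc = {}
    if scores is not None:
        for cls, sc in scores.items():
            y_bin = (truth == cls).astype(int)
            if y_bin.min() == y_bin.max():
                continue
            auc[cls] = float(roc_auc_score(y_bin, np.asarray(sc)))
    return ClassifierMetrics(
        accuracy=float(accuracy_score(truth, predictions)),
        auc=auc,
        f1=f1,
        confusion=pd.DataFrame(cm, index=present, columns=present),
    )
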