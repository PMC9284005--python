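"""Evaluation protocols and classical baselines.

Two protocols are implemented on windowed data:

* **within-subject** — per subject, trials are split 70/30 (stratified per
  class, at the trial level so windows never leak across the boundary); a
  4-fold stratified CV structure over the 70% provides the validation folds
  used for model selection / stopping; accuracy is reported on the held-out
  30%.
* **cross-subject** — subjects are partitioned 7 train / 3 test, repeated
  (default 5 times) with seeded sampling; the neural model's stopping set is
  carved from the *training* subjects' trials by default, so the reported
  test subjects are never seen during training. A ``paper_protocol`` switch
  instead uses the held-out subjects for stopping as well.

Baselines (LDA, RBF-SVM, KNN, RF) consume the standardized hand-crafted
features; the fused network additionally sees the raw windows. Accuracy is
per window; an optional trial-majority vote is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.metrics import confusion_matrix

from hcsnet.fusion_model import TrainConfig, predict, train
from hcsnet.handcrafted import FeatureConfig, extract_handcrafted_batch
from hcsnet.mcsnet import McsnetConfig
from hcsnet.preprocess import PreprocessConfig, preprocess_trial
from hcsnet.signal_io import CLASSES

BASELINE_KINDS = ("LDA", "RBFSVM", "KNN", "RF")


@dataclass
class ProtocolSpec:
    mode: str = "within_subject"  # or "cross_subject"
    train_ratio: float = 0.7
    cv_folds: int = 4
    n_train_subjects: int = 7
    n_test_subjects: int = 3
    n_repeats: int = 5
    seed: int = 0
    paper_protocol: bool = False  # cross-subject: stop on the held-out subjects
    vote: str = "window"  # or "trial" for majority voting

    def __post_init__(self) -> None:
        if not (0 < self.train_ratio < 1):
            raise ValueError("train_ratio must be in (0, 1)")
        if self.mode not in ("within_subject", "cross_subject"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")


@dataclass
class EvaluationReport:
    model: str
    protocol: dict
    per_unit: list[dict]  # unit id, accuracy, confusion matrix (rows = true class)
    mean_accuracy: float
    seed: int

    def to_json(self) -> str:
        payload = {
            "model": self.model,
            "protocol": self.protocol,
            "per_unit": self.per_unit,
            "mean_accuracy": round(self.mean_accuracy, 10),
            "seed": self.seed,
        }
        return json.dumps(payload, sort_keys=True, indent=1)


@dataclass
class WindowTable:
    """Columnar view of a preprocessed, windowed, feature-extracted dataset."""

    windows: np.ndarray  # (N, C, W)
    f_td: np.ndarray
    f_fd: np.ndarray
    labels: np.ndarray  # int codes into CLASSES
    subjects: np.ndarray  # str
    trials: np.ndarray  # int
    n_td_per_ch: int = 12
    n_fd_per_ch: int = 3

    @property
    def handcrafted(self) -> np.ndarray:
        return np.concatenate([self.f_td, self.f_fd], axis=1)

    def subset(self, mask: np.ndarray) -> "WindowTable":
        return WindowTable(
            self.windows[mask], self.f_td[mask], self.f_fd[mask],
            self.labels[mask], self.subjects[mask], self.trials[mask],
            self.n_td_per_ch, self.n_fd_per_ch,
        )


def build_window_table(
    recordings,
    pre_cfg: PreprocessConfig | None = None,
    feat_cfg: FeatureConfig | None = None,
) -> WindowTable:
    """Preprocess, window, and feature-extract a list of recordings."""
    pre_cfg = pre_cfg or PreprocessConfig()
    feat_cfg = feat_cfg or FeatureConfig(fs_hz=recordings[0].fs_hz)
    wins, labels, subjects, trials = [], [], [], []
    for rec in recordings:
        for ws in preprocess_trial(rec, pre_cfg):
            wins.append(ws.window)
            labels.append(CLASSES.index(ws.label))
            subjects.append(ws.subject_id)
            trials.append(ws.source_trial)
    windows = np.stack(wins)
    td, fd = extract_handcrafted_batch(windows, feat_cfg)
    c = windows.shape[1]
    return WindowTable(
        windows=windows,
        f_td=td,
        f_fd=fd,
        labels=np.asarray(labels),
        subjects=np.asarray(subjects),
        trials=np.asarray(trials),
        n_td_per_ch=td.shape[1] // c,
        n_fd_per_ch=fd.shape[1] // c,
    )


def fit_baseline(kind: str, features: np.ndarray, labels: np.ndarray, seed: int = 0):
    """Standardizer + classical classifier pipeline, fitted."""
    if kind not in BASELINE_KINDS:
        raise ValueError(f"unknown baseline {kind!r}; valid kinds: {BASELINE_KINDS}")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes to fit a classifier")
    if kind == "LDA":
        clf = LinearDiscriminantAnalysis()
    elif kind == "RBFSVM":
        clf = SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    elif kind == "KNN":
        clf = KNeighborsClassifier(n_neighbors=5)
    else:
        clf = RandomForestClassifier(n_estimators=100, random_state=seed)
    pipe = make_pipeline(StandardScaler(), clf)
    pipe.fit(features, labels)
    return pipe


# ---------------------------------------------------------------- splitting

def _trial_class_of(table: WindowTable, subject: str) -> tuple[np.ndarray, np.ndarray]:
    mask = table.subjects == subject
    trials = np.unique(table.trials[mask])
    classes = np.array(
        [table.labels[mask & (table.trials == t)][0] for t in trials]
    )
    return trials, classes


def split_within_subject(table: WindowTable, spec: ProtocolSpec) -> dict[str, dict]:
    """Per-subject stratified 70/30 trial split plus 4-fold CV over the 70%."""
    rng = np.random.default_rng(spec.seed)
    out: dict[str, dict] = {}
    for subject in sorted(np.unique(table.subjects)):
        trials, classes = _trial_class_of(table, subject)
        train_trials, test_trials = [], []
        for k in np.unique(classes):
            k_trials = rng.permutation(trials[classes == k])
            if len(k_trials) < spec.cv_folds:
                raise ValueError(
                    f"subject {subject} has {len(k_trials)} trials of class "
                    f"{CLASSES[k]}; need >= cv_folds ({spec.cv_folds})"
                )
            n_train = int(round(spec.train_ratio * len(k_trials)))
            train_trials.extend(k_trials[:n_train])
            test_trials.extend(k_trials[n_train:])
        train_trials = np.sort(np.array(train_trials))
        test_trials = np.sort(np.array(test_trials))
        # label-stratified folds over the training trials (round-robin per class)
        folds: list[list[int]] = [[] for _ in range(spec.cv_folds)]
        tr_classes = np.array(
            [classes[np.searchsorted(trials, t)] for t in train_trials]
        )
        for k in np.unique(tr_classes):
            k_trials = rng.permutation(train_trials[tr_classes == k])
            for i, t in enumerate(k_trials):
                folds[i % spec.cv_folds].append(int(t))
        out[subject] = {
            "train_trials": train_trials,
            "test_trials": test_trials,
            "folds": [np.sort(np.array(f)) for f in folds],
        }
    return out


def split_cross_subject(table: WindowTable, spec: ProtocolSpec) -> list[dict]:
    """Seeded repeated 7/3 subject partitions with no overlap within a repeat."""
    subjects = sorted(np.unique(table.subjects))
    need = spec.n_train_subjects + spec.n_test_subjects
    if len(subjects) < need:
        raise ValueError(f"need >= {need} subjects, dataset has {len(subjects)}")
    rng = np.random.default_rng(spec.seed)
    repeats = []
    for _ in range(spec.n_repeats):
        perm = rng.permutation(subjects)
        repeats.append(
            {
                "train_subjects": sorted(perm[: spec.n_train_subjects]),
                "test_subjects": sorted(perm[spec.n_train_subjects : need]),
            }
        )
    return repeats


def _carve_stopping_trials(
    subjects: np.ndarray, trials: np.ndarray, labels: np.ndarray, frac: float, seed: int
) -> np.ndarray:
    """Boolean mask of windows reserved for validation stopping (trial-grouped)."""
    rng = np.random.default_rng(seed)
    key = np.char.add(np.char.add(subjects.astype(str), "/"), trials.astype(str))
    stop_keys = set()
    for subject in np.unique(subjects):
        m = subjects == subject
        for k in np.unique(labels[m]):
            uniq = np.unique(key[m & (labels == k)])
            n_stop = max(1, int(round(frac * len(uniq))))
            stop_keys.update(rng.choice(uniq, size=n_stop, replace=False))
    return np.isin(key, list(stop_keys))


# ---------------------------------------------------------------- protocol run

def _evaluate_unit(
    model_kind: str,
    train_tab: WindowTable,
    stop_tab: WindowTable,
    test_tab: WindowTable,
    spec: ProtocolSpec,
    mcsnet_cfg: McsnetConfig | None,
    train_cfg: TrainConfig | None,
) -> tuple[float, list[list[int]]]:
    if model_kind.upper() in BASELINE_KINDS:
        # classical models have no stopping set; train on train + stop windows
        x = np.concatenate([train_tab.handcrafted, stop_tab.handcrafted])
        y = np.concatenate([train_tab.labels, stop_tab.labels])
        pipe = fit_baseline(model_kind.upper(), x, y, seed=spec.seed)
        pred = pipe.predict(test_tab.handcrafted)
    elif model_kind.lower() in ("hcsnet", "mcsnet", "handcrafted_attention"):
        tc = train_cfg or TrainConfig(max_epochs=100, seed=spec.seed)
        if model_kind.lower() == "mcsnet":
            tc = TrainConfig(**{**asdict(tc), "feature_sources": ("learned",)})
        elif model_kind.lower() == "handcrafted_attention":
            tc = TrainConfig(**{**asdict(tc), "feature_sources": ("handcrafted",)})
        model, _ = train(
            (train_tab.windows, train_tab.handcrafted, train_tab.labels),
            (stop_tab.windows, stop_tab.handcrafted, stop_tab.labels),
            model_cfg=mcsnet_cfg,
            train_cfg=tc,
            handcrafted_dims=(train_tab.n_td_per_ch, train_tab.n_fd_per_ch),
        )
        preds = predict(model, test_tab.windows, test_tab.handcrafted)
        pred = np.array([CLASSES.index(p.label) for p in preds])
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")

    truth = test_tab.labels
    if spec.vote == "trial":
        keys = np.char.add(np.char.add(test_tab.subjects.astype(str), "/"),
                           test_tab.trials.astype(str))
        agg_pred, agg_truth = [], []
        for k in np.unique(keys):
            m = keys == k
            votes = np.bincount(pred[m], minlength=len(CLASSES))
            agg_pred.append(int(np.argmax(votes)))
            agg_truth.append(int(truth[m][0]))
        pred, truth = np.array(agg_pred), np.array(agg_truth)
    acc = float(np.mean(pred == truth))
    cm = confusion_matrix(truth, pred, labels=list(range(len(CLASSES))))
    return acc, cm.tolist()


def run_protocol(
    table: WindowTable,
    models: list[str],
    spec: ProtocolSpec,
    mcsnet_cfg: McsnetConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> dict[str, EvaluationReport]:
    """Run every model over identical splits; one report per model."""
    reports: dict[str, EvaluationReport] = {}
    if spec.mode == "within_subject":
        splits = split_within_subject(table, spec)
        for model_kind in models:
            per_unit = []
            for subject, split in splits.items():
                subj = table.subset(table.subjects == subject)
                in_train = np.isin(subj.trials, split["train_trials"])
                in_test = np.isin(subj.trials, split["test_trials"])
                # stopping set: first CV fold of the training trials
                stop_trials = split["folds"][0]
                stop_mask = in_train & np.isin(subj.trials, stop_trials)
                fit_mask = in_train & ~stop_mask
                try:
                    acc, cm = _evaluate_unit(
                        model_kind,
                        subj.subset(fit_mask),
                        subj.subset(stop_mask),
                        subj.subset(in_test),
                        spec, mcsnet_cfg, train_cfg,
                    )
                except Exception as exc:
                    raise RuntimeError(
                        f"model {model_kind!r} failed on subject {subject}: {exc}"
                    ) from exc
                per_unit.append({"unit": subject, "accuracy": round(acc, 10), "confusion": cm})
            mean_acc = float(np.mean([u["accuracy"] for u in per_unit]))
            reports[model_kind] = EvaluationReport(
                model=model_kind, protocol=_proto_dict(spec), per_unit=per_unit,
                mean_accuracy=mean_acc, seed=spec.seed,
            )
    else:
        repeats = split_cross_subject(table, spec)
        for model_kind in models:
            per_unit = []
            for i, rep in enumerate(repeats):
                tr_mask = np.isin(table.subjects, rep["train_subjects"])
                te_mask = np.isin(table.subjects, rep["test_subjects"])
                tr = table.subset(tr_mask)
                if spec.paper_protocol:
                    fit_tab, stop_tab = tr, table.subset(te_mask)
                else:
                    stop = _carve_stopping_trials(
                        tr.subjects, tr.trials, tr.labels, 0.2, spec.seed + 100 + i
                    )
                    fit_tab, stop_tab = tr.subset(~stop), tr.subset(stop)
                try:
                    acc, cm = _evaluate_unit(
                        model_kind, fit_tab, stop_tab, table.subset(te_mask),
                        spec, mcsnet_cfg, train_cfg,
                    )
                except Exception as exc:
                    raise RuntimeError(
                        f"model {model_kind!r} failed on repeat {i}: {exc}"
                    ) from exc
                per_unit.append(
                    {"unit": f"repeat{i}", "accuracy": round(acc, 10), "confusion": cm,
                     "test_subjects": rep["test_subjects"]}
                )
            mean_acc = float(np.mean([u["accuracy"] for u in per_unit]))
            reports[model_kind] = EvaluationReport(
                model=model_kind, protocol=_proto_dict(spec), per_unit=per_unit,
                mean_accuracy=mean_acc, seed=spec.seed,
            )
    return reports


def _proto_dict(spec: ProtocolSpec) -> dict:
    return asdict(spec)


def window_sweep(
    recordings,
    window_lengths: list[int],
    step_fractions: list[float],
    pre_cfg: PreprocessConfig | None = None,
    spec: ProtocolSpec | None = None,
) -> list[dict]:
    """RBF-SVM within-subject accuracy over a (window length, step %) grid."""
    pre_cfg = pre_cfg or PreprocessConfig()
    spec = spec or ProtocolSpec()
    rows = []
    for length in window_lengths:
        for frac in step_fractions:
            if length < 1 or not (0 < frac <= 1):
                raise ValueError(f"invalid sweep cell (length={length}, step={frac})")
            step = max(1, int(round(length * frac)))
            cfg = pre_cfg.with_window(length, step)
            table = build_window_table(recordings, cfg)
            splits = split_within_subject(table, spec)
            accs = []
            for subject, split in splits.items():
                subj = table.subset(table.subjects == subject)
                in_train = np.isin(subj.trials, split["train_trials"])
                in_test = np.isin(subj.trials, split["test_trials"])
                pipe = fit_baseline(
                    "RBFSVM", subj.handcrafted[in_train], subj.labels[in_train], spec.seed
                )
                accs.append(float(np.mean(
                    pipe.predict(subj.handcrafted[in_test]) == subj.labels[in_test]
                )))
            rows.append(
                {"window_len": length, "step_fraction": frac, "step": step,
                 "mean_accuracy": float(np.mean(accs)),
                 "n_windows": int(len(table.labels))}
            )
    return rows


def sweep_to_csv(rows: list[dict], path) -> None:
    lines = ["window_len,step_fraction,step,mean_accuracy"]
    for r in rows:
        lines.append(f"{r['window_len']},{r['step_fraction']},{r['step']},{r['mean_accuracy']:.6f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
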