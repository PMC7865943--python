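"""Metrics, baseline classifiers and experiment protocols.

Metrics follow the binary definitions accuracy = (TP+TN)/total,
recall = TP/(TP+FN), precision = TP/(TP+FP) and the F-measure as their
harmonic mean, applied one-vs-rest per class and aggregated as unweighted
(macro) means; overall accuracy is the plain fraction correct.  A class
with no predicted positives gets precision (and F) 0.

Baselines cover the OS protocol (classifier trained on the pooled source
group, applied to a target subject) and the SS protocol (trained on the
target subject's own labeled data, scored out-of-fold under stratified
10-fold cross-validation).  The experiment harnesses reproduce the
3-source / 4-target grouping with 10 kept segments per class per target
subject, and the source-group-size sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureConfig, featurize_set
from .jpda import JPDAConfig, ipl_jpda_fit_predict
from .signal_model import ACTIVITIES, labels_to_codes, segment


@dataclass
class EvalReport:
    """Confusion matrix plus macro metrics, all percentages in 0..100."""

    counts: np.ndarray  # C x C, rows = true class
    row_percent: np.ndarray
    accuracy: float
    precision: float
    recall: float
    f_measure: float
    per_class: pd.DataFrame


def evaluate(y_true, y_pred, n_classes: int | None = None, class_names=None) -> EvalReport:
    """Score 1-based class-code predictions against the truth."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal lengths")
    C = int(n_classes or max(y_true.max(), y_pred.max()))
    counts = confusion_matrix(y_true, y_pred, labels=np.arange(1, C + 1))
    rowsum = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        row_percent = np.where(rowsum > 0, counts / np.where(rowsum > 0, rowsum, 1) * 100.0, 0.0)
    total = counts.sum()
    tp = np.diag(counts).astype(float)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    tn = total - tp - fp - fn

    def _safe(num, den):
        return np.where(den > 0, num / np.where(den > 0, den, 1), 0.0)

    prec = _safe(tp, tp + fp)
    if np.any((tp + fp) == 0):
        warnings.warn("class with zero predicted positives: precision set to 0", stacklevel=2)
    rec = _safe(tp, tp + fn)
    f = _safe(2 * prec * rec, prec + rec)
    names = list(class_names) if class_names is not None else list(ACTIVITIES[:C])
    if len(names) < C:
        names = [str(i) for i in range(1, C + 1)]
    per_class = pd.DataFrame(
        {"TP": tp, "FP": fp, "FN": fn, "TN": tn,
         "precision": prec * 100, "recall": rec * 100, "f_measure": f * 100},
        index=pd.Index(names, name="class"),
    )
    return EvalReport(
        counts=counts,
        row_percent=row_percent,
        accuracy=float(np.trace(counts) / total * 100.0),
        precision=float(prec.mean() * 100.0),
        recall=float(rec.mean() * 100.0),
        f_measure=float(f.mean() * 100.0),
        per_class=per_class,
    )


def labels_from_confusion(counts: np.ndarray):
    """Expand an integer confusion matrix back into (y_true, y_pred) pairs.

    Lets a printed confusion matrix be re-scored through :func:`evaluate`.
    """
    counts = np.asarray(counts)
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be integers; scale row-percentages first")
    y_true, y_pred = [], []
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            y_true += [i + 1] * int(round(counts[i, j]))
            y_pred += [j + 1] * int(round(counts[i, j]))
    return np.array(y_true), np.array(y_pred)


_BASELINES = {
    "knn": lambda seed, knn_k=1: make_pipeline(
        StandardScaler(), KNeighborsClassifier(n_neighbors=knn_k)
    ),
    "svm": lambda seed, knn_k=1: make_pipeline(StandardScaler(), SVC(random_state=seed)),
    "dt": lambda seed, knn_k=1: make_pipeline(
        StandardScaler(), DecisionTreeClassifier(random_state=seed)
    ),
}
_ALIASES = {"nearest-neighbour": "knn", "max-margin": "svm", "decision-tree": "dt"}


def baseline_fit_predict(
    kind: str,
    Xtrain: np.ndarray,
    ytrain,
    Xtest: np.ndarray | None = None,
    protocol: str = "OS",
    cv_folds: int = 10,
    seed: int = 0,
    knn_k: int = 1,
) -> np.ndarray:
    """Baseline classifier under the OS or SS protocol.

    OS: fit on (Xtrain, ytrain) — the pooled source group — and predict
    ``Xtest``; target labels are never touched except for scoring.
    SS: ``Xtrain`` is the target subject's own labeled data; returns
    out-of-fold predictions under stratified ``cv_folds``-fold CV (fold
    count is reduced, with a warning, when a class has fewer members).
    Feature matrices are d x n; standardization is fit inside each
    training split.
    """
    kind = _ALIASES.get(kind, kind)
    if kind not in _BASELINES:
        raise ValueError(f"unknown baseline kind {kind!r}")
    ytrain = np.asarray(ytrain, dtype=int)
    Xtr = np.asarray(Xtrain, dtype=float).T  # sklearn wants samples x features
    if protocol == "OS":
        if Xtest is None:
            raise ValueError("OS protocol needs Xtest")
        clf = _BASELINES[kind](seed, knn_k)
        clf.fit(Xtr, ytrain)
        return clf.predict(np.asarray(Xtest, dtype=float).T).astype(int)
    if protocol != "SS":
        raise ValueError("protocol must be 'OS' or 'SS'")
    _, counts = np.unique(ytrain, return_counts=True)
    folds = min(cv_folds, counts.min())
    if folds < cv_folds:
        warnings.warn(f"fold count reduced to {folds} (smallest class)", stacklevel=2)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty(len(ytrain), dtype=int)
    for tr, te in skf.split(Xtr, ytrain):
        clf = _BASELINES[kind](seed, knn_k)
        clf.fit(Xtr[tr], ytrain[tr])
        pred[te] = clf.predict(Xtr[te])
    return pred


DEFAULT_MODELS = ("KNN-OS", "KNN-SS", "SVM-OS", "SVM-SS", "DT-OS", "DT-SS", "IPL-JPDA")


def _featurize_subject(rec, feature_config):
    segs = segment(rec)
    fm = featurize_set(segs, feature_config)
    return fm.X, labels_to_codes(fm.y)


def select_per_class(X, y, per_class: int, rng, subject_id="?"):
    """Keep ``per_class`` random segments of each class (error if short)."""
    keep = []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if len(idx) < per_class:
            raise ValueError(
                f"subject {subject_id!r} has only {len(idx)} segments for class "
                f"{ACTIVITIES[int(c) - 1]}; {per_class} required"
            )
        keep.append(rng.choice(idx, size=per_class, replace=False))
    keep = np.sort(np.concatenate(keep))
    return X[:, keep], y[keep]


def run_group_experiment(
    recordings,
    n_source: int = 3,
    seed: int = 0,
    models=DEFAULT_MODELS,
    jpda_config: JPDAConfig | None = None,
    feature_config: FeatureConfig | None = None,
    segments_per_class_target: int = 10,
):
    """Random source/target grouping with per-target scoring.

    Splits the subjects into ``n_source`` source and the rest target; each
    target subject keeps ``segments_per_class_target`` random segments per
    class (70 by default over 7 classes).  Every requested model is scored
    per target subject; the summary averages each metric (F-measure per
    subject first) across targets.  Returns ``(summary, per_subject)``:
    a model x metric DataFrame in percent and the per-subject EvalReports.
    """
    if len(recordings) < n_source + 1:
        raise ValueError("need at least n_source + 1 subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(recordings))
    src_recs = [recordings[i] for i in order[:n_source]]
    tgt_recs = [recordings[i] for i in order[n_source:]]

    feats = {r.subject_id: _featurize_subject(r, feature_config) for r in recordings}
    Xs = np.hstack([feats[r.subject_id][0] for r in src_recs])
    ys = np.concatenate([feats[r.subject_id][1] for r in src_recs])

    per_subject: dict[str, dict[str, EvalReport]] = {}
    for rec in tgt_recs:
        Xt_full, yt_full = feats[rec.subject_id]
        Xt, yt = select_per_class(
            Xt_full, yt_full, segments_per_class_target, rng, rec.subject_id
        )
        reports = {}
        for model in models:
            if model == "IPL-JPDA":
                res = ipl_jpda_fit_predict(Xs, ys, Xt, jpda_config)
                pred = res.labels
            else:
                kind, proto = model.split("-")
                if proto == "OS":
                    pred = baseline_fit_predict(kind.lower(), Xs, ys, Xt, "OS", seed=seed)
                else:
                    pred = baseline_fit_predict(kind.lower(), Xt, yt, None, "SS", seed=seed)
            reports[model] = evaluate(yt, pred, n_classes=len(ACTIVITIES))
        per_subject[rec.subject_id] = reports

    rows = {}
    for model in models:
        reps = [per_subject[s][model] for s in per_subject]
        rows[model] = {
            "accuracy": np.mean([r.accuracy for r in reps]),
            "f_measure": np.mean([r.f_measure for r in reps]),
            "precision": np.mean([r.precision for r in reps]),
            "recall": np.mean([r.recall for r in reps]),
        }
    summary = pd.DataFrame(rows).T[["accuracy", "f_measure", "precision", "recall"]]
    summary.index.name = "model"
    return summary, per_subject


def run_source_size_sweep(
    recordings,
    sizes=(1, 2, 3, 4, 5),
    combos_per_size: int = 5,
    seed: int = 0,
    n_targets: int = 2,
    jpda_config: JPDAConfig | None = None,
    feature_config: FeatureConfig | None = None,
    segments_per_class_target: int = 10,
):
    """Accuracy of the adaptive model as the source group grows.

    Holds out ``n_targets`` test subjects, then for each source-group size
    draws ``combos_per_size`` random source subsets from the remaining
    subjects, adapts to each target, and reports the mean and standard
    deviation of target accuracy per size (a DataFrame indexed by size).
    """
    if len(recordings) < max(sizes) + n_targets:
        raise ValueError("not enough subjects for the largest source size")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(recordings))
    tgt_recs = [recordings[i] for i in order[:n_targets]]
    pool = [recordings[i] for i in order[n_targets:]]
    feats = {r.subject_id: _featurize_subject(r, feature_config) for r in recordings}
    targets = []
    for rec in tgt_recs:
        Xt, yt = select_per_class(
            *feats[rec.subject_id], segments_per_class_target, rng, rec.subject_id
        )
        targets.append((Xt, yt))

    out = {}
    for size in sizes:
        accs = []
        for _ in range(combos_per_size):
            chosen = rng.choice(len(pool), size=size, replace=False)
            Xs = np.hstack([feats[pool[i].subject_id][0] for i in chosen])
            ys = np.concatenate([feats[pool[i].subject_id][1] for i in chosen])
            run = []
            for Xt, yt in targets:
                res = ipl_jpda_fit_predict(Xs, ys, Xt, jpda_config)
                run.append(float(np.mean(res.labels == yt) * 100.0))
            accs.append(np.mean(run))
        out[size] = {"mean": float(np.mean(accs)), "std": float(np.std(accs))}
    df = pd.DataFrame(out).T
    df.index.name = "n_source"
    return df
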