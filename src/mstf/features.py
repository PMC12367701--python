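"""Multi-band microstate feature tables and cross-validated classification.

The "time-frequency" feature vector of one observation (typically one
epoch) concatenates, over frequency bands, each microstate's duration,
coverage and occurrence followed by the off-diagonal run-transition
probabilities (the diagonal is structurally zero).  Classification uses six
off-the-shelf scikit-learn models with fixed, documented hyperparameters —
the contribution is the feature set, not the classifiers — under k-fold
cross-validation with fold-internal standardization (scaler statistics come
from the training fold only, so no leakage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import FeatureTable
from .segmentation import PropertySet

__all__ = [
    "ClassifierConfig",
    "CvReport",
    "MODELS",
    "make_model",
    "build_features",
    "crossvalidate",
    "evaluate_metrics",
]

#: Fixed hyperparameters for the six reference models.
MODELS = {
    "svm": dict(kernel="rbf", C=1, gamma=1),
    "random_forest": dict(n_estimators=100, max_depth=None),
    "gradient_boosting": dict(n_estimators=100, max_depth=3),
    "knn": dict(n_neighbors=5),
    # l2 penalty is sklearn's default; passing it explicitly is deprecated
    "logistic_regression": dict(C=1, max_iter=2000),
    "lda": dict(solver="svd", tol=1e-4),
}


@dataclass(frozen=True)
class ClassifierConfig:
    model: str = "svm"
    seed: int = 42
    overrides: tuple = ()       # ((param, value), ...) hyperparameter overrides

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {sorted(MODELS)}")


def make_model(config: ClassifierConfig):
    params = dict(MODELS[config.model])
    params.update(dict(config.overrides))
    if config.model == "svm":
        return SVC(random_state=config.seed, **params)
    if config.model == "random_forest":
        return RandomForestClassifier(random_state=config.seed, **params)
    if config.model == "gradient_boosting":
        return GradientBoostingClassifier(random_state=config.seed, **params)
    if config.model == "knn":
        return KNeighborsClassifier(**params)
    if config.model == "logistic_regression":
        return LogisticRegression(random_state=config.seed, **params)
    return LinearDiscriminantAnalysis(**params)


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

def feature_columns(bands, k: int) -> list:
    """Deterministic column layout: band x state x {duration, coverage,
    occurrence}, then band x off-diagonal transition entries."""
    cols = [f"{band}_ms{s + 1}_{prop}"
            for band in bands for s in range(k)
            for prop in ("duration", "coverage", "occurrence")]
    cols += [f"{band}_p_ms{i + 1}_ms{j + 1}"
             for band in bands for i in range(k) for j in range(k) if i != j]
    return cols


def build_features(observations, class_labels, group_ids=None, bands=None,
                   pad_to_kmax: bool = False) -> FeatureTable:
    """Assemble per-observation multi-band properties into a FeatureTable.

    Parameters
    ----------
    observations : sequence of {band: PropertySet}
        One mapping per observation (epoch or subject x condition).
    class_labels : sequence
    group_ids : sequence, optional
        Subject/grouping ids for grouped CV; defaults to row index.
    bands : sequence of str, optional
        Band order; defaults to the keys of the first observation.
    pad_to_kmax : bool
        Allow observations with differing state counts by zero-padding to
        the maximum K (padded states are flagged absent).
    """
    if not observations:
        raise ValueError("no observations")
    if len(class_labels) != len(observations):
        raise ValueError("class_labels must match observations")
    if bands is None:
        bands = list(observations[0].keys())
    ks = {ps.k for obs in observations for ps in obs.values()}
    if len(ks) > 1 and not pad_to_kmax:
        raise ValueError(f"inconsistent state counts {sorted(ks)}; "
                         "pass pad_to_kmax=True to zero-pad")
    k = max(ks)
    cols = feature_columns(bands, k)
    rows = []
    absent_flags = {}
    for idx, obs in enumerate(observations):
        row, trans_part = [], []
        for band in bands:
            if band not in obs:
                raise ValueError(f"observation {idx} lacks band {band!r}")
            ps: PropertySet = obs[band]
            for s in range(k):
                vals = ((ps.duration_ms[s], ps.coverage[s], ps.occurrence[s])
                        if s < ps.k else (0.0, 0.0, 0.0))
                row.extend(vals)
                if s >= ps.k or ps.absent[s]:
                    absent_flags.setdefault(f"absent__{band}_ms{s + 1}", set()).add(idx)
            for i in range(k):
                for j in range(k):
                    if i != j:
                        trans_part.append(ps.transition[i, j] if max(i, j) < ps.k else 0.0)
        rows.append(row + trans_part)
    frame = pd.DataFrame(rows, columns=cols)
    for col, idxs in sorted(absent_flags.items()):
        frame[col] = [int(i in idxs) for i in range(len(observations))]
    frame["class_label"] = list(class_labels)
    frame["group_id"] = (list(group_ids) if group_ids is not None
                         else list(range(len(observations))))
    return FeatureTable(frame)


# ---------------------------------------------------------------------------
# Metrics and cross-validation
# ---------------------------------------------------------------------------

def evaluate_metrics(y_true, y_pred, scores=None, classes=None) -> dict:
    """Accuracy, macro precision/recall/F1, confusion matrix and one-vs-rest
    ROC points (when continuous scores are supplied)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if classes is None:
        classes = np.unique(y_true)
    prec, rec, f1, _ = skm.precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average="macro", zero_division=0)
    out = {
        "accuracy": float(skm.accuracy_score(y_true, y_pred)),
        "precision": float(prec),
        "recall": float(rec),
        "f1": float(f1),
        "confusion": skm.confusion_matrix(y_true, y_pred, labels=classes).tolist(),
        "classes": [str(c) for c in classes],
    }
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        if len(classes) < 2 or np.unique(y_true).size < 2:
            out["roc"] = None
            out["roc_note"] = "ROC undefined: fewer than two classes observed"
        else:
            roc = {}
            for ci, c in enumerate(classes):
                col = scores if scores.ndim == 1 else scores[:, ci]
                fpr, tpr, _ = skm.roc_curve((y_true == c).astype(int), col)
                roc[str(c)] = {"fpr": fpr.tolist(), "tpr": tpr.tolist(),
                               "auc": float(skm.auc(fpr, tpr))}
            out["roc"] = roc
    return out


@dataclass
class CvReport:
    """Per-fold and mean cross-validation metrics."""

    model: str
    n_folds: int
    folds: list
    mean: dict
    classes: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {"model": self.model, "n_folds": self.n_folds,
                   "folds": self.folds, "mean": self.mean, "classes": self.classes}
        txt = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(txt)
        return txt


def _fold_scores(pipe, X):
    clf = pipe[-1]
    if hasattr(clf, "decision_function"):
        return pipe.decision_function(X)
    return pipe.predict_proba(X)


def crossvalidate(features: FeatureTable, config: ClassifierConfig,
                  n_folds: int = 5, grouping: str = "stratified") -> CvReport:
    """K-fold cross-validation of one classifier on a feature table.

    ``grouping='stratified'`` uses class-stratified folds over rows (epochs);
    ``'by_group'`` keeps all rows of one group (subject) in the same fold,
    which is the conservative choice when rows within a subject are
    correlated.  Standardization is fit on each training fold only.
    """
    X, y, groups = features.X, features.y, features.groups
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError("every class needs at least n_folds observations; "
                         "reduce n_folds or add data")
    if grouping == "stratified":
        splits = StratifiedKFold(n_folds, shuffle=True,
                                 random_state=config.seed).split(X, y)
    elif grouping == "by_group":
        splits = GroupKFold(n_folds).split(X, y, groups)
    else:
        raise ValueError("grouping must be 'stratified' or 'by_group'")

    folds = []
    for tr, te in splits:
        if np.unique(y[tr]).size < classes.size:
            raise ValueError("a class is absent from a training fold; "
                             "reduce n_folds or use stratified grouping")
        pipe = Pipeline([("scale", StandardScaler()), ("clf", make_model(config))])
        pipe.fit(X[tr], y[tr])
        fold = evaluate_metrics(y[te], pipe.predict(X[te]),
                                scores=_fold_scores(pipe, X[te]), classes=classes)
        folds.append(fold)
    mean = {m: float(np.mean([f[m] for f in folds]))
            for m in ("accuracy", "precision", "recall", "f1")}
    return CvReport(config.model, n_folds, folds, mean, [str(c) for c in classes])
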