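"""Classifier training and evaluation.

Four classifier families (SVM with a degree-5 polynomial kernel, a single
hidden-layer ANN, random forest, XGBoost) and the evaluation metrics
SE/SP/AC/F1 with stratified k-fold cross-validation and a Student-t
confidence interval over fold accuracies.

Two F1 variants are exposed and must not be confused:

``f1_paper``
    the harmonic mean of accuracy and sensitivity, exactly as defined by the
    source method: F1 = 2·AC·SE / (AC + SE).
``f1_conventional``
    the textbook harmonic mean of precision and recall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

MODEL_KINDS = ("svm", "ann", "rf", "xgboost")


@dataclass(frozen=True)
class ModelSpec:
    """A classifier kind plus its hyperparameters.

    Defaults: SVM uses a fifth-order polynomial kernel with gamma=0.1, C=1;
    the ANN has one hidden layer of 19 units (softmax output); RF and
    XGBoost carry their usual tree hyperparameters.  SVM and ANN are wrapped
    with train-fitted standardization; tree models consume raw features.
    """

    kind: str = "rf"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; use one of {MODEL_KINDS}")


_DEFAULTS = {
    "svm": {"degree": 5, "gamma": 0.1, "C": 1.0},
    "ann": {"hidden_units": 19, "max_iter": 600, "early_stopping": True,
            "learning_rate_init": 0.01, "n_iter_no_change": 25},
    "rf": {"n_estimators": 50},
    "xgboost": {"n_estimators": 60, "max_depth": 4, "learning_rate": 0.3},
}


def make_classifier(spec: ModelSpec, seed: int = 0):
    """Instantiate the sklearn estimator for a spec, seed-fixed."""
    p = {**_DEFAULTS[spec.kind], **spec.params}
    if spec.kind == "svm":
        clf = SVC(kernel="poly", degree=p["degree"], gamma=p["gamma"], C=p["C"],
                  random_state=seed)
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    if spec.kind == "ann":
        clf = MLPClassifier(
            hidden_layer_sizes=(p["hidden_units"],),
            max_iter=p["max_iter"],
            early_stopping=p["early_stopping"],
            learning_rate_init=p["learning_rate_init"],
            n_iter_no_change=p["n_iter_no_change"],
            random_state=seed,
        )
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    if spec.kind == "rf":
        return RandomForestClassifier(n_estimators=p["n_estimators"], random_state=seed,
                                      n_jobs=1)
    if spec.kind == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=p["n_estimators"], max_depth=p["max_depth"],
            learning_rate=p["learning_rate"], random_state=seed,
            verbosity=0, n_jobs=1,
        )
    raise AssertionError(spec.kind)


def _encode(y):
    classes, y_enc = np.unique(np.asarray(y), return_inverse=True)
    return classes, y_enc


def train_and_predict(spec: ModelSpec, X_train, y_train, X_eval, seed: int = 0):
    """Fit on the training rows only and predict labels for the eval rows."""
    X_train = np.asarray(X_train, dtype=float)
    X_eval = np.asarray(X_eval, dtype=float)
    classes, y_enc = _encode(y_train)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    clf = make_classifier(spec, seed)
    clf.fit(X_train, y_enc)
    return classes[clf.predict(X_eval)]


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """K x K integer counts; entry (i, j) = truth i predicted j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside 0..{n_classes - 1}")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def metrics_from_confusion(confusion: np.ndarray, averaging: str = "macro") -> dict:
    """SE/SP/AC and both F1 variants (percent), one-vs-rest per class.

    ``averaging="per_class"`` returns arrays, ``"macro"`` the unweighted mean
    over classes with defined values; degenerate denominators give NaN (with
    a warning), never a silent 0.
    """
    cm = np.asarray(confusion)
    K = cm.shape[0]
    n = cm.sum()
    out: dict[str, np.ndarray] = {k: np.full(K, np.nan) for k in
                                  ("SE", "SP", "AC", "f1_paper", "f1_conventional")}
    for k in range(K):
        tp = cm[k, k]
        fn = cm[k, :].sum() - tp
        fp = cm[:, k].sum() - tp
        tn = n - tp - fn - fp
        se = 100.0 * tp / (tp + fn) if tp + fn > 0 else np.nan
        sp = 100.0 * tn / (tn + fp) if tn + fp > 0 else np.nan
        ac = 100.0 * (tp + tn) / n if n > 0 else np.nan
        prec = 100.0 * tp / (tp + fp) if tp + fp > 0 else np.nan
        out["SE"][k] = se
        out["SP"][k] = sp
        out["AC"][k] = ac
        out["f1_paper"][k] = (2 * ac * se / (ac + se)) if np.isfinite(ac) and np.isfinite(se) and ac + se > 0 else np.nan
        out["f1_conventional"][k] = (2 * prec * se / (prec + se)) if np.isfinite(prec) and np.isfinite(se) and prec + se > 0 else np.nan
    if averaging == "per_class":
        return out
    if averaging != "macro":
        raise ValueError(f"unknown averaging {averaging!r}")
    macro = {}
    for key, vals in out.items():
        if np.any(~np.isfinite(vals)):
            warnings.warn(f"{key}: undefined for some class, excluded from macro", stacklevel=2)
        macro[key] = float(np.nanmean(vals))
    return macro


@dataclass
class EvalReport:
    """Pooled cross-validation result for one classifier."""

    confusion: np.ndarray
    classes: np.ndarray
    per_class: dict
    macro: dict
    micro_accuracy: float  # pooled AC over all evaluated samples, percent
    fold_scores: np.ndarray
    ci95: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "per_class": {k: list(np.round(v, 2)) for k, v in self.per_class.items()},
            "macro": {k: round(v, 2) for k, v in self.macro.items()},
            "micro_accuracy": round(self.micro_accuracy, 2),
            "fold_scores": [float(s) for s in self.fold_scores],
            "ci95": [round(self.ci95[0], 2), round(self.ci95[1], 2)],
        }


def confidence_interval(fold_scores, level: float = 0.95) -> tuple[float, float]:
    """Student-t interval on the mean fold accuracy, in percent, clipped to
    [0, 100].  Requires at least two folds."""
    from scipy import stats

    s = np.asarray(fold_scores, dtype=float) * 100.0
    if s.size < 2:
        raise ValueError("need at least 2 fold scores for an interval")
    mean = s.mean()
    sem = s.std(ddof=1) / np.sqrt(s.size)
    if sem == 0:
        return (float(mean), float(mean))
    tcrit = stats.t.ppf(0.5 + level / 2, df=s.size - 1)
    half = tcrit * sem
    return (float(np.clip(mean - half, 0, 100)), float(np.clip(mean + half, 0, 100)))


def kfold_cv(X, y, spec: ModelSpec, k: int = 10, seed: int = 0) -> EvalReport:
    """Stratified k-fold CV with per-fold refitting (standardization included
    in the pipeline, so it is refit on each training fold); confusion counts
    pooled across folds."""
    X = np.asarray(X, dtype=float)
    classes, y_enc = _encode(y)
    counts = np.bincount(y_enc)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} samples; cannot stratify into {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = np.zeros((classes.size, classes.size), dtype=int)
    fold_scores = []
    for tr, ev in skf.split(X, y_enc):
        clf = make_classifier(spec, seed)
        clf.fit(X[tr], y_enc[tr])
        pred = clf.predict(X[ev])
        pooled += confusion_matrix(y_enc[ev], pred, classes.size)
        fold_scores.append(float(np.mean(pred == y_enc[ev])))
    fold_scores = np.asarray(fold_scores)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        per_class = metrics_from_confusion(pooled, "per_class")
        macro = metrics_from_confusion(pooled, "macro")
    micro = 100.0 * np.trace(pooled) / pooled.sum()
    return EvalReport(
        confusion=pooled,
        classes=classes,
        per_class=per_class,
        macro=macro,
        micro_accuracy=float(micro),
        fold_scores=fold_scores,
        ci95=confidence_interval(fold_scores),
    )
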