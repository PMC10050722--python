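"""Classifier harness, ROC construction, Youden thresholding, and
confusion-matrix metrics for AD-vs-HC discrimination.

The ROC, AUC (trapezoidal), Youden-optimal threshold and the five
confusion-derived proportions are implemented here from first principles —
they are the quantities the evaluation reports — with the classification
rule "score >= threshold implies AD".  The classifier roster is pluggable:
any sklearn-style estimator with ``predict_proba`` works; the default
seven cover logistic regression, k-nearest neighbours, an RBF support
vector machine, Gaussian naive Bayes, random forest, gradient-boosted
trees (XGBoost) and adaptive boosting.

The evaluation protocol defaults to stratified 5-fold cross-validation
with pooled out-of-fold scores.  Because strokes from one participant are
correlated, stroke-level folds leak participant identity between training
and test folds; ``protocol="cv5_grouped"`` keeps each participant's
strokes in a single fold, and ``protocol="resubstitution"`` scores the
training data itself (the apparent protocol of some published analyses).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold, cross_val_predict
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

logger = logging.getLogger(__name__)

POS_LABEL = "AD"
PROTOCOLS = ("cv5", "cv5_grouped", "resubstitution")


class SingleClassError(ValueError):
    """ROC analysis requires both classes."""


def _as_binary(labels, pos_label=POS_LABEL) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "ifb":
        out = y.astype(int)
        if not set(np.unique(out)) <= {0, 1}:
            raise ValueError("numeric labels must be 0/1")
    else:
        out = (y == pos_label).astype(int)
    if out.min() == out.max():
        raise SingleClassError("both classes must be present")
    return out


def roc_curve(scores, labels, pos_label=POS_LABEL) -> np.ndarray:
    """ROC points (1 - specificity, sensitivity) as thresholds sweep.

    Thresholds pass over +inf and every unique score; tied scores collapse
    into a single step, so the curve runs from (0, 0) to (1, 1) with one
    point per distinct score value.
    """
    y = _as_binary(labels, pos_label)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    distinct = np.nonzero(np.diff(s))[0]          # last index of each tie block
    idx = np.concatenate([distinct, [len(s) - 1]])
    tpr = np.concatenate([[0.0], tps[idx] / n_pos])
    fpr = np.concatenate([[0.0], fps[idx] / n_neg])
    return np.column_stack([fpr, tpr])


def auc(scores, labels, pos_label=POS_LABEL) -> float:
    """Trapezoidal area under the ROC curve.

    Equals the normalized Mann-Whitney statistic: the probability that a
    random AD score exceeds a random HC score, ties counted half.
    """
    pts = roc_curve(scores, labels, pos_label)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def youden_threshold(scores, labels, pos_label=POS_LABEL) -> tuple[float, float]:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    The rule is "score >= threshold -> AD"; candidates are every unique
    score plus +inf (call nothing positive).  Ties in J break toward the
    lower threshold, favouring sensitivity for a screening use-case.
    """
    y = _as_binary(labels, pos_label)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    candidates = np.concatenate([[np.inf], np.unique(s)[::-1]])  # descending
    best_thr, best_j = np.inf, -np.inf
    for thr in candidates:
        pred = s >= thr
        se = float((pred & (y == 1)).sum()) / n_pos
        sp = float((~pred & (y == 0)).sum()) / n_neg
        j = se + sp - 1.0
        if j > best_j or (j == best_j and thr < best_thr):
            best_j, best_thr = j, float(thr)
    return best_thr, best_j


def confusion_metrics(scores, labels, threshold: float, pos_label=POS_LABEL) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, PPV and NPV at a threshold.

    AD is the positive class; a ratio with zero denominator is reported as
    NaN (e.g. PPV when nothing is called positive).
    """
    y = _as_binary(labels, pos_label)
    pred = np.asarray(scores, dtype=float) >= threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    tn = int((~pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())

    def ratio(num, den):
        return num / den if den else float("nan")

    return {
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


# ---------------------------------------------------------------------------
# classifier harness


@dataclass
class DiagnosticReport:
    """Per-classifier evaluation: threshold metrics, AUC and the ROC curve."""

    classifier_name: str
    status: str = "ok"
    accuracy: float = float("nan")
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    ppv: float = float("nan")
    npv: float = float("nan")
    auc: float = float("nan")
    optimal_threshold: float = float("nan")
    youden_j: float = float("nan")
    protocol: str = "cv5"
    seed: int = 0
    error: str = ""
    roc_points: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classifier_name": self.classifier_name,
            "status": self.status,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "auc": self.auc,
            "optimal_threshold": self.optimal_threshold,
            "youden_j": self.youden_j,
            "protocol": self.protocol,
            "seed": self.seed,
            "error": self.error,
            "roc_points": self.roc_points,
        }


def default_roster(seed: int = 0) -> dict[str, object]:
    """The seven default classifiers, seeded where stochastic."""
    return {
        "LR": LogisticRegression(max_iter=2000),
        "KNN": KNeighborsClassifier(),
        # Platt-calibrated SVM: monotone calibration, so ranking (and AUC)
        # matches the raw decision function.
        "SVM": CalibratedClassifierCV(SVC(random_state=seed), ensemble=False),
        "GNB": GaussianNB(),
        "RF": RandomForestClassifier(random_state=seed),
        "XGB": XGBClassifier(
            eval_metric="logloss", random_state=seed, n_estimators=100, verbosity=0
        ),
        "Adaboost": AdaBoostClassifier(random_state=seed),
    }


def _oof_scores(est, X, y01, protocol, groups, seed, n_splits):
    pipe = Pipeline([("scale", StandardScaler()), ("clf", est)])
    if protocol == "resubstitution":
        pipe.fit(X, y01)
        return pipe.predict_proba(X)[:, 1]
    if protocol == "cv5":
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        return cross_val_predict(pipe, X, y01, cv=cv, method="predict_proba")[:, 1]
    if protocol == "cv5_grouped":
        if groups is None:
            raise ValueError("cv5_grouped requires participant groups")
        cv = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        return cross_val_predict(
            pipe, X, y01, cv=cv, groups=groups, method="predict_proba"
        )[:, 1]
    raise ValueError(f"unknown protocol {protocol!r}; choose one of {PROTOCOLS}")


def run_classifiers(
    X,
    labels,
    groups=None,
    protocol: str = "cv5",
    roster: dict[str, object] | None = None,
    seed: int = 0,
    n_splits: int = 5,
    keep_roc: bool = True,
) -> list[DiagnosticReport]:
    """Evaluate a roster of classifiers on a feature table.

    Features are standardized inside each training fold; per classifier the
    pooled out-of-fold probability scores feed the ROC/AUC/Youden/confusion
    machinery, with the operating point chosen by Youden's J.  A classifier
    that raises is reported with ``status="failed"`` and the run continues.
    """
    X = pd.DataFrame(X)
    if X.shape[1] < 1:
        raise ValueError("at least one feature column is required")
    y01 = _as_binary(labels)
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; choose one of {PROTOCOLS}")
    if protocol == "cv5_grouped" and groups is None:
        raise ValueError("cv5_grouped requires participant groups")
    if roster is None:
        roster = default_roster(seed)

    reports = []
    for name, est in roster.items():
        try:
            scores = _oof_scores(est, X.to_numpy(dtype=float), y01, protocol, groups, seed, n_splits)
            thr, j = youden_threshold(scores, y01)
            metrics = confusion_metrics(scores, y01, thr)
            pts = roc_curve(scores, y01)
            reports.append(DiagnosticReport(
                classifier_name=name,
                auc=auc(scores, y01),
                optimal_threshold=thr,
                youden_j=j,
                protocol=protocol,
                seed=seed,
                roc_points=pts.tolist() if keep_roc else [],
                **metrics,
            ))
        except Exception as exc:  # keep the pipeline alive on adapter failure
            logger.warning("classifier %s failed: %s", name, exc)
            reports.append(DiagnosticReport(
                classifier_name=name, status="failed", error=str(exc),
                protocol=protocol, seed=seed,
            ))
    return reports


def plot_roc(reports: list[DiagnosticReport], path) -> None:
    """One ROC curve per classifier with the chance diagonal, saved to file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for rep in reports:
        if rep.status != "ok" or not rep.roc_points:
            continue
        pts = np.asarray(rep.roc_points)
        ax.plot(pts[:, 0], pts[:, 1], label=f"{rep.classifier_name} (AUC {rep.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="chance")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
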