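"""Supervised confirmation that selected markers classify prognosis.

Patients are split stratified into training (two-thirds of each prognostic
group, rounding half up) and test thirds; a classifier — linear-kernel SVM,
random forest, or logistic regression ("GLM") on standardized markers — is
fit on the training set and evaluated on the held-out test set with
accuracy, sensitivity/specificity (the better-prognosis group is the
positive class), and a ROC curve whose AUC is the trapezoidal area,
identical to the Mann-Whitney pair-counting probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ClassifierEval",
    "split_train_test",
    "train_eval",
    "roc_auc",
    "rank_features",
]

MODEL_KINDS = ("svm", "rf", "glm")


@dataclass
class ClassifierEval:
    model_kind: str
    accuracy: float
    sensitivity: float     # for the better-prognosis (positive) class
    specificity: float
    roc_points: list[tuple[float, float]]
    auc: float
    confusion: tuple[int, int, int, int]  # tp, fp, tn, fn
    fitted_model: object = field(repr=False, default=None)
    feature_names: list[str] = field(default_factory=list)


def split_train_test(
    labels: pd.Series, train_fraction: float = 2.0 / 3.0, seed: int = 0
) -> tuple[list, list]:
    """Stratified train/test split of patient ids.

    Per class, round(train_fraction × class size) patients (rounding half
    up) go to training; the rest to test. Both classes must have at least
    three members, and the test set must be nonempty.
    """
    rng = np.random.default_rng(seed)
    train: list = []
    test: list = []
    for cls in np.unique(labels):
        ids = labels.index[labels == cls].to_numpy()
        if ids.size < 3:
            raise ValueError(f"class {cls!r} has fewer than 3 members")
        n_train = int(np.floor(train_fraction * ids.size + 0.5))
        perm = rng.permutation(ids.size)
        train.extend(ids[perm[:n_train]].tolist())
        test.extend(ids[perm[n_train:]].tolist())
    if not test:
        raise ValueError("train_fraction leaves an empty test set")
    return train, test


def _make_model(model_kind: str, seed: int):
    if model_kind == "svm":
        return Pipeline(
            [("scale", StandardScaler()), ("clf", SVC(kernel="linear", random_state=seed))]
        )
    if model_kind == "rf":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if model_kind == "glm":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(max_iter=5000, random_state=seed)),
            ]
        )
    raise ValueError(f"model_kind must be one of {MODEL_KINDS}, got {model_kind!r}")


def _scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    proba = model.predict_proba(X)
    pos_idx = list(model.classes_).index(1)
    return np.asarray(proba[:, pos_idx], dtype=float)


def train_eval(
    model_kind: str,
    markers_matrix: pd.DataFrame,
    labels: pd.Series,
    split: tuple[list, list],
    positive_label,
    seed: int = 0,
) -> ClassifierEval:
    """Fit on the training ids, evaluate on the test ids.

    ``positive_label`` names the better-prognosis class; sensitivity is its
    recall. Scores for the ROC come from the decision function (SVM, GLM)
    or the positive-class probability (RF).
    """
    train_ids, test_ids = split
    y = (labels == positive_label).astype(int)
    y_train = y.loc[train_ids]
    if y_train.nunique() < 2:
        raise ValueError("training set contains a single class")
    model = _make_model(model_kind, seed)
    X_train = markers_matrix.loc[train_ids].to_numpy(dtype=float)
    X_test = markers_matrix.loc[test_ids].to_numpy(dtype=float)
    model.fit(X_train, y_train.to_numpy())

    y_test = y.loc[test_ids].to_numpy()
    y_pred = np.asarray(model.predict(X_test), dtype=int)
    tp = int(np.sum((y_pred == 1) & (y_test == 1)))
    fp = int(np.sum((y_pred == 1) & (y_test == 0)))
    tn = int(np.sum((y_pred == 0) & (y_test == 0)))
    fn = int(np.sum((y_pred == 0) & (y_test == 1)))
    accuracy = (tp + tn) / len(y_test)
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    points, auc = roc_auc(_scores(model, X_test), y_test)
    return ClassifierEval(
        model_kind=model_kind,
        accuracy=float(accuracy),
        sensitivity=float(sensitivity),
        specificity=float(specificity),
        roc_points=points,
        auc=float(auc),
        confusion=(tp, fp, tn, fn),
        fitted_model=model,
        feature_names=list(markers_matrix.columns),
    )


def roc_auc(scores, labels) -> tuple[list[tuple[float, float]], float]:
    """ROC curve by threshold sweep over unique scores; AUC by trapezoid.

    Tied scores advance the curve diagonally, so the trapezoidal area
    equals the Mann-Whitney probability P(score⁺ > score⁻) + ½P(tie).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        tp += int(np.sum(y[i:j] == 1))
        fp += int(np.sum(y[i:j] == 0))
        points.append((fp / n_neg, tp / n_pos))
        i = j
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return points, auc


def rank_features(evaluation: ClassifierEval) -> list[str]:
    """Markers ordered by importance in a fitted logistic-regression model.

    Features are standardized before the fit, so the absolute coefficient
    orders them like the Wald z statistic. Only the "glm" model kind
    exposes this ranking.
    """
    if evaluation.model_kind != "glm":
        raise ValueError("feature ranking is defined for the glm model kind")
    model = evaluation.fitted_model
    if model is None:
        raise ValueError("evaluation carries no fitted model")
    coefs = np.abs(np.ravel(model.named_steps["clf"].coef_))
    order = np.argsort(-coefs, kind="mergesort")
    return [evaluation.feature_names[i] for i in order]
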