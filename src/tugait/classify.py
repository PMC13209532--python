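"""Hierarchical L1-logistic risk classification of gait state vectors.

Three condition labels are used: N (normal), M (mild cognitive burden) and
P (Parkinsonian-like / severe burden).  Instead of a flat three-class model,
classification is cascaded:

* Stage 1 (screening) separates N from abnormal {M, P} using the feature
  subset ``[T_total, V_walk, T_turn, N_total, CV]``; its regularization
  strength is selected by internal stratified cross-validation.
* Stage 2 (grading) separates M from P among screened-abnormal samples
  using ``[V_walk, N_walk, SL_mean, T_total, T_turn, T_sts, CV]`` with a
  fixed strength.

Both stages z-score their features with training-data statistics only and
fit L1-penalized logistic regression (sparse, interpretable coefficients).
Evaluation uses leave-one-out cross-validation with the scaler and the
strength selection refit inside every fold, so no information leaks from
the held-out trial.

Probability ties at 0.5 resolve toward "abnormal": a screening tool must
favor sensitivity over specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import EvaluationError, ParameterError, SchemaError

ALL_FEATURES = ("T_total", "V_walk", "T_turn", "T_sts", "N_total", "N_walk", "SL_mean", "CV")
SCREENING_FEATURES = ("T_total", "V_walk", "T_turn", "N_total", "CV")
GRADING_FEATURES = ("V_walk", "N_walk", "SL_mean", "T_total", "T_turn", "T_sts", "CV")

#: Internal-validation grid: 7 log-spaced inverse penalties over 4 decades.
DEFAULT_C_GRID = tuple(np.logspace(-2, 2, 7))

LABELS = ("N", "M", "P")


def _as_feature_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        missing = [f for f in ALL_FEATURES if f not in X.columns]
        if missing:
            raise SchemaError(f"feature table missing columns {missing}")
        return X[list(ALL_FEATURES)]
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(ALL_FEATURES):
        raise SchemaError(
            f"array input must have {len(ALL_FEATURES)} columns in the order "
            f"{ALL_FEATURES}, got shape {X.shape}"
        )
    return pd.DataFrame(X, columns=list(ALL_FEATURES))


def _make_pipeline(C: float, random_state: int) -> Pipeline:
    return Pipeline(
        [
            ("scaler", StandardScaler()),
            (
                "logreg",
                LogisticRegression(
                    l1_ratio=1.0,  # pure lasso penalty
                    C=float(C),
                    solver="liblinear",
                    random_state=random_state,
                    max_iter=2000,
                ),
            ),
        ]
    )


def _cv_accuracy(
    pipe: Pipeline, X: np.ndarray, y: np.ndarray, folds: int, random_state: int
) -> tuple[float, float]:
    """Stratified k-fold accuracy (mean, standard error) of a pipeline."""
    _, counts = np.unique(y, return_counts=True)
    n_splits = int(min(folds, counts.min()))
    if n_splits < 2:
        raise EvaluationError("internal validation needs >= 2 samples per class")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=random_state)
    accs = []
    for tr, te in skf.split(X, y):
        model = clone(pipe).fit(X[tr], y[tr])
        accs.append(float(np.mean(model.predict(X[te]) == y[te])))
    accs = np.asarray(accs)
    return float(accs.mean()), float(accs.std(ddof=1) / np.sqrt(len(accs)))


@dataclass
class StageModel:
    """A fitted screening or grading stage (inspectable coefficients)."""

    stage: str  # "screening" | "grading"
    feature_names: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    C: float  # inverse regularization strength
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    pipeline: Pipeline = field(repr=False, default=None)

    @property
    def n_selected(self) -> int:
        return int(np.sum(self.coefficients != 0))


def fit_stage(
    X,
    y,
    stage: str,
    reg_strength="select",
    cv_folds: int = 3,
    c_grid=DEFAULT_C_GRID,
    random_state: int = 0,
    class_weight=None,
) -> StageModel:
    """Fit one cascade stage on a labeled cohort.

    ``y`` carries the three-class labels; the stage's binary target is
    derived internally (screening: N vs {M, P}; grading: M vs P on the
    abnormal subset).  ``reg_strength="select"`` runs the internal
    cross-validated grid; a float fixes the inverse penalty C.
    """
    Xf = _as_feature_frame(X)
    y = np.asarray(y)
    if stage == "screening":
        names = SCREENING_FEATURES
        target = np.where(y == "N", "N", "A")
        keep = np.ones(len(y), dtype=bool)
    elif stage == "grading":
        names = GRADING_FEATURES
        keep = np.isin(y, ("M", "P"))
        target = y
    else:
        raise ParameterError(f"unknown stage {stage!r}")
    Xs = Xf.loc[keep, list(names)].to_numpy(dtype=float)
    ys = target[keep]
    classes, counts = np.unique(ys, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise EvaluationError(
            f"stage {stage!r} needs >= 2 samples in each of its two classes; "
            f"got {dict(zip(classes.tolist(), counts.tolist()))}"
        )

    if reg_strength == "select":
        best_C, best_acc = None, -np.inf
        for C in c_grid:  # ascending C: ties keep the sparsest (smallest C)
            pipe = _make_pipeline(C, random_state)
            if class_weight is not None:
                pipe.set_params(logreg__class_weight=class_weight)
            acc, _ = _cv_accuracy(pipe, Xs, ys, cv_folds, random_state)
            if acc > best_acc + 1e-12:
                best_acc, best_C = acc, C
        C = float(best_C)
    else:
        C = float(reg_strength)

    pipe = _make_pipeline(C, random_state)
    if class_weight is not None:
        pipe.set_params(logreg__class_weight=class_weight)
    pipe.fit(Xs, ys)
    lr: LogisticRegression = pipe.named_steps["logreg"]
    scaler: StandardScaler = pipe.named_steps["scaler"]
    return StageModel(
        stage=stage,
        feature_names=names,
        coefficients=lr.coef_.ravel().copy(),
        intercept=float(lr.intercept_[0]),
        C=C,
        scaler_mean=scaler.mean_.copy(),
        scaler_std=scaler.scale_.copy(),
        pipeline=pipe,
    )


class HierarchicalLassoClassifier(BaseEstimator, ClassifierMixin):
    """Two-stage cascaded L1-logistic classifier over gait state vectors.

    Parameters
    ----------
    stage1_C : "select" or float
        Inverse penalty for the screening stage; ``"select"`` picks it by
        internal stratified cross-validation on the training fold.
    stage2_C : float
        Fixed inverse penalty for the grading stage.
    cv_folds : int
        Folds for the internal strength selection.
    random_state : int
        Seeds the internal CV shuffling and the liblinear solver.
    class_weight : None or "balanced"
        Optional imbalance reweighting (off by default).

    Attributes
    ----------
    stage1_ : StageModel
    stage2_ : StageModel
    classes_ : ndarray of the three labels seen in fit
    """

    def __init__(
        self,
        stage1_C="select",
        stage2_C: float = 1.0,
        cv_folds: int = 3,
        c_grid=DEFAULT_C_GRID,
        random_state: int = 0,
        class_weight=None,
    ):
        self.stage1_C = stage1_C
        self.stage2_C = stage2_C
        self.cv_folds = cv_folds
        self.c_grid = c_grid
        self.random_state = random_state
        self.class_weight = class_weight

    def fit(self, X, y):
        y = np.asarray(y)
        bad = set(np.unique(y)) - set(LABELS)
        if bad:
            raise SchemaError(f"labels must be drawn from {LABELS}, got {sorted(bad)}")
        self.stage1_ = fit_stage(
            X,
            y,
            "screening",
            reg_strength=self.stage1_C,
            cv_folds=self.cv_folds,
            c_grid=self.c_grid,
            random_state=self.random_state,
            class_weight=self.class_weight,
        )
        self.stage2_ = fit_stage(
            X,
            y,
            "grading",
            reg_strength=self.stage2_C,
            cv_folds=self.cv_folds,
            c_grid=self.c_grid,
            random_state=self.random_state,
            class_weight=self.class_weight,
        )
        self.classes_ = np.array(LABELS)
        return self

    def predict(self, X):
        Xf = _as_feature_frame(X)
        X1 = Xf[list(SCREENING_FEATURES)].to_numpy(dtype=float)
        X2 = Xf[list(GRADING_FEATURES)].to_numpy(dtype=float)
        pipe1 = self.stage1_.pipeline
        # ties at p=0.5 go to "abnormal": screening favors sensitivity
        idx_a = list(pipe1.classes_).index("A")
        p_abnormal = pipe1.predict_proba(X1)[:, idx_a]
        abnormal = p_abnormal >= 0.5
        out = np.full(len(Xf), "N", dtype=object)
        if abnormal.any():
            out[abnormal] = self.stage2_.pipeline.predict(X2[abnormal])
        return out


@dataclass
class ClassificationReport:
    """LOOCV evaluation summary in confusion-matrix form."""

    labels: tuple[str, ...]
    y_true: np.ndarray
    y_pred: np.ndarray
    confusion: np.ndarray  # rows = true, cols = predicted
    precision: dict
    recall: dict
    f1: dict
    accuracy: float
    screening_accuracy: float

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "confusion_matrix": self.confusion.tolist(),
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "screening_accuracy": self.screening_accuracy,
        }


def metrics_from_confusion(confusion: np.ndarray, labels=LABELS):
    """Per-class precision/recall/F1 from a confusion matrix (rows = true)."""
    confusion = np.asarray(confusion, dtype=float)
    precision, recall, f1 = {}, {}, {}
    for i, lab in enumerate(labels):
        col = confusion[:, i].sum()
        row = confusion[i, :].sum()
        p = confusion[i, i] / col if col > 0 else 0.0
        r = confusion[i, i] / row if row > 0 else 0.0
        precision[lab] = float(p)
        recall[lab] = float(r)
        f1[lab] = float(2 * p * r / (p + r)) if (p + r) > 0 else 0.0
    return precision, recall, f1


def loocv_evaluate(X, y, **clf_params) -> ClassificationReport:
    """Leave-one-out evaluation of the full cascade.

    Both stages — including the scaler and the screening-strength selection —
    are refit on every training fold; the held-out trial is then predicted by
    the cascade.  Per-subject grouping is not applied here; callers wanting a
    subject-level screening figure can aggregate ``y_pred`` themselves.
    """
    Xf = _as_feature_frame(X)
    y = np.asarray(y)
    n = len(y)
    preds = np.empty(n, dtype=object)
    base = HierarchicalLassoClassifier(**clf_params)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        try:
            model = clone(base).fit(Xf[tr], y[tr])
        except EvaluationError as exc:
            raise EvaluationError(f"LOOCV fold {i} (held-out sample {i}): {exc}")
        preds[i] = model.predict(Xf[~tr])[0]
    confusion = np.zeros((len(LABELS), len(LABELS)), dtype=int)
    lab_idx = {lab: i for i, lab in enumerate(LABELS)}
    for t, p in zip(y, preds):
        confusion[lab_idx[t], lab_idx[p]] += 1
    precision, recall, f1 = metrics_from_confusion(confusion)
    accuracy = float(np.mean(preds == y))
    screening_accuracy = float(np.mean((preds == "N") == (y == "N")))
    return ClassificationReport(
        labels=LABELS,
        y_true=y,
        y_pred=preds,
        confusion=confusion,
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=accuracy,
        screening_accuracy=screening_accuracy,
    )


def regularization_sweep(
    X,
    y,
    stage: str = "screening",
    grid=DEFAULT_C_GRID,
    cv_folds: int = 3,
    random_state: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Sparsity/accuracy trade-off across the regularization path.

    For each inverse penalty C the stage is fit on the whole cohort (feature
    count) and scored by internal stratified CV (accuracy).  Returns the
    sweep table and the sparsest C within one standard error of the best
    accuracy (the usual 1-SE rule).
    """
    grid = list(grid)
    if len(grid) == 0:
        raise ParameterError("empty regularization grid")
    rows = []
    for C in grid:
        model = fit_stage(
            X, y, stage, reg_strength=float(C), cv_folds=cv_folds, random_state=random_state
        )
        Xf = _as_feature_frame(X)
        if stage == "screening":
            Xs = Xf[list(SCREENING_FEATURES)].to_numpy(dtype=float)
            ys = np.where(np.asarray(y) == "N", "N", "A")
        else:
            keep = np.isin(np.asarray(y), ("M", "P"))
            Xs = Xf.loc[keep, list(GRADING_FEATURES)].to_numpy(dtype=float)
            ys = np.asarray(y)[keep]
        acc, se = _cv_accuracy(
            _make_pipeline(float(C), random_state), Xs, ys, cv_folds, random_state
        )
        rows.append(
            {
                "C": float(C),
                "penalty": 1.0 / float(C),
                "n_selected_features": model.n_selected,
                "cv_accuracy": acc,
                "cv_accuracy_se": se,
            }
        )
    table = pd.DataFrame(rows).sort_values("C").reset_index(drop=True)
    best = table.loc[table["cv_accuracy"].idxmax()]
    threshold = best["cv_accuracy"] - best["cv_accuracy_se"]
    eligible = table[table["cv_accuracy"] >= threshold]
    chosen = float(eligible["C"].min())  # smallest C = strongest penalty = sparsest
    return table, chosen
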