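"""Classifiers, leave-one-out evaluation, and significance testing.

Three classifiers are supported on any feature block: a linear
soft-margin SVM, l2-regularised logistic regression, and Gaussian naive
Bayes.  Evaluation is leave-one-out cross-validation (LOOCV) with
hyperparameters chosen *inside* each training fold: the penalty C by
stratified 3-fold search over a log grid (SVM: 2^-4..2^6, logistic:
2^-5..2^5), and the naive-Bayes decision threshold on the typical-class
posterior by inner LOOCV over a grid on (0, 1).  Accuracy is weighted
(balanced) so each class contributes equally:

    wacc = (n_-1 c_1 + n_1 c_-1) / (2 n_1 n_-1)

where n_k / c_k are class sizes and per-class correct counts — i.e. the
mean of the two recalls.  Significance is assessed by rerunning the full
LOOCV pipeline on label permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import LinearSVC

from .containers import ValidationError

__all__ = [
    "ClassifierSpec",
    "ClassificationReport",
    "weighted_accuracy",
    "nested_select",
    "loocv",
    "stack_mmse",
    "permutation_test",
    "evaluate",
]

#: positive class (the clinical group); the other label is "TD"
POSITIVE = "ASD"

SVM_GRID = 2.0 ** np.arange(-4, 7)
LOGREG_GRID = 2.0 ** np.arange(-5, 6)
NB_THRESHOLD_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)


@dataclass
class ClassifierSpec:
    """One classifier configuration.

    ``kind``: ``"svm"`` (linear margin), ``"logreg"`` (l2 logistic) or
    ``"nb"`` (Gaussian naive Bayes).  ``c_grid`` is the penalty search
    grid for the first two; ``threshold_grid`` the posterior cut grid
    for naive Bayes.  Class weights are inverse-frequency when
    ``class_weighting`` is on.
    """

    kind: str = "nb"
    c_grid: np.ndarray = field(default_factory=lambda: SVM_GRID.copy())
    inner_folds: int = 3
    class_weighting: bool = True
    threshold_grid: np.ndarray = field(
        default_factory=lambda: NB_THRESHOLD_GRID.copy()
    )

    def __post_init__(self) -> None:
        if self.kind not in ("svm", "logreg", "nb"):
            raise ValidationError(f"unknown classifier kind '{self.kind}'")
        if self.kind == "logreg" and np.array_equal(self.c_grid, SVM_GRID):
            self.c_grid = LOGREG_GRID.copy()
        if len(self.c_grid) == 0 or len(self.threshold_grid) == 0:
            raise ValidationError("hyperparameter grids must be non-empty")
        if self.inner_folds < 2:
            raise ValidationError("inner_folds must be >= 2")


def weighted_accuracy(truth: np.ndarray, pred: np.ndarray) -> float:
    """Mean of per-class recalls (balanced accuracy)."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    classes = np.unique(truth)
    if classes.size < 2:
        raise ValidationError("weighted accuracy needs both classes in truth")
    recalls = [
        (pred[truth == c] == c).mean() for c in classes
    ]
    return float(np.mean(recalls))


def _make_estimator(spec: ClassifierSpec, c: float, seed: int):
    weight = "balanced" if spec.class_weighting else None
    if spec.kind == "svm":
        return LinearSVC(C=c, class_weight=weight, random_state=seed, max_iter=20000)
    if spec.kind == "logreg":
        return LogisticRegression(
            C=c, class_weight=weight, random_state=seed, max_iter=5000
        )
    raise ValidationError(spec.kind)  # pragma: no cover


def _fold_score(spec, c, X, y, train, test, seed) -> float:
    est = _make_estimator(spec, c, seed)
    est.fit(X[train], y[train])
    pred = est.predict(X[test])
    # a single-class test part falls back to plain accuracy
    if np.unique(y[test]).size < 2:
        return float((pred == y[test]).mean())
    return weighted_accuracy(y[test], pred)


def nested_select(
    spec: ClassifierSpec, X_train: np.ndarray, y_train: np.ndarray, seed: int
) -> float:
    """Choose the penalty C by stratified 3-fold search on the training fold.

    Each grid value is scored by training on two parts and evaluating
    weighted accuracy on the third, rotating through all assignments and
    averaging; ties go to the smallest (most regularised) value.
    """
    y_train = np.asarray(y_train)
    skf = StratifiedKFold(
        n_splits=spec.inner_folds, shuffle=True, random_state=seed
    )
    try:
        splits = list(skf.split(X_train, y_train))
    except ValueError as exc:
        raise ValidationError(
            "training fold cannot be split into stratified parts"
        ) from exc
    best_c, best_score = None, -np.inf
    for c in sorted(spec.c_grid):
        score = float(
            np.mean(
                [
                    _fold_score(spec, c, X_train, y_train, tr, te, seed)
                    for tr, te in splits
                ]
            )
        )
        if score > best_score:  # strict: ties keep the smaller C
            best_c, best_score = float(c), score
    return best_c


def _nb_posteriors(X_train, y_train, X_eval) -> np.ndarray:
    """Posterior probability of the typical (non-positive) class.

    Class-conditional variances are floored at 1% of each feature's
    overall variance so that a class with (near-)constant features —
    e.g. a single training subject — keeps a usable likelihood width.
    """
    nb = GaussianNB()
    nb.fit(X_train, y_train)
    floor = 0.01 * np.asarray(X_train).var(axis=0) + 1e-12
    nb.var_ = np.maximum(nb.var_, floor)
    td_col = list(nb.classes_).index(
        next(c for c in nb.classes_ if c != POSITIVE)
    )
    return nb.predict_proba(X_eval)[:, td_col]


def _nb_threshold_select(
    spec: ClassifierSpec, X_train, y_train
) -> float:
    """Inner-LOOCV search for the typical-class posterior cut.

    Each candidate threshold is scored by leave-one-out within the
    training fold; ties prefer the cut closest to 0.5 (then the
    smaller one).
    """
    n = len(y_train)
    post = np.full(n, np.nan)
    for i in range(n):
        tr = np.arange(n) != i
        if np.unique(y_train[tr]).size < 2:
            continue  # leaving i out empties a class; skip this inner fold
        post[i] = _nb_posteriors(X_train[tr], y_train[tr], X_train[i : i + 1])[0]
    valid = ~np.isnan(post)
    if not valid.any() or np.unique(y_train[valid]).size < 2:
        return 0.5
    best_t, best_key = None, None
    for t in spec.threshold_grid:
        pred = np.where(post[valid] > t, "TD", POSITIVE)
        score = weighted_accuracy(y_train[valid], pred)
        key = (-score, abs(t - 0.5), t)
        if best_key is None or key < best_key:
            best_t, best_key = float(t), key
    return best_t


def fit_predict_nb(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    spec: ClassifierSpec | None = None,
) -> tuple[np.ndarray, float]:
    """Gaussian naive Bayes with a tuned typical-class posterior cut.

    Returns (predictions, chosen threshold).  GaussianNB applies a
    variance floor internally, so zero-variance features do not break
    the likelihoods.
    """
    spec = spec or ClassifierSpec(kind="nb")
    y_train = np.asarray(y_train)
    t = _nb_threshold_select(spec, X_train, y_train)
    post = _nb_posteriors(X_train, y_train, X_test)
    return np.where(post > t, "TD", POSITIVE), t


def loocv(
    spec: ClassifierSpec, X: np.ndarray, y: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, list]:
    """Leave-one-out predictions with per-fold nested selection.

    Returns (out-of-fold predictions, chosen hyperparameter per fold).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValidationError("LOOCV needs at least two subjects per class")
    n = len(y)
    preds = np.empty(n, dtype=object)
    chosen = []
    for i in range(n):
        tr = np.arange(n) != i
        if np.unique(y[tr]).size < 2:
            raise ValidationError("class absent in a training fold")
        if spec.kind == "nb":
            pred, t = fit_predict_nb(X[tr], y[tr], X[i : i + 1], spec)
            preds[i] = pred[0]
            chosen.append(t)
        else:
            c = nested_select(spec, X[tr], y[tr], seed)
            est = _make_estimator(spec, c, seed)
            est.fit(X[tr], y[tr])
            preds[i] = est.predict(X[i : i + 1])[0]
            chosen.append(c)
    return preds, chosen


def stack_mmse(
    selected: np.ndarray,
    mmse: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    c: float = 0.1,
) -> np.ndarray:
    """Append an out-of-fold SVM prediction from the entropy block.

    A linear SVM (fixed C, inverse-frequency class weights) is
    evaluated on the high-dimensional multiscale-entropy features by
    LOOCV; each subject's out-of-fold hard label (1 = positive class)
    becomes feature 24 alongside the 23 selected features.  Stacking a
    prediction instead of concatenating avoids the entropy block's
    dimensionality swamping the 23 features.
    """
    selected = np.asarray(selected, dtype=np.float64)
    mmse = np.asarray(mmse, dtype=np.float64)
    y = np.asarray(y)
    if selected.shape[0] != mmse.shape[0]:
        raise ValidationError("feature blocks cover different subject counts")
    n = selected.shape[0]
    col = np.empty(n)
    for i in range(n):
        tr = np.arange(n) != i
        est = LinearSVC(
            C=c, class_weight="balanced", random_state=seed, max_iter=20000
        )
        est.fit(mmse[tr], y[tr])
        col[i] = 1.0 if est.predict(mmse[i : i + 1])[0] == POSITIVE else 0.0
    return np.column_stack([selected, col])


def permutation_test(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Label-permutation significance of the LOOCV weighted accuracy.

    Returns (observed accuracy, p-value, permuted accuracies) with the
    +1-corrected p: (1 + #{perm >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    y = np.asarray(y)
    preds, _ = loocv(spec, X, y, seed)
    observed = weighted_accuracy(y, preds)
    rng = np.random.default_rng(seed)
    perm_acc = np.empty(n_perm)
    for k in range(n_perm):
        y_perm = rng.permutation(y)
        preds_k, _ = loocv(spec, X, y_perm, seed)
        perm_acc[k] = weighted_accuracy(y_perm, preds_k)
    p = (1 + int((perm_acc >= observed).sum())) / (n_perm + 1)
    return observed, float(p), perm_acc


@dataclass
class ClassificationReport:
    """Out-of-fold results for one feature set x classifier."""

    truth: np.ndarray
    predictions: np.ndarray
    weighted_accuracy: float
    sensitivity: float
    specificity: float
    chosen: list
    permutation_p: float | None = None

    @classmethod
    def from_predictions(
        cls, truth: np.ndarray, preds: np.ndarray, chosen: list | None = None
    ) -> "ClassificationReport":
        truth = np.asarray(truth)
        preds = np.asarray(preds)
        pos = truth == POSITIVE
        return cls(
            truth=truth,
            predictions=preds,
            weighted_accuracy=weighted_accuracy(truth, preds),
            sensitivity=float((preds[pos] == POSITIVE).mean()),
            specificity=float((preds[~pos] != POSITIVE).mean()),
            chosen=chosen or [],
        )


def evaluate(
    feature_sets: dict[str, np.ndarray],
    y: np.ndarray,
    specs: list[ClassifierSpec] | None = None,
    seed: int = 0,
    subgroups: dict[str, np.ndarray] | None = None,
) -> dict[tuple[str, str], ClassificationReport]:
    """LOOCV every feature set under every classifier.

    ``subgroups`` maps a name to a boolean subject mask (e.g. males
    only); each valid subgroup is re-evaluated from scratch on its
    subset.  Keys of the result are ``(feature_set, classifier)`` or
    ``(feature_set, classifier @ subgroup)``.
    """
    import warnings as _warnings

    specs = specs or [
        ClassifierSpec(kind="svm"),
        ClassifierSpec(kind="logreg"),
        ClassifierSpec(kind="nb"),
    ]
    y = np.asarray(y)
    out: dict[tuple[str, str], ClassificationReport] = {}
    for fname, X in feature_sets.items():
        for spec in specs:
            preds, chosen = loocv(spec, X, y, seed)
            out[(fname, spec.kind)] = ClassificationReport.from_predictions(
                y, preds, chosen
            )
            for sname, m in (subgroups or {}).items():
                ys = y[m]
                if np.unique(ys).size < 2 or min(
                    (ys == c).sum() for c in np.unique(ys)
                ) < 2:
                    _warnings.warn(
                        f"subgroup '{sname}' lacks two subjects per class; skipped",
                        stacklevel=2,
                    )
                    continue
                preds_s, chosen_s = loocv(spec, X[m], ys, seed)
                out[(fname, f"{spec.kind} @ {sname}")] = (
                    ClassificationReport.from_predictions(ys, preds_s, chosen_s)
                )
    return out
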