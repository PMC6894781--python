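"""Maximum-margin classification/regression with exhaustive subset search.

The discrimination and prediction analyses fit linear support vector
machines (classification) and epsilon-SVR (regression) on the 13 speech
features, evaluated by leave-one-out cross-validation (LOOCV): each
participant is predicted by a model trained on all the others.  Class
weights inversely proportional to class size compensate the ASD/TD
imbalance.  Feature subsets are selected by evaluating the LOOCV
criterion for every non-empty subset (2^13 - 1 = 8191 for 13 features).

Models are scikit-learn's libsvm-backed SVC/SVR.  Because the exhaustive
search performs hundreds of thousands of tiny fits, it calls the
low-level libsvm binding directly when available (bypassing per-call
estimator overhead); the public-API path is kept as a fallback and the
two are asserted equivalent in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC, SVR

from .errors import ValidationError

try:  # low-level libsvm binding: same solver, far less per-call overhead
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
    _HAVE_RAW_LIBSVM = True
except ImportError:  # pragma: no cover
    _HAVE_RAW_LIBSVM = False

MAX_SEARCH_FEATURES = 20


@dataclass(frozen=True)
class ModelConfig:
    """Linear-kernel SVM settings.

    ``class_weighting`` weights each class's errors inversely to its size
    (classification only); ``epsilon`` is the SVR insensitivity tube.
    """

    C: float = 1.0
    class_weighting: bool = True
    epsilon: float = 0.1

    def __post_init__(self):
        if not self.C > 0:
            raise ValidationError("C must be > 0")


@dataclass(frozen=True)
class SubsetSearchResult:
    """One evaluated feature subset."""

    subset: int  # bitmask over feature columns
    features: tuple[str, ...]
    value: float  # LOOCV accuracy (classification) or RMSE (regression)


@dataclass
class EvalMetrics:
    """Printed evaluation metrics.

    Classification: 2x2 confusion (rows = correct class, columns =
    predicted), accuracy % and F-measure % with ASD as the positive class.
    Regression: Pearson r of pooled LOO predictions vs rated scores, MAE,
    RMSE.  Unused fields are NaN/None.
    """

    confusion: pd.DataFrame | None = None
    accuracy_pct: float = math.nan
    f_measure_pct: float = math.nan
    r: float = math.nan
    mae: float = math.nan
    rmse: float = math.nan
    r_defined: bool = True


def _class_weights(y_codes: np.ndarray, enabled: bool) -> np.ndarray:
    """Per-class error weights proportional to inverse class size."""
    counts = np.bincount(y_codes.astype(int), minlength=2)
    if enabled:
        return y_codes.size / (2.0 * counts)
    return np.ones(2)


def _fit_predict_public(
    Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray,
    task: str, cfg: ModelConfig,
) -> np.ndarray:
    if task == "classify":
        w = _class_weights(ytr, cfg.class_weighting)
        est = SVC(kernel="linear", C=cfg.C, class_weight={0: w[0], 1: w[1]})
    else:
        est = SVR(kernel="linear", C=cfg.C, epsilon=cfg.epsilon)
    est.fit(Xtr, ytr)
    return est.predict(Xte)


def _fit_predict_raw(
    Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray,
    task: str, cfg: ModelConfig,
) -> np.ndarray:
    if task == "classify":
        svm_type = 0
        cw = _class_weights(ytr, cfg.class_weighting)
    else:
        svm_type = 3
        cw = np.empty(0)
    model = _libsvm.fit(
        np.ascontiguousarray(Xtr), ytr.astype(np.float64),
        svm_type=svm_type, kernel="linear", C=cfg.C,
        class_weight=np.asarray(cw, dtype=np.float64),
        epsilon=cfg.epsilon, tol=1e-3,
    )
    support, sv, n_sv, coef, intercept, prob_a, prob_b, _, _ = model
    return _libsvm.predict(
        np.ascontiguousarray(Xte), support, sv, n_sv, coef, intercept,
        prob_a, prob_b, svm_type=svm_type, kernel="linear",
    )


_fit_predict = _fit_predict_raw if _HAVE_RAW_LIBSVM else _fit_predict_public


class LoocvEngine:
    """Leave-one-out evaluator over column subsets of one feature matrix.

    Per-fold standardization statistics (training rows only) are
    precomputed once; evaluating a subset then costs one tiny SVM fit per
    fold on pre-scaled data.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        task: Literal["classify", "regress"],
        cfg: ModelConfig = ModelConfig(),
        use_raw_backend: bool | None = None,
    ):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValidationError("X must be 2-D")
        if not np.all(np.isfinite(X)):
            raise ValidationError("X contains missing or non-finite values")
        n, d = X.shape
        if task == "classify":
            classes, y_codes = np.unique(y, return_inverse=True)
            if classes.size != 2:
                raise ValidationError(f"need exactly 2 classes, got {classes.size}")
            counts = np.bincount(y_codes)
            if counts.min() < 2:
                lone = int(np.nonzero(y_codes == np.argmin(counts))[0][0])
                raise ValidationError(
                    f"class {classes[np.argmin(counts)]!r} has a single member; "
                    f"the fold leaving out row {lone} would train on one class"
                )
            self.classes = classes
            self._y = y_codes.astype(np.float64)
        else:
            self._y = np.asarray(y, dtype=np.float64)
            if not np.all(np.isfinite(self._y)):
                raise ValidationError("y contains missing values")
            self.classes = None
        self.task = task
        self.cfg = cfg
        self.n, self.d = n, d
        if use_raw_backend is None:
            use_raw_backend = _HAVE_RAW_LIBSVM
        self._fit_predict = _fit_predict_raw if use_raw_backend else _fit_predict_public

        # per-fold standardization from training-fold statistics only
        s = X.sum(axis=0)
        q = (X**2).sum(axis=0)
        mean_k = (s[None, :] - X) / (n - 1)                     # (n, d)
        var_k = np.maximum((q[None, :] - X**2) / (n - 1) - mean_k**2, 0.0)
        std_k = np.sqrt(var_k)
        std_k[std_k == 0] = 1.0  # constant training column: leave centred
        # scaled[k] = (X - mean_k) / std_k, the fold-k view of all rows
        self._scaled = (X[None, :, :] - mean_k[:, None, :]) / std_k[:, None, :]
        self._train_idx = [
            np.concatenate([np.arange(k), np.arange(k + 1, n)]) for k in range(n)
        ]

    def predictions(self, subset: Sequence[int]) -> np.ndarray:
        """LOO prediction for every row, restricted to ``subset`` columns."""
        cols = np.asarray(subset, dtype=int)
        if cols.size == 0:
            raise ValidationError("feature subset must be non-empty")
        preds = np.empty(self.n)
        for k in range(self.n):
            rows = self._train_idx[k]
            A = self._scaled[k]
            preds[k] = self._fit_predict(
                A[rows][:, cols], self._y[rows], A[k, cols][None, :],
                self.task, self.cfg,
            )[0]
        return preds

    def criterion(self, subset: Sequence[int]) -> float:
        """LOOCV accuracy (classification) or RMSE (regression)."""
        preds = self.predictions(subset)
        if self.task == "classify":
            return float(np.mean(preds == self._y))
        return float(np.sqrt(np.mean((preds - self._y) ** 2)))

    def decode(self, preds: np.ndarray) -> np.ndarray:
        """Map numeric classifier output back to the original labels."""
        if self.classes is None:
            return preds
        return self.classes[preds.astype(int)]


def loocv_predictions(
    X: np.ndarray,
    y: np.ndarray,
    subset: Sequence[int],
    cfg: ModelConfig = ModelConfig(),
    task: Literal["classify", "regress"] = "classify",
) -> np.ndarray:
    """Leave-one-out predictions on ``subset`` columns of ``X``.

    Features are standardized with training-fold statistics only; the
    prediction for row *k* comes from a model trained on all other rows.
    Classification predictions are returned as the original labels.
    """
    engine = LoocvEngine(X, y, task, cfg)
    return engine.decode(engine.predictions(subset))


def _popcount_mask_to_cols(mask: int, d: int) -> np.ndarray:
    return np.array([j for j in range(d) if mask >> j & 1], dtype=int)


def exhaustive_subset_search(
    X: np.ndarray,
    y: np.ndarray,
    task: Literal["classify", "regress"] = "classify",
    cfg: ModelConfig = ModelConfig(),
    feature_names: Sequence[str] | None = None,
    criterion: Callable[[np.ndarray], float] | None = None,
    maximize: bool | None = None,
) -> list[SubsetSearchResult]:
    """Evaluate every non-empty feature subset by its LOOCV criterion.

    Returns all ``2^d - 1`` subsets ranked best-first: highest LOOCV
    accuracy for classification, lowest RMSE for regression.  Ties are
    broken deterministically by smaller subset size, then by bitmask.  A
    custom ``criterion`` (called with the column indices of a subset) may
    replace the LOOCV evaluation; ``maximize`` then states its direction.
    """
    X = np.asarray(X, dtype=np.float64)
    d = X.shape[1]
    if d > MAX_SEARCH_FEATURES:
        raise ValidationError(
            f"{d} features would require 2^{d}-1 subset evaluations; "
            f"the exhaustive search is limited to d <= {MAX_SEARCH_FEATURES}"
        )
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(d)]
    if criterion is None:
        engine = LoocvEngine(X, y, task, cfg)
        criterion = engine.criterion
        maximize = task == "classify"
    elif maximize is None:
        raise ValidationError("custom criterion requires an explicit `maximize`")

    results = []
    for mask in range(1, 1 << d):
        cols = _popcount_mask_to_cols(mask, d)
        value = float(criterion(cols))
        results.append((mask, cols, value))
    sign = -1.0 if maximize else 1.0
    results.sort(key=lambda item: (sign * item[2], len(item[1]), item[0]))
    return [
        SubsetSearchResult(
            mask, tuple(feature_names[j] for j in cols), value
        )
        for mask, cols, value in results
    ]


def classification_metrics(
    y_true: Sequence, y_pred: Sequence, positive: str = "ASD"
) -> EvalMetrics:
    """Confusion matrix, accuracy % and F-measure % (positive class ASD).

    The confusion matrix follows the convention rows = correct class,
    columns = predicted class, with the positive class first.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    labels = [positive] + sorted(
        (set(map(str, y_true)) | set(map(str, y_pred))) - {positive}
    )
    if len(labels) > 2:
        raise ValidationError(f"labels must be binary, got {labels}")
    cm = np.zeros((2, 2), dtype=int)
    for t, p in zip(map(str, y_true), map(str, y_pred)):
        cm[labels.index(t), labels.index(p)] += 1
    confusion = pd.DataFrame(cm, index=pd.Index(labels, name="correct"),
                             columns=pd.Index(labels, name="predicted"))
    return metrics_from_confusion(confusion)


def metrics_from_confusion(confusion: pd.DataFrame | np.ndarray) -> EvalMetrics:
    """Accuracy % and F-measure % from a 2x2 confusion matrix.

    Rows are the correct class and columns the predicted class, with the
    positive class (ASD) first.
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.shape != (2, 2):
        raise ValidationError("confusion matrix must be 2x2")
    if not isinstance(confusion, pd.DataFrame):
        confusion = pd.DataFrame(
            cm.astype(int),
            index=pd.Index(["ASD", "TD"], name="correct"),
            columns=pd.Index(["ASD", "TD"], name="predicted"),
        )
    tp, fn = cm[0]
    fp, tn = cm[1]
    n = cm.sum()
    accuracy = 100.0 * (tp + tn) / n
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f_measure = (
        200.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return EvalMetrics(
        confusion=confusion, accuracy_pct=float(accuracy), f_measure_pct=float(f_measure)
    )


def regression_metrics(y_true: Sequence[float], y_pred: Sequence[float]) -> EvalMetrics:
    """Pearson r, MAE and RMSE of pooled LOO predictions.

    With constant predictions r is undefined (NaN, ``r_defined=False``);
    MAE and RMSE are still returned.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size < 2 or y_true.shape != y_pred.shape:
        raise ValidationError("need >= 2 aligned pairs")
    err = y_pred - y_true
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    if np.ptp(y_pred) == 0 or np.ptp(y_true) == 0:
        return EvalMetrics(mae=mae, rmse=rmse, r=math.nan, r_defined=False)
    r = float(np.corrcoef(y_true, y_pred)[0, 1])
    return EvalMetrics(r=r, mae=mae, rmse=rmse)
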