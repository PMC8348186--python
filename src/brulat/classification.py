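"""The four classification learners and their evaluation machinery.

Families (MATLAB Classification-Learner counterparts in parentheses):

* ``QSVM`` — support vector machine with the inhomogeneous quadratic kernel
  (x.z + 1)^2, box constraint C = 1, one-vs-one multiclass, features
  standardised by training mean/SD.
* ``FKNN`` — "fine" k-nearest neighbours: k = 1, Euclidean, equal weights.
* ``LDA`` — linear discriminant with pooled within-class covariance,
  ridge-regularised by eps * trace(S)/p on the diagonal (eps = 1e-6,
  escalated only if the Cholesky factorisation still fails) because p = 288
  reflectance bands against a few hundred samples makes exact singularity
  routine.
* ``ESD`` — ensemble subspace discriminant: 30 LDA learners, each on a
  128-feature random subspace drawn without replacement, combined by
  majority vote (ties broken toward the larger training prior, then
  lexicographically).

Training uses seeded stratified k-fold cross-validation (10 folds, clamped
to the smallest class size); the reported CV accuracy is the pooled
out-of-fold correct fraction and the returned model is refit on all rows.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

FAMILIES = ("QSVM", "FKNN", "LDA", "ESD")


class RegularizedLDA(BaseEstimator, ClassifierMixin):
    """Pooled-covariance linear discriminant with Ledoit-Wolf shrinkage.

    With p comparable to n the small eigenvalues of the pooled sample
    covariance are badly underestimated and a naive inverse is dominated by
    noise directions; the within-class covariance is therefore shrunk toward
    scaled identity with the Ledoit-Wolf intensity estimated from the
    class-centred residuals (``shrinkage="ledoit-wolf"``, default) or a
    fixed intensity in [0, 1].  ``eps`` adds a trace-scaled ridge floor that
    is escalated only if the Cholesky factorisation still fails.
    """

    def __init__(self, shrinkage="ledoit-wolf", eps: float = 1e-6):
        self.shrinkage = shrinkage
        self.eps = eps

    def fit(self, X, y):
        from sklearn.covariance import ledoit_wolf_shrinkage

        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, p = X.shape
        k = len(self.classes_)
        if k < 2:
            raise ValueError("need at least 2 classes")
        self.priors_ = np.bincount(y_idx, minlength=k) / n
        self.means_ = np.vstack([X[y_idx == c].mean(axis=0) for c in range(k)])
        centred = X - self.means_[y_idx]
        cov = centred.T @ centred / max(n - k, 1)
        if self.shrinkage == "ledoit-wolf":
            alpha = float(ledoit_wolf_shrinkage(centred, assume_centered=True))
        else:
            alpha = float(self.shrinkage)
        if not 0.0 <= alpha <= 1.0:
            raise ValueError(f"shrinkage intensity must be in [0, 1], got {alpha}")
        mu = np.trace(cov) / p
        cov = (1.0 - alpha) * cov + alpha * mu * np.eye(p)
        ridge = self.eps * max(np.trace(cov), 1e-300) / p
        for _ in range(12):
            try:
                self._chol = linalg.cho_factor(
                    cov + ridge * np.eye(p), lower=True)
                break
            except linalg.LinAlgError:
                ridge = max(ridge * 10, 1e-12)
        else:
            raise ValueError("within-class covariance could not be regularised")
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        solved = linalg.cho_solve(self._chol, self.means_.T)  # p x k
        scores = X @ solved - 0.5 * np.einsum("kp,pk->k", self.means_, solved)
        scores = scores + np.log(self.priors_)
        if len(self.classes_) == 2:
            return scores[:, 1] - scores[:, 0]
        return scores

    def _full_scores(self, X):
        d = self.decision_function(X)
        if d.ndim == 1:
            return np.column_stack([-d, d])
        return d

    def predict(self, X):
        return self.classes_[np.argmax(self._full_scores(X), axis=1)]


class SubspaceDiscriminantEnsemble(BaseEstimator, ClassifierMixin):
    """Majority-vote ensemble of discriminants on random feature subspaces.

    Each learner sees a subspace of ``subspace_dim`` features sampled
    uniformly without replacement, independently per learner.  Vote ties go
    to the class with the larger training prior, then lexicographic order.
    """

    def __init__(self, n_learners: int = 30, subspace_dim: int = 128,
                 seed: int = 0, shrinkage="ledoit-wolf", eps: float = 1e-6):
        self.n_learners = n_learners
        self.subspace_dim = subspace_dim
        self.seed = seed
        self.shrinkage = shrinkage
        self.eps = eps

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n, p = X.shape
        if self.subspace_dim > p:
            raise ValueError(f"subspace_dim ({self.subspace_dim}) exceeds "
                             f"feature count ({p})")
        rng = np.random.default_rng(self.seed)
        self.classes_ = np.unique(y)
        counts = np.array([(y == c).sum() for c in self.classes_])
        self.priors_ = counts / n
        self.learners_ = []
        for _ in range(self.n_learners):
            idx = np.sort(rng.choice(p, size=self.subspace_dim, replace=False))
            lda = RegularizedLDA(shrinkage=self.shrinkage,
                                 eps=self.eps).fit(X[:, idx], y)
            self.learners_.append((idx, lda))
        return self

    def _votes(self, X):
        X = np.asarray(X, dtype=float)
        class_pos = {c: i for i, c in enumerate(self.classes_)}
        votes = np.zeros((X.shape[0], len(self.classes_)))
        for idx, lda in self.learners_:
            pred = lda.predict(X[:, idx])
            for i, c in enumerate(pred):
                votes[i, class_pos[c]] += 1
        return votes

    def predict_proba(self, X):
        return self._votes(X) / self.n_learners

    def predict(self, X):
        votes = self._votes(X)
        # priors (< 1) break vote ties; argmax's first-hit rule then breaks
        # exact prior ties lexicographically (classes_ is sorted)
        return self.classes_[np.argmax(votes + 0.5 * self.priors_, axis=1)]


@dataclass(frozen=True)
class ClassifierSpec:
    """Family name plus hyperparameter overrides and a seed."""

    family: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of "
                             f"{FAMILIES}")

    def build(self):
        p = dict(self.params)
        if self.family == "QSVM":
            # gamma="scale" divides the inner product by p*var(x): the
            # kernel-scale normalisation MATLAB's quadratic preset applies;
            # a raw (x.z + 1)^2 on hundreds of standardized features is so
            # ill-conditioned that C = 1 underfits even separable data
            return Pipeline([
                ("scale", StandardScaler()),
                ("svm", SVC(kernel="poly", degree=2,
                            gamma=p.pop("gamma", "scale"),
                            coef0=p.pop("coef0", 1.0), C=p.pop("C", 1.0),
                            decision_function_shape="ovr", **p)),
            ])
        if self.family == "FKNN":
            return KNeighborsClassifier(n_neighbors=p.pop("k", 1),
                                        metric="euclidean", weights="uniform",
                                        **p)
        if self.family == "LDA":
            return RegularizedLDA(**p)
        return SubspaceDiscriminantEnsemble(
            n_learners=p.pop("n_learners", 30),
            subspace_dim=p.pop("subspace_dim", 128), seed=self.seed, **p)


def esd_fit(X, y, n_learners: int = 30, subspace_dim: int = 128,
            seed: int = 0) -> SubspaceDiscriminantEnsemble:
    """Convenience constructor+fit for the subspace-discriminant ensemble."""
    return SubspaceDiscriminantEnsemble(n_learners, subspace_dim, seed).fit(X, y)


def train(spec: ClassifierSpec, X, y, n_folds: int = 10):
    """Seeded stratified CV then refit on all rows.

    Returns ``(fitted model, cv_accuracy_percent)``.  The fold count is
    clamped to the smallest class size; a class with fewer than 2 members is
    an error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        offender = classes[np.argmin(counts)]
        raise ValueError(f"class {offender!r} has fewer than 2 samples")
    folds = int(min(n_folds, counts.min()))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
    correct = 0
    for train_idx, test_idx in skf.split(X, y):
        model = clone(spec.build()).fit(X[train_idx], y[train_idx])
        correct += int((model.predict(X[test_idx]) == y[test_idx]).sum())
    cv_accuracy = 100.0 * correct / len(y)
    final = clone(spec.build()).fit(X, y)
    return final, cv_accuracy


@dataclass
class EvaluationReport:
    """Accuracy/AUC/confusion summary of one fitted model on one test set."""

    classes: np.ndarray
    cv_accuracy: float | None
    test_accuracy: float
    auc: float
    confusion: np.ndarray        # rows = true classes, columns = predicted
    tpr_per_class: np.ndarray
    fnr_per_class: np.ndarray
    prediction_speed: float | None = None   # observations / second
    normalized_speed: float | None = None

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "cv_accuracy": self.cv_accuracy,
            "test_accuracy": self.test_accuracy,
            "auc": None if np.isnan(self.auc) else float(self.auc),
            "confusion": self.confusion.tolist(),
            "tpr_per_class": [None if np.isnan(v) else float(v)
                              for v in self.tpr_per_class],
            "fnr_per_class": [None if np.isnan(v) else float(v)
                              for v in self.fnr_per_class],
            "prediction_speed": self.prediction_speed,
            "normalized_speed": self.normalized_speed,
        }


def _class_scores(model, X) -> np.ndarray:
    """(n, k) ranking scores aligned with ``model.classes_``."""
    if hasattr(model, "decision_function"):
        d = np.asarray(model.decision_function(X))
        if d.ndim == 1:
            return np.column_stack([-d, d])
        return d
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X))
    pred = model.predict(X)
    return (pred[:, None] == model.classes_[None, :]).astype(float)


def binary_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Mann-Whitney AUC of ``scores`` for the boolean positives ``truth``."""
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        return float("nan")
    return float(roc_auc_score(truth, scores))


def evaluate(model, X_test, y_test, positive_class=None,
             cv_accuracy: float | None = None) -> EvaluationReport:
    """Accuracy, AUC, and confusion matrix with per-class TPR/FNR.

    Binary AUC ranks the positive-class score (Mann-Whitney); multiclass AUC
    is the unweighted mean of the one-vs-rest AUCs over classes present in
    the test set.  Rows of the confusion matrix are true classes.
    """
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test)
    if len(y_test) == 0:
        raise ValueError("test set is empty")
    classes = np.asarray(model.classes_)
    unseen = set(y_test) - set(classes)
    if unseen:
        raise ValueError(f"test labels unseen in training: {sorted(unseen)}")

    pred = model.predict(X_test)
    accuracy = 100.0 * float((pred == y_test).mean())
    scores = _class_scores(model, X_test)

    if len(classes) == 2:
        pos = positive_class if positive_class is not None else classes[1]
        pos_col = int(np.flatnonzero(classes == pos)[0])
        auc = binary_auc(scores[:, pos_col], y_test == pos)
    else:
        aucs = [binary_auc(scores[:, i], y_test == c)
                for i, c in enumerate(classes)]
        aucs = [a for a in aucs if not np.isnan(a)]
        auc = float(np.mean(aucs)) if aucs else float("nan")

    cm = confusion_matrix(y_test, pred, labels=classes)
    row_sums = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = np.where(row_sums > 0, np.diag(cm) / row_sums, np.nan)
    return EvaluationReport(classes, cv_accuracy, accuracy, auc, cm,
                            tpr, 1.0 - tpr)


def prediction_speed(model, X, repetitions: int = 5) -> float:
    """Observations/second, median wall-clock timing over ``repetitions``."""
    X = np.asarray(X)
    if X.shape[0] == 0:
        raise ValueError("cannot time prediction on an empty input")
    if repetitions < 3:
        raise ValueError("need at least 3 timing repetitions")
    times = []
    for _ in range(repetitions):
        start = time.perf_counter()
        model.predict(X)
        times.append(time.perf_counter() - start)
    return float(X.shape[0] / np.median(times))


def normalize_speeds(speeds) -> list[float]:
    """Divide each entry by the maximum so the fastest is exactly 1."""
    speeds = np.asarray(list(speeds), dtype=float)
    if speeds.size == 0:
        raise ValueError("no speeds to normalize")
    return (speeds / speeds.max()).tolist()
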