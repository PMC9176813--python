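"""Repeated nested cross-validated linear-SVM classification.

Every data-dependent fitting step — per-feature standardization, PCA
retaining a fixed fraction of variance, the C-grid search, and the sigmoid
probability calibration — happens strictly inside each training fold, so no
statistic of a held-out speaker can influence any fitted parameter.  Each
repetition scores every speaker exactly once with the model of the outer
fold that excludes it; AUC is rank-based (Mann-Whitney with midrank ties)
on the pooled out-of-fold probabilities.

PCA is computed from the training-fold Gram matrix, which for the typical
regime here (tens of speakers, thousands of features) is both exact and far
cheaper than an SVD of the full matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "DesignMatrix",
    "CVConfig",
    "RepetitionResult",
    "ClassificationSummary",
    "FoldModel",
    "ClassifierError",
    "stratified_folds",
    "fit_fold",
    "predict_scores",
    "single_repetition",
    "repeated_nested_cv",
    "roc_auc",
    "confusion_stats",
    "summarize",
]


class ClassifierError(ValueError):
    """Raised for contract violations in the classification machinery."""


@dataclass(frozen=True)
class DesignMatrix:
    """Speakers-by-features matrix with binary labels (1 = positive class)."""

    X: np.ndarray
    y: np.ndarray
    speaker_ids: tuple[str, ...]
    positive_label: str = "ASD"

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=np.float64)
        y = np.asarray(self.y, dtype=np.int64)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "speaker_ids", tuple(self.speaker_ids))
        if X.ndim != 2:
            raise ClassifierError("X must be 2-D (speakers x features)")
        if not np.all(np.isfinite(X)):
            raise ClassifierError("X contains NaN/Inf")
        if y.shape != (X.shape[0],) or len(self.speaker_ids) != X.shape[0]:
            raise ClassifierError("rows of X, y and speaker_ids must align")
        if not np.isin(y, (0, 1)).all():
            raise ClassifierError("y must be binary 0/1")
        if min((y == 0).sum(), (y == 1).sum()) < 2:
            raise ClassifierError("need at least 2 speakers per class")


@dataclass(frozen=True)
class CVConfig:
    """Repeated nested cross-validation configuration."""

    outer_folds: int = 10
    repeats: int = 101       # desk scale; 5001 for full-scale runs
    inner_folds: int = 5
    c_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0)
    pca_variance: float = 0.95
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repeats % 2 == 0:
            raise ClassifierError("repeats must be odd for a unique median repetition")
        if not (0 < self.pca_variance <= 1):
            raise ClassifierError("pca_variance must be in (0, 1]")
        if any(c <= 0 for c in self.c_grid):
            raise ClassifierError("C grid values must be positive")


@dataclass
class RepetitionResult:
    """Pooled out-of-fold scores and statistics of one CV repetition."""

    scores: np.ndarray      # positive-class probability per speaker
    predicted: np.ndarray   # hard label at threshold 0.5
    auc: float
    acc: float
    sens: float
    spec: float
    chosen_c: list[float] = field(default_factory=list)


@dataclass
class ClassificationSummary:
    """Median-repetition statistics plus the aggregated confusion matrix."""

    median_auc: float
    acc: float
    sens: float
    spec: float
    auc_distribution: np.ndarray
    aggregated_confusion: np.ndarray  # rows: true (neg, pos); cols: predicted
    median_repetition: int


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

def stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Stratified fold assignment (one fold id per sample), seeded."""
    y = np.asarray(y)
    counts = np.bincount(y, minlength=2)
    if k > counts.min():
        raise ClassifierError(
            f"outer_folds={k} exceeds the minority class count {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31))
    assignment = np.empty(y.size, dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((y.size, 1)), y)):
        assignment[test_idx] = fold
    return assignment


# ---------------------------------------------------------------------------
# Single-fold pipeline
# ---------------------------------------------------------------------------

@dataclass
class FoldModel:
    """Frozen parameters of one training-fold pipeline."""

    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray   # features x kept components
    pca_mean: np.ndarray     # mean in standardized space
    chosen_c: float
    svm_w: np.ndarray        # SVM weights in PC space, intercept last
    sigmoid_ab: tuple[float, float]  # calibrator slope/offset on decisions
    n_components: int


def _fit_linear_svc(Z: np.ndarray, y: np.ndarray, c: float,
                    w0: Optional[np.ndarray] = None,
                    tol: float = 1e-9, max_iter: int = 100) -> np.ndarray:
    """L2-regularized squared-hinge linear SVM (primal Newton).

    Same objective as liblinear's default (penalized intercept via an
    augmented constant column): 0.5 ||w||^2 + C sum max(0, 1 - y w.x)^2.
    Deterministic; agrees with sklearn LinearSVC(dual=False) to ~1e-6,
    which the test suite verifies as an independent cross-check.
    """
    n, k = Z.shape
    A = np.hstack([Z, np.ones((n, 1))])
    s = np.where(np.asarray(y) == 1, 1.0, -1.0)
    w = np.zeros(k + 1) if w0 is None else w0.copy()

    def objective(wv: np.ndarray) -> float:
        v = np.maximum(0.0, 1.0 - (A @ wv) * s)
        return 0.5 * float(wv @ wv) + c * float(v @ v)

    f = objective(w)
    for _ in range(max_iter):
        margins = (A @ w) * s
        active = margins < 1.0
        grad = w - 2.0 * c * (A[active].T @ (s[active] * (1.0 - margins[active])))
        if np.linalg.norm(grad) <= tol * (1.0 + np.linalg.norm(w)):
            break
        hess = np.eye(k + 1) + 2.0 * c * (A[active].T @ A[active])
        step = np.linalg.solve(hess, grad)
        t = 1.0
        for _ in range(30):
            w_new = w - t * step
            f_new = objective(w_new)
            if f_new <= f - 1e-4 * t * float(grad @ step):
                break
            t *= 0.5
        w, f = w_new, f_new
    return w


def _svc_decision(w: np.ndarray, Z: np.ndarray) -> np.ndarray:
    return Z @ w[:-1] + w[-1]


def _fit_sigmoid(d: np.ndarray, y: np.ndarray, ridge: float = 1e-6,
                 max_iter: int = 50) -> tuple[float, float]:
    """Platt-style sigmoid calibration: logistic fit of y on decision values.

    Classes are weighted to equal total mass.  Without this, the intercept
    encodes the training fold's class imbalance — which, under stratified
    cross-validation of a finite cohort, is *anti*-correlated with the test
    fold's composition (a test fold rich in positives comes from a training
    set poor in them), so unbalanced calibration systematically shifts
    whole test folds in the wrong direction and biases the pooled AUC
    downward under the null.
    """
    yv = np.asarray(y, dtype=np.float64)
    base = float(np.clip(yv.mean(), 1e-9, 1 - 1e-9))
    sw = np.where(yv == 1, 0.5 / base, 0.5 / (1.0 - base))
    X = np.column_stack([d, np.ones_like(d)])
    w = np.array([1.0, 0.0])
    for _ in range(max_iter):
        z = np.clip(X @ w, -35.0, 35.0)
        p = 1.0 / (1.0 + np.exp(-z))
        grad = X.T @ (sw * (p - yv)) + ridge * w
        weights = np.maximum(sw * p * (1.0 - p), 1e-12)
        hess = (X * weights[:, None]).T @ X + ridge * np.eye(2)
        step = np.linalg.solve(hess, grad)
        w = w - step
        if np.abs(step).max() < 1e-10:
            break
    return float(w[0]), float(w[1])


def _sigmoid_proba(ab: tuple[float, float], d: np.ndarray) -> np.ndarray:
    z = np.clip(ab[0] * d + ab[1], -35.0, 35.0)
    return 1.0 / (1.0 + np.exp(-z))


def fit_fold(X_train: np.ndarray, y_train: np.ndarray, cfg: CVConfig,
             seed: int = 0) -> FoldModel:
    """Fit standardization -> PCA -> inner C-grid search -> SVM + calibrator.

    All statistics come from the training rows only.  PCA keeps the smallest
    number of components reaching ``pca_variance`` of the training variance
    (capped at n_train - 1); the C grid is scored by AUC of pooled
    inner-fold decision values, ties going to the larger C; a sigmoid
    calibrator (logistic fit on those same held-out decision values) maps
    decisions to probabilities.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.int64)
    classes = np.unique(y_train)
    if classes.size != 2:
        raise ClassifierError("single-class training fold: stratification bug")
    n = X_train.shape[0]

    if cfg.standardize:
        mean = X_train.mean(axis=0)
        scale = np.maximum(X_train.std(axis=0), 1e-8)
    else:
        mean = np.zeros(X_train.shape[1])
        scale = np.ones(X_train.shape[1])
    # single precision for the wide (n x p) intermediates: the Gram spectrum
    # and projections are accurate to ~1e-6 relative, far below any
    # statistical resolution here, at half the memory traffic
    Xs = ((X_train - mean) / scale).astype(np.float32)
    pca_mean = Xs.mean(axis=0, dtype=np.float64).astype(np.float32)
    Xc = Xs - pca_mean

    # PCA via the Gram matrix (exact for n << p)
    gram = (Xc @ Xc.T).astype(np.float64)
    eigvals, eigvecs = np.linalg.eigh(gram)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.maximum(eigvals[order], 0.0)
    eigvecs = eigvecs[:, order]
    total = eigvals.sum()
    if total <= 0:
        raise ClassifierError("degenerate training fold: zero variance")
    ratio = np.cumsum(eigvals) / total
    k = int(np.searchsorted(ratio, cfg.pca_variance - 1e-12) + 1)
    k = min(k, n - 1, int(np.sum(eigvals > total * 1e-12)))
    k = max(k, 1)
    sv = np.sqrt(eigvals[:k])
    components = (Xc.T @ eigvecs[:, :k].astype(np.float32)) / sv.astype(np.float32)
    Z = eigvecs[:, :k] * sv                    # training scores (float64)

    # inner C-grid search on pooled held-out decision values
    inner = StratifiedKFold(n_splits=cfg.inner_folds, shuffle=True,
                            random_state=int(seed) % (2**31))
    splits = list(inner.split(Z, y_train))
    c_grid = tuple(sorted(cfg.c_grid))
    pooled = {c: np.empty(n) for c in c_grid}
    for train_idx, test_idx in splits:
        w_prev = None
        for c in c_grid:  # ascending C: warm-start each fit from the last
            w_prev = _fit_linear_svc(Z[train_idx], y_train[train_idx], c, w0=w_prev)
            pooled[c][test_idx] = _svc_decision(w_prev, Z[test_idx])
    aucs = {c: roc_auc(pooled[c], y_train) for c in c_grid}
    best_auc = max(aucs.values())
    # ties go to the LARGEST tying C: ties arise in (near-)separable folds,
    # where heavier regularization shrinks decision values toward zero and
    # makes pooled cross-fold probabilities incomparable
    chosen_c = max(c for c in c_grid if aucs[c] >= best_auc - 1e-12)

    sigmoid_ab = _fit_sigmoid(pooled[chosen_c], y_train)
    svm_w = _fit_linear_svc(Z, y_train, chosen_c)
    return FoldModel(mean=mean, scale=scale, components=components,
                     pca_mean=pca_mean, chosen_c=chosen_c, svm_w=svm_w,
                     sigmoid_ab=sigmoid_ab, n_components=k)


def predict_scores(model: FoldModel, X: np.ndarray) -> np.ndarray:
    """Positive-class probabilities for new rows under a fitted fold model."""
    Xs = ((np.asarray(X, dtype=np.float64) - model.mean) / model.scale).astype(np.float32)
    Z = ((Xs - model.pca_mean) @ model.components).astype(np.float64)
    return _sigmoid_proba(model.sigmoid_ab, _svc_decision(model.svm_w, Z))


# ---------------------------------------------------------------------------
# Repeated CV
# ---------------------------------------------------------------------------

def _rep_seeds(seed: int, rep: int) -> tuple[int, int]:
    state = np.random.SeedSequence([int(seed) % (2**31), rep]).generate_state(2)
    return int(state[0] % (2**31)), int(state[1] % (2**31))


def single_repetition(dm: DesignMatrix, cfg: CVConfig, rep: int = 0) -> RepetitionResult:
    """One full outer-fold pass; every speaker scored exactly once."""
    fold_seed, inner_seed = _rep_seeds(cfg.seed, rep)
    assignment = stratified_folds(dm.y, cfg.outer_folds, fold_seed)
    scores = np.empty(dm.y.size)
    chosen = []
    for fold in range(cfg.outer_folds):
        test = assignment == fold
        model = fit_fold(dm.X[~test], dm.y[~test], cfg, seed=inner_seed + fold)
        scores[test] = predict_scores(model, dm.X[test])
        chosen.append(model.chosen_c)
    predicted = (scores >= 0.5).astype(np.int64)
    acc, sens, spec = confusion_stats(predicted, dm.y)
    return RepetitionResult(scores=scores, predicted=predicted,
                            auc=roc_auc(scores, dm.y), acc=acc, sens=sens,
                            spec=spec, chosen_c=chosen)


def repeated_nested_cv(dm: DesignMatrix, cfg: CVConfig) -> list[RepetitionResult]:
    """``cfg.repeats`` independent repetitions, deterministic given cfg.seed."""
    return [single_repetition(dm, cfg, rep=r) for r in range(cfg.repeats)]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def roc_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ClassifierError("AUC undefined: both classes must be present")
    ranks = rankdata(scores, method="average")
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def confusion_stats(predicted: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(accuracy, sensitivity = positive recall, specificity = negative recall)."""
    predicted = np.asarray(predicted)
    y = np.asarray(y)
    if predicted.shape != y.shape:
        raise ClassifierError("predicted and y must have the same length")
    acc = float(np.mean(predicted == y))
    sens = float(np.mean(predicted[y == 1] == 1)) if (y == 1).any() else float("nan")
    spec = float(np.mean(predicted[y == 0] == 0)) if (y == 0).any() else float("nan")
    return acc, sens, spec


def _confusion_matrix(predicted: np.ndarray, y: np.ndarray) -> np.ndarray:
    cm = np.zeros((2, 2), dtype=np.int64)
    for t in (0, 1):
        for p in (0, 1):
            cm[t, p] = int(np.sum((y == t) & (predicted == p)))
    return cm


def summarize(results: Sequence[RepetitionResult],
              y: np.ndarray) -> ClassificationSummary:
    """Median-AUC repetition statistics + confusion counts over all repetitions.

    The accuracy/sensitivity/specificity reported at the top level belong to
    the median-AUC repetition; the aggregated confusion matrix sums hard
    predictions over every repetition (its entries total repeats x speakers).
    """
    if len(results) == 0:
        raise ClassifierError("summarize requires at least one repetition")
    aucs = np.array([r.auc for r in results])
    order = np.argsort(aucs, kind="stable")
    med = int(order[len(results) // 2])
    agg = np.zeros((2, 2), dtype=np.int64)
    y = np.asarray(y)
    for r in results:
        agg += _confusion_matrix(r.predicted, y)
    m = results[med]
    return ClassificationSummary(
        median_auc=float(m.auc), acc=m.acc, sens=m.sens, spec=m.spec,
        auc_distribution=aucs, aggregated_confusion=agg, median_repetition=med,
    )
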