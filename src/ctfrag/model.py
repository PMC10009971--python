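"""Gradient-boosted classification and evaluation.

The 17-feature matrix is classified with gradient-boosted trees. Performance
is estimated by leave-one-out cross-validation (LOOCV): each sample is scored
by a model trained on all other samples, with hyperparameters chosen by a
grid search nested inside the training fold only (inner stratified 5-fold
CV on AUC), so neither the held-out sample nor the validation cohort ever
influences model selection. The operating threshold maximizes Youden's
J = sensitivity + specificity - 1 on the out-of-fold discovery scores and is
frozen before touching the validation cohort.

Every fit uses class-balancing sample weights so that removing one sample in
LOOCV does not shift the effective class prior of the training fold (the
classical source of pessimistic bias in leave-one-out ROC estimates).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

DEFAULT_GRID: dict[str, list] = {
    "max_depth": [2, 3],
    "learning_rate": [0.1, 0.3],
    "n_estimators": [50, 100],
    "subsample": [1.0],
}


@dataclass
class ModelConfig:
    """Hyperparameter grid and seeding for the boosted-tree classifier."""

    grid: dict[str, list] = field(default_factory=lambda: dict(DEFAULT_GRID))
    rng_seed: int = 0
    inner_folds: int = 5

    def __post_init__(self) -> None:
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("hyperparameter grid must be non-empty")

    def combinations(self) -> list[dict]:
        keys = sorted(self.grid)
        return [dict(zip(keys, vals)) for vals in itertools.product(*(self.grid[k] for k in keys))]


@dataclass
class RocResult:
    """Out-of-fold scores with the ROC curve and Youden operating point."""

    scores: np.ndarray
    y: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    youden_threshold: float
    sensitivity: float
    specificity: float


def _make_estimator(params: dict, seed: int) -> XGBClassifier:
    # exact splits use midpoints between observations, which generalize
    # better than histogram bin edges at this tiny sample scale
    return XGBClassifier(
        tree_method="exact",
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
        **params,
    )


def _balanced_weights(y: np.ndarray) -> np.ndarray:
    w = np.empty(y.size, dtype=float)
    for cls in (0, 1):
        m = y == cls
        w[m] = y.size / (2.0 * m.sum())
    return w


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")


def _inner_cv_auc(X: np.ndarray, y: np.ndarray, params: dict, config: ModelConfig) -> float:
    folds = min(config.inner_folds, int(np.bincount(y).min()))
    skf = StratifiedKFold(n_splits=max(2, folds), shuffle=True, random_state=config.rng_seed)
    scores = np.empty(y.size)
    for tr, te in skf.split(X, y):
        if len(np.unique(y[tr])) < 2:
            return 0.5
        est = _make_estimator(params, config.rng_seed)
        est.fit(X[tr], y[tr], sample_weight=_balanced_weights(y[tr]))
        scores[te] = est.predict_proba(X[te])[:, 1]
    return _auc_from_scores(scores, y)


def grid_search_fit(X: np.ndarray, y: np.ndarray, config: ModelConfig) -> XGBClassifier:
    """Select hyperparameters by inner stratified CV on AUC (first-listed
    combination wins ties) and fit on all supplied rows."""
    _check_two_classes(y)
    combos = config.combinations()
    if len(combos) == 1:
        best = combos[0]
    else:
        aucs = [_inner_cv_auc(X, y, p, config) for p in combos]
        best = combos[int(np.argmax(aucs))]
    est = _make_estimator(best, config.rng_seed)
    est.fit(X, y, sample_weight=_balanced_weights(y))
    return est


def loocv_scores(
    X: np.ndarray, y: np.ndarray, config: ModelConfig, search: bool = True
) -> np.ndarray:
    """Out-of-fold probability for every sample under leave-one-out CV.

    With ``search=False`` the first grid combination is used in every fold
    (no inner selection); deterministic for a fixed seed either way.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if y.size < 4:
        raise ValueError("need at least 4 samples for LOOCV")
    _check_two_classes(y)
    cfg = config if search else ModelConfig(
        grid={k: v[:1] for k, v in config.grid.items()}, rng_seed=config.rng_seed,
        inner_folds=config.inner_folds,
    )
    scores = np.empty(y.size)
    for i in range(y.size):
        mask = np.ones(y.size, dtype=bool)
        mask[i] = False
        est = grid_search_fit(X[mask], y[mask], cfg)
        scores[i] = est.predict_proba(X[i : i + 1])[:, 1][0]
    return scores


# ---------------------------------------------------------------------------
# ROC / thresholding


def _roc_points(scores: np.ndarray, y: np.ndarray):
    """Threshold sweep over the unique scores (positive call: score >= t).

    Returns (fpr, tpr, thresholds) anchored at (0,0); tied scores move both
    rates in one step, which makes the trapezoidal AUC equal the normalized
    Mann-Whitney U statistic.
    """
    thresholds = np.unique(scores)[::-1]
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        call = scores >= t
        tpr.append(((y == 1) & call).sum() / n_pos)
        fpr.append(((y == 0) & call).sum() / n_neg)
    return np.array(fpr), np.array(tpr), np.concatenate([[np.inf], thresholds])


def _auc_from_scores(scores: np.ndarray, y: np.ndarray) -> float:
    fpr, tpr, _ = _roc_points(scores, y)
    return float(np.trapezoid(tpr, fpr))


def roc_auc(scores: np.ndarray, y: np.ndarray) -> RocResult:
    """ROC analysis of a score vector: curve, trapezoidal AUC, Youden
    threshold and the sensitivity/specificity it attains."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_two_classes(y)
    if np.unique(scores).size == 1:
        warnings.warn("constant scores: AUC is 0.5 by convention", stacklevel=2)
    fpr, tpr, thr = _roc_points(scores, y)
    auc = float(np.trapezoid(tpr, fpr))
    t = youden_threshold_from_curve(tpr, fpr, thr)
    sens, spec = sens_spec_at(t, scores, y)
    return RocResult(
        scores=scores, y=y, fpr=fpr, tpr=tpr, thresholds=thr,
        auc=auc, youden_threshold=t, sensitivity=sens, specificity=spec,
    )


def youden_threshold_from_curve(
    tpr: np.ndarray, fpr: np.ndarray, thresholds: np.ndarray
) -> float:
    """Threshold maximizing J = TPR - FPR over the finite candidates; ties
    break toward the higher threshold (higher specificity)."""
    j = tpr - fpr
    finite = np.isfinite(thresholds)
    j, thresholds = j[finite], thresholds[finite]
    # tolerance absorbs float jitter between mathematically tied J values;
    # thresholds are sorted descending, so the first near-maximal J is the
    # highest cut
    best = np.flatnonzero(j >= j.max() - 1e-12)
    return float(thresholds[best[0]])


def youden_threshold(roc: RocResult) -> float:
    return roc.youden_threshold


def sens_spec_at(threshold: float, scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sensitivity and specificity calling positive when score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_two_classes(y)
    call = scores >= threshold
    tp = int(((y == 1) & call).sum())
    fn = int(((y == 1) & ~call).sum())
    tn = int(((y == 0) & ~call).sum())
    fp = int(((y == 0) & call).sum())
    return tp / (tp + fn), tn / (tn + fp)


def external_validate(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: ModelConfig,
    frozen_threshold: float,
    train_ids: np.ndarray | None = None,
    val_ids: np.ndarray | None = None,
) -> RocResult:
    """Fit once on the full discovery cohort, score the independent
    validation cohort, and report AUC plus sensitivity/specificity at the
    threshold frozen from discovery. No refitting or rethresholding."""
    if train_ids is not None and val_ids is not None:
        overlap = set(map(str, train_ids)) & set(map(str, val_ids))
        if overlap:
            raise ValueError(f"cohorts overlap: {sorted(overlap)[:5]}")
    est = grid_search_fit(np.asarray(X_train, float), np.asarray(y_train, int), config)
    scores = est.predict_proba(np.asarray(X_val, float))[:, 1]
    y_val = np.asarray(y_val, int)
    _check_two_classes(y_val)
    fpr, tpr, thr = _roc_points(scores, y_val)
    sens, spec = sens_spec_at(frozen_threshold, scores, y_val)
    return RocResult(
        scores=scores, y=y_val, fpr=fpr, tpr=tpr, thresholds=thr,
        auc=float(np.trapezoid(tpr, fpr)), youden_threshold=frozen_threshold,
        sensitivity=sens, specificity=spec,
    )


def permutation_null_aucs(
    X: np.ndarray, y: np.ndarray, config: ModelConfig, n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """LOOCV AUC under label permutation (fixed hyperparameters, no inner
    search) — the chance-level reference for the observed AUC."""
    aucs = np.empty(n_permutations)
    for k in range(n_permutations):
        yp = rng.permutation(y)
        while len(np.unique(yp)) < 2:  # pragma: no cover - only for tiny y
            yp = rng.permutation(y)
        s = loocv_scores(X, yp, config, search=False)
        aucs[k] = _auc_from_scores(s, yp)
    return aucs


# ---------------------------------------------------------------------------
# group comparison


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    # pairwise count with half credit for ties
    return float((a[:, None] > b[None, :]).sum() + 0.5 * (a[:, None] == b[None, :]).sum())


def compare_feature_groups(
    values_cancer: np.ndarray, values_healthy: np.ndarray, exact_max_n: int = 12
) -> float:
    """One-tailed Mann-Whitney U p-value (alternative: cancer > healthy).

    Small samples (n1 + n2 <= ``exact_max_n``) use exact enumeration over all
    group assignments of the pooled values (ties get half credit, so tied
    data are handled without correction terms); larger samples use the
    normal approximation with tie correction and continuity correction.
    """
    a = np.asarray(values_cancer, dtype=float)
    b = np.asarray(values_healthy, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size + b.size <= exact_max_n:
        pooled = np.concatenate([a, b])
        u_obs = _u_statistic(a, b)
        count = 0
        total = 0
        for idx in itertools.combinations(range(pooled.size), a.size):
            sel = np.zeros(pooled.size, dtype=bool)
            sel[list(idx)] = True
            if _u_statistic(pooled[sel], pooled[~sel]) >= u_obs - 1e-12:
                count += 1
            total += 1
        return count / total
    res = stats.mannwhitneyu(a, b, alternative="greater", method="asymptotic")
    return float(res.pvalue)


def mann_whitney_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Normalized U statistic U / (n1 * n0) — the rank-based AUC identity
    used as the independent cross-check of :func:`roc_auc`."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    return _u_statistic(scores[y == 1], scores[y == 0]) / ((y == 1).sum() * (y == 0).sum())
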