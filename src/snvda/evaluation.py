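"""Choosing the sparsity K, estimating predictive performance, and testing
model significance by label permutation.

The sparsity level K (number of features retained per component) is tuned by
nested cross-validation: for every outer fold of a repeated 10-fold CV, an
inner 10-fold CV on the outer-training samples scores every candidate K, and
the inner-best K is recorded.  Fifteen repeats of 10 outer folds yield 150
selected values; the optimum is the (rounded) mode of a Gaussian kernel
density over those values — more robust than the raw histogram mode when
the grid is coarse.

Performance of the tuned model is then estimated by fifteen fresh 10-fold
cross-validations: within each repeat, held-out continuous scores are pooled
across the 10 folds, giving one AUC, one predictive accuracy and one
sensitivity per group per repeat; the summary is the mean over repeats with
a normal-approximation 95% CI.

Significance is a permutation test: each of (default) 1000 tests permutes
the group labels, runs one 10-fold CV at the tuned K, and records the pooled
AUC; the p-value is the fraction of permuted AUCs at or above the true AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

from .matrix import SnvMatrix
from .splsda import (
    SplsdaModel,
    _centered_dummy,
    _na_cov_with_y,
    _na_matvec,
    fit_splsda_raw,
    impute_test_na,
    predict_splsda,
    soft_threshold_top_k,
    standardize_fit,
)

# ---------------------------------------------------------------------------
# Designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CvDesign:
    """Repeated, stratified k-fold cross-validation design."""

    n_folds: int = 10
    n_repeats: int = 15
    stratified: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass(frozen=True)
class KGrid:
    """Candidate K values: k_min..k_max every ``step``."""

    k_min: int
    k_max: int
    step: int = 1

    def __post_init__(self) -> None:
        if self.k_min < 1 or self.step < 1 or self.k_max < self.k_min:
            raise ValueError(f"invalid K grid {self.k_min}:{self.k_max}:{self.step}")

    def values(self, n_features: int | None = None) -> list[int]:
        ks = list(range(self.k_min, self.k_max + 1, self.step))
        if n_features is not None:
            ks = sorted({min(k, n_features) for k in ks})
        return ks


@dataclass
class KSelectionResult:
    selected_ks: list[int]
    density_grid: np.ndarray
    density_values: np.ndarray
    optimal_k: int


@dataclass
class PerformanceSummary:
    """Mean AUC with 95% CI, predictive accuracy and per-group sensitivities
    over repeated cross-validation, plus the per-repeat metric vectors."""

    auc_mean: float
    auc_ci_low: float
    auc_ci_high: float
    predictive_accuracy: float
    sensitivity: dict[str, float]
    per_repeat_auc: list[float]
    per_repeat_accuracy: list[float]
    per_repeat_sensitivity: dict[str, list[float]]


@dataclass
class PermutationResult:
    n_perm: int
    true_auc: float
    permuted_aucs: list[float]
    p_value: float

    @property
    def p_display(self) -> str:
        """Paper-style display: a zero count is reported as "<1/n_perm"."""
        if self.p_value == 0.0:
            return f"<{1.0 / self.n_perm:g}"
        return f"{self.p_value:g}"


# ---------------------------------------------------------------------------
# Fold construction
# ---------------------------------------------------------------------------


def stratified_fold_ids(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Assign each sample a fold id 0..n_folds-1, dealing each class
    round-robin after a shuffle so per-fold class counts differ by <=1."""
    fold = np.empty(len(y), dtype=int)
    start = 0
    for g in np.unique(y):
        idx = np.flatnonzero(y == g)
        rng.shuffle(idx)
        fold[idx] = (np.arange(len(idx)) + start) % n_folds
        start += len(idx)  # stagger so small classes spread over all folds
    return fold


def _fold_ids(y: np.ndarray, design_folds: int, stratified: bool, rng) -> np.ndarray:
    n = len(y)
    n_folds = min(design_folds, n)
    if stratified:
        return stratified_fold_ids(y, n_folds, rng)
    perm = rng.permutation(n)
    fold = np.empty(n, dtype=int)
    fold[perm] = np.arange(n) % n_folds
    return fold


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------


def auc_of_scores(scores, labels, positive) -> float:
    """Area under the ROC curve via the Mann-Whitney pair statistic: the
    fraction of (positive, negative) pairs ordered correctly, ties half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)  # midranks handle ties at 1/2 per pair
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Single-component fast CV path
# ---------------------------------------------------------------------------


def _multi_k_test_scores(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    ks: list[int],
    groups: tuple[str, str],
) -> np.ndarray:
    """Continuous group_B-positive scores of test samples for every K at once.

    One standardization and one dense weight vector serve all Ks, since the
    sparsity operator only re-thresholds the same dense direction.  Single
    component (the default model).
    """
    params = standardize_fit(X_train)
    Zt = params.transform(X_train)
    yc = _centered_dummy(y_train, groups)
    w_dense = _na_cov_with_y(Zt, yc)

    # imputation fill = mean of the two training-group standardized means
    import warnings as _warnings

    fill = np.zeros(Zt.shape[1])
    gm = np.full((2, Zt.shape[1]), np.nan)
    for gi, g in enumerate(groups):
        rows = Zt[y_train == g]
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            gm[gi] = np.nanmean(rows, axis=0)
    for gi in (0, 1):
        miss = np.isnan(gm[gi])
        gm[gi, miss] = gm[1 - gi, miss]
    fill = np.nan_to_num(gm).mean(axis=0)

    Zs = params.transform(X_test)
    nan_mask = np.isnan(Zs)
    Zs[nan_mask] = np.broadcast_to(fill, Zs.shape)[nan_mask]

    W = np.zeros((Zt.shape[1], len(ks)))
    q = np.zeros(len(ks))
    for j, k in enumerate(ks):
        w = soft_threshold_top_k(w_dense, k)
        t = _na_matvec(Zt, w)
        tt = float(t @ t)
        W[:, j] = w
        q[j] = (float(t @ yc) / tt) if tt > 0 else 0.0
    return (Zs @ W) * q


def _cv_pooled_scores(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    fold_ids: np.ndarray,
    groups: tuple[str, str],
    n_components: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Held-out continuous scores and predicted labels for every sample of a
    single k-fold CV (samples x features input)."""
    scores = np.zeros(len(y))
    labels = np.empty(len(y), dtype=object)
    for f in np.unique(fold_ids):
        test = fold_ids == f
        train = ~test
        if len(np.unique(y[train])) < 2:
            raise ValueError("a training split lost a class; use stratified folds")
        if n_components == 1:
            s = _multi_k_test_scores(X[train], y[train], X[test], [k], groups)[:, 0]
            scores[test] = s
            labels[test] = np.where(s > 0, groups[1], groups[0])
        else:
            model = fit_splsda_raw(X[train], y[train], k, n_components=n_components)
            s, lab = predict_splsda(model, X[test])
            scores[test] = s
            labels[test] = lab
    return scores, labels


def _matrix_xy(m: SnvMatrix) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    m.check_modelable()
    X = m.values.to_numpy(dtype=float).T  # samples x features
    y = m.labels.to_numpy()
    groups = tuple(m.groups)
    return X, y, groups  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Nested CV selection of K
# ---------------------------------------------------------------------------


def nested_cv_select_k(
    m: SnvMatrix,
    grid: KGrid,
    design: CvDesign = CvDesign(),
    inner_folds: int = 10,
    bandwidth: float | None = None,
) -> KSelectionResult:
    """Nested cross-validation selection of the sparsity K.

    For each outer fold of each repeat, every K in the grid is scored by an
    inner ``inner_folds``-fold CV on the outer-training samples (held-out
    scores pooled over inner folds, one AUC per K); the inner-best K (ties
    broken toward the smaller, more parsimonious K) is recorded.  The
    optimum is the kernel-density mode of all recorded Ks.
    """
    X, y, groups = _matrix_xy(m)
    ks = grid.values(X.shape[1])
    rng = np.random.default_rng(design.rng_seed)
    selected: list[int] = []
    for _rep in range(design.n_repeats):
        outer = _fold_ids(y, design.n_folds, design.stratified, rng)
        for f in np.unique(outer):
            tr = outer != f
            X_tr, y_tr = X[tr], y[tr]
            _, class_counts = np.unique(y_tr, return_counts=True)
            if len(class_counts) < 2 or class_counts.min() < 2:
                logger.warning("outer fold %d skipped: a class has <2 training samples", f)
                continue
            inner = _fold_ids(y_tr, inner_folds, design.stratified, rng)
            pooled = np.zeros((len(y_tr), len(ks)))
            for g in np.unique(inner):
                ite = inner == g
                pooled[ite] = _multi_k_test_scores(
                    X_tr[~ite], y_tr[~ite], X_tr[ite], ks, groups
                )
            aucs = [auc_of_scores(pooled[:, j], y_tr, groups[1]) for j in range(len(ks))]
            best = ks[int(np.argmax(aucs))]  # argmax takes first (smallest K) on ties
            selected.append(best)
    grid_x, dens, k_opt = _kde_mode(np.asarray(selected, dtype=float), bandwidth)
    return KSelectionResult(
        selected_ks=selected,
        density_grid=grid_x,
        density_values=dens,
        optimal_k=k_opt,
    )


def _bw_nrd0(x: np.ndarray) -> float:
    """Silverman rule-of-thumb bandwidth (R's ``bw.nrd0``)."""
    n = len(x)
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    lo = min(sd, iqr / 1.34)
    if lo == 0.0:
        lo = sd or abs(float(x[0])) or 1.0
    return 0.9 * lo * n ** (-0.2)


def _kde_mode(
    x: np.ndarray, bandwidth: float | None = None, n_grid: int = 512
) -> tuple[np.ndarray, np.ndarray, int]:
    if len(x) == 0:
        raise ValueError("no selected K values")
    if np.ptp(x) == 0.0:
        v = int(round(float(x[0])))
        return np.array([float(v)]), np.array([1.0]), v
    bw = bandwidth if bandwidth is not None else _bw_nrd0(x)
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, n_grid)
    z = (grid[:, None] - x[None, :]) / bw
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (len(x) * bw * np.sqrt(2 * np.pi))
    k_opt = max(1, int(round(float(grid[np.argmax(dens)]))))
    return grid, dens, k_opt


def optimal_k_from_density(
    selected_ks: list[int] | np.ndarray, bandwidth: float | None = None
) -> int:
    """Rounded argmax of a Gaussian KDE over the selected K values."""
    _, _, k_opt = _kde_mode(np.asarray(selected_ks, dtype=float), bandwidth)
    return k_opt


# ---------------------------------------------------------------------------
# Repeated-CV evaluation
# ---------------------------------------------------------------------------


def evaluate_model(
    m: SnvMatrix,
    k: int,
    design: CvDesign = CvDesign(),
    n_components: int = 1,
) -> PerformanceSummary:
    """Repeated stratified 10-fold CV at a fixed K.

    Within each repeat, held-out scores are pooled over the folds before the
    AUC is computed (fold-level AUCs can be undefined when a fold holds one
    class); accuracy and sensitivities are computed from the pooled hard
    labels.  The 95% CI is mean +/- 1.96 sd / sqrt(n_repeats).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X, y, groups = _matrix_xy(m)
    rng = np.random.default_rng(design.rng_seed)
    aucs, accs = [], []
    sens: dict[str, list[float]] = {g: [] for g in groups}
    for _rep in range(design.n_repeats):
        folds = _fold_ids(y, design.n_folds, design.stratified, rng)
        scores, labels = _cv_pooled_scores(X, y, k, folds, groups, n_components)
        aucs.append(auc_of_scores(scores, y, groups[1]))
        accs.append(float(np.mean(labels == y)))
        for g in groups:
            mask = y == g
            sens[g].append(float(np.mean(labels[mask] == y[mask])))
    auc_mean = float(np.mean(aucs))
    sd = float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0
    half = 1.96 * sd / np.sqrt(len(aucs))
    return PerformanceSummary(
        auc_mean=auc_mean,
        auc_ci_low=auc_mean - half,
        auc_ci_high=auc_mean + half,
        predictive_accuracy=float(np.mean(accs)),
        sensitivity={g: float(np.mean(v)) for g, v in sens.items()},
        per_repeat_auc=[float(a) for a in aucs],
        per_repeat_accuracy=[float(a) for a in accs],
        per_repeat_sensitivity={g: [float(x) for x in v] for g, v in sens.items()},
    )


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------


def permutation_test(
    m: SnvMatrix,
    k: int,
    true_auc: float,
    n_perm: int = 1000,
    design: CvDesign = CvDesign(),
    n_components: int = 1,
) -> PermutationResult:
    """Label-permutation null of the cross-validated AUC.

    Each test permutes the sample labels uniformly, runs one stratified
    ``design.n_folds``-fold CV at the tuned K with a fresh fold split, and
    records the pooled AUC.  p = #(permuted AUC >= true AUC) / n_perm.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X, y, groups = _matrix_xy(m)
    rng = np.random.default_rng(design.rng_seed)
    perm_aucs = []
    for _i in range(n_perm):
        y_perm = rng.permutation(y)
        folds = _fold_ids(y_perm, design.n_folds, design.stratified, rng)
        scores, _labels = _cv_pooled_scores(X, y_perm, k, folds, groups, n_components)
        perm_aucs.append(auc_of_scores(scores, y_perm, groups[1]))
    count = int(np.sum(np.asarray(perm_aucs) >= true_auc))
    return PermutationResult(
        n_perm=n_perm,
        true_auc=float(true_auc),
        permuted_aucs=[float(a) for a in perm_aucs],
        p_value=count / n_perm,
    )
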