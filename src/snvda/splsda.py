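"""Sparse PLS-DA for two-class problems, tolerant of missing values.

PLS-DA regresses a dummy-coded class response Y on the feature matrix X
through latent components; the sparse variant retains exactly K features per
component by soft-thresholding the dense weight vector at the (K+1)-th
largest absolute value (survivors are shrunk by the threshold and the vector
renormalised), so the model both classifies and selects features.

Missing values (NA = inadequate read coverage) are handled asymmetrically,
matching how they arise: during training, inner products are NA-aware — a
sum over observed entries is rescaled by (number of terms in the full sum) /
(number observed), the NIPALS convention — while test data must be complete,
so NAs in a test sample are imputed with the mean of the two training-group
means of the standardized feature ("mean of the means").

With two classes the centered dummy response has rank one, so the dense
weight direction is proportional to X^T y_c where y_c is the centered
indicator of the second group; one component is the default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


@dataclass
class StandardizationParams:
    """Per-feature mean and standard deviation over observed training entries.

    Features observed in fewer than two samples or with zero variance are
    flagged constant; they standardize to all-zeros and can never be selected.
    """

    mean: np.ndarray
    sd: np.ndarray
    constant: np.ndarray  # boolean flag per feature

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Standardize (columns = features may hold NaN; NaN stays NaN)."""
        sd_safe = np.where(self.constant, 1.0, self.sd)
        Z = (X - self.mean) / sd_safe
        Z[:, self.constant] = np.where(
            np.isnan(X[:, self.constant]), np.nan, 0.0
        )
        return Z


def standardize_fit(X: np.ndarray, ddof: int = 1) -> StandardizationParams:
    """Fit per-feature mean/sd over non-NA entries of a samples x features array."""
    if X.shape[0] < 2:
        raise ValueError("standardization requires at least 2 samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN feature slices
        mean = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0, ddof=ddof)
    n_obs = np.sum(~np.isnan(X), axis=0)
    constant = ~(sd > _EPS) | (n_obs < 2)
    mean = np.where(n_obs > 0, mean, 0.0)
    sd = np.where(constant, 0.0, sd)
    return StandardizationParams(mean=mean, sd=sd, constant=constant)


# ---------------------------------------------------------------------------
# Sparsity operator
# ---------------------------------------------------------------------------


def soft_threshold_top_k(w: np.ndarray, keep_k: int) -> np.ndarray:
    """Keep the ``keep_k`` largest-|w| entries, shrink them by the (K+1)-th
    largest absolute value, and renormalise to unit Euclidean norm.

    Ties at the K-th largest magnitude are broken toward the lower feature
    index (stable ordering), and a survivor whose shrunk magnitude would be
    exactly zero is kept at a tiny sign-preserving value so the nonzero count
    is exactly min(K, p).
    """
    p = w.size
    k = min(keep_k, p)
    if k <= 0:
        raise ValueError("keep_k must be >= 1")
    order = np.argsort(-np.abs(w), kind="stable")
    out = np.zeros_like(w, dtype=float)
    survivors = order[:k]
    lam = np.abs(w[order[k]]) if k < p else 0.0
    shrunk = np.abs(w[survivors]) - lam
    shrunk = np.where(shrunk > 0, shrunk, _EPS)  # boundary ties survive
    out[survivors] = np.sign(w[survivors]) * shrunk
    nrm = np.linalg.norm(out)
    if nrm > 0:
        out /= nrm
    return out


# ---------------------------------------------------------------------------
# NA-aware linear algebra
# ---------------------------------------------------------------------------


def _na_matvec(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise inner products X @ w over observed entries, each rescaled by
    (#features with nonzero weight) / (#those observed in the row)."""
    active = w != 0
    n_active = int(active.sum())
    Xa = X[:, active]
    obs = ~np.isnan(Xa)
    n_obs = obs.sum(axis=1)
    t = np.nansum(Xa * w[active], axis=1)
    scale = np.where(n_obs > 0, n_active / np.maximum(n_obs, 1), 0.0)
    return t * scale


def _na_cov_with_y(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature inner product X^T y over observed entries, rescaled by
    n / n_observed per feature."""
    obs = ~np.isnan(X)
    n = X.shape[0]
    n_obs = obs.sum(axis=0)
    w = np.nansum(X * y[:, None], axis=0)
    return w * np.where(n_obs > 0, n / np.maximum(n_obs, 1), 0.0)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


@dataclass
class SplsdaModel:
    """A fitted sparse PLS-DA model for two groups.

    ``groups`` is the sorted pair (group_A, group_B); the continuous
    prediction score is the predicted dummy value for group_B minus group_A,
    so positive scores vote group_B.
    """

    groups: tuple[str, str]
    keep_k: int
    n_components: int
    weights: np.ndarray  # p x H sparse X-weights, unit norm per component
    x_loadings: np.ndarray  # p x H regression of X on scores
    scores: np.ndarray  # n x H training score vectors
    y_coef: np.ndarray  # H, regression of centered y on each score
    standardization: StandardizationParams
    group_means_std: np.ndarray  # 2 x p standardized training means per group
    train_prevalent: str  # tie-break label (larger training group)
    decision_rule: str = "max_dist"
    feature_names: list[str] | None = None

    @property
    def selected(self) -> np.ndarray:
        """Boolean mask of features with a nonzero weight in any component."""
        return (self.weights != 0).any(axis=1)


def _centered_dummy(y: np.ndarray, groups: tuple[str, str]) -> np.ndarray:
    ind_b = (y == groups[1]).astype(float)
    return ind_b - ind_b.mean()


def fit_splsda(
    X_std: np.ndarray,
    y: np.ndarray,
    keep_k: int,
    n_components: int = 1,
    standardization: StandardizationParams | None = None,
    feature_names: list[str] | None = None,
) -> SplsdaModel:
    """Fit sparse PLS-DA on a standardized samples x features matrix.

    ``X_std`` may contain NaN (training tolerates missingness); ``y`` holds
    the two group labels.  ``keep_k`` larger than the feature count is
    clamped with a warning.  Constant features (flagged in
    ``standardization``) carry zero weight by construction.
    """
    X_std = np.asarray(X_std, dtype=float)
    y = np.asarray(y)
    n, p = X_std.shape
    groups = tuple(sorted(np.unique(y).tolist()))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    if keep_k > p:
        logger.warning("keep_k=%d exceeds feature count %d; clamped", keep_k, p)
        keep_k = p
    yc = _centered_dummy(y, groups)

    Xh = X_std.copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    for h in range(n_components):
        w_dense = _na_cov_with_y(Xh, yc)
        if not np.any(w_dense):
            break
        w = soft_threshold_top_k(w_dense, keep_k)
        t = _na_matvec(Xh, w)
        tt = float(t @ t)
        if tt < _EPS:
            break
        p_load = _na_cov_with_y(Xh, t) / tt  # X^T t / t't, NA-aware
        q_h = float(t @ yc) / tt
        W[:, h], P[:, h], T[:, h], q[h] = w, p_load, t, q_h
        Xh = Xh - np.outer(t, p_load)  # NaN cells stay NaN

    counts = {g: int((y == g).sum()) for g in groups}
    prevalent = max(groups, key=lambda g: (counts[g], g))

    # standardized per-group means over observed entries (for test imputation)
    gm = np.zeros((2, p))
    for gi, g in enumerate(groups):
        rows = X_std[y == g]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m_g = np.nanmean(rows, axis=0)
        n_obs = np.sum(~np.isnan(rows), axis=0)
        gm[gi] = np.where(n_obs > 0, m_g, np.nan)
    # a group never observed for a feature falls back to the other group
    for gi in (0, 1):
        missing = np.isnan(gm[gi])
        if missing.any():
            logger.info(
                "%d feature(s) unobserved in group %s; imputation falls back "
                "to the other group's mean",
                int(missing.sum()),
                groups[gi],
            )
            gm[gi, missing] = gm[1 - gi, missing]
    gm = np.nan_to_num(gm)  # feature unobserved in both groups -> 0

    if standardization is None:
        standardization = StandardizationParams(
            mean=np.zeros(p), sd=np.ones(p), constant=np.zeros(p, dtype=bool)
        )
    return SplsdaModel(
        groups=groups,
        keep_k=keep_k,
        n_components=n_components,
        weights=W,
        x_loadings=P,
        scores=T,
        y_coef=q,
        standardization=standardization,
        group_means_std=gm,
        train_prevalent=prevalent,
        feature_names=feature_names,
    )


def fit_splsda_raw(
    X_raw: np.ndarray,
    y: np.ndarray,
    keep_k: int,
    n_components: int = 1,
    feature_names: list[str] | None = None,
) -> SplsdaModel:
    """Standardize a raw samples x features AF matrix, then fit."""
    params = standardize_fit(X_raw)
    return fit_splsda(
        params.transform(X_raw),
        y,
        keep_k,
        n_components=n_components,
        standardization=params,
        feature_names=feature_names,
    )


# ---------------------------------------------------------------------------
# Test-set imputation and prediction
# ---------------------------------------------------------------------------


def impute_test_na(X_test_std: np.ndarray, model: SplsdaModel) -> np.ndarray:
    """Fill NAs in a standardized test matrix with the mean of the two
    training-group means of that feature ("mean of the means")."""
    fill = model.group_means_std.mean(axis=0)
    out = X_test_std.copy()
    nan_mask = np.isnan(out)
    out[nan_mask] = np.broadcast_to(fill, out.shape)[nan_mask]
    return out


def predict_splsda(
    model: SplsdaModel, X_new: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Score new samples on the original AF scale (NA allowed).

    Returns ``(scores, labels)``: the continuous score is the predicted
    centered-dummy value for group_B minus group_A; the label is group_B
    where the score is positive, group_A where negative, and the more
    prevalent training group on an exact tie.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != model.weights.shape[0]:
        raise ValueError(
            f"feature mismatch: model has {model.weights.shape[0]} features, "
            f"input has {X_new.shape[1]}"
        )
    Z = model.standardization.transform(X_new)
    Z = impute_test_na(Z, model)
    # component-wise scoring with the training deflation replayed on Z
    pred = np.zeros(Z.shape[0])
    Zh = Z
    for h in range(model.n_components):
        t_new = Zh @ model.weights[:, h]
        pred += t_new * model.y_coef[h]
        Zh = Zh - np.outer(t_new, model.x_loadings[:, h])
    # pred estimates centered indicator of group_B; (B - A) dummy difference
    # is 2*pred, which shares its sign
    score = 2.0 * pred
    labels = np.where(
        score > 0,
        model.groups[1],
        np.where(score < 0, model.groups[0], model.train_prevalent),
    )
    return score, labels
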