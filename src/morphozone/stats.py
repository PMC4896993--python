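"""Multivariate statistics for aligned shape data.

Mean-shape tests (two-sample Hotelling T²), cross-validated discriminant
classification, permutation inference (Mantel test, multivariate regression of
shape on a covariate), between-group PCA ordination, shape-change-vector angle
tests, familywise-error control, and rank tests for size.

Every randomized procedure takes an explicit seed; there is no global random
state. Permutation p-values use the (b + 1)/(m + 1) estimator, so the smallest
attainable p at m permutations is 1/(m + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats as sps
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "HotellingResult",
    "RegressionResult",
    "AngleResult",
    "MantelResult",
    "pca_reduce",
    "hotelling_two_sample",
    "lda_loocv",
    "holm_adjust",
    "mantel_test",
    "ShapeCovariateRegression",
    "shape_regression_permutation",
    "BetweenGroupPCA",
    "between_group_pca",
    "angle_test",
    "pairwise_rank_test",
]


@dataclass
class HotellingResult:
    """Two-sample Hotelling T² with its F approximation."""

    t2: float
    f_stat: float
    df1: int
    df2: int
    p_raw: float
    p_adjusted: float | None = None


@dataclass
class RegressionResult:
    """Multivariate regression of shape on a scalar covariate."""

    coefficient_vector: np.ndarray
    pct_var_explained: float
    p_perm: float
    n_perm: int
    projection_scores: np.ndarray


@dataclass
class AngleResult:
    """Angle between two shape-change vectors with its random-direction null."""

    angle_deg: float
    dim: int
    p_raw: float
    p_adjusted: float | None = None


@dataclass
class MantelResult:
    """Correlation between two distance matrices with permutation p-value."""

    r: float
    p_perm: float
    n_perm: int


def pca_reduce(X: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Project onto the leading principal components of the sample covariance.

    Returns ``(scores, variance_fractions)`` where ``scores`` is N × n and
    ``variance_fractions`` holds the full spectrum's explained-variance
    fractions (descending, summing to 1).
    """
    X = np.asarray(X, float)
    n, d = X.shape
    if not 1 <= n_components <= min(n - 1, d):
        raise ValueError(
            f"n_components must be in [1, min(N-1, D)] = [1, {min(n - 1, d)}]"
        )
    if np.allclose(X, X[0], atol=1e-12):
        raise ValueError("X has zero variance; PCA is undefined")
    pca = PCA(n_components=None)
    scores = pca.fit_transform(X)
    return scores[:, :n_components], pca.explained_variance_ratio_


def hotelling_two_sample(X1: np.ndarray, X2: np.ndarray) -> HotellingResult:
    """Two-sample Hotelling T² test on p-variate observations.

    Uses the pooled covariance; the F statistic is
    ``T² (n1 + n2 − p − 1) / (p (n1 + n2 − 2))`` on ``(p, n1 + n2 − p − 1)``
    degrees of freedom.
    """
    X1 = np.atleast_2d(np.asarray(X1, float))
    X2 = np.atleast_2d(np.asarray(X2, float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("samples must share the number of variables")
    n1, p = X1.shape
    n2 = X2.shape[0]
    df2 = n1 + n2 - p - 1
    if df2 < 1:
        raise ValueError(
            f"need n1 + n2 − p − 1 ≥ 1 (got {df2}); reduce dimensionality"
        )
    diff = X1.mean(axis=0) - X2.mean(axis=0)
    s_pooled = ((n1 - 1) * np.cov(X1, rowvar=False) + (n2 - 1) * np.cov(X2, rowvar=False)) / (
        n1 + n2 - 2
    )
    s_pooled = np.atleast_2d(s_pooled)
    try:
        sol = np.linalg.solve(s_pooled, diff)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular pooled covariance; retain fewer components"
        ) from exc
    if not np.all(np.isfinite(sol)) or np.linalg.cond(s_pooled) > 1e12:
        raise ValueError("near-singular pooled covariance; retain fewer components")
    t2 = float(n1 * n2 / (n1 + n2) * diff @ sol)
    f_stat = t2 * df2 / (p * (n1 + n2 - 2))
    p_raw = float(sps.f.sf(f_stat, p, df2))
    return HotellingResult(t2=t2, f_stat=float(f_stat), df1=p, df2=df2, p_raw=p_raw)


def lda_loocv(scores: np.ndarray, labels: np.ndarray) -> float:
    """Leave-one-out misclassification rate of a two-class linear discriminant.

    For each specimen the discriminant (pooled within-class covariance,
    class-proportional priors) is refit on the remaining N − 1 specimens and
    used to classify the held-out one. Returns the fraction misclassified.
    """
    X = np.asarray(scores, float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {len(classes)}")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 members")
    centered = np.concatenate([X[y == c] - X[y == c].mean(axis=0) for c in classes])
    if np.linalg.matrix_rank(centered, tol=1e-10) < X.shape[1]:
        raise ValueError("singular within-class covariance; retain fewer components")
    n = X.shape[0]
    errors = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        clf = LinearDiscriminantAnalysis(solver="svd")
        clf.fit(X[mask], y[mask])
        if clf.predict(X[i : i + 1])[0] != y[i]:
            errors += 1
        mask[i] = True
    return errors / n


def holm_adjust(p_values) -> np.ndarray:
    """Holm–Bonferroni step-down adjustment, order-preserving, capped at 1."""
    p = np.asarray(p_values, float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        running_max = max(running_max, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running_max)
    return adjusted


def _check_distance_matrix(d: np.ndarray, name: str) -> np.ndarray:
    d = np.asarray(d, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError(f"{name} must have a zero diagonal")
    return d


def mantel_test(
    D1: np.ndarray, D2: np.ndarray, n_perm: int = 10000, seed: int | None = None
) -> MantelResult:
    """Mantel test of association between two distance matrices.

    ``r`` is the Pearson correlation of the upper-triangle entries; the
    two-sided p-value counts simultaneous row/column permutations of ``D2``
    with ``|r*| ≥ |r|``, using the (b + 1)/(n_perm + 1) estimator.
    """
    D1 = _check_distance_matrix(D1, "D1")
    D2 = _check_distance_matrix(D2, "D2")
    if D1.shape != D2.shape:
        raise ValueError("distance matrices must have the same shape")
    n = D1.shape[0]
    iu = np.triu_indices(n, k=1)
    v1 = D1[iu]

    def corr(mat: np.ndarray) -> float:
        return float(np.corrcoef(v1, mat[iu])[0, 1])

    r_obs = corr(D2)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if abs(corr(D2[np.ix_(perm, perm)])) >= abs(r_obs) - 1e-12:
            count += 1
    return MantelResult(r=r_obs, p_perm=(count + 1) / (n_perm + 1), n_perm=n_perm)


class ShapeCovariateRegression(BaseEstimator):
    """Multivariate regression of shape on a scalar covariate.

    ``fit`` regresses every shape coordinate on the covariate by least
    squares, reports the percentage of total shape variance the covariate
    predicts (summed over coordinates), and assesses significance by
    permuting the covariate across specimens ``n_perm`` times and counting
    permuted predicted sums of squares at least as large as the observed one.

    Attributes
    ----------
    coefficient_vector_ : ndarray (D,)
        Shape change per unit covariate.
    pct_var_explained_ : float
    p_perm_ : float
    projection_scores_ : ndarray (N,)
        Centered shapes projected onto the unit coefficient vector — the
        univariate visualization of the multivariate regression.
    """

    def __init__(self, n_perm: int = 10000, seed: int | None = None) -> None:
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ShapeCovariateRegression":
        X = np.asarray(X, float)
        z = np.asarray(y, float).ravel()
        n = X.shape[0]
        if z.shape[0] != n:
            raise ValueError("covariate length must match number of specimens")
        if n < 3:
            raise ValueError("need at least 3 specimens")
        if np.ptp(z) == 0:
            raise ValueError("covariate has zero variance")
        Xc = X - X.mean(axis=0)
        zc = z - z.mean()
        zz = float(zc @ zc)
        beta = Xc.T @ zc / zz
        ss_total = float(np.sum(Xc**2))
        if ss_total <= 0:
            raise ValueError("shapes have zero variance")
        ss_pred = float(np.sum((Xc.T @ zc) ** 2)) / zz

        rng = np.random.default_rng(self.seed)
        # all permuted predicted SS in one matrix product: (D,N) @ (N,m)
        perms = np.stack([rng.permutation(zc) for _ in range(self.n_perm)], axis=1)
        ss_perm = np.sum((Xc.T @ perms) ** 2, axis=0) / zz
        b = int(np.sum(ss_perm >= ss_pred - 1e-12 * max(ss_pred, 1.0)))

        self.coefficient_vector_ = beta
        self.mean_shape_ = X.mean(axis=0)
        self.mean_covariate_ = float(z.mean())
        self.pct_var_explained_ = 100.0 * ss_pred / ss_total
        self.p_perm_ = (b + 1) / (self.n_perm + 1)
        unit = beta / np.linalg.norm(beta) if np.linalg.norm(beta) > 0 else beta
        self.projection_scores_ = Xc @ unit
        return self

    def predict(self, z: np.ndarray) -> np.ndarray:
        """Expected shape at covariate values ``z``."""
        z = np.asarray(z, float).ravel()
        return self.mean_shape_ + np.outer(z - self.mean_covariate_, self.coefficient_vector_)

    def result_(self) -> RegressionResult:
        return RegressionResult(
            coefficient_vector=self.coefficient_vector_,
            pct_var_explained=self.pct_var_explained_,
            p_perm=self.p_perm_,
            n_perm=self.n_perm,
            projection_scores=self.projection_scores_,
        )


def shape_regression_permutation(
    X: np.ndarray, z: np.ndarray, n_perm: int = 10000, seed: int | None = None
) -> RegressionResult:
    """Functional wrapper over :class:`ShapeCovariateRegression`."""
    return ShapeCovariateRegression(n_perm=n_perm, seed=seed).fit(X, z).result_()


class BetweenGroupPCA(BaseEstimator, TransformerMixin):
    """Principal components of group mean shapes, with individual projection.

    The eigen-decomposition uses only the matrix of group means (unweighted),
    so the ordination is driven by between-group differences; ``transform``
    projects individual specimens onto the same axes.

    Attributes
    ----------
    components_ : ndarray (n_axes, D)
    group_scores_ : ndarray (G, n_axes)
    eigenvalues_ : ndarray (n_axes,)
    groups_ : ndarray (G,)
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BetweenGroupPCA":
        X = np.asarray(X, float)
        y = np.asarray(y)
        self.groups_ = np.unique(y)
        g = len(self.groups_)
        if g < 2:
            raise ValueError("between-group PCA needs at least 2 groups")
        means = np.stack([X[y == grp].mean(axis=0) for grp in self.groups_])
        self.grand_mean_ = means.mean(axis=0)
        centered = means - self.grand_mean_
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        n_axes = min(g - 1, X.shape[1])
        self.components_ = vt[:n_axes]
        self.eigenvalues_ = (s[:n_axes] ** 2) / max(g - 1, 1)
        self.group_scores_ = centered @ self.components_.T
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        return (X - self.grand_mean_) @ self.components_.T


def between_group_pca(
    X: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Between-group PCA: returns (axes, group scores, individual projections)."""
    est = BetweenGroupPCA().fit(X, labels)
    return est.components_, est.group_scores_, est.transform(X)


def random_direction_angle_cdf(angle_deg: float, dim: int) -> float:
    """P(angle ≤ θ) for two independent uniform random directions in R^dim.

    The null density is proportional to sin^(dim−2)θ on [0°, 180°]; the CDF is
    evaluated in closed form with the regularized incomplete beta function.
    """
    if dim < 2:
        raise ValueError("dim must be ≥ 2")
    theta = np.deg2rad(angle_deg)
    x = np.sin(theta) ** 2
    half = 0.5 * special.betainc((dim - 1) / 2.0, 0.5, x)
    return float(half if angle_deg <= 90.0 else 1.0 - half)


def angle_test(v1: np.ndarray, v2: np.ndarray, dim: int) -> AngleResult:
    """Angle between two shape-change vectors with a random-direction null.

    ``p_raw`` is the probability that two independent uniformly random
    directions in ``dim`` dimensions subtend an angle no larger than the
    observed one; small values indicate directions more parallel than chance.
    """
    v1 = np.asarray(v1, float).ravel()
    v2 = np.asarray(v2, float).ravel()
    if v1.shape != v2.shape:
        raise ValueError("vectors must have equal length")
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("angle undefined for a zero vector")
    cosine = float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))
    angle = float(np.degrees(np.arccos(cosine)))
    return AngleResult(
        angle_deg=angle, dim=dim, p_raw=random_direction_angle_cdf(angle, dim)
    )


def pairwise_rank_test(values: np.ndarray, labels: np.ndarray):
    """All-pairs two-sided Mann–Whitney tests with Holm correction.

    Returns a tidy table (list of dicts) with one row per group pair:
    ``group_a, group_b, u_stat, p_raw, p_holm``. Exact enumeration is used
    when both groups have ≤ 8 observations and no ties straddle them;
    otherwise the normal approximation with tie correction.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    by_group = {g: values[labels == g] for g in groups}
    for g, v in by_group.items():
        if v.size == 0:
            raise ValueError(f"group {g!r} is empty")
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            va, vb = by_group[a], by_group[b]
            has_ties = np.unique(np.concatenate([va, vb])).size < va.size + vb.size
            method = "exact" if (max(va.size, vb.size) <= 8 and not has_ties) else "asymptotic"
            res = sps.mannwhitneyu(va, vb, alternative="two-sided", method=method)
            rows.append(
                {
                    "group_a": a.item() if hasattr(a, "item") else a,
                    "group_b": b.item() if hasattr(b, "item") else b,
                    "u_stat": float(res.statistic),
                    "p_raw": float(res.pvalue),
                }
            )
    adjusted = holm_adjust([r["p_raw"] for r in rows])
    for r, p in zip(rows, adjusted):
        r["p_holm"] = float(p)
    return rows
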