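"""Tests for multivariate shape statistics.

Each implemented procedure is checked against an independent oracle where one
exists (pingouin for Hotelling T², statsmodels for Holm, scikit-bio for the
Mantel test) and against first-principles properties (invariances, exact
special cases, Monte-Carlo calibration with pre-registered bounds).
"""

import itertools

import numpy as np
import pingouin
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from morphozone.stats import (
    BetweenGroupPCA,
    ShapeCovariateRegression,
    angle_test,
    between_group_pca,
    holm_adjust,
    hotelling_two_sample,
    lda_loocv,
    mantel_test,
    pairwise_rank_test,
    pca_reduce,
    random_direction_angle_cdf,
    shape_regression_permutation,
)


# ---------------------------------------------------------------- pca_reduce


def test_pca_scores_match_eigendecomposition(rng):
    X = rng.normal(size=(40, 6))
    scores, fracs = pca_reduce(X, 3)
    # oracle: eigen-decomposition of the sample covariance
    Xc = X - X.mean(axis=0)
    evals, evecs = np.linalg.eigh(np.cov(X, rowvar=False))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    expected = Xc @ evecs[:, :3]
    # columns are defined up to sign
    for j in range(3):
        assert (
            np.allclose(scores[:, j], expected[:, j], atol=1e-9)
            or np.allclose(scores[:, j], -expected[:, j], atol=1e-9)
        )
    assert np.allclose(fracs, evals / evals.sum(), atol=1e-12)
    assert fracs.sum() == pytest.approx(1.0, abs=1e-12)


def test_pca_scores_are_uncorrelated_and_variance_sorted(rng):
    X = rng.normal(size=(30, 5)) @ np.diag([3.0, 2.0, 1.0, 0.5, 0.1])
    scores, _ = pca_reduce(X, 4)
    cov = np.cov(scores, rowvar=False)
    off = cov - np.diag(np.diag(cov))
    assert np.max(np.abs(off)) < 1e-9
    assert np.all(np.diff(np.diag(cov)) <= 1e-12)


def test_pca_rejects_constant_and_out_of_range(rng):
    with pytest.raises(ValueError, match="zero variance"):
        pca_reduce(np.ones((10, 4)), 2)
    with pytest.raises(ValueError, match="n_components"):
        pca_reduce(rng.normal(size=(10, 4)), 0)
    with pytest.raises(ValueError, match="n_components"):
        pca_reduce(rng.normal(size=(10, 4)), 5)


# ------------------------------------------------------- hotelling_two_sample


def test_hotelling_matches_pingouin(rng):
    X1 = rng.normal(size=(18, 4))
    X2 = rng.normal(size=(15, 4)) + 0.4
    res = hotelling_two_sample(X1, X2)
    oracle = pingouin.multivariate_ttest(X1, X2).loc["hotelling"]
    assert res.t2 == pytest.approx(float(oracle["T2"]), rel=1e-9)
    assert res.f_stat == pytest.approx(float(oracle["F"]), rel=1e-9)
    assert res.df1 == int(oracle["df1"])
    assert res.df2 == int(oracle["df2"])
    assert res.p_raw == pytest.approx(float(oracle["pval"]), rel=1e-9)


def test_hotelling_affine_invariance(rng):
    X1 = rng.normal(size=(20, 3))
    X2 = rng.normal(size=(17, 3)) + [0.3, -0.2, 0.5]
    A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
    b = rng.normal(size=3)
    base = hotelling_two_sample(X1, X2)
    mapped = hotelling_two_sample(X1 @ A + b, X2 @ A + b)
    assert mapped.t2 == pytest.approx(base.t2, rel=1e-8)
    assert mapped.p_raw == pytest.approx(base.p_raw, rel=1e-8)


def test_hotelling_zero_for_identical_means(rng):
    X = rng.normal(size=(12, 3))
    res = hotelling_two_sample(X, X.copy())
    assert res.t2 == pytest.approx(0.0, abs=1e-12)
    assert res.p_raw == pytest.approx(1.0, abs=1e-12)


def test_hotelling_p_matches_label_permutation_null(rng):
    # under exchangeability the parametric F p-value should agree with a
    # brute-force relabeling permutation p-value within Monte-Carlo error
    n1, n2, p = 15, 15, 3
    X1 = rng.normal(size=(n1, p))
    X2 = rng.normal(size=(n2, p)) + 0.35
    res = hotelling_two_sample(X1, X2)
    pooled = np.vstack([X1, X2])
    n_perm = 5000
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n1 + n2)
        t2 = hotelling_two_sample(pooled[perm[:n1]], pooled[perm[n1:]]).t2
        if t2 >= res.t2 - 1e-12:
            count += 1
    p_perm = (count + 1) / (n_perm + 1)
    se = np.sqrt(max(res.p_raw * (1 - res.p_raw), 1e-4) / n_perm)
    assert abs(p_perm - res.p_raw) <= 3 * se + 0.01


def test_hotelling_input_validation(rng):
    with pytest.raises(ValueError, match="share the number of variables"):
        hotelling_two_sample(rng.normal(size=(5, 3)), rng.normal(size=(5, 2)))
    with pytest.raises(ValueError, match="n1 \\+ n2"):
        hotelling_two_sample(rng.normal(size=(3, 8)), rng.normal(size=(3, 8)))
    X = rng.normal(size=(8, 3))
    X[:, 2] = X[:, 0] + X[:, 1]  # rank-deficient pooled covariance
    with pytest.raises(ValueError, match="singular"):
        hotelling_two_sample(X, X + [0.1, 0.2, 0.3])


# ------------------------------------------------------------------ lda_loocv


def test_lda_loocv_separable_classes_classify_perfectly(rng):
    X = np.vstack([rng.normal(size=(12, 2)), rng.normal(size=(12, 2)) + 10.0])
    y = np.repeat(["a", "b"], 12)
    assert lda_loocv(X, y) == 0.0


def test_lda_loocv_random_labels_no_better_than_chance(rng):
    # with labels independent of the data LOOCV cannot beat chance; with
    # proportional priors it is in fact anti-conservative (holding a specimen
    # out makes its own class the minority), so error >= ~50% is the property
    X = rng.normal(size=(60, 3))
    y = np.repeat(["a", "b"], 30)
    assert lda_loocv(X, y) >= 0.45


def test_lda_loocv_matches_manual_discriminant(rng):
    # independent oracle: pooled-covariance Gaussian discriminant with
    # class-proportional priors, refit by hand for every held-out specimen
    X = np.vstack([rng.normal(size=(10, 3)), rng.normal(size=(14, 3)) + 0.8])
    y = np.repeat(["a", "b"], [10, 14])
    errors = 0
    for i in range(len(y)):
        mask = np.ones(len(y), bool)
        mask[i] = False
        Xt, yt = X[mask], y[mask]
        scores = {}
        parts = [Xt[yt == c] - Xt[yt == c].mean(axis=0) for c in ("a", "b")]
        pooled = np.vstack(parts).T @ np.vstack(parts) / (len(yt) - 2)
        inv = np.linalg.inv(pooled)
        for c in ("a", "b"):
            mu = Xt[yt == c].mean(axis=0)
            prior = np.mean(yt == c)
            scores[c] = X[i] @ inv @ mu - 0.5 * mu @ inv @ mu + np.log(prior)
        if max(scores, key=scores.get) != y[i]:
            errors += 1
    assert lda_loocv(X, y) == pytest.approx(errors / len(y), abs=1e-12)


def test_lda_loocv_validation(rng):
    X = rng.normal(size=(9, 2))
    with pytest.raises(ValueError, match="two classes"):
        lda_loocv(X, np.array(["a"] * 9))
    with pytest.raises(ValueError, match="at least 2 members"):
        lda_loocv(X, np.array(["a"] * 8 + ["b"]))
    degenerate = np.zeros((8, 2))
    with pytest.raises(ValueError, match="singular"):
        lda_loocv(degenerate, np.repeat(["a", "b"], 4))


# ---------------------------------------------------------------- holm_adjust


def test_holm_matches_statsmodels(rng):
    for _ in range(20):
        p = rng.uniform(size=rng.integers(1, 12))
        _, expected, _, _ = multipletests(p, method="holm")
        assert np.allclose(holm_adjust(p), expected, atol=1e-12)


def test_holm_matches_bruteforce_stepdown():
    # independent direct implementation of the step-down definition
    p = np.array([0.04, 0.001, 0.03, 0.2, 0.01])
    m = len(p)
    order = np.argsort(p)
    expected = np.empty(m)
    prev = 0.0
    for rank, idx in enumerate(order):
        prev = max(prev, min(1.0, (m - rank) * p[idx]))
        expected[idx] = prev
    assert np.allclose(holm_adjust(p), expected, atol=1e-15)


def test_holm_properties(rng):
    p = rng.uniform(size=10)
    adj = holm_adjust(p)
    assert np.all(adj >= p - 1e-15)  # adjustment never decreases p
    assert np.all(adj <= 1.0)
    # order preserved: sorting p sorts adj identically
    assert np.all(np.diff(adj[np.argsort(p, kind="stable")]) >= -1e-15)
    assert holm_adjust([0.5])[0] == pytest.approx(0.5)
    with pytest.raises(ValueError, match="\\[0, 1\\]"):
        holm_adjust([0.1, 1.5])


# ---------------------------------------------------------------- mantel_test


def _random_distance_matrix(rng, n, d=3):
    pts = rng.normal(size=(n, d))
    diff = pts[:, None, :] - pts[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def test_mantel_r_matches_skbio(rng):
    from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

    D1 = _random_distance_matrix(rng, 10)
    D2 = 0.8 * D1 + 0.2 * _random_distance_matrix(rng, 10)
    np.fill_diagonal(D2, 0.0)
    res = mantel_test(D1, D2, n_perm=999, seed=5)
    r_oracle, p_oracle, _ = skbio_mantel(
        DistanceMatrix(D1), DistanceMatrix(D2), permutations=999, alternative="two-sided"
    )
    assert res.r == pytest.approx(float(r_oracle), abs=1e-10)
    # both p-values are permutation estimates of the same null
    assert abs(res.p_perm - float(p_oracle)) <= 0.05


def test_mantel_perfect_linear_relation(rng):
    D1 = _random_distance_matrix(rng, 9)
    res = mantel_test(D1, 2.0 * D1, n_perm=999, seed=1)
    assert res.r == pytest.approx(1.0, abs=1e-12)
    assert res.p_perm <= 0.05


def test_mantel_type_one_error_calibrated():
    # pre-registered: 400 independent null replicates at alpha = 0.05 must
    # reject at a rate inside [0.015, 0.085] (about +-3 binomial s.e.)
    rng = np.random.default_rng(777)
    rejections = 0
    n_rep = 400
    for _ in range(n_rep):
        D1 = _random_distance_matrix(rng, 10)
        D2 = _random_distance_matrix(rng, 10)
        res = mantel_test(D1, D2, n_perm=99, seed=int(rng.integers(2**31)))
        rejections += res.p_perm <= 0.05
    assert 0.015 <= rejections / n_rep <= 0.085


def test_mantel_validation(rng):
    D = _random_distance_matrix(rng, 6)
    with pytest.raises(ValueError, match="symmetric"):
        mantel_test(D, D + np.triu(np.ones((6, 6)), 1))
    bad_diag = D + np.eye(6)
    with pytest.raises(ValueError, match="zero diagonal"):
        mantel_test(D, bad_diag)
    with pytest.raises(ValueError, match="same shape"):
        mantel_test(D, _random_distance_matrix(rng, 7))


# ------------------------------------------------- shape-covariate regression


def test_regression_recovers_exact_linear_relation(rng):
    z = rng.uniform(0, 1, size=25)
    direction = rng.normal(size=12)
    X = 3.0 + np.outer(z, direction)
    res = shape_regression_permutation(X, z, n_perm=199, seed=3)
    assert res.pct_var_explained == pytest.approx(100.0, abs=1e-9)
    assert res.p_perm == pytest.approx(1 / 200, abs=1e-12)
    # coefficient vector parallel to the generating direction with unit slope
    assert np.allclose(res.coefficient_vector, direction, atol=1e-9)


def test_regression_projection_scores_track_covariate(rng):
    z = rng.uniform(size=30)
    X = np.outer(z, rng.normal(size=8)) + 0.05 * rng.normal(size=(30, 8))
    res = shape_regression_permutation(X, z, n_perm=99, seed=0)
    r = np.corrcoef(res.projection_scores, z)[0, 1]
    assert r > 0.95
    assert res.projection_scores.mean() == pytest.approx(0.0, abs=1e-10)


def test_regression_seeded_runs_bit_identical(rng):
    X = rng.normal(size=(20, 6))
    z = rng.uniform(size=20)
    a = shape_regression_permutation(X, z, n_perm=500, seed=42)
    b = shape_regression_permutation(X, z, n_perm=500, seed=42)
    assert a.p_perm == b.p_perm
    assert np.array_equal(a.coefficient_vector, b.coefficient_vector)


def test_regression_predict_interpolates_fit(rng):
    z = rng.uniform(size=15)
    X = 1.0 + np.outer(z, rng.normal(size=5))
    est = ShapeCovariateRegression(n_perm=49, seed=0).fit(X, z)
    assert np.allclose(est.predict(z), X, atol=1e-9)


def test_regression_type_one_error_calibrated():
    # pre-registered envelope as for the Mantel calibration
    rng = np.random.default_rng(555)
    rejections = 0
    n_rep = 400
    for _ in range(n_rep):
        X = rng.normal(size=(30, 10))
        z = rng.uniform(size=30)
        res = shape_regression_permutation(X, z, n_perm=99, seed=int(rng.integers(2**31)))
        rejections += res.p_perm <= 0.05
    assert 0.015 <= rejections / n_rep <= 0.085


def test_regression_validation(rng):
    X = rng.normal(size=(10, 4))
    with pytest.raises(ValueError, match="covariate length"):
        shape_regression_permutation(X, np.arange(9))
    with pytest.raises(ValueError, match="zero variance"):
        shape_regression_permutation(X, np.ones(10))


# ---------------------------------------------------------- between-group PCA


def test_bgpca_axes_orthonormal_and_span_means(rng):
    X = rng.normal(size=(40, 7))
    y = rng.integers(0, 4, size=40)
    est = BetweenGroupPCA().fit(X, y)
    gram = est.components_ @ est.components_.T
    assert np.allclose(gram, np.eye(est.components_.shape[0]), atol=1e-10)
    assert est.components_.shape[0] == len(np.unique(y)) - 1
    # projecting the group means reproduces the stored group scores
    means = np.stack([X[y == g].mean(axis=0) for g in est.groups_])
    assert np.allclose(est.transform(means), est.group_scores_, atol=1e-10)


def test_bgpca_first_axis_recovers_group_ordering(rng):
    # three groups displaced along a single direction must map onto PC1 in
    # monotone order
    direction = rng.normal(size=6)
    direction /= np.linalg.norm(direction)
    X = np.vstack(
        [0.01 * rng.normal(size=(10, 6)) + c * direction for c in (0.0, 1.0, 2.0)]
    )
    y = np.repeat([0, 1, 2], 10)
    _, group_scores, proj = between_group_pca(X, y)
    pc1 = group_scores[:, 0]
    assert np.all(np.diff(pc1) > 0) or np.all(np.diff(pc1) < 0)
    assert proj.shape == (30, 2)


def test_bgpca_requires_two_groups(rng):
    with pytest.raises(ValueError, match="at least 2 groups"):
        BetweenGroupPCA().fit(rng.normal(size=(5, 3)), np.zeros(5))


# ------------------------------------------------------------------ angle test


def test_angle_cdf_closed_form_values():
    # in 3 dimensions P(angle <= theta) = (1 - cos theta)/2
    for theta in (10.0, 45.0, 60.0, 90.0, 120.0, 170.0):
        expected = (1 - np.cos(np.deg2rad(theta))) / 2
        assert random_direction_angle_cdf(theta, 3) == pytest.approx(expected, abs=1e-12)
    assert random_direction_angle_cdf(60.0, 3) == pytest.approx(0.25, abs=1e-12)


def test_angle_cdf_matches_monte_carlo():
    rng = np.random.default_rng(2024)
    n = 100_000
    for dim in (2, 5, 20):
        u = rng.normal(size=(n, dim))
        v = rng.normal(size=(n, dim))
        cosines = np.sum(u * v, axis=1) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
        )
        angles = np.degrees(np.arccos(np.clip(cosines, -1, 1)))
        for theta in (30.0, 75.0, 110.0):
            mc = np.mean(angles <= theta)
            se = np.sqrt(max(mc * (1 - mc), 1e-6) / n)
            assert abs(random_direction_angle_cdf(theta, dim) - mc) <= 4 * se + 1e-4


def test_angle_cdf_monotone_in_angle_and_concentrates_with_dim():
    grid = np.linspace(1, 179, 90)
    vals = [random_direction_angle_cdf(t, 10) for t in grid]
    assert np.all(np.diff(vals) > 0)
    # higher dimension concentrates angles near 90 degrees, so the CDF at a
    # small angle shrinks with dim
    small = [random_direction_angle_cdf(30.0, d) for d in (3, 10, 50)]
    assert small[0] > small[1] > small[2]


def test_angle_test_geometry(rng):
    v = rng.normal(size=8)
    assert angle_test(v, 2.5 * v, dim=8).angle_deg == pytest.approx(0.0, abs=1e-5)
    assert angle_test(v, -v, dim=8).angle_deg == pytest.approx(180.0, abs=1e-5)
    w = rng.normal(size=8)
    w -= (w @ v) / (v @ v) * v
    res = angle_test(v, w, dim=8)
    assert res.angle_deg == pytest.approx(90.0, abs=1e-6)
    with pytest.raises(ValueError, match="zero vector"):
        angle_test(v, np.zeros(8), dim=8)
    with pytest.raises(ValueError, match="equal length"):
        angle_test(v, np.zeros(5), dim=8)


# --------------------------------------------------------- pairwise rank test


def test_pairwise_rank_test_table_shape_and_holm(rng):
    values = rng.normal(size=24)
    labels = np.repeat([0, 1, 2, 3], 6)
    rows = pairwise_rank_test(values, labels)
    assert len(rows) == len(list(itertools.combinations(range(4), 2)))
    raw = np.array([r["p_raw"] for r in rows])
    holm = np.array([r["p_holm"] for r in rows])
    assert np.allclose(holm, holm_adjust(raw), atol=1e-12)


def test_pairwise_rank_test_detects_shift(rng):
    values = np.concatenate([rng.normal(size=8), rng.normal(size=8) + 8.0])
    labels = np.repeat(["small", "large"], 8)
    (row,) = pairwise_rank_test(values, labels)
    oracle = sps.mannwhitneyu(
        values[:8], values[8:], alternative="two-sided", method="exact"
    )
    assert row["p_raw"] == pytest.approx(float(oracle.pvalue), abs=1e-12)
    assert row["p_holm"] < 0.01


def test_pairwise_rank_test_handles_ties(rng):
    values = np.concatenate([np.repeat([1.0, 2.0], 5), np.repeat([2.0, 3.0], 5)])
    labels = np.repeat(["a", "b"], 10)
    (row,) = pairwise_rank_test(values, labels)
    assert 0.0 < row["p_raw"] <= 1.0
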