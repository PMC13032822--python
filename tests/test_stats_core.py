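"""Quartiles, Kruskal-Wallis, PCA, distances, PERMANOVA, beta-dispersion.

The PERMANOVA oracle here enumerates every distinct label vector and
computes F from the raw points (within-group scatter around centroids) —
an independent route from the implementation, which works on the distance
matrix via the Gower partition.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karyocov.stats_core import (
    beta_dispersion,
    euclidean_distance_matrix,
    kruskal_wallis,
    pca,
    permanova,
    quartiles,
)


# ---------------------------------------------------------------------------
# Oracle: brute-force PERMANOVA from raw points
# ---------------------------------------------------------------------------


def _f_from_points(X, labels):
    labels = np.asarray(labels)
    n = len(X)
    groups = sorted(set(labels.tolist()))
    k = len(groups)
    grand = X.mean(axis=0)
    ss_total = float(((X - grand) ** 2).sum())
    ss_within = 0.0
    for g in groups:
        pts = X[labels == g]
        ss_within += float(((pts - pts.mean(axis=0)) ** 2).sum())
    ss_between = ss_total - ss_within
    if ss_within <= 1e-300:
        return 0.0 if ss_between <= 1e-12 * max(ss_total, 1.0) else np.inf
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def brute_force_permanova(X, labels):
    """Exact p over every distinct label vector, F computed from points."""
    labels = list(labels)
    f_obs = _f_from_points(X, labels)
    seen = set()
    n_ge = total = 0
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        f = _f_from_points(X, list(perm))
        if f >= f_obs or np.isclose(f, f_obs, rtol=1e-12, atol=1e-12):
            n_ge += 1
    return f_obs, n_ge / total, total


# ---------------------------------------------------------------------------
# Quartiles
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "values, expected",
    [
        ([0, 1, 2, 3, 4], (1.0, 2.0, 3.0)),
        ([1, 2, 3, 4], (1.75, 2.5, 3.25)),  # interpolated ranks 1.75/2.5/3.25
        ([5, 5, 5, 5], (5.0, 5.0, 5.0)),
    ],
)
def test_quartiles_linear_interpolation(values, expected):
    assert quartiles(values) == pytest.approx(expected)


def test_quartiles_need_two_values():
    with pytest.raises(ValueError):
        quartiles([1.0])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(-100, 100), min_size=3, max_size=30),
    st.floats(0.1, 50),
)
def test_q3_monotone_under_high_additions(values, bump):
    """Adding a value above Q3 never decreases Q3."""
    _, _, q3 = quartiles(values)
    _, _, q3b = quartiles(values + [q3 + bump])
    assert q3b >= q3 - 1e-12


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------


class TestKruskalWallis:
    def test_identical_groups_no_effect(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_ranked_two_groups(self):
        # ranks: group1 -> 1,2,3  group2 -> 4,5,6; no ties
        # H = 12/(n(n+1)) * sum R_g^2/n_g - 3(n+1) = 12/42*(36/3+225/3) - 21
        h, p = kruskal_wallis([[1, 2, 3], [10, 11, 12]])
        expected = 12 / (6 * 7) * (6**2 / 3 + 15**2 / 3) - 3 * 7
        assert h == pytest.approx(expected)
        assert 0 < p < 1

    def test_all_identical_observations(self):
        assert kruskal_wallis([[7, 7], [7, 7, 7]]) == (0.0, 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


class TestPCA:
    def test_reconstruction_identity(self, rng):
        X = rng.normal(size=(20, 4))
        res = pca(X)
        np.testing.assert_allclose(
            res.scores @ res.loadings.T, X - res.centering_vector, atol=1e-8
        )

    def test_components_orthonormal_and_variance_ordered(self, rng):
        X = rng.normal(size=(30, 5)) * [5, 3, 2, 1, 0.5]
        res = pca(X)
        np.testing.assert_allclose(res.loadings.T @ res.loadings, np.eye(5), atol=1e-8)
        assert np.all(np.diff(res.explained_variance) <= 1e-12)

    def test_explained_variance_sums_to_total(self, rng):
        X = rng.normal(size=(25, 3))
        res = pca(X)
        total = ((X - X.mean(0)) ** 2).sum() / (len(X) - 1)
        assert res.explained_variance.sum() == pytest.approx(total, rel=1e-8)

    def test_collinear_data_rank_one(self):
        x = np.arange(10.0)
        X = np.column_stack([x, 3 * x])
        res = pca(X)
        assert res.explained_variance[1] == pytest.approx(0.0, abs=1e-10)

    def test_known_principal_axis(self, rng):
        # points on y = 2x with tiny isotropic noise -> PC1 along (1,2)/sqrt(5)
        x = rng.normal(size=500)
        X = np.column_stack([x, 2 * x]) + rng.normal(0, 1e-3, size=(500, 2))
        res = pca(X)
        axis = res.loadings[:, 0] * np.sign(res.loadings[0, 0])
        np.testing.assert_allclose(axis, np.array([1, 2]) / np.sqrt(5), atol=1e-3)

    def test_zero_variance_feature_with_scale_rejected(self):
        X = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError):
            pca(X, scale=True)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def test_euclidean_345():
    D = euclidean_distance_matrix({"a": (0, 0), "b": (3, 4)})
    assert D.d[0, 1] == pytest.approx(5.0)
    assert D.d[0, 0] == 0 == D.d[1, 1]


def test_collinear_triangle_equality():
    D = euclidean_distance_matrix({"a": (0,), "b": (1,), "c": (2,)})
    i, j, k = (D.labels.index(x) for x in "abc")
    assert D.d[i, k] == pytest.approx(D.d[i, j] + D.d[j, k])


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


class TestPermanova:
    def _dm(self, X):
        return euclidean_distance_matrix({f"s{i}": X[i] for i in range(len(X))})

    @pytest.mark.parametrize("n, k, seed", [(6, 2, 0), (7, 2, 1), (8, 2, 2), (6, 3, 3)])
    def test_exhaustive_equals_brute_force_oracle(self, n, k, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 2))
        labels = [i % k for i in range(n)]
        res = permanova(self._dm(X), labels)
        f_oracle, p_oracle, total = brute_force_permanova(X, labels)
        assert res.exhaustive
        assert res.n_permutations_used == total
        assert res.F_stat == pytest.approx(f_oracle, rel=1e-9)
        assert res.p_value == p_oracle

    def test_separated_3v3_clusters(self):
        X = np.vstack([np.zeros((3, 2)) + [0, 0.01 * i] for i in range(1)])
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.1, (3, 2)), rng.normal(10, 0.1, (3, 2))])
        res = permanova(self._dm(X), ["a"] * 3 + ["b"] * 3)
        f_oracle, p_oracle, total = brute_force_permanova(X, ["a"] * 3 + ["b"] * 3)
        assert total == 20
        assert res.p_value == p_oracle == pytest.approx(2 / 20)

    def test_coincident_points_no_structure(self):
        X = np.zeros((6, 2))
        res = permanova(self._dm(X), ["a"] * 3 + ["b"] * 3)
        assert res.F_stat == 0.0
        assert res.p_value == 1.0

    def test_sampled_p_never_zero_and_floor(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (12, 2)), rng.normal(50, 0.1, (12, 2))])
        res = permanova(self._dm(X), ["a"] * 12 + ["b"] * 12, n_perm=999, seed=7)
        assert not res.exhaustive  # C(24,12) > 10,000
        assert res.p_value >= 1 / (res.n_permutations_used + 1)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_invariant_to_group_names_and_sample_order(self, rng):
        X = rng.normal(size=(7, 3))
        lab = ["a", "a", "a", "b", "b", "b", "b"]
        res1 = permanova(self._dm(X), lab)
        res2 = permanova(self._dm(X), ["grp2" if l == "b" else "grp1" for l in lab])
        order = rng.permutation(7)
        pts = {f"s{i}": X[i] for i in order}
        res3 = permanova(
            euclidean_distance_matrix(pts), {f"s{i}": lab[i] for i in range(7)}
        )
        assert res1.p_value == res2.p_value == res3.p_value
        assert res1.F_stat == pytest.approx(res3.F_stat, rel=1e-9)

    def test_single_group_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        with pytest.raises(ValueError):
            permanova(self._dm(X), ["a"] * 5)

    def test_matches_skbio_f_statistic(self, rng):
        """Independent cross-check of the F statistic against scikit-bio."""
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        X = rng.normal(size=(15, 3))
        X[:7] += 0.8
        lab = ["a"] * 7 + ["b"] * 8
        D = self._dm(X)
        res = permanova(D, lab, n_perm=999, seed=0)
        sk = skbio_distance.permanova(
            skbio_distance.DistanceMatrix(D.d, ids=D.labels), lab, permutations=99
        )
        assert res.F_stat == pytest.approx(sk["test statistic"], rel=1e-9)


# ---------------------------------------------------------------------------
# Beta-dispersion
# ---------------------------------------------------------------------------


class TestBetaDispersion:
    def test_square_closed_form(self):
        pts = {"a": (1, 1), "b": (1, -1), "c": (-1, 1), "d": (-1, -1)}
        res = beta_dispersion(pts, {k: "g" for k in pts})
        assert res.per_group["g"] == pytest.approx(np.sqrt(2), rel=1e-9)
        assert res.mean_dispersion == pytest.approx(np.sqrt(2), rel=1e-9)

    def test_singleton_group_zero(self):
        res = beta_dispersion({"a": (3, 4)}, {"a": "g"})
        assert res.per_group["g"] == 0.0

    def test_mean_dispersion_unweighted_over_groups(self):
        pts = {"a": (0, 0), "b": (2, 0), "c": (10, 10)}
        res = beta_dispersion(pts, {"a": "g1", "b": "g1", "c": "g2"})
        assert res.per_group["g1"] == pytest.approx(1.0)
        assert res.per_group["g2"] == 0.0
        assert res.mean_dispersion == pytest.approx(0.5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
            min_size=2, max_size=12,
        ),
        st.floats(-100, 100), st.floats(-100, 100), st.floats(0, 2 * np.pi),
    )
    def test_translation_and_rotation_invariance(self, coords, tx, ty, theta):
        pts = {f"s{i}": np.asarray(c, float) for i, c in enumerate(coords)}
        labels = {k: i % 2 for i, k in enumerate(pts)}
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = {k: R @ v + np.array([tx, ty]) for k, v in pts.items()}
        a = beta_dispersion(pts, labels)
        b = beta_dispersion(moved, labels)
        for g in a.per_group:
            assert b.per_group[g] == pytest.approx(a.per_group[g], abs=1e-7)

    def test_spatial_median_option(self):
        # median of 3 collinear points is the middle point, not the centroid
        pts = {"a": (0.0, 0.0), "b": (1.0, 0.0), "c": (10.0, 0.0)}
        lab = {k: "g" for k in pts}
        cen = beta_dispersion(pts, lab, center="centroid")
        med = beta_dispersion(pts, lab, center="spatial_median")
        assert med.per_group["g"] == pytest.approx((1 + 9) / 3, rel=1e-6)
        assert cen.per_group["g"] != pytest.approx(med.per_group["g"])
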