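"""Multivariate and nonparametric statistics shared by all callers.

PERMANOVA here is the one-factor permutational MANOVA on a distance matrix
(the ADONIS-style test): the total sum of squared pairwise distances is
partitioned into between- and within-group components via the Gower
identity

    SS_total  = (1/n)   * sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    F = (SS_between / (k-1)) / (SS_within / (n-k))

and significance comes from relabelling: exhaustively over every distinct
label vector when there are at most ``EXHAUSTIVE_LIMIT`` of them, otherwise
from seeded random permutations with the identity included in numerator and
denominator so p is never 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from sympy.utilities.iterables import multiset_permutations

EXHAUSTIVE_LIMIT = 10_000

#: Quantile convention: linear interpolation at rank 1 + q*(n-1)
#: (numpy's default, R ``quantile`` type 7 — the convention of prcomp's
#: home environment).  Config-visible because it sets the outlier bounds.
QUANTILE_METHOD = "linear"


def quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    """(Q1, Q2, Q3) by linear interpolation between order statistics."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("quartiles need at least 2 values")
    if not np.all(np.isfinite(v)):
        raise ValueError("quartiles require finite values")
    q1, q2, q3 = np.quantile(v, [0.25, 0.5, 0.75], method=QUANTILE_METHOD)
    return float(q1), float(q2), float(q3)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Rank-based H (tie-corrected) and chi-square p on k-1 df."""
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("kruskal_wallis groups must be non-empty")
    flat = np.concatenate([np.asarray(g, float) for g in groups])
    if np.all(flat == flat[0]):  # scipy raises on all-identical data
        return 0.0, 1.0
    h, p = sps.kruskal(*[np.asarray(g, float) for g in groups])
    return float(h), float(p)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    scores: np.ndarray            # samples x components
    loadings: np.ndarray          # features x components (orthonormal columns)
    explained_variance: np.ndarray
    centering_vector: np.ndarray
    scaling_vector: np.ndarray | None
    sign_convention_applied: bool = False

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new rows using the training centering/scaling."""
        Xc = np.asarray(X, float) - self.centering_vector
        if self.scaling_vector is not None:
            Xc = Xc / self.scaling_vector
        return Xc @ self.loadings

    def flip_component(self, k: int) -> None:
        self.loadings[:, k] *= -1.0
        self.scores[:, k] *= -1.0
        self.sign_convention_applied = True


def pca(matrix: np.ndarray, center: bool = True, scale: bool = False) -> PCAResult:
    """Eigendecomposition of the (co)variance of centered data, via SVD.

    Deterministic up to component sign; callers that need a fixed sign apply
    their own convention through :meth:`PCAResult.flip_component`.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("pca needs a 2-D matrix with >=3 samples and >=2 features")
    if not np.all(np.isfinite(X)):
        raise ValueError("pca input contains non-finite values")
    mu = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - mu
    sd = None
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("cannot scale a zero-variance feature")
        Xc = Xc / sd
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = vt.T
    scores = Xc @ loadings
    ev = s**2 / (X.shape[0] - 1)
    return PCAResult(
        scores=scores, loadings=loadings, explained_variance=ev,
        centering_vector=mu, scaling_vector=sd,
    )


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


def euclidean_distance_matrix(points: Mapping[str, Sequence[float]]) -> DistanceMatrix:
    labels = list(points)
    X = np.asarray([points[k] for k in labels], dtype=float)
    if X.ndim != 2:
        raise ValueError("all point vectors must have the same length")
    diff = X[:, None, :] - X[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=labels, d=d)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    F_stat: float
    p_value: float
    n_permutations_used: int
    exhaustive: bool


def _group_codes(labels: Sequence) -> tuple[np.ndarray, int]:
    uniq = list(dict.fromkeys(labels))
    codes = np.asarray([uniq.index(x) for x in labels], dtype=np.int64)
    return codes, len(uniq)


def _f_from_d2(d2: np.ndarray, codes: np.ndarray, k: int) -> float:
    n = len(codes)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(k):
        m = codes == g
        ng = int(m.sum())
        ss_within += d2[np.ix_(m, m)].sum() / (2.0 * ng)
    ss_between = ss_total - ss_within
    if ss_within <= 1e-300:
        return 0.0 if ss_between <= 1e-12 * max(ss_total, 1.0) else np.inf
    return float((ss_between / (k - 1)) / (ss_within / (n - k)))


def _f_batch_2group(d2: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """F for many 2-group label vectors at once; Z is (B, n) 0/1 for group 1."""
    n = d2.shape[0]
    tot = d2.sum() / (2.0 * n)
    n1 = Z.sum(axis=1)
    n0 = n - n1
    w1 = np.einsum("bi,ij,bj->b", Z, d2, Z) / 2.0
    Zc = 1.0 - Z
    w0 = np.einsum("bi,ij,bj->b", Zc, d2, Zc) / 2.0
    ss_w = w1 / n1 + w0 / n0
    ss_b = tot - ss_w
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_b / 1.0) / (ss_w / (n - 2))
    f = np.where(ss_w <= 1e-300, np.where(ss_b <= 1e-12 * max(tot, 1.0), 0.0, np.inf), f)
    return f


def _n_distinct_relabellings(counts: Sequence[int]) -> int:
    n = factorial(sum(counts))
    for c in counts:
        n //= factorial(c)
    return n


def permanova(
    D: DistanceMatrix,
    labels: Mapping[str, object] | Sequence[object],
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    Labels are permuted freely (no strata).  When the number of distinct
    label vectors is at most :data:`EXHAUSTIVE_LIMIT` every one is evaluated
    exactly once and ``p = #(F_perm >= F_obs) / #(all)``; otherwise ``n_perm``
    seeded permutations are drawn and the identity is counted in both
    numerator and denominator.  Ties in F count as >=.
    """
    if isinstance(labels, Mapping):
        lab = [labels[s] for s in D.labels]
    else:
        lab = list(labels)
    if len(lab) != len(D.labels):
        raise ValueError("labels must cover every sample in the distance matrix")
    codes, k = _group_codes(lab)
    if k < 2:
        raise ValueError("permanova needs at least 2 groups")
    d2 = D.d**2
    n = len(codes)
    f_obs = _f_from_d2(d2, codes, k)

    counts = np.bincount(codes, minlength=k)
    n_distinct = _n_distinct_relabellings(counts.tolist())
    if n_distinct <= EXHAUSTIVE_LIMIT:
        n_ge = 0
        total = 0
        for perm in multiset_permutations(codes.tolist()):
            f = _f_from_d2(d2, np.asarray(perm), k)
            total += 1
            if f >= f_obs or np.isclose(f, f_obs, rtol=1e-12, atol=1e-12):
                n_ge += 1
        return PermanovaResult(
            F_stat=f_obs, p_value=n_ge / total,
            n_permutations_used=total, exhaustive=True,
        )

    rng = np.random.default_rng(seed)
    if k == 2:
        Z = np.empty((n_perm, n))
        base = (codes == 1).astype(float)
        for b in range(n_perm):
            Z[b] = rng.permutation(base)
        f_perm = _f_batch_2group(d2, Z)
    else:
        f_perm = np.empty(n_perm)
        for b in range(n_perm):
            f_perm[b] = _f_from_d2(d2, rng.permutation(codes), k)
    n_ge = int(np.sum((f_perm >= f_obs) | np.isclose(f_perm, f_obs, rtol=1e-12)))
    p = (1 + n_ge) / (n_perm + 1)
    return PermanovaResult(
        F_stat=f_obs, p_value=p, n_permutations_used=n_perm, exhaustive=False
    )


# ---------------------------------------------------------------------------
# Beta-dispersion
# ---------------------------------------------------------------------------


@dataclass
class DispersionResult:
    per_group: dict[object, float]
    mean_dispersion: float


def _spatial_median(X: np.ndarray, tol: float = 1e-10, max_iter: int = 500) -> np.ndarray:
    """Weiszfeld iteration for the geometric median."""
    m = X.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(X - m, axis=1)
        if np.any(d < tol):
            return m
        w = 1.0 / d
        m_new = (X * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(m_new - m) < tol:
            return m_new
        m = m_new
    return m


def beta_dispersion(
    points: Mapping[str, Sequence[float]],
    labels: Mapping[str, object],
    center: str = "centroid",
) -> DispersionResult:
    """Per-group mean distance of members to the group centre.

    ``center`` is "centroid" (arithmetic mean; the default, closed-form
    testable) or "spatial_median".  ``mean_dispersion`` is the unweighted
    average over groups; a single-member group has dispersion 0.
    """
    if center not in ("centroid", "spatial_median"):
        raise ValueError("center must be 'centroid' or 'spatial_median'")
    groups: dict[object, list[str]] = {}
    for s in points:
        groups.setdefault(labels[s], []).append(s)
    per_group: dict[object, float] = {}
    for g, members in groups.items():
        X = np.asarray([points[s] for s in members], dtype=float)
        c = X.mean(axis=0) if center == "centroid" else _spatial_median(X)
        per_group[g] = float(np.linalg.norm(X - c, axis=1).mean())
    return DispersionResult(
        per_group=per_group, mean_dispersion=float(np.mean(list(per_group.values())))
    )
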