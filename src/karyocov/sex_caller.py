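"""Sex-chromosome karyotype inference from joint X/Y normalized coverage.

X and Y are analysed together because their coverage is tied to the same
karyotype: each sample becomes a point (x_norm, y_norm) per normalization
scheme, XX and XY reference clusters are recovered unsupervised (2-means
with outlier trimming), and copy numbers are read off relative to the
cluster centres:

    x_copy = 2 * x_norm / mean_x(XX cluster)      (XX centre == 2 copies)
    y_copy = 1 * y_norm / mean_y(XY cluster)      (XY centre == 1 copy)

Referencing Y to the XY centroid rather than to absolute ratios makes the
calls portable across capture kits, whose Y target efficiency differs
widely.  Estimates are averaged over the top-3 schemes and matched to the
integer karyotype grid (X0, XX, XY, XXX, XXY, XYY); a copy estimate at
least 0.25 away from every integer marks a mosaic.  Candidate outliers are
tested against the nearest reference cluster by PERMANOVA on the Euclidean
distance matrix (significant at p < .01, suggestive at p < .05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .control_builder import NormalizationScheme, normalized_ratio
from .coverage_io import SampleCoverage
from .stats_core import PermanovaResult, euclidean_distance_matrix, permanova

logger = logging.getLogger("karyocov")

KARYOTYPE_GRID: dict[tuple[int, int], str] = {
    (2, 0): "XX", (1, 1): "XY", (1, 0): "X0",
    (2, 1): "XXY", (3, 0): "XXX", (1, 2): "XYY",
}
BASELINES = {"XX": (2.0, 0.0), "XY": (1.0, 1.0)}

MOSAIC_COPY_MARGIN = 0.25       # copy-units off any integer => mosaic
TRIM_RADIUS_DISPERSIONS = 6.0   # trim controls this far from both centroids
P_SIGNIFICANT = 0.01
P_SUGGESTIVE = 0.05


@dataclass
class SexPoint:
    sample_id: str
    per_scheme: dict[str, tuple[float, float]]  # normalizer id -> (x_norm, y_norm)


@dataclass
class SchemeClusters:
    xx_centroid: tuple[float, float]
    xy_centroid: tuple[float, float]
    xx_dispersion: float
    xy_dispersion: float
    xx_members: list[str]
    xy_members: list[str]
    trimmed: list[str]


@dataclass
class SexClusterModel:
    schemes: list[str]                      # normalizer ids, e.g. ["12", "ALL", "2"]
    per_scheme: dict[str, SchemeClusters]


@dataclass
class SexCallResult:
    sample_id: str
    x_copy_est: float
    y_copy_est: float
    karyotype: str
    mosaic: bool
    mosaic_fraction_est: float
    deviation_toward: str | None
    baseline: str
    permanova_p: dict[str, float] = field(default_factory=dict)
    significance: str = "untested"          # significant | suggestive | ns | untested
    consistent_across_schemes: bool = True
    per_scheme_copies: dict[str, tuple[float, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Points
# ---------------------------------------------------------------------------


def compute_sex_points(
    samples: Sequence[SampleCoverage], normalizers: Sequence[str]
) -> dict[str, SexPoint]:
    """Per sample and per normalizer, the (X ratio, Y ratio) pair."""
    out: dict[str, SexPoint] = {}
    for s in samples:
        per_scheme = {}
        for norm in normalizers:
            x = normalized_ratio(s, NormalizationScheme("X", norm))
            y = normalized_ratio(s, NormalizationScheme("Y", norm))
            per_scheme[norm] = (x, y)
        out[s.sample_id] = SexPoint(sample_id=s.sample_id, per_scheme=per_scheme)
    return out


# ---------------------------------------------------------------------------
# Reference clusters
# ---------------------------------------------------------------------------


def _two_means(X: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Lloyd 2-means initialized at the extreme-y and minimal-y points."""
    c = np.vstack([X[np.argmax(X[:, 1])], X[np.argmin(X[:, 1])]])
    assign = np.zeros(len(X), dtype=int)
    for _ in range(max_iter):
        d = np.linalg.norm(X[:, None, :] - c[None, :, :], axis=2)
        new_assign = d.argmin(axis=1)
        if np.array_equal(new_assign, assign) and _ > 0:
            break
        assign = new_assign
        for g in (0, 1):
            if np.any(assign == g):
                c[g] = X[assign == g].mean(axis=0)
    return assign


def _fit_one_scheme(ids: list[str], X: np.ndarray) -> SchemeClusters:
    assign = _two_means(X)
    trimmed_mask = np.zeros(len(X), dtype=bool)
    for _round in range(2):  # fit, trim once, refit
        cents, disps = [], []
        for g in (0, 1):
            pts = X[(assign == g) & ~trimmed_mask]
            cent = pts.mean(axis=0)
            cents.append(cent)
            disps.append(float(np.linalg.norm(pts - cent, axis=1).mean()))
        if _round == 1:
            break
        far = np.ones(len(X), dtype=bool)
        for g in (0, 1):
            d = np.linalg.norm(X - cents[g], axis=1)
            far &= d > TRIM_RADIUS_DISPERSIONS * disps[g]
        if not far.any():
            break
        trimmed_mask = far
        keep = ~trimmed_mask
        assign_kept = _two_means(X[keep])
        assign = np.zeros(len(X), dtype=int)
        assign[keep] = assign_kept
    # label: lower mean y_norm => XX
    xx_g = 0 if cents[0][1] < cents[1][1] else 1
    xy_g = 1 - xx_g
    keep = ~trimmed_mask
    xx_members = [ids[i] for i in range(len(ids)) if keep[i] and assign[i] == xx_g]
    xy_members = [ids[i] for i in range(len(ids)) if keep[i] and assign[i] == xy_g]
    if len(xx_members) < 3 or len(xy_members) < 3:
        raise ValueError(
            "XX/XY clusters collapsed (fewer than 3 members in one cluster); "
            "the cohort may be single-sex — supply cluster labels explicitly"
        )
    res = SchemeClusters(
        xx_centroid=tuple(cents[xx_g]), xy_centroid=tuple(cents[xy_g]),
        xx_dispersion=disps[xx_g], xy_dispersion=disps[xy_g],
        xx_members=xx_members, xy_members=xy_members,
        trimmed=[ids[i] for i in range(len(ids)) if trimmed_mask[i]],
    )
    if res.xx_centroid[0] <= res.xy_centroid[0]:
        logger.warning(
            "XX centroid x_norm (%.3f) not above XY centroid x_norm (%.3f); "
            "cluster labelling may be unreliable",
            res.xx_centroid[0], res.xy_centroid[0],
        )
    return res


def fit_sex_clusters(control_points: Mapping[str, SexPoint]) -> SexClusterModel:
    """Unsupervised XX/XY reference clusters per scheme, with one trim pass.

    Control-set sex aneuploidies would drag a centroid; points farther than
    6 cluster-dispersions from *both* centroids are trimmed and the clusters
    refitted once.
    """
    ids = list(control_points)
    if len(ids) < 6:
        raise ValueError("need at least 6 control points to fit XX/XY clusters")
    schemes = list(next(iter(control_points.values())).per_scheme)
    per_scheme = {}
    for norm in schemes:
        X = np.asarray([control_points[s].per_scheme[norm] for s in ids], float)
        per_scheme[norm] = _fit_one_scheme(ids, X)
    return SexClusterModel(schemes=schemes, per_scheme=per_scheme)


# ---------------------------------------------------------------------------
# Karyotype calls
# ---------------------------------------------------------------------------


def _choose_baseline(x_copy: float, y_copy: float) -> str:
    """Nearest normal karyotype, preferring the one a single-chromosome
    deviation would depart from (the coordinate closest to baseline wins)."""
    best, best_key = None, None
    for name, (bx, by) in BASELINES.items():
        dx, dy = abs(x_copy - bx), abs(y_copy - by)
        key = (min(dx, dy), np.hypot(dx, dy))
        if best_key is None or key < best_key:
            best, best_key = name, key
    return best


def call_sex_karyotype(
    point: SexPoint,
    model: SexClusterModel,
    partial_y_heuristic: bool = True,
) -> SexCallResult:
    """Copy estimates, karyotype-grid match, mosaic fraction and flags."""
    per_scheme_copies: dict[str, tuple[float, float]] = {}
    for norm in model.schemes:
        if norm not in point.per_scheme:
            raise ValueError(f"point {point.sample_id} missing scheme {norm!r}")
        sc = model.per_scheme[norm]
        x, y = point.per_scheme[norm]
        per_scheme_copies[norm] = (
            2.0 * x / sc.xx_centroid[0],
            1.0 * y / sc.xy_centroid[1],
        )
    cop = np.asarray(list(per_scheme_copies.values()))
    x_copy, y_copy = float(cop[:, 0].mean()), float(cop[:, 1].mean())

    xg = int(np.clip(round(x_copy), 0, 3))
    yg = int(np.clip(round(y_copy), 0, 2))
    karyotype = KARYOTYPE_GRID.get((xg, yg), "ambiguous")

    baseline = _choose_baseline(x_copy, y_copy)
    bx, by = BASELINES[baseline]
    dx, dy = x_copy - bx, y_copy - by
    frac = float(max(abs(dx), abs(dy)))
    # target grid point in the deviation's direction
    if abs(dx) >= abs(dy):
        tgt = (int(np.clip(bx + np.sign(dx), 0, 3)), int(by)) if dx != 0 else (int(bx), int(by))
    else:
        tgt = (int(bx), int(np.clip(by + np.sign(dy), 0, 2)))
    deviation_toward = KARYOTYPE_GRID.get(tgt) if tgt != (int(bx), int(by)) else None

    off_integer = max(
        abs(x_copy - round(x_copy)), abs(y_copy - round(y_copy))
    )
    mosaic = off_integer >= MOSAIC_COPY_MARGIN

    if partial_y_heuristic and abs(x_copy - 1.0) < MOSAIC_COPY_MARGIN:
        if 1.25 < y_copy < 1.75:
            karyotype = "partial_Y_gain"
        elif 0.25 < y_copy < 0.75:
            karyotype = "partial_Y_loss"

    directions = []
    for norm, (xs, ys) in per_scheme_copies.items():
        dxs, dys = xs - bx, ys - by
        directions.append(np.sign(dxs if abs(dx) >= abs(dy) else dys))
    consistent = len(set(directions)) <= 1

    return SexCallResult(
        sample_id=point.sample_id,
        x_copy_est=x_copy, y_copy_est=y_copy,
        karyotype=karyotype, mosaic=mosaic,
        mosaic_fraction_est=frac,
        deviation_toward=deviation_toward,
        baseline=baseline,
        consistent_across_schemes=bool(consistent),
        per_scheme_copies=per_scheme_copies,
    )


# ---------------------------------------------------------------------------
# Outlier significance
# ---------------------------------------------------------------------------


def test_outlier_significance(
    control_points: Mapping[str, SexPoint],
    candidate_points: Mapping[str, SexPoint],
    model: SexClusterModel,
    n_perm: int = 999,
    seed: int = 0,
    pooled: bool = False,
) -> dict[str, dict[str, PermanovaResult]]:
    """PERMANOVA of each candidate (or the pooled set) against its nearest
    reference cluster, per scheme.  Returns candidate -> scheme -> result."""
    overlap = set(candidate_points) & set(control_points)
    if overlap:
        raise ValueError(f"candidate(s) also in the control set: {sorted(overlap)}")
    groups: list[list[str]] = (
        [list(candidate_points)] if pooled else [[c] for c in candidate_points]
    )
    out: dict[str, dict[str, PermanovaResult]] = {}
    for members in groups:
        key = "+".join(members)
        out[key] = {}
        for norm in model.schemes:
            sc = model.per_scheme[norm]
            cand_xy = np.asarray(
                [candidate_points[m].per_scheme[norm] for m in members], float
            ).mean(axis=0)
            d_xx = np.linalg.norm(cand_xy - np.asarray(sc.xx_centroid))
            d_xy = np.linalg.norm(cand_xy - np.asarray(sc.xy_centroid))
            ref = sc.xx_members if d_xx <= d_xy else sc.xy_members
            pts = {m: candidate_points[m].per_scheme[norm] for m in members}
            pts.update({r: control_points[r].per_scheme[norm] for r in ref})
            if len(pts) < 4:
                raise ValueError("need candidate + reference cluster >= 4 points")
            labels = {m: "candidate" for m in members}
            labels.update({r: "reference" for r in ref})
            D = euclidean_distance_matrix(pts)
            out[key][norm] = permanova(D, labels, n_perm=n_perm, seed=seed)
    return out


def significance_grade(p_values: Mapping[str, float]) -> str:
    p = max(p_values.values())  # consistent across all schemes
    if p < P_SIGNIFICANT:
        return "significant"
    if p < P_SUGGESTIVE:
        return "suggestive"
    return "ns"
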