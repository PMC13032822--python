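"""Control-cohort construction, batch testing, and normalization ranking.

A control cohort is the QC-passed, batch-homogeneous set of reference
samples against which queries are compared.  Batches are defined by the
capture kit (clinical vs whole exome) and the indexing mode (single/dual),
because per-chromosome capture efficiency differs between kits and the
differences do not cancel across batches.

Normalization means dividing a chromosome's mean coverage by a normalizer
from the *same* sample, which cancels the sample's global depth.  For each
autosomal target the candidate normalizers are every other single autosome
except 13, 18 and 21 (viable trisomies could corrupt a normalizer) plus the
pooled mean of all other autosomes; candidates are ranked by the cohort
standard deviation of the resulting ratio and the three tightest win.  For
the sex chromosomes the candidates are each single autosome and the pooled
autosomal mean, ranked by the beta-dispersion of the XX and XY clusters in
the (X, Y) normalized plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .coverage_io import AUTOSOMES, CoverageTable, SampleCoverage
from .stats_core import DispersionResult, beta_dispersion, kruskal_wallis

logger = logging.getLogger("karyocov")

ALL_OTHER = "ALL_OTHER"   # pooled mean of the other 21 autosomes (autosomal targets)
ALL_AUTOSOMES = "ALL"     # pooled mean of all 22 autosomes (sex targets)

#: Autosomes with viable full trisomies, never used as single normalizers
#: for autosomal targets (they remain eligible for sex-chromosome targets
#: and still contribute to the pooled denominators).
VIABLE_TRISOMY_CHROMS = frozenset({"13", "18", "21"})

BATCH_P_THRESHOLD = 0.01


@dataclass(frozen=True)
class QCConfig:
    """Minimum autosomal mean depth for a sample to be analysable.

    50x is where chromosome-mean noise is small enough that a full-aneuploidy
    shift clears the baseline by more than 3 standard deviations.
    """

    min_autosomal_mean: float = 50.0
    rationale_zscore: float = 3.0

    def __post_init__(self) -> None:
        if self.min_autosomal_mean <= 0:
            raise ValueError("min_autosomal_mean must be > 0")


@dataclass(frozen=True)
class NormalizationScheme:
    target: str
    normalizer: str  # single chromosome, ALL_OTHER, or ALL

    def __post_init__(self) -> None:
        if self.normalizer == self.target:
            raise ValueError("normalizer must differ from target")
        if self.target in AUTOSOMES:
            if self.normalizer == ALL_AUTOSOMES:
                raise ValueError("ALL_AUTOSOMES normalizer is for sex targets only")
            if self.normalizer in VIABLE_TRISOMY_CHROMS:
                raise ValueError(
                    f"chr{self.normalizer} is excluded as a single normalizer "
                    "for autosomal targets (viable trisomy)"
                )
        elif self.target in ("X", "Y"):
            if self.normalizer == ALL_OTHER:
                raise ValueError("ALL_OTHER normalizer is for autosomal targets only")
        else:
            raise ValueError(f"unknown target {self.target!r}")

    @property
    def id(self) -> str:
        return f"{self.target}/{self.normalizer}"


@dataclass
class NormalizationRanking:
    target: str
    ranked: list[tuple[NormalizationScheme, float]]

    @property
    def top3(self) -> list[NormalizationScheme]:
        return [s for s, _ in self.ranked[:3]]


@dataclass
class ControlCohort:
    group_key: tuple[str, str]
    samples: CoverageTable
    qc: QCConfig
    excluded_sample_ids: list[str] = field(default_factory=list)
    size_floor: int = 30

    def __post_init__(self) -> None:
        for s in self.samples:
            if (s.capture, s.index_mode) != self.group_key:
                raise ValueError(
                    f"sample {s.sample_id} has group {(s.capture, s.index_mode)}, "
                    f"cohort is {self.group_key}"
                )
        if 0 < len(self.samples) < 100:
            logger.warning(
                "cohort %s has only %d samples; rankings may be unstable",
                self.group_key, len(self.samples),
            )

    @property
    def usable(self) -> bool:
        return len(self.samples) >= self.size_floor


# ---------------------------------------------------------------------------
# QC and grouping
# ---------------------------------------------------------------------------


def qc_filter(table: CoverageTable, qc: QCConfig) -> tuple[CoverageTable, list[str]]:
    """Keep samples with autosomal mean >= threshold ('lower than' is strict)."""
    if len(table) == 0:
        raise ValueError("empty coverage table")
    kept, excluded = [], []
    for s in table:
        if s.autosomal_mean < qc.min_autosomal_mean:
            logger.info(
                "QC exclude %s: autosomal mean %.2fx < %.2fx",
                s.sample_id, s.autosomal_mean, qc.min_autosomal_mean,
            )
            excluded.append(s.sample_id)
        else:
            kept.append(s)
    if not kept:
        raise ValueError(
            f"all {len(table)} samples fail QC at {qc.min_autosomal_mean}x; "
            "review the threshold or the input coverage"
        )
    return CoverageTable(kept, provenance=table.provenance), excluded


def split_groups(
    table: CoverageTable, qc: QCConfig = QCConfig(), size_floor: int = 30
) -> list[ControlCohort]:
    """One cohort per observed (capture, index_mode) pair, QC applied per group."""
    by_key: dict[tuple[str, str], list[SampleCoverage]] = {}
    for s in table:
        by_key.setdefault((s.capture, s.index_mode), []).append(s)
    cohorts = []
    for key in sorted(by_key):
        sub = CoverageTable(by_key[key], provenance=table.provenance)
        kept, excluded = qc_filter(sub, qc)
        cohort = ControlCohort(
            group_key=key, samples=kept, qc=qc,
            excluded_sample_ids=excluded, size_floor=size_floor,
        )
        if not cohort.usable:
            logger.warning(
                "cohort %s unusable: %d samples < floor %d", key, len(kept), size_floor
            )
        cohorts.append(cohort)
    return cohorts


def batch_significance(table: CoverageTable) -> dict[str, tuple[float, float]]:
    """Kruskal-Wallis per autosome on depth-normalized coverage across batches.

    The tested quantity is mean_cov[chrom] / autosomal_mean, i.e. each
    autosome normalized by the sample's mean autosomal coverage; p < .01
    flags batch heterogeneity on that chromosome.
    """
    by_key: dict[tuple[str, str], list[SampleCoverage]] = {}
    for s in table:
        by_key.setdefault((s.capture, s.index_mode), []).append(s)
    if len(by_key) < 2:
        raise ValueError("batch_significance needs at least 2 (capture, index) groups")
    out: dict[str, tuple[float, float]] = {}
    for c in AUTOSOMES:
        groups = [
            [s.mean_cov[c] / s.autosomal_mean for s in members]
            for members in by_key.values()
        ]
        out[c] = kruskal_wallis(groups)
    return out


# ---------------------------------------------------------------------------
# Normalized ratios
# ---------------------------------------------------------------------------


def _pooled_autosome_mean(
    sample: SampleCoverage, exclude: str | None, weighted: bool = True
) -> float:
    chroms = [c for c in AUTOSOMES if c != exclude]
    if weighted and sample.target_bases:
        tb = sample.target_bases
        den = sum(tb[c] for c in chroms)
        if den > 0:
            return sum(sample.mean_cov[c] * tb[c] for c in chroms) / den
    return float(np.mean([sample.mean_cov[c] for c in chroms]))


def normalized_ratio(
    sample: SampleCoverage, scheme: NormalizationScheme, weighted: bool = True
) -> float:
    """Target chromosome coverage divided by the scheme's normalizer."""
    num = sample.mean_cov[scheme.target]
    if scheme.normalizer == ALL_OTHER:
        den = _pooled_autosome_mean(sample, exclude=scheme.target, weighted=weighted)
    elif scheme.normalizer == ALL_AUTOSOMES:
        den = _pooled_autosome_mean(sample, exclude=None, weighted=weighted)
    else:
        den = sample.mean_cov[scheme.normalizer]
    if den <= 0:
        raise ValueError(
            f"zero/negative denominator for normalizer {scheme.normalizer!r} "
            f"in sample {sample.sample_id}"
        )
    return num / den


def ratio_matrix(
    samples: Sequence[SampleCoverage] | CoverageTable,
    schemes: Sequence[NormalizationScheme],
) -> np.ndarray:
    return np.asarray(
        [[normalized_ratio(s, sch) for sch in schemes] for s in samples], dtype=float
    )


# ---------------------------------------------------------------------------
# Rankings
# ---------------------------------------------------------------------------


def _sort_key(scheme: NormalizationScheme, spread: float) -> tuple:
    # deterministic tie-break: pooled normalizer first, then chromosome number
    pooled = 0 if scheme.normalizer in (ALL_OTHER, ALL_AUTOSOMES) else 1
    num = 0 if pooled == 0 else int(scheme.normalizer)
    return (spread, pooled, num)


def rank_autosome_normalizations(
    cohort: ControlCohort, target: str
) -> NormalizationRanking:
    """Rank candidate normalizers for one autosome by cohort ratio SD (ddof=1)."""
    if not cohort.usable:
        raise ValueError(
            f"cohort {cohort.group_key} has {len(cohort.samples)} samples, "
            f"below the floor of {cohort.size_floor}"
        )
    if target not in AUTOSOMES:
        raise ValueError(f"target must be an autosome, got {target!r}")
    candidates = [
        NormalizationScheme(target, j)
        for j in AUTOSOMES
        if j != target and j not in VIABLE_TRISOMY_CHROMS
    ]
    candidates.append(NormalizationScheme(target, ALL_OTHER))
    scored = []
    for sch in candidates:
        ratios = [normalized_ratio(s, sch) for s in cohort.samples]
        scored.append((sch, float(np.std(ratios, ddof=1))))
    scored.sort(key=lambda t: _sort_key(*t))
    return NormalizationRanking(target=target, ranked=scored)


def rank_sex_normalizations(
    cohort: ControlCohort,
    cluster_labels: Mapping[str, str],
    center: str = "centroid",
) -> tuple[NormalizationRanking, dict[str, DispersionResult]]:
    """Rank sex-chromosome normalizers by XX/XY cluster beta-dispersion.

    One ranking is shared by X and Y: each candidate produces 2-D points
    (X ratio, Y ratio) and is scored by the mean of the XX- and XY-cluster
    dispersions.  Chromosomes 13/18/21 are eligible here.  Returns the
    ranking plus the full per-candidate dispersion table.
    """
    if not cohort.usable:
        raise ValueError(f"cohort {cohort.group_key} below size floor")
    for lab in ("XX", "XY"):
        n = sum(1 for s in cohort.samples if cluster_labels.get(s.sample_id) == lab)
        if n < 3:
            raise ValueError(f"cluster {lab} has {n} members; need >= 3")
    candidates = [j for j in AUTOSOMES] + [ALL_AUTOSOMES]
    scored = []
    details: dict[str, DispersionResult] = {}
    for norm in candidates:
        sx = NormalizationScheme("X", norm)
        sy = NormalizationScheme("Y", norm)
        points = {
            s.sample_id: (normalized_ratio(s, sx), normalized_ratio(s, sy))
            for s in cohort.samples
            if cluster_labels.get(s.sample_id) in ("XX", "XY")
        }
        labels = {sid: cluster_labels[sid] for sid in points}
        disp = beta_dispersion(points, labels, center=center)
        details[norm] = disp
        scored.append((sx, disp.mean_dispersion))
    scored.sort(key=lambda t: _sort_key(*t))
    ranking = NormalizationRanking(target="XY", ranked=scored)
    return ranking, details
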