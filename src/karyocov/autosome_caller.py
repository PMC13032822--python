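"""Autosomal aneuploidy calling: PC1 projection + interquartile outlier rule.

For each autosome, every sample is summarised by its three best normalized
coverage ratios.  A PCA is fitted on the control cohort (centering only, no
scaling); queries are projected into that space and PC1 — oriented so that
higher coverage means higher PC1 — carries essentially all copy-number
signal because the three ratios co-vary with copy number.  A query is
flagged when its PC1 falls strictly outside

    [Q1 - m*IQR,  Q3 + m*IQR],   m = 5.5 by default,

with the quartiles taken over the control PC1 values.  The direction and an
apparent mosaic fraction follow from the mean ratio r relative to the
control median: an f-fraction trisomy multiplies coverage by (2 + f)/2 and
an f-fraction monosomy by (2 - f)/2, so f_hat = 2*|r - 1|.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .control_builder import (
    ControlCohort,
    NormalizationRanking,
    QCConfig,
    ratio_matrix,
)
from .coverage_io import AUTOSOMES, CoverageTable
from .stats_core import pca, quartiles

logger = logging.getLogger("karyocov")


@dataclass(frozen=True)
class OutlierRule:
    multiplier: float = 5.5

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValueError("multiplier must be > 0")


@dataclass
class AutosomeCallResult:
    sample_id: str
    chromosome: str
    pc1: float
    lower_bound: float
    upper_bound: float
    flagged: bool
    direction: str                    # gain | loss | none
    mosaic_fraction_est: float
    ratios: tuple[float, float, float]
    normalization_ids: tuple[str, str, str]
    status: str = "evaluated"         # evaluated | not_evaluated
    notes: list[str] = field(default_factory=list)


def project_pc1(
    control_ratios: np.ndarray,
    query_ratios: np.ndarray,
    fit_on: str = "controls",
) -> tuple[np.ndarray, np.ndarray]:
    """Fit PCA on the control ratio matrix and project queries onto PC1.

    ``fit_on='all'`` mirrors a joint control+query fit (the unsupervised
    variant); the default fits on controls only so an aberrant query cannot
    shift its own threshold.  PC1 is oriented so that larger normalized
    coverage gives larger PC1 (positive correlation with the per-sample mean
    of the three ratios).
    """
    C = np.asarray(control_ratios, float)
    Q = np.asarray(query_ratios, float).reshape(-1, C.shape[1])
    if C.shape[0] < 30:
        raise ValueError("need at least 30 control samples to fit PC1")
    if np.all(C.std(axis=0) == 0):
        # fully degenerate controls (e.g. a noiseless synthetic cohort): PC1
        # degenerates to the mean-ratio axis, control scores are all 0 and
        # the downstream IQR=0 warning path takes over
        logger.warning(
            "control ratios have zero variance; using the mean-ratio axis as PC1"
        )
        axis = np.ones(C.shape[1]) / np.sqrt(C.shape[1])
        mu = C.mean(axis=0)
        return (C - mu) @ axis, (Q - mu) @ axis
    fit_matrix = C if fit_on == "controls" else np.vstack([C, Q])
    res = pca(fit_matrix, center=True, scale=False)
    control_pc1 = res.transform(C)[:, 0]
    if np.corrcoef(control_pc1, C.mean(axis=1))[0, 1] < 0:
        res.flip_component(0)
        control_pc1 = -control_pc1
    query_pc1 = res.transform(Q)[:, 0]
    return control_pc1, query_pc1


def flag_outliers(
    control_pc1: np.ndarray,
    query_pc1: np.ndarray,
    rule: OutlierRule = OutlierRule(),
) -> tuple[np.ndarray, float, float]:
    """Strict-inequality IQR flags; returns (flags, lower_bound, upper_bound)."""
    q1, q2, q3 = quartiles(control_pc1)
    iqr = q3 - q1
    if iqr == 0:
        warnings.warn(
            "control PC1 IQR is 0; flagging any query PC1 different from the median",
            stacklevel=2,
        )
        flags = np.asarray(query_pc1) != q2
        return flags, q2, q2
    lo = q1 - rule.multiplier * iqr
    hi = q3 + rule.multiplier * iqr
    q = np.asarray(query_pc1, float)
    return (q < lo) | (q > hi), lo, hi


def estimate_direction_and_fraction(
    ratios: np.ndarray, control_median_ratios: np.ndarray
) -> tuple[str, float]:
    """Direction and apparent cell fraction from the mean relative ratio."""
    med = np.asarray(control_median_ratios, float)
    if np.any(med <= 0):
        raise ValueError("control median ratios must be positive")
    r = float(np.mean(np.asarray(ratios, float) / med))
    direction = "gain" if r > 1 else ("loss" if r < 1 else "none")
    return direction, 2.0 * abs(r - 1.0)


def call_autosomes(
    cohort: ControlCohort,
    rankings: dict[str, NormalizationRanking],
    queries: CoverageTable,
    rule: OutlierRule = OutlierRule(),
    qc: QCConfig | None = None,
    fit_on: str = "controls",
    consistency_filter: bool = False,
) -> list[AutosomeCallResult]:
    """One result per (query, autosome) against a fitted control cohort.

    Queries failing the same QC as the controls are reported with status
    ``not_evaluated``.  When a chromosome is flagged in a query, every other
    chromosome whose top-3 schemes use the flagged chromosome as a single
    normalizer receives a cross-contamination note (an aneuploid normalizer
    distorts the ratios it serves).  The optional consistency filter keeps a
    flag only when all three ratios deviate in the same direction.
    """
    qc = qc or cohort.qc
    for s in queries:
        if (s.capture, s.index_mode) != cohort.group_key:
            raise ValueError(
                f"query {s.sample_id} group {(s.capture, s.index_mode)} does not "
                f"match cohort {cohort.group_key}"
            )
    evaluable = [s for s in queries if s.autosomal_mean >= qc.min_autosomal_mean]
    skipped = [s for s in queries if s.autosomal_mean < qc.min_autosomal_mean]
    results: list[AutosomeCallResult] = []
    for s in skipped:
        for chrom in AUTOSOMES:
            results.append(
                AutosomeCallResult(
                    sample_id=s.sample_id, chromosome=chrom, pc1=np.nan,
                    lower_bound=np.nan, upper_bound=np.nan, flagged=False,
                    direction="none", mosaic_fraction_est=np.nan,
                    ratios=(np.nan,) * 3, normalization_ids=("",) * 3,
                    status="not_evaluated",
                    notes=[f"autosomal mean {s.autosomal_mean:.1f}x below QC"],
                )
            )

    per_query_flags: dict[str, set[str]] = {s.sample_id: set() for s in evaluable}
    evaluated: list[AutosomeCallResult] = []
    for chrom in AUTOSOMES:
        ranking = rankings[chrom]
        schemes = ranking.top3
        scheme_ids = tuple(sch.id for sch in schemes)
        C = ratio_matrix(cohort.samples, schemes)
        if not evaluable:
            continue
        Q = ratio_matrix(evaluable, schemes)
        control_pc1, query_pc1 = project_pc1(C, Q, fit_on=fit_on)
        flags, lo, hi = flag_outliers(control_pc1, query_pc1, rule)
        med = np.median(C, axis=0)
        for i, s in enumerate(evaluable):
            direction, frac = estimate_direction_and_fraction(Q[i], med)
            flagged = bool(flags[i])
            if flagged and consistency_filter:
                dev = Q[i] / med - 1.0
                if not (np.all(dev > 0) or np.all(dev < 0)):
                    flagged = False
            if not flagged:
                direction_out, frac_out = "none", frac
            else:
                direction_out, frac_out = direction, frac
                per_query_flags[s.sample_id].add(chrom)
            evaluated.append(
                AutosomeCallResult(
                    sample_id=s.sample_id, chromosome=chrom,
                    pc1=float(query_pc1[i]), lower_bound=lo, upper_bound=hi,
                    flagged=flagged, direction=direction_out,
                    mosaic_fraction_est=frac_out,
                    ratios=tuple(float(x) for x in Q[i]),
                    normalization_ids=scheme_ids,
                )
            )

    # cross-contamination notes: flagged chromosome used as a normalizer elsewhere
    for res in evaluated:
        flagged_chroms = per_query_flags.get(res.sample_id, set())
        users = [
            f for f in flagged_chroms
            if f != res.chromosome
            and any(nid.endswith(f"/{f}") for nid in res.normalization_ids)
        ]
        if users:
            res.notes.append(
                "normalizer(s) flagged in this sample may distort this "
                f"chromosome's ratios: chr{', chr'.join(sorted(users, key=int))}"
            )
    results.extend(evaluated)
    return results
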