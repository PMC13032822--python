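"""Synthetic mosaic spike-ins and per-chromosome detectability calibration.

A mosaic aneuploidy present in a fraction f of cells shifts a chromosome's
expected coverage multiplicatively: a trisomy by (2 + f)/2 and a monosomy
by (2 - f)/2 ("cell_fraction" convention).  The alternative
"coverage_change" convention interprets f directly as the relative coverage
change (factors 1 + f / 1 - f); both are implemented because percentage
mosaicism and percentage coverage change are easily conflated.  Spiking is
a deterministic rescaling of the chromosome mean — equivalent in
expectation to read-level subsampling, and exactly reproducible.

The calibration sweep spikes real (or simulated) control individuals at a
grid of fractions and asks the autosomal caller to find them, yielding the
minimal reliably-detectable fraction per chromosome for gains and losses
separately, and a status class at a probe fraction (default 20%):
``both`` / ``gain_only`` / ``loss_only`` / ``none``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autosome_caller import OutlierRule, flag_outliers, project_pc1
from .control_builder import ControlCohort, NormalizationRanking, ratio_matrix
from .coverage_io import AUTOSOMES, SampleCoverage

CONVENTIONS = ("cell_fraction", "coverage_change")
DEFAULT_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))


@dataclass(frozen=True)
class MosaicSpec:
    base_sample_id: str
    chromosome: str
    kind: str                      # trisomy | monosomy
    fraction: float
    convention: str = "cell_fraction"

    def __post_init__(self) -> None:
        if self.kind not in ("trisomy", "monosomy"):
            raise ValueError("kind must be 'trisomy' or 'monosomy'")
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if self.convention not in CONVENTIONS:
            raise ValueError(f"convention must be one of {CONVENTIONS}")

    @property
    def coverage_factor(self) -> float:
        f = self.fraction
        sign = 1.0 if self.kind == "trisomy" else -1.0
        delta = f / 2.0 if self.convention == "cell_fraction" else f
        return 1.0 + sign * delta


@dataclass
class ThresholdResult:
    chromosome: str
    min_fraction_gain: float | None
    min_fraction_loss: float | None
    status_at_probe: str
    probe_fraction: float
    sweep: dict[float, tuple[float, float]] = field(default_factory=dict)
    convention: str = "cell_fraction"


def make_mosaic(sample: SampleCoverage, spec: MosaicSpec) -> SampleCoverage:
    """Spike one chromosome of a base sample with a mosaic aneuploidy."""
    factor = spec.coverage_factor
    if factor <= 0:
        raise ValueError(
            "coverage_change monosomy at fraction 1 would zero the chromosome"
        )
    mean_cov = dict(sample.mean_cov)
    mean_cov[spec.chromosome] *= factor
    new_id = (
        f"{sample.sample_id}+{spec.kind[:3]}{spec.chromosome}"
        f"_f{spec.fraction:g}_{spec.convention}"
    )
    return replace(sample, sample_id=new_id, mean_cov=mean_cov, autosomal_mean=None)


def _status(gain_ok: bool, loss_ok: bool) -> str:
    if gain_ok and loss_ok:
        return "both"
    if gain_ok:
        return "gain_only"
    if loss_ok:
        return "loss_only"
    return "none"


def sweep_thresholds(
    cohort: ControlCohort,
    rankings: dict[str, NormalizationRanking],
    chromosome: str,
    grid: tuple[float, ...] = DEFAULT_GRID,
    n_base: int = 25,
    rule: OutlierRule = OutlierRule(),
    seed: int = 0,
    convention: str = "cell_fraction",
    detection_quorum: float = 0.9,
    probe_fraction: float = 0.2,
) -> ThresholdResult:
    """Minimal reliably-detectable mosaic fraction for one chromosome.

    For every grid fraction and each of trisomy/monosomy, ``n_base`` distinct
    control individuals (seeded draw) are spiked, projected, and flagged by
    the interquartile rule; the minimal fraction is the smallest grid value
    whose flagged rate reaches ``detection_quorum``.
    """
    if not grid:
        raise ValueError("empty fraction grid")
    if chromosome not in AUTOSOMES:
        raise ValueError(f"threshold sweep targets autosomes, got {chromosome!r}")
    if not cohort.usable:
        raise ValueError("cohort below size floor")
    grid = tuple(sorted(grid))
    schemes = rankings[chromosome].top3
    C = ratio_matrix(cohort.samples, schemes)
    rng = np.random.default_rng(seed)
    n_base_eff = min(n_base, len(cohort.samples))
    base_idx = rng.choice(len(cohort.samples), size=n_base_eff, replace=False)
    bases = [cohort.samples.samples[i] for i in base_idx]

    sweep: dict[float, tuple[float, float]] = {}
    import warnings as _warnings

    cpc1, _ = project_pc1(C, C[:1])
    for f in grid:
        rates = []
        for kind in ("trisomy", "monosomy"):
            spiked = [
                make_mosaic(
                    b,
                    MosaicSpec(b.sample_id, chromosome, kind, f, convention),
                )
                for b in bases
            ]
            Q = ratio_matrix(spiked, schemes)
            _, qpc1 = project_pc1(C, Q)
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")  # IQR=0 path is expected at sigma=0
                flags, _, _ = flag_outliers(cpc1, qpc1, rule)
            rates.append(float(np.mean(flags)))
        sweep[float(f)] = (rates[0], rates[1])

    def _min_fraction(which: int) -> float | None:
        for f in grid:
            if sweep[float(f)][which] >= detection_quorum:
                return float(f)
        return None

    probe = min(grid, key=lambda f: abs(f - probe_fraction))
    gain_ok = sweep[float(probe)][0] >= detection_quorum
    loss_ok = sweep[float(probe)][1] >= detection_quorum
    return ThresholdResult(
        chromosome=chromosome,
        min_fraction_gain=_min_fraction(0),
        min_fraction_loss=_min_fraction(1),
        status_at_probe=_status(gain_ok, loss_ok),
        probe_fraction=float(probe),
        sweep=sweep,
        convention=convention,
    )
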