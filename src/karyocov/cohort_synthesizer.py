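"""Synthetic coverage cohorts with known karyotype truth.

The generative model for sample s and chromosome c is

    mean_cov[s, c] = D_s * e_c * (cn_{s,c} / 2) * eps_{s,c}

with per-sample depth D_s ~ LogNormal(depth_log_mean, depth_log_sd),
per-chromosome capture efficiency e_c (a property of the kit), copy number
cn from the karyotype and any spike-ins, and multiplicative noise
eps ~ Normal(1, sigma_c) truncated at 0.2.  Samples without a Y chromosome
still show a residual Y signal D_s * y_background * eps (reads mismapping
to X-homologous Y targets).  At clinical depths (>= 50x over many targeted
bases) chromosome-mean noise is well approximated as multiplicative, which
is why no read-level (Poisson) machinery is modelled.

Three named capture presets ship with the package, parameterised so the
XX/XY cluster centres land where each kit family puts them (clinical-exome
Y panels are small but deep; whole-exome kits tile a much wider Y region)
and so the per-chromosome noise ordering is realistic: gene-dense,
GC-extreme chromosomes (16, 17, 19, 20, 22) and the sparsely targeted 13
are noisy, mid-size chromosomes are quiet.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .coverage_io import AUTOSOMES, CANONICAL_CHROMS, CoverageTable, SampleCoverage
from .mosaic_simulator import MosaicSpec, make_mosaic

SEX_KARYOTYPES = ("XX", "XY", "X0", "XXX", "XXY", "XYY")

#: (x copies, y copies) per sex karyotype
_SEX_COPIES = {
    "XX": (2, 0), "XY": (1, 1), "X0": (1, 0),
    "XXX": (3, 0), "XXY": (2, 1), "XYY": (1, 2),
}

#: Baseline per-chromosome noise SD of the chromosome-mean coverage.
DEFAULT_NOISE_SD: dict[str, float] = {
    **{c: 0.02 for c in CANONICAL_CHROMS},
    "13": 0.045, "16": 0.04, "17": 0.03, "18": 0.025, "19": 0.06,
    "20": 0.03, "21": 0.03, "22": 0.045, "X": 0.025, "Y": 0.05,
}

#: Approximate targeted megabases per chromosome (exome-like design), used
#: as target-base counts so weighted autosomal means are exercised.
DEFAULT_TARGET_MB: dict[str, float] = {
    "1": 7.5, "2": 5.4, "3": 4.4, "4": 3.1, "5": 3.5, "6": 3.9, "7": 3.6,
    "8": 2.7, "9": 3.1, "10": 3.0, "11": 4.3, "12": 4.0, "13": 1.4,
    "14": 2.4, "15": 2.6, "16": 3.3, "17": 4.3, "18": 1.2, "19": 4.2,
    "20": 1.9, "21": 0.8, "22": 1.7, "X": 2.6, "Y": 0.2,
}


def _capture_profile(e_x: float, e_y: float, rng_seed: int) -> dict[str, float]:
    # mild, kit-specific autosomal efficiency texture around 1
    rng = np.random.default_rng(rng_seed)
    prof = {c: float(np.exp(rng.normal(0.0, 0.08))) for c in AUTOSOMES}
    prof["X"] = e_x
    prof["Y"] = e_y
    return prof


#: Named presets; sex-chromosome efficiencies follow the cluster centres the
#: kit families produce (see module docstring): clinical exome XY cluster at
#: (x ~ 0.5, y ~ 1), WES-single (~0.8, ~0.8), WES-dual (~0.5, ~0.6).
PRESETS: dict[str, dict] = {
    "CES-like": dict(group_key=("CES", "single"), e_x=1.0, e_y=2.0, profile_seed=11),
    "WES-single-like": dict(group_key=("WES", "single"), e_x=1.6, e_y=1.6, profile_seed=12),
    "WES-dual-like": dict(group_key=("WES", "dual"), e_x=1.0, e_y=1.2, profile_seed=13),
}


@dataclass
class SimulationConfig:
    n_samples: int = 300
    capture_profile: dict[str, float] = field(default_factory=lambda: _capture_profile(1.0, 2.0, 11))
    depth_log_mean: float = float(np.log(100.0))
    depth_log_sd: float = 0.25
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    y_background: float = 0.01
    sex_ratio: float = 0.5
    spikes: list[tuple[object, int]] = field(default_factory=list)
    group_key: tuple[str, str] = ("CES", "single")
    seed: int = 0
    target_mb: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TARGET_MB))

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if any(v <= 0 for v in self.capture_profile.values()):
            raise ValueError("capture efficiencies must be positive")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise SDs must be non-negative")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")
        if sum(n for _, n in self.spikes) > self.n_samples:
            raise ValueError("spike counts exceed n_samples")

    @staticmethod
    def from_preset(name: str, **overrides) -> "SimulationConfig":
        p = PRESETS[name]
        cfg = SimulationConfig(
            capture_profile=_capture_profile(p["e_x"], p["e_y"], p["profile_seed"]),
            group_key=p["group_key"],
        )
        for k, v in overrides.items():
            if k == "noise_sd" and isinstance(v, Mapping):
                cfg.noise_sd.update(v)
            else:
                setattr(cfg, k, v)
        cfg.__post_init__()
        return cfg


@dataclass
class TruthRecord:
    sex_karyotype: str
    autosomal_spikes: list[tuple[str, str, float]] = field(default_factory=list)
    sex_spike: str | None = None
    sex_spike_fraction: float | None = None


@dataclass
class TruthTable:
    records: dict[str, TruthRecord]

    def __getitem__(self, sample_id: str) -> TruthRecord:
        return self.records[sample_id]


def _truncated_normal(rng: np.random.Generator, sd: float, size) -> np.ndarray:
    eps = rng.normal(1.0, sd, size=size)
    return np.maximum(eps, 0.2)


def spike_karyotype(
    sample: SampleCoverage,
    spec,
    truth: TruthRecord,
    fraction: float = 1.0,
) -> tuple[SampleCoverage, TruthRecord]:
    """Apply a sex-karyotype change or an autosomal mosaic to a sample.

    ``spec`` is a sex karyotype name ("XXY", ...) applied at cell fraction
    ``fraction``, or a (chromosome, kind, fraction) autosomal triple.  Sex
    gains/losses scale relative to the baseline copy count: an XY sample
    gaining one X in a fraction f of cells goes 1 -> 2 copies, factor 1 + f.
    """
    if isinstance(spec, str):
        if spec not in _SEX_COPIES:
            raise ValueError(f"unknown sex karyotype {spec!r}")
        bx, by = _SEX_COPIES[truth.sex_karyotype]
        tx, ty = _SEX_COPIES[spec]
        mean_cov = dict(sample.mean_cov)
        for chrom, base, tgt in (("X", bx, tx), ("Y", by, ty)):
            if base == tgt:
                continue
            if base == 0:
                raise ValueError(
                    f"cannot spike {spec} onto {truth.sex_karyotype}: "
                    f"{chrom} gain from 0 copies has no coverage baseline"
                )
            mean_cov[chrom] *= 1.0 + fraction * (tgt - base) / base
        out = replace(
            sample,
            sample_id=f"{sample.sample_id}+{spec}" + (f"_f{fraction:g}" if fraction < 1 else ""),
            mean_cov=mean_cov,
            autosomal_mean=None,
        )
        new_truth = replace(
            truth,
            sex_spike=spec,
            sex_spike_fraction=fraction,
            sex_karyotype=spec if fraction == 1.0 else truth.sex_karyotype,
        )
        return out, new_truth
    chrom, kind, frac = spec
    if any(c == chrom for c, _, _ in truth.autosomal_spikes):
        raise ValueError(f"conflicting double spike on chromosome {chrom}")
    out = make_mosaic(sample, MosaicSpec(sample.sample_id, chrom, kind, frac))
    new_truth = replace(
        truth, autosomal_spikes=truth.autosomal_spikes + [(chrom, kind, frac)]
    )
    return out, new_truth


def simulate_cohort(config: SimulationConfig) -> tuple[CoverageTable, TruthTable]:
    """Draw a cohort from the generative model; reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    depths = np.exp(rng.normal(config.depth_log_mean, config.depth_log_sd, size=n))
    sexes = np.where(rng.random(n) < config.sex_ratio, "XY", "XX")
    tb = {c: int(config.target_mb[c] * 1e6) for c in CANONICAL_CHROMS}

    samples: list[SampleCoverage] = []
    records: dict[str, TruthRecord] = {}
    capture, index_mode = config.group_key
    prefix = f"{capture}{index_mode[0].upper()}"
    for i in range(n):
        sid = f"{prefix}{i:04d}"
        sex = str(sexes[i])
        xcn, ycn = _SEX_COPIES[sex]
        mean_cov: dict[str, float] = {}
        for c in CANONICAL_CHROMS:
            eps = float(_truncated_normal(rng, config.noise_sd[c], None))
            if c == "X":
                cn = xcn
            elif c == "Y":
                cn = ycn
            else:
                cn = 2
            if c == "Y" and ycn == 0:
                mean_cov[c] = depths[i] * config.y_background * eps
            else:
                mean_cov[c] = depths[i] * config.capture_profile[c] * (cn / 2.0) * eps
        samples.append(
            SampleCoverage(
                sample_id=sid, capture=capture, index_mode=index_mode,
                mean_cov=mean_cov, target_bases=dict(tb),
            )
        )
        records[sid] = TruthRecord(sex_karyotype=sex)

    # spike-ins replace the earliest compatible samples (deterministic given seed);
    # a sex spike needs the right baseline (X0/XXX arise from XX, XXY/XYY from XY)
    required_baseline = {"X0": "XX", "XXX": "XX", "XXY": "XY", "XYY": "XY"}
    used: set[int] = set()

    def _next_compatible(base_sex: str | None) -> int:
        for j in range(n):
            if j in used:
                continue
            if base_sex is None or records[samples[j].sample_id].sex_karyotype == base_sex:
                return j
        raise ValueError(f"no unspiked {base_sex} sample left for spiking")

    for spec, count in config.spikes:
        for _ in range(count):
            fraction = 1.0
            if isinstance(spec, str):
                name = spec
            elif len(spec) == 2 and isinstance(spec[0], str) and spec[0] in _SEX_COPIES:
                name, fraction = spec  # ("XXY", fraction) mosaic sex spike
            else:
                name = None
            if name is not None:
                pos = _next_compatible(required_baseline.get(name))
                new_s, new_t = spike_karyotype(
                    samples[pos], name, records[samples[pos].sample_id], fraction
                )
            else:
                pos = _next_compatible(None)
                new_s, new_t = spike_karyotype(
                    samples[pos], spec, records[samples[pos].sample_id]
                )
            old_id = samples[pos].sample_id
            samples[pos] = new_s
            del records[old_id]
            records[new_s.sample_id] = new_t
            used.add(pos)

    return CoverageTable(samples, provenance=f"simulated:{config.group_key}"), TruthTable(records)
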