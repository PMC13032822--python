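"""Per-chromosome mean coverage: computation from per-base depth, table I/O.

The atomic record of the whole pipeline is one sample's mean on-target depth
per chromosome (autosomes 1..22 plus X and Y) together with its batch
metadata (capture kit and indexing mode).  Mean coverage of a chromosome is
defined over the *targeted* bases of that chromosome: positions inside the
capture design that received no reads count as depth 0, positions outside
the design are ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("karyocov")

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
SEX_CHROMS: tuple[str, ...] = ("X", "Y")
CANONICAL_CHROMS: tuple[str, ...] = AUTOSOMES + SEX_CHROMS

UNSUPPORTED = "unsupported"

CAPTURES = ("CES", "WES")
INDEX_MODES = ("single", "dual")


def normalize_chrom_label(label: str) -> str:
    """Map a chromosome label to its canonical form ("1".."22", "X", "Y").

    Strips a leading "chr"/"Chr" prefix, maps the numeric aliases 23 -> X and
    24 -> Y, and upper-cases x/y.  Any contig outside the canonical set
    (MT, alts, decoys, ...) yields the sentinel :data:`UNSUPPORTED`.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s == "23":
        return "X"
    if s == "24":
        return "Y"
    if s.upper() in ("X", "Y"):
        return s.upper()
    return s if s in AUTOSOMES else UNSUPPORTED


# ---------------------------------------------------------------------------
# Targets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicTargets:
    """Merged capture-design intervals, 0-based half-open, per chromosome.

    ``intervals`` maps canonical chromosome -> (starts, ends) sorted, merged
    arrays; ``total_bases_per_chromosome`` is the targeted-base count after
    merging, so no position is ever double-counted.
    """

    intervals: Mapping[str, tuple[np.ndarray, np.ndarray]]
    total_bases_per_chromosome: Mapping[str, int]

    @staticmethod
    def from_intervals(raw: Iterable[tuple[str, int, int]]) -> "GenomicTargets":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        n_dropped = 0
        for chrom, start, end in raw:
            if end <= start:
                raise ValueError(f"invalid interval {chrom}:{start}-{end} (end <= start)")
            c = normalize_chrom_label(chrom)
            if c == UNSUPPORTED:
                n_dropped += 1
                continue
            by_chrom.setdefault(c, []).append((int(start), int(end)))
        if n_dropped:
            logger.warning("dropped %d target interval(s) on unsupported contigs", n_dropped)
        if not by_chrom:
            raise ValueError("no usable target intervals on canonical chromosomes")
        merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        totals: dict[str, int] = {}
        for c, ivs in by_chrom.items():
            ivs.sort()
            starts: list[int] = []
            ends: list[int] = []
            for s, e in ivs:
                if starts and s <= ends[-1]:
                    ends[-1] = max(ends[-1], e)
                else:
                    starts.append(s)
                    ends.append(e)
            sa, ea = np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)
            merged[c] = (sa, ea)
            totals[c] = int((ea - sa).sum())
        return GenomicTargets(intervals=merged, total_bases_per_chromosome=totals)

    @staticmethod
    def from_bed(path) -> "GenomicTargets":
        bed = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=["chrom", "start", "end"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64},
        )
        return GenomicTargets.from_intervals(bed.itertuples(index=False, name=None))


# ---------------------------------------------------------------------------
# SampleCoverage / CoverageTable
# ---------------------------------------------------------------------------


def _autosomal_mean(
    mean_cov: Mapping[str, float], target_bases: Mapping[str, int] | None, weighted: bool = True
) -> float:
    """Mean autosomal depth; target-base weighted when counts are available."""
    if weighted and target_bases:
        num = sum(mean_cov[c] * target_bases[c] for c in AUTOSOMES if c in target_bases)
        den = sum(target_bases[c] for c in AUTOSOMES if c in target_bases)
        if den > 0:
            return float(num / den)
    return float(np.mean([mean_cov[c] for c in AUTOSOMES]))


@dataclass
class SampleCoverage:
    """One sample's mean coverage per chromosome plus batch metadata."""

    sample_id: str
    capture: str
    index_mode: str
    mean_cov: dict[str, float]
    target_bases: dict[str, int] | None = None
    autosomal_mean: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.capture not in CAPTURES:
            raise ValueError(f"capture must be one of {CAPTURES}, got {self.capture!r}")
        if self.index_mode not in INDEX_MODES:
            raise ValueError(f"index_mode must be one of {INDEX_MODES}, got {self.index_mode!r}")
        missing = [c for c in CANONICAL_CHROMS if c not in self.mean_cov]
        if missing:
            raise ValueError(f"mean_cov missing chromosome(s): {missing}")
        for c, v in self.mean_cov.items():
            if v < 0 or not np.isfinite(v):
                raise ValueError(f"mean_cov[{c}] must be finite and >= 0, got {v}")
        if self.autosomal_mean is None:
            self.autosomal_mean = _autosomal_mean(self.mean_cov, self.target_bases)

    def scaled(self, factor: float, suffix: str = "") -> "SampleCoverage":
        """Return a copy with every chromosome's coverage multiplied by ``factor``."""
        return replace(
            self,
            sample_id=self.sample_id + suffix,
            mean_cov={c: v * factor for c, v in self.mean_cov.items()},
            autosomal_mean=self.autosomal_mean * factor,
        )


@dataclass
class CoverageTable:
    samples: list[SampleCoverage]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_id(s): {dups}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[SampleCoverage]:
        return iter(self.samples)

    def get(self, sample_id: str) -> SampleCoverage:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def subset(self, ids: Iterable[str]) -> "CoverageTable":
        wanted = set(ids)
        return CoverageTable(
            [s for s in self.samples if s.sample_id in wanted], provenance=self.provenance
        )

    def matrix(self, chroms: Iterable[str] = CANONICAL_CHROMS) -> pd.DataFrame:
        """Samples x chromosomes mean-coverage matrix (index: sample_id)."""
        chroms = list(chroms)
        data = {c: [s.mean_cov[c] for s in self.samples] for c in chroms}
        return pd.DataFrame(data, index=self.sample_ids)


# ---------------------------------------------------------------------------
# Mean coverage from per-base depth
# ---------------------------------------------------------------------------


def compute_mean_coverage(
    depth_stream: Iterable[tuple[str, int, float]],
    targets: GenomicTargets,
    sample_id: str,
    capture: str,
    index_mode: str,
) -> SampleCoverage:
    """Per-chromosome mean on-target depth from (chrom, 1-based pos, depth) records.

    Depth records may arrive in any order.  A targeted position never reported
    in the stream contributes depth 0; off-target positions are ignored.
    Chromosomes present in the targets with zero targeted bases are excluded
    with a warning (they cannot define a mean).
    """
    totals = {
        c: n for c, n in targets.total_bases_per_chromosome.items() if n > 0
    }
    for c, n in targets.total_bases_per_chromosome.items():
        if n <= 0:
            logger.warning("chromosome %s has zero targeted bases; excluded", c)
    if not totals:
        raise ValueError("targets contain no chromosome with targeted bases")

    depth_sum: dict[str, float] = {c: 0.0 for c in totals}
    for chrom, pos, depth in depth_stream:
        c = normalize_chrom_label(chrom)
        if c not in totals:
            continue
        starts, ends = targets.intervals[c]
        p0 = int(pos) - 1  # stream is 1-based, intervals 0-based half-open
        k = int(np.searchsorted(starts, p0, side="right")) - 1
        if k >= 0 and p0 < ends[k]:
            depth_sum[c] += float(depth)

    mean_cov = {c: 0.0 for c in CANONICAL_CHROMS}
    target_bases = {c: 0 for c in CANONICAL_CHROMS}
    for c, n in totals.items():
        mean_cov[c] = depth_sum[c] / n
        target_bases[c] = n
    return SampleCoverage(
        sample_id=sample_id,
        capture=capture,
        index_mode=index_mode,
        mean_cov=mean_cov,
        target_bases=target_bases,
    )


def read_depth_tsv(path) -> Iterator[tuple[str, int, float]]:
    """Stream (chrom, pos, depth) records from a samtools-depth style TSV."""
    for chunk in pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "pos", "depth"],
        dtype={"chrom": str, "pos": np.int64, "depth": np.float64},
        chunksize=1_000_000,
    ):
        yield from chunk.itertuples(index=False, name=None)


# ---------------------------------------------------------------------------
# Coverage-table TSV round trip
# ---------------------------------------------------------------------------

_META_COLS = ["sample_id", "capture", "index_mode"]


def write_coverage_table(table: CoverageTable, path) -> None:
    rows = []
    has_tb = all(s.target_bases is not None for s in table.samples)
    for s in table.samples:
        row: dict[str, object] = {
            "sample_id": s.sample_id, "capture": s.capture, "index_mode": s.index_mode
        }
        # repr of a Python float round-trips exactly through the TSV
        row.update({c: repr(float(s.mean_cov[c])) for c in CANONICAL_CHROMS})
        if has_tb:
            row.update({f"tb_{c}": s.target_bases[c] for c in CANONICAL_CHROMS})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_coverage_table(path) -> CoverageTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in _META_COLS:
        if col not in df.columns:
            raise ValueError(f"coverage table missing required column {col!r}")
    colmap: dict[str, str] = {}
    for col in df.columns:
        if col in _META_COLS or col.startswith("tb_"):
            continue
        c = normalize_chrom_label(col)
        if c != UNSUPPORTED:
            colmap[c] = col
    missing = [c for c in CANONICAL_CHROMS if c not in colmap]
    if missing:
        raise ValueError(f"coverage table missing chromosome column(s): {missing}")
    tb_cols = {c: f"tb_{c}" for c in CANONICAL_CHROMS if f"tb_{c}" in df.columns}
    samples = []
    for _, row in df.iterrows():
        tb = None
        if len(tb_cols) == len(CANONICAL_CHROMS):
            tb = {c: int(row[tb_cols[c]]) for c in CANONICAL_CHROMS}
        samples.append(
            SampleCoverage(
                sample_id=str(row["sample_id"]),
                capture=str(row["capture"]),
                index_mode=str(row["index_mode"]),
                mean_cov={c: float(row[colmap[c]]) for c in CANONICAL_CHROMS},
                target_bases=tb,
            )
        )
    return CoverageTable(samples)
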