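"""Evaluation utilities: promoter assignment, replicate reproducibility
and truth-based benchmarking of peak calls."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

from .io_formats import read_bed_intervals
from .simulate import TruthPeak


class Region(NamedTuple):
    chrom: str
    start: int
    end: int
    score: float = 0.0


@dataclass(frozen=True)
class RegionSet:
    """A sorted set of scored genomic intervals (peak calls)."""

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        for r in self.regions:
            if r.start >= r.end:
                raise ValueError(f"empty interval {r}")
        object.__setattr__(
            self, "regions", tuple(sorted(self.regions, key=lambda r: (r.chrom, r.start)))
        )

    @classmethod
    def from_bed(cls, path: str | Path) -> "RegionSet":
        return cls(tuple(Region(c, s, e, sc) for c, s, e, _n, sc, _st in read_bed_intervals(path)))

    @classmethod
    def from_peaks(cls, peaks) -> "RegionSet":
        return cls(tuple(Region(p.chrom, p.start, p.end, p.score) for p in peaks))

    def __len__(self) -> int:
        return len(self.regions)


class TssEntry(NamedTuple):
    gene_id: str
    chrom: str
    tss: int
    strand: str


@dataclass(frozen=True)
class TssTable:
    """Canonical transcription start sites, one row per gene."""

    entries: tuple[TssEntry, ...]

    @classmethod
    def from_bed(cls, path: str | Path) -> "TssTable":
        """Read a BED6 of TSSs: the interval start is the TSS, name the gene id."""
        return cls(tuple(
            TssEntry(name, chrom, start, strand)
            for chrom, start, _end, name, _score, strand in read_bed_intervals(path)
        ))


def assign_to_promoters(peaks: RegionSet, tss: TssTable, window: int = 2000) -> set[str]:
    """Genes whose promoter window a peak touches.

    A gene is a predicted target iff some peak interval intersects the
    closed window [tss − window, tss + window]; the window is symmetric
    and strand-ignored. Each gene is reported at most once.
    """
    hits: set[str] = set()
    for entry in tss.entries:
        lo, hi = entry.tss - window, entry.tss + window
        for r in peaks.regions:
            # [start, end) intersects closed [lo, hi] iff start <= hi and end > lo
            if r.chrom == entry.chrom and r.start <= hi and r.end > lo:
                hits.add(entry.gene_id)
                break
    return hits


def jaccard_index(set_a: set, set_b: set) -> float:
    """|A ∩ B| / |A ∪ B|; 0 when both sets are empty."""
    union = set_a | set_b
    if not union:
        return 0.0
    return len(set_a & set_b) / len(union)


def _intersects(r: Region, t: TruthPeak, slack: int) -> bool:
    return r.chrom == t.chrom and r.start < t.end + slack and r.end > t.start - slack


def match_to_truth(
    peaks: RegionSet, truth: Sequence[TruthPeak], slack: int = 0
) -> tuple[float, float]:
    """(precision, recall) of peak calls against slack-expanded truth peaks.

    A truth peak is recovered iff some called peak intersects it after
    expanding truth by ``slack`` on both sides; a called peak is correct
    iff it intersects some expanded truth peak. With no calls and no
    truth both are vacuously 1.
    """
    if slack < 0:
        raise ValueError("slack must be non-negative")
    truth = list(truth)
    if not truth:
        recall = 1.0
        precision = 1.0 if not peaks.regions else 0.0
        return precision, recall
    if not peaks.regions:
        return 0.0, 0.0
    correct = sum(1 for r in peaks.regions if any(_intersects(r, t, slack) for t in truth))
    recovered = sum(1 for t in truth if any(_intersects(r, t, slack) for r in peaks.regions))
    return correct / len(peaks.regions), recovered / len(truth)


def read_truth_bed(path: str | Path) -> list[TruthPeak]:
    """Load a truth BED (score column = fold) as written by the simulator."""
    return [
        TruthPeak(chrom, start, end, score)
        for chrom, start, end, _name, score, _strand in read_bed_intervals(path)
    ]
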