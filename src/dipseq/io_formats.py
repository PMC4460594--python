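"""Reading and writing of alignment tracks, genome tables and peak calls.

All coordinates are 0-based, half-open (BED convention). BAM records are
converted on read. Reads are represented by their full mapped interval but
all downstream counting uses the leftmost coordinate only; strand is
retained but unused by the core algorithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file did not parse in the declared format."""


class ReadAlignment(NamedTuple):
    """One aligned, deduplicated single-end read."""

    chrom: str
    start: int  # 0-based leftmost mapped position
    end: int    # exclusive
    strand: str = "+"


class PeakRecord(NamedTuple):
    """A called peak region with its divergence score."""

    chrom: str
    start: int
    end: int
    name: str
    score: float


@dataclass(frozen=True)
class GenomeTable:
    """Ordered chromosome-name -> length (bp) table (UCSC chrom.sizes style)."""

    entries: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, length in self.entries.items():
            if length <= 0:
                raise ValueError(f"non-positive length for chromosome {name!r}: {length}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.entries

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def length(self, chrom: str) -> int:
        return self.entries[chrom]

    def order(self, chrom: str) -> int:
        """Rank of a chromosome in table order, for deterministic sorting."""
        return list(self.entries).index(chrom)

    def sort_key(self):
        ranks = {c: i for i, c in enumerate(self.entries)}
        return lambda chrom: ranks[chrom]


def read_genome_table(path: str | Path) -> GenomeTable:
    """Read a two-column TSV of chromosome name and length, preserving order."""
    entries: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer length {fields[1]!r}") from exc
            if name in entries:
                raise FormatError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            if length <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive length {length} for {name!r}")
            entries[name] = length
    return GenomeTable(entries)


def _read_alignments_bed(path: str | Path, genome: GenomeTable) -> tuple[list[ReadAlignment], int]:
    reads: list[ReadAlignment] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if not 0 <= start < end:
                raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "+"
            if chrom not in genome:
                dropped += 1
                continue
            reads.append(ReadAlignment(chrom, start, end, strand))
    return reads, dropped


def _read_alignments_bam(path: str | Path, genome: GenomeTable) -> tuple[list[ReadAlignment], int]:
    import pysam

    reads: list[ReadAlignment] = []
    dropped = 0
    with pysam.AlignmentFile(str(path), "rb", check_sq=False) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            chrom = rec.reference_name
            if chrom not in genome:
                dropped += 1
                continue
            strand = "-" if rec.is_reverse else "+"
            reads.append(ReadAlignment(chrom, rec.reference_start, rec.reference_end, strand))
    return reads, dropped


def read_alignments(
    path: str | Path, format: str | None = None, genome: GenomeTable | None = None
) -> list[ReadAlignment]:
    """Load mapped primary reads from a BED or BAM track.

    Records on chromosomes absent from ``genome`` are dropped (logged count).
    No deduplication is performed: the input contract is that duplicates were
    removed upstream of peak calling.
    """
    if genome is None:
        raise ValueError("a GenomeTable is required to validate chromosome names")
    if format is None:
        format = "bam" if str(path).endswith(".bam") else "bed"
    if format == "bed":
        reads, dropped = _read_alignments_bed(path, genome)
    elif format == "bam":
        reads, dropped = _read_alignments_bam(path, genome)
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    if dropped:
        logger.info("dropped %d reads on chromosomes absent from the genome table", dropped)
    if not reads:
        logger.warning("no usable reads in %s", path)
    return reads


def write_alignments_bed(reads: Iterable[ReadAlignment], path: str | Path) -> None:
    """Write reads as BED6 (name='.', score=0); deterministic formatting."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t.\t0\t{r.strand}\n")


def write_alignments_bam(
    reads: Sequence[ReadAlignment], path: str | Path, genome: GenomeTable
) -> None:
    """Write reads to a coordinate-unsorted BAM (50M CIGAR-free stub records)."""
    import pysam

    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": c, "LN": genome.length(c)} for c in genome],
    }
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, r in enumerate(reads):
            rec = pysam.AlignedSegment(bam.header)
            rec.query_name = f"read{i}"
            rec.reference_id = bam.header.references.index(r.chrom)
            rec.reference_start = r.start
            rec.mapping_quality = 60
            rec.cigartuples = [(0, r.end - r.start)]
            rec.query_sequence = "N" * (r.end - r.start)
            rec.flag = 16 if r.strand == "-" else 0
            bam.write(rec)


def write_peaks_bed(peaks: Sequence[PeakRecord], path: str | Path) -> None:
    """Write peaks as BED6 with the raw region score at 4 decimal places.

    The score column carries the divergence score directly rather than the
    BED 0-1000 convention. Input must already be sorted by (chrom, start):
    the writer is pure and deterministic, so identical input gives
    byte-identical output.
    """
    finished: set[str] = set()
    prev_chrom: str | None = None
    prev_start = 0
    for p in peaks:
        if p.chrom != prev_chrom:
            if p.chrom in finished:
                raise ValueError(f"peaks not grouped by chromosome at {p.chrom}:{p.start}")
            if prev_chrom is not None:
                finished.add(prev_chrom)
            prev_chrom, prev_start = p.chrom, p.start
        elif p.start < prev_start:
            raise ValueError(f"peaks not sorted by start at {p.chrom}:{p.start}")
        else:
            prev_start = p.start
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:.4f}\t.\n")


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int, str, float, str]]:
    """Parse a BED3..6 file into (chrom, start, end, name, score, strand) tuples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            strand = f[5] if len(f) > 5 else "."
            out.append((f[0], start, end, name, score, strand))
    return out
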