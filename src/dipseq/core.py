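"""The dIP (differential ImmunoPrecipitation) peak-calling algorithm.

The method scores fixed-length genomic segments against an empirical null
built jointly from the IP and matched-control tracks, with no parametric
assumption about peak magnitude. For every segment of length ``L`` it
records the IP read count (*magnitude*, m) and the total read count across
both tracks (*amplitude*, a = m + m̄, with m̄ the control count). The table
N(a, m) of segment counts over all (a, m) pairs, pooled genome-wide, is the
null: at each amplitude the minimum significant magnitude m_min(a) is the
smallest m whose upper-tail fraction

    U(a, m) = Σ_{m' ≥ m} N(a, m') / Σ_{m'} N(a, m')

does not exceed the FDR cutoff φ, then forced non-decreasing in a via
m_min(a) ← max(m_min(a), m_min(a−1)). Significant segments closer than a
gap δ are merged into candidate regions; regions shorter than k or with a
control-read fraction ≥ φ are discarded; survivors are scored with

    score = Σ_segments a · ln(m / m̄)
          = D_KL(m ‖ m̄) − D_KL(m̄ ‖ m)

over the scanned segments fully contained in the region (unnormalized-count
Kullback-Leibler convention).
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left, bisect_right
from collections import Counter
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .io_formats import GenomeTable, PeakRecord, ReadAlignment

logger = logging.getLogger(__name__)

__all__ = [
    "DipConfig",
    "SegmentCounts",
    "NullTable",
    "ThresholdTable",
    "CandidateRegion",
    "DipResult",
    "normalize_tracks",
    "scan_segments",
    "build_null_table",
    "compute_min_magnitude",
    "flag_significant",
    "merge_significant",
    "filter_regions",
    "score_regions",
    "standardize_region_length",
    "call_peaks",
    "run_dip",
]


@dataclass(frozen=True)
class DipConfig:
    """Tunable parameters of the caller.

    L
        Segment length in bp; a lower bound on the immunoprecipitated
        fragment length.
    step
        Offset between successive segment starts; must divide L. The
        default L/4 gives 75% overlap between consecutive segments.
    delta
        Merge gap δ: significant segments closer than this are joined.
    k
        Minimum length of an emitted region.
    phi
        FDR cutoff φ, used both for the per-segment magnitude threshold
        and the region-level control-read fraction.
    seed
        Seed for the resampling step of track normalization.
    pseudocount
        Added to m and m̄ inside the score's logarithm only when one of
        them is zero (the score is otherwise undefined there).
    standard_length
        If set, every reported peak is re-centred to this fixed length
        (clipped at chromosome ends); ``None`` reports raw region spans.
    read_offset
        Optional shift added to each read's leftmost coordinate before
        counting (never applied by default; fragment-shift experiments
        only).
    """

    L: int = 100
    step: int = 25
    delta: int = 1000
    k: int = 150
    phi: float = 0.1
    seed: int = 0
    pseudocount: float = 0.5
    standard_length: int | None = 800
    read_offset: int = 0

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("segment length L must be positive")
        if self.step <= 0 or self.L % self.step != 0:
            raise ValueError("step must be a positive divisor of L")
        if not 0.0 < self.phi < 1.0:
            raise ValueError("phi must lie in (0, 1)")
        if self.k <= 0:
            raise ValueError("minimum region length k must be positive")
        if self.delta < 0:
            raise ValueError("merge gap delta must be non-negative")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.standard_length is not None and self.standard_length <= 0:
            raise ValueError("standard_length must be positive or None")


class SegmentCounts(NamedTuple):
    """A fixed-length scanned window with its IP and control read counts."""

    chrom: str
    start: int
    m: int      # IP reads (magnitude)
    mbar: int   # control reads

    @property
    def a(self) -> int:
        """Amplitude: total reads across both tracks."""
        return self.m + self.mbar


@dataclass(frozen=True)
class NullTable:
    """Empirical counts N(a, m) over all scanned genome segments."""

    counts: dict[tuple[int, int], int]
    totals: dict[int, int]
    n_segments: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_segments:
            raise ValueError("N(a, m) does not sum to the number of segments")


@dataclass(frozen=True)
class ThresholdTable:
    """Minimum significant magnitude per amplitude at FDR phi.

    ``enforced[a]`` is defined for every a in 0..amax (absent amplitudes
    inherit the previous value during the monotone sweep); ``raw`` holds
    the pre-sweep threshold for amplitudes present in the null table.
    A value of a+1 encodes "no magnitude at this amplitude is significant".
    """

    raw: dict[int, int]
    enforced: np.ndarray
    phi: float

    @property
    def amax(self) -> int:
        return len(self.enforced) - 1

    def mmin(self, a: int) -> int:
        if a < 0 or a > self.amax:
            raise KeyError(f"amplitude {a} absent from threshold table (amax={self.amax})")
        return int(self.enforced[a])

    def to_frame(self):
        """Threshold curve as a DataFrame (amplitude, m_min_raw, m_min_enforced)."""
        import pandas as pd

        amps = np.arange(self.amax + 1)
        return pd.DataFrame(
            {
                "amplitude": amps,
                "m_min_raw": [self.raw.get(int(a), np.nan) for a in amps],
                "m_min_enforced": self.enforced.astype(int),
            }
        )


@dataclass
class CandidateRegion:
    """A merged run of significant segments, with recounted totals."""

    chrom: str
    start: int
    end: int
    m_total: int
    mbar_total: int
    segments: tuple[SegmentCounts, ...] = ()
    score: float = 0.0


@dataclass(frozen=True)
class DipResult:
    """Full output of one caller run, for inspection beyond the peak list."""

    peaks: list[PeakRecord]
    regions: list[CandidateRegion]
    thresholds: ThresholdTable
    null_table: NullTable
    n_segments: int
    n_significant: int


def normalize_tracks(
    ip: Sequence[ReadAlignment],
    control: Sequence[ReadAlignment],
    seed: int = 0,
) -> tuple[list[ReadAlignment], list[ReadAlignment]]:
    """Equalize library sizes by upsampling the smaller track.

    The smaller track is augmented with draws with replacement from itself
    until both tracks have max(|ip|, |control|) reads; the larger track is
    returned unchanged. Normalization is global (whole-genome), matching a
    total-read-count normalization, and is deterministic given ``seed``.
    """
    if not ip or not control:
        raise ValueError("both an IP and a control track are required (method is defined only with controls)")
    ip, control = list(ip), list(control)
    target = max(len(ip), len(control))
    rng = np.random.default_rng(seed)

    def upsample(reads: list[ReadAlignment]) -> list[ReadAlignment]:
        extra = target - len(reads)
        if extra == 0:
            return reads
        idx = rng.integers(0, len(reads), size=extra)
        return reads + [reads[i] for i in idx]

    if len(ip) < len(control):
        return upsample(ip), control
    return ip, upsample(control)


def _positions_by_chrom(reads: Sequence[ReadAlignment], offset: int = 0) -> dict[str, np.ndarray]:
    by: dict[str, list[int]] = {}
    for r in reads:
        by.setdefault(r.chrom, []).append(r.start + offset)
    return {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in by.items()}


def _count_in(pos: np.ndarray, start: int, end: int) -> int:
    return int(np.searchsorted(pos, end, side="left") - np.searchsorted(pos, start, side="left"))


def scan_segments(
    ip: Sequence[ReadAlignment],
    control: Sequence[ReadAlignment],
    genome: GenomeTable,
    config: DipConfig = DipConfig(),
) -> list[SegmentCounts]:
    """Count reads in overlapping fixed-length windows across the genome.

    On a chromosome of length C, segments start at 0, step, 2·step, ...
    while start + L ≤ C. A read belongs to a segment iff its leftmost
    mapped coordinate lies in [start, start + L); there is no strand shift
    or fragment extension. Every segment is emitted, including empty ones:
    the a = 0 segments populate N(0, 0) in the null table.
    """
    ip_pos = _positions_by_chrom(ip, config.read_offset)
    ct_pos = _positions_by_chrom(control, config.read_offset)
    empty = np.empty(0, dtype=np.int64)
    segments: list[SegmentCounts] = []
    for chrom in genome:
        C = genome.length(chrom)
        if C < config.L:
            logger.info("chromosome %s (%d bp) shorter than L=%d: no segments", chrom, C, config.L)
            continue
        starts = np.arange(0, C - config.L + 1, config.step, dtype=np.int64)
        ipp = ip_pos.get(chrom, empty)
        ctp = ct_pos.get(chrom, empty)
        m = np.searchsorted(ipp, starts + config.L) - np.searchsorted(ipp, starts)
        mbar = np.searchsorted(ctp, starts + config.L) - np.searchsorted(ctp, starts)
        segments.extend(
            SegmentCounts(chrom, int(s), int(mi), int(bi))
            for s, mi, bi in zip(starts, m, mbar)
        )
    return segments


def build_null_table(segments: Sequence[SegmentCounts]) -> NullTable:
    """Tally N(a, m) over one genome-wide scan."""
    if not segments:
        raise ValueError("cannot build a null table from zero segments")
    counts = Counter((s.a, s.m) for s in segments)
    totals: Counter[int] = Counter()
    for (a, _m), n in counts.items():
        totals[a] += n
    return NullTable(dict(counts), dict(totals), len(segments))


def compute_min_magnitude(null: NullTable, phi: float) -> ThresholdTable:
    """Derive m_min(a) at FDR phi from the empirical null.

    Raw threshold: the smallest m in 0..a+1 whose upper-tail fraction
    U(a, m) = Σ_{m'≥m} N(a, m') / totals[a] satisfies U ≤ phi (U(a, a+1)
    is 0, so a threshold always exists; U(a, 0) is 1, so m_min ≥ 1).
    The monotone sweep then sets m_min(a) ← max(m_min(a), m_min(a−1)),
    with amplitudes absent from the table inheriting the previous value.
    """
    if not 0.0 < phi < 1.0:
        raise ValueError("phi must lie in (0, 1)")
    if not null.totals:
        raise ValueError("empty null table")
    raw: dict[int, int] = {}
    for a, total in null.totals.items():
        # suffix sums of N(a, .) over m = a..0
        tail = 0
        mmin = a + 1  # U(a, a+1) = 0 <= phi always
        for m in range(a, -1, -1):
            tail += null.counts.get((a, m), 0)
            if tail / total <= phi:
                mmin = m
            else:
                break
        raw[a] = mmin
    amax = max(raw)
    enforced = np.empty(amax + 1, dtype=np.int64)
    prev = 0
    for a in range(amax + 1):
        if a in raw:
            prev = max(prev, raw[a])
        enforced[a] = prev
    return ThresholdTable(raw, enforced, phi)


def flag_significant(
    segments: Sequence[SegmentCounts], thresholds: ThresholdTable
) -> list[SegmentCounts]:
    """Keep exactly the segments with m ≥ m_min(a)."""
    out = []
    for s in segments:
        if s.a > thresholds.amax:
            raise KeyError(
                f"segment amplitude {s.a} exceeds threshold table (amax={thresholds.amax}); "
                "thresholds must be built from the same scan"
            )
        if s.m >= thresholds.mmin(s.a):
            out.append(s)
    return out


def merge_significant(
    significant: Sequence[SegmentCounts],
    all_reads_ip: Sequence[ReadAlignment],
    all_reads_control: Sequence[ReadAlignment],
    config: DipConfig = DipConfig(),
    all_segments: Sequence[SegmentCounts] | None = None,
) -> list[CandidateRegion]:
    """Join nearby significant segments into candidate regions.

    On each chromosome, consecutive significant segment spans [start,
    start+L) whose gap (next.start − current region end) is < δ are merged
    transitively; overlapping or abutting spans (gap ≤ 0) always merge.
    Region read totals are recounted from the raw reads over the merged
    interval — overlapping windows would otherwise count each read up to
    L/step times. Each region also collects the scanned segments fully
    contained in it (from ``all_segments`` when given, so that scoring can
    aggregate all evidence, not only the significant windows).
    """
    L = config.L
    ip_pos = _positions_by_chrom(all_reads_ip, config.read_offset)
    ct_pos = _positions_by_chrom(all_reads_control, config.read_offset)
    pool = significant if all_segments is None else all_segments
    seg_by_chrom: dict[str, list[SegmentCounts]] = {}
    for s in pool:
        seg_by_chrom.setdefault(s.chrom, []).append(s)
    for segs in seg_by_chrom.values():
        segs.sort(key=lambda s: s.start)

    empty = np.empty(0, dtype=np.int64)
    regions: list[CandidateRegion] = []

    def close(chrom: str, start: int, end: int) -> None:
        m_total = _count_in(ip_pos.get(chrom, empty), start, end)
        mbar_total = _count_in(ct_pos.get(chrom, empty), start, end)
        segs = seg_by_chrom.get(chrom, [])
        starts = [s.start for s in segs]
        lo = bisect_left(starts, start)
        hi = bisect_right(starts, end - L)
        contained = tuple(segs[lo:hi])
        regions.append(CandidateRegion(chrom, start, end, m_total, mbar_total, contained))

    cur_chrom: str | None = None
    cur_start = cur_end = 0
    for s in significant:
        span_start, span_end = s.start, s.start + L
        if cur_chrom is None:
            cur_chrom, cur_start, cur_end = s.chrom, span_start, span_end
            continue
        if s.chrom == cur_chrom and span_start < cur_start:
            raise ValueError("significant segments must be sorted by (chrom, start)")
        gap = span_start - cur_end
        if s.chrom == cur_chrom and (gap <= 0 or gap < config.delta):
            cur_end = max(cur_end, span_end)
        else:
            close(cur_chrom, cur_start, cur_end)
            cur_chrom, cur_start, cur_end = s.chrom, span_start, span_end
    if cur_chrom is not None:
        close(cur_chrom, cur_start, cur_end)
    return regions


def filter_regions(
    regions: Sequence[CandidateRegion], config: DipConfig = DipConfig()
) -> list[CandidateRegion]:
    """Apply the region-level length and control-fraction filters.

    A region survives iff end − start ≥ k and its control-read fraction
    m̄_total / (m_total + m̄_total) is strictly below φ; empty regions
    (no reads at all) are dropped.
    """
    kept = []
    for r in regions:
        total = r.m_total + r.mbar_total
        if total == 0:
            continue
        if r.end - r.start < config.k:
            continue
        if r.mbar_total / total < config.phi:
            kept.append(r)
    return kept


def segment_score(m: int, mbar: int, pseudocount: float = 0.5) -> float:
    """One segment's contribution a·ln(m/m̄), pseudocounted only at zeros."""
    a = m + mbar
    if a == 0:
        return 0.0
    if m == 0 or mbar == 0:
        return a * math.log((m + pseudocount) / (mbar + pseudocount))
    return a * math.log(m / mbar)


def score_regions(
    regions: Sequence[CandidateRegion], config: DipConfig = DipConfig()
) -> list[CandidateRegion]:
    """Score each region as Σ a·ln(m/m̄) over its contained segments.

    Algebraically this equals D_KL(m‖m̄) − D_KL(m̄‖m) in the
    unnormalized-count convention D_KL(x‖y) = Σ x·ln(x/y). The pseudocount
    enters the logarithm only for segments where m or m̄ is zero.
    """
    out = []
    for r in regions:
        if not r.segments:
            logger.warning("region %s:%d-%d contains no scanned segments; score 0", r.chrom, r.start, r.end)
            out.append(replace_score(r, 0.0))
            continue
        score = sum(segment_score(s.m, s.mbar, config.pseudocount) for s in r.segments)
        out.append(replace_score(r, score))
    return out


def replace_score(region: CandidateRegion, score: float) -> CandidateRegion:
    return CandidateRegion(
        region.chrom, region.start, region.end,
        region.m_total, region.mbar_total, region.segments, score,
    )


def standardize_region_length(
    regions: Sequence[CandidateRegion],
    length: int,
    genome: GenomeTable | None = None,
    name_prefix: str = "dip_peak",
) -> list[PeakRecord]:
    """Re-centre every region to a fixed length (default use: 800 bases).

    Each record spans [center − length/2, center + length/2) with
    center = (start + end) // 2, clipped at chromosome boundaries when a
    genome table is supplied. Scores are carried over unchanged.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    out = []
    for i, r in enumerate(regions, start=1):
        center = (r.start + r.end) // 2
        start = center - length // 2
        end = start + length
        if start < 0:
            start = 0
        if genome is not None and r.chrom in genome:
            end = min(end, genome.length(r.chrom))
        out.append(PeakRecord(r.chrom, start, end, f"{name_prefix}_{i}", r.score))
    return out


def run_dip(
    ip: Sequence[ReadAlignment],
    control: Sequence[ReadAlignment],
    genome: GenomeTable,
    config: DipConfig = DipConfig(),
) -> DipResult:
    """Run the full pipeline, returning peaks plus all intermediate tables.

    Stages: normalize → scan → null table → thresholds → flag → merge →
    filter → score (→ optional fixed-length standardization). Fully
    deterministic given ``config.seed``.
    """
    ip_n, control_n = normalize_tracks(ip, control, config.seed)
    segments = scan_segments(ip_n, control_n, genome, config)
    null = build_null_table(segments)
    thresholds = compute_min_magnitude(null, config.phi)
    significant = flag_significant(segments, thresholds)
    regions = merge_significant(significant, ip_n, control_n, config, all_segments=segments)
    regions = filter_regions(regions, config)
    regions = score_regions(regions, config)

    key = genome.sort_key()
    regions.sort(key=lambda r: (key(r.chrom), r.start, r.end))
    if config.standard_length is not None:
        peaks = standardize_region_length(regions, config.standard_length, genome)
    else:
        peaks = [
            PeakRecord(r.chrom, r.start, r.end, f"dip_peak_{i}", r.score)
            for i, r in enumerate(regions, start=1)
        ]
    return DipResult(peaks, regions, thresholds, null, len(segments), len(significant))


def call_peaks(
    ip: Sequence[ReadAlignment],
    control: Sequence[ReadAlignment],
    genome: GenomeTable,
    config: DipConfig = DipConfig(),
) -> list[PeakRecord]:
    """Call peaks; convenience wrapper around :func:`run_dip`."""
    return run_dip(ip, control, genome, config).peaks
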