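"""Synthetic ChIP-seq track generator.

Emulates the two features of real IP/control pairs that the caller's null
model exists to handle: a shared non-uniform background intensity
(identical in IP and control, standing in for mappability/accessibility
bias and region-specific non-specific pull-down) and localized IP-only
enrichment peaks of configurable fold and width.

The background is piecewise-constant over equal-width bins with
log-normal intensities; control read leftmost positions are drawn from
that intensity alone, IP positions from the same intensity with each peak
interval's mass multiplied by its fold and the mixture renormalized.
Positions are uniform within the chosen constant-intensity stretch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .io_formats import GenomeTable, ReadAlignment, write_alignments_bed


class TruthPeak(NamedTuple):
    chrom: str
    start: int
    end: int
    fold: float


class Peak(NamedTuple):
    """A spiked enrichment site: center (bp), width (bp), fold ≥ 1."""

    center: int
    width: int
    fold: float


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic tracks.

    Defaults model a 1 Mb single-chromosome genome sequenced to 10^5
    deduplicated 50-base single-end reads per track, with background bias
    varying on a 1 kb scale with log-sd 0.5 (roughly a 1.6-fold typical
    bin-to-bin intensity ratio).
    """

    genome_length: int = 1_000_000
    chrom_name: str = "chr1"
    n_reads_ip: int = 100_000
    n_reads_control: int = 100_000
    read_length: int = 50
    background_bins: int = 1000
    background_log_sd: float = 0.5
    peaks: tuple[Peak, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.genome_length, self.n_reads_ip, self.n_reads_control,
               self.read_length, self.background_bins) <= 0:
            raise ValueError("all counts and lengths must be positive")
        if self.background_log_sd < 0:
            raise ValueError("background_log_sd must be non-negative")
        object.__setattr__(self, "peaks", tuple(Peak(*p) for p in self.peaks))
        for p in self.peaks:
            if p.fold < 1:
                raise ValueError(f"peak fold must be ≥ 1, got {p.fold}")
            if p.width <= 0:
                raise ValueError("peak width must be positive")
            start = p.center - p.width // 2
            if start < 0 or start + p.width > self.genome_length:
                raise ValueError(f"peak {p} extends outside the genome")

    def genome(self) -> GenomeTable:
        return GenomeTable({self.chrom_name: self.genome_length})

    def truth(self) -> list[TruthPeak]:
        return [
            TruthPeak(self.chrom_name, p.center - p.width // 2,
                      p.center - p.width // 2 + p.width, p.fold)
            for p in self.peaks
        ]


def spike_peak_layout(
    genome_length: int,
    n_peaks: int,
    width: int,
    fold: float,
    rng: np.random.Generator,
) -> tuple[Peak, ...]:
    """Evenly spaced spiked peaks with jittered centers.

    Peaks are laid out one per genome_length/n_peaks slot with the center
    jittered uniformly within the middle half of its slot, so peaks never
    collide or leave the genome.
    """
    spacing = genome_length // n_peaks
    if spacing < 2 * width:
        raise ValueError("peaks do not fit the genome at this count and width")
    centers = [
        i * spacing + spacing // 2 + int(rng.integers(-spacing // 4, spacing // 4 + 1))
        for i in range(n_peaks)
    ]
    return tuple(Peak(c, width, fold) for c in centers)


def build_background_intensity(config: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-bin background intensities, log-normal(0, log_sd), summing to 1.

    The same table is used for IP and control (shared technical bias).
    With log_sd = 0 every bin gets 1/n_bins.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.background_log_sd == 0:
        w = np.ones(config.background_bins)
    else:
        w = rng.lognormal(mean=0.0, sigma=config.background_log_sd, size=config.background_bins)
    return w / w.sum()


def _subintervals(config: SimConfig, intensity: np.ndarray):
    """Break the genome at bin and peak edges; return per-piece densities.

    Returns (edges, control_weight, ip_weight) where edges has K+1
    breakpoints and the weights are unnormalized sampling masses of the K
    constant-density pieces.
    """
    G = config.genome_length
    bin_edges = np.linspace(0, G, config.background_bins + 1)
    cuts = set(np.rint(bin_edges).astype(int).tolist())
    for p in config.peaks:
        s = p.center - p.width // 2
        cuts.update((s, s + p.width))
    edges = np.array(sorted(c for c in cuts if 0 <= c <= G), dtype=np.int64)
    lo, hi = edges[:-1], edges[1:]
    lengths = hi - lo
    # background density per bp of the bin each piece falls in
    bin_len = G / config.background_bins
    bin_idx = np.minimum((lo / bin_len).astype(int), config.background_bins - 1)
    density = intensity[bin_idx] / bin_len
    ctrl_w = density * lengths
    fold = np.ones(len(lo))
    for p in config.peaks:
        s = p.center - p.width // 2
        inside = (lo >= s) & (hi <= s + p.width)
        fold[inside] *= p.fold
    ip_w = ctrl_w * fold
    return edges, ctrl_w, ip_w


def _draw_positions(
    rng: np.random.Generator, edges: np.ndarray, weights: np.ndarray, n: int, max_start: int
) -> np.ndarray:
    p = weights / weights.sum()
    idx = rng.choice(len(weights), size=n, p=p)
    lo, hi = edges[:-1][idx], edges[1:][idx]
    pos = rng.integers(lo, hi)
    return np.minimum(pos, max_start)  # clip so the read fits the chromosome


def simulate_tracks(
    config: SimConfig,
) -> tuple[list[ReadAlignment], list[ReadAlignment], list[TruthPeak]]:
    """Draw IP and control tracks plus the truth peak list.

    Exact requested read counts; leftmost positions are clipped so reads
    fit the chromosome. With zero peaks (or all folds 1) IP and control
    follow the identical generative law.
    """
    rng = np.random.default_rng(config.seed)
    intensity = build_background_intensity(config, rng)
    edges, ctrl_w, ip_w = _subintervals(config, intensity)
    max_start = config.genome_length - config.read_length
    rl, chrom = config.read_length, config.chrom_name

    ip_pos = _draw_positions(rng, edges, ip_w, config.n_reads_ip, max_start)
    ip_strand = rng.choice(np.array(["+", "-"]), size=config.n_reads_ip)
    ct_pos = _draw_positions(rng, edges, ctrl_w, config.n_reads_control, max_start)
    ct_strand = rng.choice(np.array(["+", "-"]), size=config.n_reads_control)

    ip = [ReadAlignment(chrom, int(s), int(s) + rl, str(st)) for s, st in zip(ip_pos, ip_strand)]
    control = [ReadAlignment(chrom, int(s), int(s) + rl, str(st)) for s, st in zip(ct_pos, ct_strand)]
    return ip, control, config.truth()


def write_simulation(
    ip: Sequence[ReadAlignment],
    control: Sequence[ReadAlignment],
    truth: Sequence[TruthPeak],
    genome: GenomeTable,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write ip.bed, control.bed, truth.bed and genome.tsv; deterministic."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ip": out / "ip.bed",
        "control": out / "control.bed",
        "truth": out / "truth.bed",
        "genome": out / "genome.tsv",
    }
    write_alignments_bed(ip, paths["ip"])
    write_alignments_bed(control, paths["control"])
    with open(paths["truth"], "w") as fh:
        for i, t in enumerate(truth, start=1):
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\ttruth_{i}\t{t.fold:g}\t.\n")
    with open(paths["genome"], "w") as fh:
        for chrom in genome:
            fh.write(f"{chrom}\t{genome.length(chrom)}\n")
    return paths
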