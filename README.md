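# dipseq

Nonparametric peak calling for ChIP-seq experiments with matched
non-specific-antibody controls (e.g. IgG).

Global background models mis-score genomic regions whose read coverage is
driven by local accessibility, mappability or chance pull-down rather than
true binding. `dipseq` sidesteps distributional assumptions entirely: it
conditions each candidate window on how many reads it attracted *in total*
across the IP and control tracks, and asks how unusual the IP's share of
those reads is compared with every other window in the genome with the same
total. The control experiment, not a fitted model, defines the null.

## The method

After equalizing library sizes (resampling the smaller track with
replacement), the genome is scanned in windows of length *L* (default 100 bp)
at offsets of *L*/4, so consecutive windows overlap by 75%. Each window
carries a **magnitude** *m* (IP reads, counted by leftmost coordinate) and an
**amplitude** *a* = *m* + *m̄* (IP + control reads). The empirical table
*N*(*a*, *m*) — how many windows genome-wide show each pair — is the null
distribution. For each amplitude the minimum significant magnitude is

> *m*<sub>min</sub>(*a*) = min { *m* : Σ<sub>*m*′ ≥ *m*</sub> *N*(*a*, *m*′) / Σ<sub>*m*′</sub> *N*(*a*, *m*′) ≤ φ }

at FDR cutoff φ (default 0.1), forced non-decreasing in *a* by
*m*<sub>min</sub>(*a*) ← max(*m*<sub>min</sub>(*a*), *m*<sub>min</sub>(*a*−1)).
Significant windows closer than δ (default 1000 bp) merge into candidate
regions; regions shorter than *k* (default 150 bp) or whose control-read
fraction *m̄*/(*m* + *m̄*) is ≥ φ are discarded. Surviving regions are scored

> score = Σ<sub>segments</sub> *a* · ln(*m* / *m̄*) = *D*<sub>KL</sub>(*m* ‖ *m̄*) − *D*<sub>KL</sub>(*m̄* ‖ *m*),

the difference of unnormalized Kullback–Leibler divergences: large when the
IP carries far more information than the control, zero when the tracks agree.
Reported peaks are optionally re-centred to a fixed 800 bp.

The package also ships a synthetic read simulator (shared non-uniform
background plus IP-only spiked peaks) and evaluation utilities: promoter
assignment within ±2 kb of TSSs, target-gene Jaccard reproducibility, and
truth-based precision/recall.

## Worked example

`examples/01_call_peaks.py` simulates a 1 Mb chromosome with five planted
20-fold binding sites and 10⁴ reads per track, then calls peaks:

```
scanned 39997 segments, 367 significant, 19 regions survive the length and control-fraction filters

  chr1:99775-100250  m=21 mbar=2 score=166.3
  chr1:299775-300600  m=176 mbar=18 score=2085.6
  chr1:499750-500025  m=21 mbar=0 score=104.2
  chr1:899925-900250  m=38 mbar=3 score=427.9
  ...
against the 5 planted sites (500 bp slack): precision=0.21 recall=0.80
```

Four of the five planted sites are called, and they are the top-scoring
regions by a wide margin; the remaining calls are sparse IP-only read
clusters with near-minimal scores, which a score threshold would remove.
`examples/02_threshold_curve.py` prints the *m*<sub>min</sub>(*a*) curve,
`examples/03_benchmark_recovery.py` shows recovery as a function of fold
enrichment, and `examples/04_replicate_reproducibility.py` computes
target-gene Jaccard between simulated replicates.

## Command line

```bash
dipseq simulate --genome-length 1000000 --peaks "500000:400:20" --seed 1 --out-dir sim/
dipseq call --ip sim/ip.bed --control sim/control.bed --genome sim/genome.tsv \
            --out peaks.bed --fdr 0.1 --seed 1 --dump-thresholds thresholds.tsv
dipseq bench --peaks peaks.bed --truth sim/truth.bed --slack 500
dipseq compare --peaks-a a.bed --peaks-b b.bed --tss tss.bed --window 2000
```

Input tracks are BED6 or BAM of aligned, deduplicated single-end reads;
peaks are written as BED6 with the raw divergence score (4 decimals) in the
score column.

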