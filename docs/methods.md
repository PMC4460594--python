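# Methods

## Model

`dipseq` treats peak calling as a conditional two-sample problem. Under the
null hypothesis — no specific binding — the IP and control tracks are two
samples from the same position-dependent intensity, whatever that intensity
is. Conditioning a window on its amplitude *a* (total reads in both tracks)
removes the intensity from the problem: all that remains is how the *a*
reads split between IP and control. Instead of modelling that split (after
library-size normalization it would be close to Binomial(*a*, ½), but with
overdispersion from correlated fragments and imperfect normalization), the
method uses the genome itself as the reference: the empirical distribution
of magnitudes among *all* windows of amplitude *a*. A window is significant
when its IP share falls in the upper φ-tail of that empirical distribution.

The assumptions this rests on:

- the control captures the same non-specific binding landscape as the IP
  (same antibody class, same chromatin preparation);
- true binding sites occupy a small fraction of windows at any amplitude,
  so the empirical table is dominated by null windows;
- reads are independent enough that a window's magnitude, given its
  amplitude, is exchangeable across the genome.

The second assumption is the important one and is the first thing to break
at small genome sizes (see *Limitations*).

## Pipeline and parameters

| parameter | default | meaning |
|---|---|---|
| `L` | 100 bp | window length; a lower bound on fragment length |
| `step` | `L`/4 = 25 bp | scan offset; 75% overlap between windows |
| `phi` | 0.1 | FDR cutoff, for both the magnitude threshold and the region-level control fraction |
| `delta` | 1000 bp | merge gap between significant window spans |
| `k` | 150 bp | minimum emitted region length (about half a fragment) |
| `pseudocount` | 0.5 | added inside the score's log only when m or m̄ is 0 |
| `standard_length` | 800 bp | fixed output peak length (`None` = raw spans) |
| `seed` | 0 | drives the resampling in library normalization |

Stages: normalize library sizes (upsample the smaller track with
replacement) → scan windows → tally N(a, m) genome-wide → threshold
m_min(a) at φ with the monotone sweep → flag windows with m ≥ m_min(a) →
merge flagged spans closer than δ → drop regions shorter than k or with
control fraction ≥ φ → score surviving regions → optionally re-centre to a
fixed length. Every stage is deterministic given the seed.

## Numerical and procedural choices

- **Threshold convention.** Significance uses the upper-tail fraction
  U(a, m) = Σ_{m'≥m} N(a, m') / Σ N(a, m') with a *non-strict* comparison
  U ≤ φ, so a tail that lands exactly on φ is significant. U(a, 0) = 1
  forces m_min ≥ 1 (empty windows are never significant) and U(a, a+1) = 0
  guarantees a threshold exists; m_min = a + 1 encodes "nothing callable at
  this amplitude".
- **Monotone sweep.** Raw thresholds can dip at sparsely populated
  amplitudes; the sweep m_min(a) ← max(m_min(a), m_min(a−1)) runs over the
  dense amplitude index 0..a_max, with amplitudes absent from the table
  inheriting the previous value.
- **Read assignment.** A read belongs to a window iff its leftmost mapped
  coordinate lies in it. No strand shift and no fragment extension are
  applied; a `read_offset` option exists but is never applied silently.
- **Region recounting.** Merged-region totals are recounted from the raw
  reads over the merged interval. Summing window counts would count each
  read up to L/step times.
- **Region scoring** sums over *all* scanned windows fully contained in the
  region, not only the flagged ones, so that long regions aggregate all of
  their evidence. Windows with a = 0 contribute zero. The 0.5 pseudocount
  enters only where m or m̄ is zero, added to both numerator and
  denominator, preserving the zero-at-equality and antisymmetry properties.
- **Normalization** is global (whole genome), not per chromosome, and the
  upsampled reads are drawn by index with a single seeded generator so that
  repeated runs are byte-identical.
- **Sorting** is by (genome-table chromosome order, start, end); the BED
  writer refuses unsorted input rather than sorting silently.
- **Fixed-length output.** Re-centred peaks span [c − 400, c + 400) around
  the region midpoint c (integer division) and are clipped, not shifted, at
  chromosome boundaries.

## The simulator

`simulate` models exactly the two data features the null construction must
survive: (1) a shared background intensity, piecewise-constant over equal
bins with log-normal(0, σ) levels, identical for IP and control — a
two-parameter stand-in for mappability/accessibility bias and
region-specific non-specific pull-down; (2) IP-only enrichment, implemented
by multiplying the background mass inside each peak interval by its fold
and renormalizing the IP mixture. Read leftmost positions are uniform
within a constant-intensity stretch; strands are random and unused by the
caller. Defaults are a 1 Mb chromosome, 10⁵ reads per track, 1 kb bins,
σ = 0.5.

It does **not** model sequencing error, PCR duplicates (inputs are defined
as deduplicated), paired ends, strand-asymmetric 5′ read placement around
binding sites, or mappability holes. Passing tests on these tracks
demonstrate the statistical machinery — calibration of the empirical
threshold, merging, filtering, scoring, determinism — not robustness to
those artefacts.

## Test and benchmark problem sizes

The suite and `scripts/acceptance.py` run the caller on 1 Mb genomes with
10⁴–10⁵ reads per track (about 40 000 windows per scan), 5–10 seeds per
condition, and verify the threshold table against an exhaustive scan on
1000 random sparse tables. These sizes keep a full run in tens of seconds
while leaving every amplitude row well populated.

## Limitations and operating range

- **Self-contaminating null at simulation scale.** On a 1 Mb genome a
  spiked peak set can own entire amplitude rows: windows inside strong
  peaks reach amplitudes no background window attains, so the "null" at
  those amplitudes is the peaks themselves and the threshold adapts to
  them. On a real genome (three orders of magnitude more windows per
  amplitude) this contamination is negligible; at desk scale it caps the
  flaggable share of peak windows near φ. Heavy-tailed backgrounds
  (σ ≈ 1), which populate high amplitudes with null windows, restore
  normal behaviour and are used in the examples.
- **The control-fraction filter sets a hard fold floor.** A region passes
  only if m̄/(m + m̄) < φ, i.e. the local IP:control ratio exceeds
  (1 − φ)/φ = 9 at the default φ = 0.1. A peak of fold f yields an
  expected in-peak ratio of f/Z, where Z ≥ 1 is the IP mixture's
  renormalization constant, so f = 10 sits *at* the floor: in expectation
  such regions fail the filter, and merging with adjacent balanced windows
  (which adds equal IP and control reads) pushes them further below it.
  Recovery of 10-fold spike-ins at φ = 0.1 is therefore poor by
  construction — the acceptance report states the measured values — while
  ≳ 20-fold sites are recovered reliably. On real data the same arithmetic
  applies to the *local* IP:IgG density ratio, which at genuine binding
  sites is typically far above 10.
- **At high read density the flagged-window rate approaches φ** (≈ 6% at
  10 windows per track per segment), and with δ = 1000 those windows chain
  into large merged regions whose balanced counts the control-fraction
  filter then removes. The defaults are tuned to the sparse-coverage
  regime of real experiments (≲ 0.01 reads/bp per track).
- No sub-region summit localization is attempted; merged regions are
  reported as spans (or fixed-length re-centred peaks).
- Scores are comparable within a run but have no absolute calibration;
  ranking and thresholding by score is the intended use.
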