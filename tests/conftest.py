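import numpy as np
import pytest

from dipseq import GenomeTable, ReadAlignment


@pytest.fixture
def tiny_genome():
    return GenomeTable({"chr1": 400})


@pytest.fixture
def small_genome():
    return GenomeTable({"chr1": 100_000})


def make_reads(positions, chrom="chr1", read_length=50):
    return [ReadAlignment(chrom, int(p), int(p) + read_length) for p in positions]


def random_null_counts(rng, max_amp=30, max_count=10_000):
    """A random sparse N(a, m) table: the raw material for threshold tests."""
    counts = {}
    amps = rng.choice(max_amp + 1, size=rng.integers(1, 12), replace=False)
    for a in amps:
        n_ms = int(rng.integers(1, min(int(a), 6) + 2))
        ms = rng.choice(int(a) + 1, size=min(n_ms, int(a) + 1), replace=False)
        for m in ms:
            counts[(int(a), int(m))] = int(rng.integers(1, max_count + 1))
    return counts


def brute_force_min_magnitude(counts, phi):
    """Exhaustive upper-tail threshold scan, independent of the package.

    For every amplitude: walk m upward from 0 and take the first m whose
    upper-tail fraction is <= phi; then apply the monotone max-sweep with
    absent amplitudes inheriting the previous value.
    """
    totals = {}
    for (a, _m), n in counts.items():
        totals[a] = totals.get(a, 0) + n
    raw = {}
    for a, total in totals.items():
        for m in range(0, a + 2):
            tail = sum(counts.get((a, mp), 0) for mp in range(m, a + 1))
            if tail / total <= phi:
                raw[a] = m
                break
    amax = max(raw)
    enforced = []
    prev = 0
    for a in range(amax + 1):
        if a in raw:
            prev = max(prev, raw[a])
        enforced.append(prev)
    return raw, enforced


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
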