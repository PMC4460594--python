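import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dipseq import (
    CandidateRegion,
    DipConfig,
    GenomeTable,
    NullTable,
    SegmentCounts,
    build_null_table,
    call_peaks,
    compute_min_magnitude,
    filter_regions,
    flag_significant,
    merge_significant,
    normalize_tracks,
    run_dip,
    scan_segments,
    score_regions,
    segment_score,
    standardize_region_length,
)
from dipseq.simulate import SimConfig, simulate_tracks

from .conftest import brute_force_min_magnitude, make_reads, random_null_counts


class TestNormalizeTracks:
    def test_smaller_track_upsampled_to_match(self):
        ip = make_reads(range(0, 1000, 10))       # 100 reads
        control = make_reads(range(0, 800, 10))   # 80 reads
        ip2, ct2 = normalize_tracks(ip, control, seed=3)
        assert len(ip2) == len(ct2) == 100
        assert ip2 == ip  # larger track untouched
        # upsampled track = original multiset plus draws from itself
        extra = Counter(ct2) - Counter(control)
        assert sum(extra.values()) == 20
        assert set(extra) <= set(control)

    def test_equal_sizes_returned_unchanged(self):
        ip = make_reads([1, 2, 3])
        control = make_reads([7, 8, 9])
        ip2, ct2 = normalize_tracks(ip, control, seed=0)
        assert ip2 == ip and ct2 == control

    def test_reproducible_given_seed(self):
        ip = make_reads(range(50))
        control = make_reads(range(30))
        _, a = normalize_tracks(ip, control, seed=11)
        _, b = normalize_tracks(ip, control, seed=11)
        assert a == b

    def test_empty_track_is_fatal(self):
        with pytest.raises(ValueError, match="control"):
            normalize_tracks(make_reads([1]), [], seed=0)


class TestScanSegments:
    def test_400bp_chromosome_gives_13_segments(self, tiny_genome):
        segs = scan_segments([], [], tiny_genome, DipConfig())
        assert len(segs) == 13
        assert [s.start for s in segs] == list(range(0, 325, 25))
        assert all(s.a == 0 for s in segs)

    def test_single_read_counted_in_covering_windows(self, tiny_genome):
        segs = scan_segments(make_reads([60]), [], tiny_genome, DipConfig())
        hits = {s.start for s in segs if s.m == 1}
        assert hits == {0, 25, 50}
        assert all(s.m == 0 for s in segs if s.start not in hits)

    def test_chromosome_shorter_than_L_yields_nothing(self):
        genome = GenomeTable({"tiny": 80, "chr1": 400})
        segs = scan_segments([], [], genome, DipConfig())
        assert {s.chrom for s in segs} == {"chr1"}

    def test_counts_match_naive_interval_oracle(self, rng, small_genome):
        ip = make_reads(rng.integers(0, 99_000, size=300))
        ct = make_reads(rng.integers(0, 99_000, size=200))
        cfg = DipConfig()
        segs = scan_segments(ip, ct, small_genome, cfg)
        ip_pos = [r.start for r in ip]
        ct_pos = [r.start for r in ct]
        for s in rng.choice(len(segs), size=50, replace=False):
            seg = segs[s]
            assert seg.m == sum(seg.start <= p < seg.start + cfg.L for p in ip_pos)
            assert seg.mbar == sum(seg.start <= p < seg.start + cfg.L for p in ct_pos)


class TestNullTable:
    def test_all_empty_segments(self, tiny_genome):
        segs = scan_segments([], [], tiny_genome, DipConfig())
        null = build_null_table(segs)
        assert null.counts == {(0, 0): 13}
        assert null.totals == {0: 13}

    def test_simple_tally(self):
        segs = [
            SegmentCounts("chr1", 0, 1, 1),
            SegmentCounts("chr1", 25, 1, 1),
            SegmentCounts("chr1", 50, 2, 0),
        ]
        null = build_null_table(segs)
        assert null.counts == {(2, 1): 2, (2, 2): 1}
        assert null.totals == {2: 3}

    def test_total_mass_equals_segment_count(self, rng):
        segs = [
            SegmentCounts("chr1", 25 * i, int(rng.integers(0, 5)), int(rng.integers(0, 5)))
            for i in range(500)
        ]
        null = build_null_table(segs)
        assert sum(null.counts.values()) == 500
        # independent tally
        expect = Counter((s.m + s.mbar, s.m) for s in segs)
        assert null.counts == dict(expect)

    def test_empty_input_fatal(self):
        with pytest.raises(ValueError):
            build_null_table([])


class TestMinMagnitude:
    def test_mass_concentrated_at_zero(self):
        null = NullTable({(5, 0): 100}, {5: 100}, 100)
        table = compute_min_magnitude(null, 0.1)
        assert table.raw[5] == 1  # U(5,1)=0 <= 0.1

    def test_boundary_tail_exactly_phi_is_significant(self):
        # N(4, m) = [10, 20, 40, 20, 10]: U(4,4) = 0.10 <= 0.1
        counts = {(4, m): n for m, n in enumerate([10, 20, 40, 20, 10])}
        null = NullTable(counts, {4: 100}, 100)
        table = compute_min_magnitude(null, 0.1)
        assert table.raw[4] == 4

    def test_monotone_enforcement_of_dipping_thresholds(self):
        # crafted so the raw thresholds for a = 0..3 are [1, 1, 3, 2]
        counts = {
            (0, 0): 100,
            (1, 0): 100,
            (2, 0): 50, (2, 2): 50,
            (3, 1): 95, (3, 2): 5,
        }
        null = NullTable(counts, {0: 100, 1: 100, 2: 100, 3: 100}, 400)
        table = compute_min_magnitude(null, 0.1)
        assert [table.raw[a] for a in range(4)] == [1, 1, 3, 2]
        assert list(table.enforced) == [1, 1, 3, 3]

    def test_absent_amplitudes_inherit_previous_threshold(self):
        null = NullTable({(0, 0): 50, (5, 0): 50}, {0: 50, 5: 50}, 100)
        table = compute_min_magnitude(null, 0.1)
        assert [table.mmin(a) for a in range(5)] == [1, 1, 1, 1, 1]

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(200):
            counts = random_null_counts(rng)
            phi = float(rng.uniform(0.02, 0.5))
            null = NullTable(counts, _totals(counts), sum(counts.values()))
            table = compute_min_magnitude(null, phi)
            raw, enforced = brute_force_min_magnitude(counts, phi)
            assert table.raw == raw
            assert list(table.enforced) == enforced

    def test_thresholds_always_monotone(self, rng):
        for _ in range(50):
            counts = random_null_counts(rng)
            null = NullTable(counts, _totals(counts), sum(counts.values()))
            enforced = compute_min_magnitude(null, 0.1).enforced
            assert np.all(np.diff(enforced) >= 0)

    @pytest.mark.parametrize("phi", [0.0, 1.0, -0.3, 2.0])
    def test_invalid_phi_fatal(self, phi):
        null = NullTable({(1, 0): 5}, {1: 5}, 5)
        with pytest.raises(ValueError):
            compute_min_magnitude(null, phi)


def _totals(counts):
    totals = {}
    for (a, _m), n in counts.items():
        totals[a] = totals.get(a, 0) + n
    return totals


class TestFlagSignificant:
    def _table(self):
        counts = {(5, m): n for m, n in enumerate([40, 20, 20, 10, 6, 4])}
        return compute_min_magnitude(NullTable(counts, {5: 100}, 100), 0.1)

    def test_keeps_only_segments_at_or_above_threshold(self):
        table = self._table()  # m_min(5) = 4: U(5,4)=0.10
        assert table.mmin(5) == 4
        kept = flag_significant(
            [SegmentCounts("chr1", 0, 5, 0), SegmentCounts("chr1", 25, 3, 2)], table
        )
        assert [s.m for s in kept] == [5]

    def test_amplitude_beyond_table_is_misuse(self):
        with pytest.raises(KeyError):
            flag_significant([SegmentCounts("chr1", 0, 9, 0)], self._table())

    def test_matches_brute_force_filter_on_scan(self, rng, small_genome):
        ip = make_reads(rng.integers(0, 99_000, size=2000))
        ct = make_reads(rng.integers(0, 99_000, size=2000))
        segs = scan_segments(ip, ct, small_genome, DipConfig())
        table = compute_min_magnitude(build_null_table(segs), 0.1)
        kept = flag_significant(segs, table)
        oracle = [s for s in segs if s.m >= int(table.enforced[s.m + s.mbar])]
        assert kept == oracle


class TestMergeSignificant:
    def test_segments_within_delta_merge(self):
        sig = [SegmentCounts("chr1", 100, 5, 0), SegmentCounts("chr1", 900, 5, 0)]
        ip = make_reads([150] * 5 + [950] * 5)
        regions = merge_significant(sig, ip, [], DipConfig())
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (100, 1000)
        assert regions[0].m_total == 10 and regions[0].mbar_total == 0

    def test_segments_beyond_delta_stay_separate(self):
        sig = [SegmentCounts("chr1", 100, 5, 0), SegmentCounts("chr1", 1500, 5, 0)]
        regions = merge_significant(sig, [], [], DipConfig())
        assert [(r.start, r.end) for r in regions] == [(100, 200), (1500, 1600)]

    def test_single_segment_maps_to_own_span(self):
        regions = merge_significant([SegmentCounts("chr1", 100, 5, 0)], [], [], DipConfig())
        assert [(r.start, r.end) for r in regions] == [(100, 200)]

    def test_overlapping_segments_merge_even_at_delta_zero(self):
        cfg = DipConfig(delta=0)
        sig = [SegmentCounts("chr1", 100, 5, 0), SegmentCounts("chr1", 175, 5, 0)]
        regions = merge_significant(sig, [], [], cfg)
        assert [(r.start, r.end) for r in regions] == [(100, 275)]

    def test_region_collects_all_contained_scanned_segments(self):
        sig = [SegmentCounts("chr1", 100, 5, 0), SegmentCounts("chr1", 300, 5, 0)]
        all_segs = [SegmentCounts("chr1", s, 1, 1) for s in range(0, 500, 25)]
        regions = merge_significant(sig, [], [], DipConfig(), all_segments=all_segs)
        (region,) = regions
        # contained = segments with span inside [100, 400): starts 100..300
        assert [s.start for s in region.segments] == list(range(100, 325, 25))

    def test_chromosomes_never_merge_together(self):
        sig = [SegmentCounts("chr1", 100, 5, 0), SegmentCounts("chr2", 150, 5, 0)]
        regions = merge_significant(sig, [], [], DipConfig())
        assert len(regions) == 2

    def test_recount_uses_leftmost_coordinates(self):
        # read starting inside but ending outside still counts; the reverse does not
        sig = [SegmentCounts("chr1", 100, 1, 0)]
        ip = make_reads([199])       # leftmost inside [100, 200)
        ct = make_reads([99])        # leftmost before the region
        (region,) = merge_significant(sig, ip, ct, DipConfig())
        assert region.m_total == 1 and region.mbar_total == 0


class TestFilterRegions:
    def _region(self, length, m, mbar):
        return CandidateRegion("chr1", 1000, 1000 + length, m, mbar)

    def test_zero_control_region_kept(self):
        assert filter_regions([self._region(900, 50, 0)], DipConfig())

    def test_high_control_fraction_dropped(self):
        assert filter_regions([self._region(900, 40, 10)], DipConfig()) == []

    def test_short_region_dropped_regardless_of_counts(self):
        assert filter_regions([self._region(100, 500, 0)], DipConfig()) == []

    def test_empty_region_dropped(self):
        assert filter_regions([self._region(900, 0, 0)], DipConfig()) == []

    def test_boundary_length_kept(self):
        assert filter_regions([self._region(150, 50, 0)], DipConfig())


class TestScoring:
    def test_balanced_segment_scores_zero(self):
        assert segment_score(10, 10) == 0.0

    def test_twofold_segment(self):
        assert segment_score(20, 10) == pytest.approx(30 * math.log(2))

    def test_pseudocount_only_at_zeros(self):
        assert segment_score(5, 0, 0.5) == pytest.approx(5 * math.log(5.5 / 0.5))
        assert segment_score(0, 0) == 0.0

    def test_swap_negates_contribution(self, rng):
        for _ in range(100):
            m, mbar = int(rng.integers(0, 40)), int(rng.integers(0, 40))
            assert segment_score(m, mbar) == pytest.approx(-segment_score(mbar, m), abs=1e-12)

    def test_score_equals_kl_divergence_difference(self, rng):
        """Sum a·ln(m/mbar) == D_KL(m||mbar) - D_KL(mbar||m), unnormalized counts."""
        ms = rng.integers(1, 200, size=1000)
        mbars = rng.integers(1, 200, size=1000)
        total = sum(segment_score(int(m), int(mb)) for m, mb in zip(ms, mbars))
        d_ip_ct = float(np.sum(ms * np.log(ms / mbars)))
        d_ct_ip = float(np.sum(mbars * np.log(mbars / ms)))
        assert total == pytest.approx(d_ip_ct - d_ct_ip, rel=1e-9)

    def test_region_score_sums_contained_segments(self):
        segs = (SegmentCounts("chr1", 100, 20, 10), SegmentCounts("chr1", 125, 10, 10))
        region = CandidateRegion("chr1", 100, 225, 30, 20, segs)
        (scored,) = score_regions([region], DipConfig())
        assert scored.score == pytest.approx(30 * math.log(2))

    def test_region_without_segments_scores_zero(self):
        region = CandidateRegion("chr1", 100, 900, 10, 0, ())
        (scored,) = score_regions([region], DipConfig())
        assert scored.score == 0.0


class TestStandardize:
    def test_already_standard_is_fixed_point(self):
        (rec,) = standardize_region_length([CandidateRegion("chr1", 100, 900, 1, 0)], 800)
        assert (rec.start, rec.end) == (100, 900)

    def test_centering(self):
        (rec,) = standardize_region_length([CandidateRegion("chr1", 0, 2000, 1, 0)], 800)
        assert (rec.start, rec.end) == (600, 1400)

    def test_clipped_at_chromosome_start(self):
        (rec,) = standardize_region_length([CandidateRegion("chr1", 0, 100, 1, 0)], 800)
        assert rec.start == 0 and rec.end == 450

    def test_clipped_at_chromosome_end(self, tiny_genome):
        (rec,) = standardize_region_length(
            [CandidateRegion("chr1", 300, 400, 1, 0)], 800, tiny_genome
        )
        assert rec.end == 400

    def test_score_carried_over(self):
        (rec,) = standardize_region_length(
            [CandidateRegion("chr1", 0, 2000, 1, 0, (), 42.5)], 800
        )
        assert rec.score == 42.5


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"L": 0},
            {"step": 30},          # does not divide L=100
            {"phi": 0.0},
            {"phi": 1.0},
            {"k": 0},
            {"delta": -1},
            {"pseudocount": 0.0},
            {"standard_length": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DipConfig(**kwargs)


class TestCallPeaks:
    def test_isolated_cluster_over_shared_background_is_one_peak(self, small_genome, rng):
        """A dense IP-only read cluster on an otherwise identical pair of
        tracks is called as exactly one peak covering the cluster."""
        background = list(rng.integers(0, 99_000, size=3000))
        cluster = list(rng.integers(50_000, 50_400, size=200))
        ip = make_reads(background + cluster)
        control = make_reads(background)
        cfg = DipConfig(seed=1, standard_length=None)
        peaks = call_peaks(ip, control, small_genome, cfg)
        assert len(peaks) == 1
        assert peaks[0].start <= 50_000 and peaks[0].end >= 50_400
        assert peaks[0].score > 0

    def test_identical_tracks_yield_no_peaks(self, small_genome, rng):
        reads = make_reads(rng.integers(0, 99_000, size=5000))
        assert call_peaks(reads, list(reads), small_genome, DipConfig(seed=0)) == []

    def test_deterministic_given_seed(self, small_genome, rng):
        ip = make_reads(rng.integers(0, 99_000, size=4000))
        ct = make_reads(rng.integers(0, 99_000, size=3000))  # forces resampling
        cfg = DipConfig(seed=5)
        assert call_peaks(ip, ct, small_genome, cfg) == call_peaks(ip, ct, small_genome, cfg)

    def test_output_sorted_by_genome_order(self, rng):
        genome = GenomeTable({"chrB": 100_000, "chrA": 100_000})
        background = list(rng.integers(0, 99_000, size=2000))
        ip, ct = [], []
        for chrom in ("chrA", "chrB"):
            ip += make_reads(background, chrom) + make_reads(
                rng.integers(20_000, 20_400, size=150), chrom
            )
            ct += make_reads(background, chrom)
        peaks = call_peaks(ip, ct, genome, DipConfig(seed=2, standard_length=None))
        chroms = [p.chrom for p in peaks]
        assert chroms == sorted(chroms, key={"chrB": 0, "chrA": 1}.get)


class TestMergingSanity:
    def test_regions_disjoint_and_cover_each_significant_segment_once(self, rng):
        cfg = SimConfig(genome_length=200_000, n_reads_ip=20_000, n_reads_control=20_000,
                        background_bins=200, peaks=((60_000, 400, 10.0),), seed=9)
        ip, ct, _ = simulate_tracks(cfg)
        dcfg = DipConfig(seed=9)
        segs = scan_segments(ip, ct, cfg.genome(), dcfg)
        table = compute_min_magnitude(build_null_table(segs), dcfg.phi)
        sig = flag_significant(segs, table)
        regions = merge_significant(sig, ip, ct, dcfg, all_segments=segs)
        # pairwise disjoint, separated by >= delta between significant spans
        for r1, r2 in zip(regions, regions[1:]):
            assert r1.end <= r2.start
            assert r2.start - r1.end >= dcfg.delta
        # every significant segment contained in exactly one region
        for s in sig:
            containing = [
                r for r in regions if r.start <= s.start and s.start + dcfg.L <= r.end
            ]
            assert len(containing) == 1


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    pairs=st.lists(
        st.tuples(st.integers(0, 15), st.integers(0, 15)), min_size=1, max_size=200
    ),
    phi=st.floats(0.01, 0.99),
)
def test_threshold_flag_rate_never_exceeds_phi(pairs, phi):
    """At every amplitude, the flagged fraction of the very segments the
    null was built from is at most phi — the FDR bound is structural."""
    segs = [SegmentCounts("chr1", 25 * i, m, mb) for i, (m, mb) in enumerate(pairs)]
    null = build_null_table(segs)
    table = compute_min_magnitude(null, phi)
    kept = [s for s in segs if s.m >= table.mmin(s.a)]
    for a in null.totals:
        kept_a = sum(1 for s in kept if s.a == a)
        assert kept_a <= phi * null.totals[a] + 1e-9
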