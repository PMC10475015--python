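"""K-string interval spectrum: worked examples, oracle and invariants."""

import pytest

from horscope.grm import (
    GRMConfig,
    detect_peaks,
    extract_repeat_copies,
    kstring_interval_histogram,
    locate_tandem_regions,
    validate_hor_signature,
)
from horscope.synthetic import mutate, revcomp
from tests.conftest import brute_interval_histogram, random_dna


class TestHistogram:
    def test_periodic_toy_sequence(self):
        d = kstring_interval_histogram("ACGTACGTACGT", GRMConfig(k=4))
        assert d.histogram == {4: 5}

    def test_all_unique_kmers_empty(self):
        # no 4-mer recurs in this sequence
        seq = "AACCGGTTACGT"
        d = kstring_interval_histogram(seq, GRMConfig(k=4))
        assert d.histogram == {}

    def test_concatenated_unit_interval_identity(self):
        # a 50-mer with unique internal 10-mers, concatenated 10 times:
        # 491 windows, 50 distinct 10-strings -> 441 intervals, all = 50
        unit = random_dna(50, seed=12)
        assert len({unit[i : i + 10] for i in range(41)}) == 41  # internal uniqueness
        seq = unit * 10
        d = kstring_interval_histogram(seq, GRMConfig(k=10))
        assert d.histogram == {50: 441}

    def test_shorter_than_k_is_empty(self):
        assert kstring_interval_histogram("ACG", GRMConfig(k=12)).histogram == {}

    @pytest.mark.parametrize("seed", [0, 1])
    def test_mass_conservation_against_brute_force(self, seed):
        seq = random_dna(3000, seed=seed) + "N" * 17 + random_dna(1500, seed=seed + 50)
        for k in (4, 8, 12):
            cfg = GRMConfig(k=k, max_length=500)
            got = kstring_interval_histogram(seq, cfg).histogram
            assert got == brute_interval_histogram(seq, k, 500)

    def test_reverse_complement_invariance(self):
        seq = random_dna(800, seed=2) + random_dna(100, seed=3) * 5
        cfg = GRMConfig(k=8)
        a = kstring_interval_histogram(seq, cfg).histogram
        b = kstring_interval_histogram(revcomp(seq), cfg).histogram
        assert a == b

    def test_adding_copy_never_decreases_unit_peak(self):
        unit = random_dna(120, seed=9)
        cfg = GRMConfig(k=12)
        prev = 0
        for n in (5, 6, 7):
            seq = random_dna(500, seed=1) + unit * n + random_dna(500, seed=4)
            count = kstring_interval_histogram(seq, cfg).histogram.get(120, 0)
            assert count >= prev
            prev = count

    def test_large_k_string_path(self):
        # k > 32 falls back to string keys; 4 concatenated 100-mers give
        # 361 windows over 100 distinct 40-strings: 261 intervals of 100
        unit = random_dna(100, seed=21)
        d = kstring_interval_histogram(unit * 4, GRMConfig(k=40))
        assert d.histogram == {100: 261}


class TestPeaks:
    def test_single_bin(self):
        from horscope.grm import GRMDiagram

        peaks = detect_peaks(GRMDiagram({4: 5}), GRMConfig())
        assert [(p.length, p.count) for p in peaks] == [(4, 5)]

    def test_empty(self):
        from horscope.grm import GRMDiagram

        assert detect_peaks(GRMDiagram({}), GRMConfig()) == []

    def test_relative_merge_radius(self):
        from horscope.grm import GRMDiagram

        hist = {1600: 900, 1590: 40, 3200: 300, 4800: 500, 7: 100000}
        peaks = detect_peaks(GRMDiagram(hist), GRMConfig())
        by_len = {p.length: p.count for p in peaks}
        # 1590 merges into 1600 (within 3%), the 7 bp bin stays separate
        assert by_len[1600] == 940
        assert by_len[7] == 100000 and by_len[4800] == 500 and by_len[3200] == 300
        assert peaks[0].length == 7  # sorted by count descending

    def test_min_count_filter(self):
        from horscope.grm import GRMDiagram

        peaks = detect_peaks(GRMDiagram({10: 2, 20: 9}), GRMConfig(min_count=5))
        assert [p.length for p in peaks] == [20]


class TestHORSignature:
    def test_stated_multiples_rule(self):
        from horscope.grm import GRMDiagram

        d = GRMDiagram({1600: 100, 3210: 50, 4795: 40})
        assert validate_hor_signature(d, 1600, n=3, tol=0.05)

    def test_missing_multiples_fail(self):
        from horscope.grm import GRMDiagram

        d = GRMDiagram({1600: 100})
        assert not validate_hor_signature(d, 1600, n=3)

    def test_planted_canonical_array_zero_noise(self, family_bases):
        seq = random_dna(30_000, seed=1) + "".join(family_bases) * 10 + random_dna(
            30_000, seed=2
        )
        d = kstring_interval_histogram(seq, GRMConfig())
        assert validate_hor_signature(d, 1600, n=3)


class TestTandemRegions:
    def test_planted_exact_array(self):
        unit = random_dna(50, seed=5)
        seq = random_dna(50_000, seed=6) + unit * 100 + random_dna(50_000, seed=7)
        regions = locate_tandem_regions(seq, GRMConfig(), unit_range=(20, 200))
        assert len(regions) == 1
        r = regions[0]
        assert r.unit_length == 50
        assert abs(r.n_units - 100) <= 2
        assert abs(r.start - 50_000) <= 50 and abs(r.end - 55_000) <= 50

    def test_pure_random_has_no_regions(self):
        seq = random_dna(100_000, seed=8)
        assert locate_tandem_regions(seq, GRMConfig(), unit_range=(20, 10_000)) == []

    def test_two_arrays_far_apart_stay_separate(self):
        unit = random_dna(50, seed=9)
        seq = (
            random_dna(10_000, seed=10)
            + unit * 20
            + random_dna(50_000, seed=11)
            + unit * 30
            + random_dna(10_000, seed=12)
        )
        regions = locate_tandem_regions(seq, GRMConfig(), unit_range=(20, 200))
        assert len(regions) == 2
        assert regions[0].start < regions[1].start


class TestExtractCopies:
    def test_toy_enumeration(self):
        from horscope.grm import TandemRegion

        region = TandemRegion(start=0, end=12, unit_length=4, n_units=3, key="ACGT")
        assert extract_repeat_copies("ACGTACGTACGT", region) == ["ACGT", "ACGT"]

    def test_zero_noise_copies_identical_to_unit(self):
        unit = random_dna(300, seed=13)
        seq = unit * 10
        from horscope.grm import TandemRegion

        region = TandemRegion(0, len(seq), 300, 10, key=unit[:12])
        copies = extract_repeat_copies(seq, region)
        assert len(copies) == 9
        assert all(c == unit for c in copies)

    def test_mutated_copies_stay_close_to_unit(self):
        from horscope.families import pairwise_divergence
        from horscope.grm import TandemRegion

        unit = random_dna(300, seed=14)
        key = unit[:12]
        # mutate only past the key so every copy is segmentable
        copies_in = [key + mutate(unit[12:], 0.01, 0.0, seed=s) for s in range(8)]
        seq = "".join(copies_in)
        region = TandemRegion(0, len(seq), 300, 8, key=key)
        copies = extract_repeat_copies(seq, region)
        assert len(copies) == 7
        for c in copies:
            assert pairwise_divergence(c, unit) < 0.02

    def test_missing_key_raises(self):
        from horscope.grm import TandemRegion

        region = TandemRegion(0, 8, 4, 2, key="AAAA")
        with pytest.raises(ValueError):
            extract_repeat_copies("CGCGCGCG", region)
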