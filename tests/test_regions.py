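"""Interval algebra for neutral-region construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paleoselect.regions import (
    ChromosomeRegistryError,
    IntervalSet,
    buffer_intervals,
    build_neutral_regions,
    drop_short,
    exclude_chromosome_edges,
    overlap_length,
    subtract,
    union,
)

LEN_1MB = {"1": 1_000_000}


def iset(records, lengths=LEN_1MB):
    return IntervalSet.from_records(records, lengths)


class TestNormalisation:
    def test_overlapping_intervals_merge(self):
        s = iset([("1", 0, 100), ("1", 50, 200), ("1", 200, 300)])
        assert s.to_records() == [("1", 0, 300)]

    def test_empty_and_inverted_intervals_dropped(self):
        s = iset([("1", 10, 10), ("1", 30, 20)])
        assert s.n_intervals() == 0


class TestBuffer:
    def test_zero_flank_is_identity(self):
        s = iset([("1", 100, 200), ("1", 500, 600)])
        assert buffer_intervals(s, 0) == s

    def test_flank_clipped_to_chromosome(self):
        s = iset([("1", 100_000, 200_000)])
        assert buffer_intervals(s, 100_000).to_records() == [("1", 0, 300_000)]

    def test_nearby_intervals_merge_after_buffering(self):
        s = iset([("1", 200_000, 210_000), ("1", 360_000, 370_000)])
        # gap of 150 kb, each side extends 100 kb -> overlap -> one interval
        assert buffer_intervals(s, 100_000).n_intervals() == 1

    def test_unknown_chromosome_rejected(self):
        s = IntervalSet({"7": [(0, 10)]}, {})
        with pytest.raises(ChromosomeRegistryError):
            buffer_intervals(s, 10)


class TestSubtract:
    def test_empty_exclusions_return_universe(self):
        u = iset([("1", 0, 1000)])
        assert subtract(u, []) == u

    def test_full_cover_gives_empty_set(self):
        u = iset([("1", 0, 1000)])
        assert subtract(u, [iset([("1", 0, 1000)])]).n_intervals() == 0

    def test_overlapping_exclusions(self):
        u = iset([("1", 0, 1000)])
        ex = iset([("1", 100, 200), ("1", 150, 300)])
        assert subtract(u, [ex]).to_records() == [("1", 0, 100), ("1", 300, 1000)]

    def test_exclusion_order_immaterial(self, rng):
        u = iset([("1", 0, 1_000_000)])
        sets = [
            iset([("1", int(a), int(a) + 5000)])
            for a in rng.integers(0, 900_000, size=8)
        ]
        fwd = subtract(u, sets)
        rev = subtract(u, sets[::-1])
        assert fwd == rev


class TestEdges:
    def test_edges_removed(self):
        s = IntervalSet.whole_genome(LEN_1MB)
        out = exclude_chromosome_edges(s, 40_000)
        assert out.to_records() == [("1", 40_000, 960_000)]

    def test_centromere_spanning_remainder_gives_empty(self):
        s = IntervalSet.whole_genome(LEN_1MB)
        cen = iset([("1", 40_000, 960_000)])
        assert exclude_chromosome_edges(s, 40_000, cen).n_intervals() == 0

    def test_short_chromosome_becomes_empty(self):
        s = IntervalSet.whole_genome({"s": 50_000})
        assert exclude_chromosome_edges(s, 40_000).n_intervals() == 0


class TestDropShort:
    @pytest.mark.parametrize(
        "interval,kept",
        [((0, 999), False), ((0, 1000), True), ((0, 1001), True)],
    )
    def test_length_boundary(self, interval, kept):
        s = iset([("1", *interval)])
        assert (drop_short(s, 1000).n_intervals() == 1) is kept


FEATURES = dict(
    segdups=IntervalSet(),
    cnvs=IntervalSet(),
    conserved=IntervalSet(),
    cpg_islands=IntervalSet(),
    repeats=IntervalSet(),
    centromeres=IntervalSet(),
)


class TestBuildNeutralRegions:
    def test_no_features_leaves_interior(self):
        out = build_neutral_regions(
            genes=IntervalSet(), chrom_lengths=LEN_1MB, **FEATURES
        )
        assert out.to_records() == [("1", 40_000, 960_000)]

    def test_toy_gene_and_repeat_hand_computed(self):
        genes = iset([("1", 300_000, 320_000)])
        feats = dict(FEATURES)
        feats["repeats"] = iset([("1", 600_000, 650_000)])
        out = build_neutral_regions(genes=genes, chrom_lengths=LEN_1MB, **feats)
        # gene buffered to [200k, 420k); edges strip 40 kb each side
        assert out.to_records() == [
            ("1", 40_000, 200_000),
            ("1", 420_000, 600_000),
            ("1", 650_000, 960_000),
        ]

    def test_deterministic(self):
        genes = iset([("1", 300_000, 320_000)])
        a = build_neutral_regions(genes=genes, chrom_lengths=LEN_1MB, **FEATURES)
        b = build_neutral_regions(genes=genes, chrom_lengths=LEN_1MB, **FEATURES)
        assert a == b

    def test_output_disjoint_from_buffered_exclusions(self, rng):
        for _ in range(20):
            genes = iset(
                [
                    ("1", int(a), int(a + rng.integers(1000, 50_000)))
                    for a in rng.integers(0, 900_000, size=3)
                ]
            )
            feats = dict(FEATURES)
            feats["repeats"] = iset(
                [
                    ("1", int(a), int(a + rng.integers(1000, 30_000)))
                    for a in rng.integers(0, 900_000, size=3)
                ]
            )
            out = build_neutral_regions(
                genes=genes, chrom_lengths=LEN_1MB, **feats
            )
            assert overlap_length(out, buffer_intervals(genes, 100_000)) == 0
            assert overlap_length(out, feats["repeats"]) == 0

    def test_monotone_in_exclusions(self):
        genes = iset([("1", 300_000, 320_000)])
        small = build_neutral_regions(
            genes=genes, chrom_lengths=LEN_1MB, **FEATURES
        )
        feats = dict(FEATURES)
        feats["repeats"] = iset([("1", 500_000, 520_000)])
        larger_excl = build_neutral_regions(
            genes=genes, chrom_lengths=LEN_1MB, **feats
        )
        assert larger_excl.total_length() <= small.total_length()
        assert small.total_length() <= sum(LEN_1MB.values())

    def test_idempotent_on_own_output(self):
        genes = iset([("1", 300_000, 320_000)])
        out = build_neutral_regions(genes=genes, chrom_lengths=LEN_1MB, **FEATURES)
        # rebuilding with no exclusions and no edge/flank keeps the set
        again = build_neutral_regions(
            genes=IntervalSet(),
            chrom_lengths=LEN_1MB,
            flank_bp=0,
            edge_bp=0,
            min_bp=1000,
            **FEATURES,
        )
        assert subtract(out, [subtract(IntervalSet.whole_genome(LEN_1MB), [again])]) == out

    def test_three_chromosome_toy_genome(self):
        lengths = {"1": 200_000, "2": 150_000, "3": 90_000}
        genes = IntervalSet.from_records([("2", 60_000, 70_000)], lengths)
        feats = {k: IntervalSet() for k in FEATURES}
        out = build_neutral_regions(
            genes=genes, chrom_lengths=lengths,
            flank_bp=10_000, edge_bp=40_000, min_bp=1000, **feats,
        )
        assert out.to_records() == [
            ("1", 40_000, 160_000),
            ("2", 40_000, 50_000),
            ("2", 80_000, 110_000),
            ("3", 40_000, 50_000),
        ]


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.integers(0, 900_000), st.integers(1, 50_000)
        ),
        max_size=6,
    )
)
def test_union_subtract_partition_genome(raw):
    """Exclusions and their complement partition the chromosome exactly."""
    excl = IntervalSet.from_records(
        [("1", a, min(a + l, 1_000_000)) for a, l in raw], LEN_1MB
    )
    genome = IntervalSet.whole_genome(LEN_1MB)
    remaining = subtract(genome, [excl])
    assert remaining.total_length() + excl.total_length() == 1_000_000
    assert overlap_length(remaining, excl) == 0
    assert union([remaining, excl]) == genome
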