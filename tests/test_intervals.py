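"""Interval algebra: merge semantics, overlap pairing, masked-genome shuffling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cartatac.intervals import (GenomeModel, PositionSet, _FlatSpace, as_intervals,
                                count_positions_in_union, merge_intervals, overlap,
                                shuffle_regions)

from conftest import random_intervals, random_positions


def merge_oracle(intervals, gap):
    """O(n^2) transitive-closure union: repeatedly join any two intervals on
    the same chromosome whose separation is <= gap, until a fixed point."""
    items = [list(r) for r in intervals[["chrom", "start", "end"]].itertuples(index=False)]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a[0] != b[0]:
                    continue
                if a[1] - b[2] <= gap and b[1] - a[2] <= gap:
                    items[i] = [a[0], min(a[1], b[1]), max(a[2], b[2])]
                    del items[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(tuple(x) for x in items)


def overlap_oracle(query, subject_intervals):
    pairs = []
    for qi, q in query.iterrows():
        for si, s in subject_intervals.iterrows():
            if q["chrom"] == s["chrom"] and q["start"] < s["end"] and s["start"] < q["end"]:
                pairs.append((qi, si))
    return sorted(pairs)


class TestMerge:
    def test_empty_input(self):
        assert len(merge_intervals(as_intervals([]), gap=300)) == 0

    def test_gap_semantics_joins_within_distance(self):
        # inter-interval distance 250 <= 300 merges into one region
        out = merge_intervals(as_intervals([("chr1", 100, 200), ("chr1", 450, 500)]), gap=300)
        assert list(out[["start", "end"]].itertuples(index=False, name=None)) == [(100, 500)]
        assert out["id"].tolist() == ["chr1:100-500"]

    def test_gap_semantics_keeps_beyond_distance(self):
        # separation 301 bp > 300 stays split; exactly 300 merges
        out = merge_intervals(as_intervals([("chr1", 100, 200), ("chr1", 501, 600)]), gap=300)
        assert len(out) == 2
        out = merge_intervals(as_intervals([("chr1", 100, 200), ("chr1", 500, 600)]), gap=300)
        assert len(out) == 1

    def test_bookended_merge_at_gap_zero(self):
        out = merge_intervals(as_intervals([("chr1", 0, 10), ("chr1", 10, 20)]), gap=0)
        assert out["end"].tolist() == [20]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        iv = random_intervals(rng, 200)
        gap = int(rng.integers(0, 400))
        got = merge_intervals(iv, gap)
        assert [tuple(r) for r in got[["chrom", "start", "end"]].itertuples(index=False)] \
            == merge_oracle(iv, gap)

    def test_unknown_chromosome_rejected(self, toy_genome):
        iv = as_intervals([("chr9", 0, 10)])
        with pytest.raises(ValueError, match="chr9"):
            merge_intervals(iv, 0, genome=toy_genome)

    @given(st.integers(0, 2**31 - 1), st.integers(0, 500))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_idempotent(self, seed, gap):
        iv = random_intervals(np.random.default_rng(seed), 40)
        once = merge_intervals(iv, gap)
        twice = merge_intervals(once, gap)
        pd.testing.assert_frame_equal(once, twice)

    def test_zero_gap_covers_same_bp(self, rng):
        iv = random_intervals(rng, 60)
        merged = merge_intervals(iv, 0)
        for df in (iv, merged):
            df["bp"] = df["end"] - df["start"]
        covered = set()
        for r in iv.itertuples(index=False):
            covered.update((r.chrom, x) for x in range(r.start, r.end))  # fine at this scale
        assert merged["bp"].sum() == len(covered)


class TestOverlap:
    def test_position_at_last_bp_included(self):
        hits = overlap(as_intervals([("chr1", 0, 10)]), pd.DataFrame({"chrom": ["chr1"], "pos": [9]}))
        assert len(hits) == 1

    def test_position_at_end_excluded(self):
        hits = overlap(as_intervals([("chr1", 0, 10)]), pd.DataFrame({"chrom": ["chr1"], "pos": [10]}))
        assert len(hits) == 0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_nested_loop_oracle_large(self, seed):
        rng = np.random.default_rng(seed)
        q = random_intervals(rng, 500)
        s = random_intervals(rng, 500)
        got = list(overlap(q, s).itertuples(index=False, name=None))
        assert got == overlap_oracle(q, s)

    def test_pair_count_symmetric(self, rng):
        a = random_intervals(rng, 80)
        b = random_intervals(rng, 80)
        assert len(overlap(a, b)) == len(overlap(b, a))

    def test_union_count_counts_each_position_once(self, rng):
        regions = random_intervals(rng, 50)
        pos = random_positions(rng, 400)
        expected = sum(
            any(r.chrom == p.chrom and r.start <= p.pos < r.end
                for r in regions.itertuples(index=False))
            for p in pos.itertuples(index=False))
        assert count_positions_in_union(pos, regions) == expected


class TestShuffle:
    def test_forced_placement(self):
        genome = GenomeModel(chromosomes=(("chr1", 1000),),
                             gaps=as_intervals([("chr1", 0, 400), ("chr1", 500, 1000)]))
        out = shuffle_regions(as_intervals([("chr1", 0, 100)]), genome, seed=3,
                              chroms=["chr1"])
        assert out[["start", "end"]].values.tolist() == [[400, 500]]

    def test_same_seed_identical(self, toy_genome, rng):
        regions = random_intervals(np.random.default_rng(5), 30)
        a = shuffle_regions(regions, toy_genome, seed=11)
        b = shuffle_regions(regions, toy_genome, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_lengths_conserved_and_gaps_avoided(self, toy_genome):
        regions = random_intervals(np.random.default_rng(6), 100)
        out = shuffle_regions(regions, toy_genome, seed=1)
        assert sorted((out["end"] - out["start"]).tolist()) \
            == sorted((regions["end"] - regions["start"]).tolist())
        assert set(out["chrom"]) <= set(toy_genome.autosomes)
        gap_hits = overlap(out, toy_genome.gaps)
        assert len(gap_hits) == 0

    def test_start_distribution_uniform(self):
        genome = GenomeModel(chromosomes=(("chr1", 10_000),))
        region = as_intervals([("chr1", 0, 100)])
        rng = np.random.default_rng(12)
        starts = np.array([shuffle_regions(region, genome, rng)["start"].iloc[0]
                           for _ in range(10_000)])
        # valid starts are 0..9900; chi-square GOF over 20 bins
        hist, _ = np.histogram(starts, bins=20, range=(0, 9901))
        p = stats.chisquare(hist).pvalue
        assert p > 0.01

    def test_oversized_region_rejected(self, toy_genome):
        big = as_intervals([("chr1", 0, 99_999)])
        big["id"] = ["wide"]
        with pytest.raises(ValueError, match="wide"):
            shuffle_regions(big, toy_genome, seed=0)

    def test_flat_space_counts_match_reference(self, toy_genome, rng):
        regions = random_intervals(rng, 60)
        pos = random_positions(rng, 500)
        space = _FlatSpace(toy_genome, chroms=["chr1", "chr2"])
        starts, lengths = space.flatten_intervals(regions)
        got = space.count_in_union(space.flatten_positions(pos), starts, lengths)
        assert got == count_positions_in_union(pos, regions)

    def test_flat_shuffle_uniform(self):
        genome = GenomeModel(chromosomes=(("chr1", 10_000),))
        space = _FlatSpace(genome, chroms=["chr1"])
        rng = np.random.default_rng(3)
        starts = np.concatenate([space.shuffle_starts(np.array([100]), rng)
                                 for _ in range(10_000)])
        hist, _ = np.histogram(starts, bins=20, range=(0, 9901))
        assert stats.chisquare(hist).pvalue > 0.01


class TestGenomeModel:
    def test_autosome_inference_excludes_sex(self, toy_genome):
        assert toy_genome.autosomes == ("chr1", "chr2")

    def test_unmasked_segments_complement_gaps(self, toy_genome):
        segs = toy_genome.unmasked_segments(["chr1"])
        assert segs[["start", "end"]].values.tolist() == [[0, 40_000], [45_000, 100_000]]

    def test_overlapping_gaps_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            GenomeModel(chromosomes=(("chr1", 1000),),
                        gaps=as_intervals([("chr1", 0, 500), ("chr1", 400, 600)]))

    def test_position_set_validation(self, toy_genome):
        ps = PositionSet(pd.DataFrame({"chrom": ["chr1"], "pos": [100_000]}))
        with pytest.raises(ValueError):
            ps.validate(toy_genome)
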