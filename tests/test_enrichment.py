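"""Permutation odds-ratio enrichment and cell-type-specific enhancer tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cartatac.atlas import AnnotationCatalog
from cartatac.enrichment import (baseline_band, celltype_enrichment, celltype_specific,
                                 permutation_or, tier_curves)
from cartatac.intervals import GenomeModel, PositionSet, as_intervals

from conftest import random_intervals, random_positions


@pytest.fixture(scope="module")
def genome():
    return GenomeModel(chromosomes=(("chr1", 200_000), ("chr2", 200_000)))


def uniform_sets(rng, n_fore=2000, n_back=4000):
    fore = PositionSet(random_positions(rng, n_fore, max_pos=199_999))
    back = PositionSet(random_positions(rng, n_back, max_pos=199_999), role="background")
    return fore, back


class TestPermutationOr:
    def test_deterministic_under_seed(self, genome):
        rng = np.random.default_rng(0)
        fore, back = uniform_sets(rng)
        regions = random_intervals(rng, 100, max_pos=190_000)
        a = permutation_or(regions, fore, back, genome, n_perm=20, seed=5)
        b = permutation_or(regions, fore, back, genome, n_perm=20, seed=5)
        assert a == b

    def test_null_interval_covers_one(self, genome):
        rng = np.random.default_rng(1)
        fore, back = uniform_sets(rng, 4000, 8000)
        regions = random_intervals(rng, 200, max_pos=190_000)
        res = permutation_or(regions, fore, back, genome, n_perm=100, seed=2)
        assert res.ci_low <= 1.0 <= res.ci_high
        assert res.ci_low <= res.or_mean <= res.ci_high

    def test_invariant_to_position_order(self, genome):
        rng = np.random.default_rng(2)
        fore, back = uniform_sets(rng)
        regions = random_intervals(rng, 80, max_pos=190_000)
        reordered = PositionSet(fore.positions.sample(frac=1, random_state=0)
                                .reset_index(drop=True))
        a = permutation_or(regions, fore, back, genome, n_perm=10, seed=3)
        b = permutation_or(regions, reordered, back, genome, n_perm=10, seed=3)
        assert a.or_mean == b.or_mean

    def test_doubling_background_keeps_or_within_interval(self, genome):
        rng = np.random.default_rng(3)
        fore, back = uniform_sets(rng, 2000, 3000)
        extra = PositionSet(pd.concat([back.positions,
                                       random_positions(rng, 3000, max_pos=199_999)],
                                      ignore_index=True), role="background")
        regions = random_intervals(rng, 150, max_pos=190_000)
        a = permutation_or(regions, fore, back, genome, n_perm=50, seed=4)
        b = permutation_or(regions, fore, extra, genome, n_perm=50, seed=4)
        assert a.ci_low <= b.or_mean <= a.ci_high

    def test_empty_region_set_rejected(self, genome):
        rng = np.random.default_rng(4)
        fore, back = uniform_sets(rng)
        with pytest.raises(ValueError, match="empty region set"):
            permutation_or(as_intervals([]), fore, back, genome, n_perm=5, seed=0)

    def test_background_missing_from_regions_rejected(self, genome):
        fore = PositionSet(pd.DataFrame({"chrom": ["chr1"], "pos": [50]}))
        back = PositionSet(pd.DataFrame({"chrom": ["chr2"], "pos": [100_000]}),
                           role="background")
        regions = as_intervals([("chr1", 0, 100)])
        with pytest.raises(ValueError, match="background"):
            permutation_or(regions, fore, back, genome, n_perm=5, seed=0)

    def test_nonautosomal_regions_dropped(self):
        g = GenomeModel(chromosomes=(("chr1", 100_000), ("chrX", 100_000)))
        rng = np.random.default_rng(5)
        fore = PositionSet(pd.DataFrame({"chrom": "chr1",
                                         "pos": rng.integers(0, 100_000, 500)}))
        back = PositionSet(pd.DataFrame({"chrom": "chr1",
                                         "pos": rng.integers(0, 100_000, 500)}),
                           role="background")
        regions = as_intervals([("chr1", 0, 5000), ("chrX", 0, 5000)])
        res = permutation_or(regions, fore, back, g, n_perm=5, seed=0)
        assert res.n_regions == 1

    def test_baseline_band_brackets_null(self, genome):
        rng = np.random.default_rng(6)
        fore, back = uniform_sets(rng, 3000, 6000)
        regions = random_intervals(rng, 150, max_pos=190_000)
        lo, hi = baseline_band(regions, fore, back, genome, n_draws=10, n_perm=30, seed=1)
        assert lo < 1.0 < hi


class TestTierCurves:
    def test_loosest_tier_equals_full_set(self, genome):
        rng = np.random.default_rng(7)
        peaks = random_intervals(rng, 120, max_pos=190_000)
        peaks["id"] = [f"pk{i}" for i in range(len(peaks))]
        diff = pd.DataFrame({"fdr": rng.uniform(size=120)}, index=peaks["id"])
        fore, back = uniform_sets(rng)
        curves = tier_curves(diff, peaks, fore, back, genome, tiers=(1.0,),
                             n_perm=10, seed=8)
        full = permutation_or(peaks, fore, back, genome, n_perm=10, seed=8)
        assert curves.iloc[0]["n_peaks"] == 120
        assert curves.iloc[0]["observed_fore"] == full.observed_fore

    def test_composition_fractions_reported(self, genome):
        rng = np.random.default_rng(8)
        peaks = random_intervals(rng, 60, max_pos=190_000)
        peaks["id"] = [f"pk{i}" for i in range(len(peaks))]
        diff = pd.DataFrame({"fdr": rng.uniform(size=60)}, index=peaks["id"])
        ann = pd.Series(["enhancer" if i % 2 else "promoter" for i in range(60)],
                        index=peaks["id"])
        fore, back = uniform_sets(rng)
        curves = tier_curves(diff, peaks, fore, back, genome, tiers=(1.0,),
                             annotation=ann, n_perm=5, seed=9)
        assert abs(curves.iloc[0]["frac_enhancer"] - 0.5) < 1e-12


class TestCelltypeSpecific:
    def make_catalog(self, dens_rows, types=("A", "B", "C", "D")):
        cl = pd.DataFrame([("chr1", i * 1000, i * 1000 + 500, *d)
                           for i, d in enumerate(dens_rows)],
                          columns=["chrom", "start", "end", *types])
        el = pd.DataFrame([("chr1", 0, 1, "promoter")],
                          columns=["chrom", "start", "end", "label"])
        return AnnotationCatalog(elements=el, clusters=cl)

    def test_twofold_rule(self):
        cat = self.make_catalog([(2.0, 1.0, 1.0, 0.0)])
        spec = celltype_specific(cat, fold=2.0)
        assert len(spec["A"]) == 1
        assert all(len(spec[t]) == 0 for t in "BCD")

    def test_equal_densities_specific_to_none(self):
        cat = self.make_catalog([(1.0, 1.0, 1.0, 1.0)])
        spec = celltype_specific(cat)
        assert all(len(v) == 0 for v in spec.values())

    def test_matches_direct_predicate(self, rng):
        dens = rng.uniform(0, 3, size=(100, 4))
        cat = self.make_catalog([tuple(r) for r in dens])
        spec = celltype_specific(cat, fold=2.0)
        for k, t in enumerate("ABCD"):
            expected = {i for i in range(100)
                        if dens[i].mean() > 0 and dens[i, k] >= 2.0 * dens[i].mean()}
            got = set(spec[t]["start"] // 1000)
            assert got == expected

    def test_specific_sets_shrink_with_fold(self, rng):
        dens = rng.uniform(0, 3, size=(200, 4))
        cat = self.make_catalog([tuple(r) for r in dens])
        n2 = sum(len(v) for v in celltype_specific(cat, fold=2.0).values())
        n3 = sum(len(v) for v in celltype_specific(cat, fold=3.0).values())
        assert n3 <= n2


class TestCelltypeEnrichment:
    def test_balanced_table_or_one_p_one(self, rng):
        # construct diff and control sets with identical overlap structure
        robust = as_intervals([("chr1", i * 1000, i * 1000 + 100) for i in range(40)])
        robust["id"] = [f"p{i}" for i in range(40)]
        diff = robust.iloc[:20].reset_index(drop=True)
        clusters = as_intervals([("chr1", i * 1000, i * 1000 + 100) for i in range(0, 40, 2)])
        sets = {"ct": clusters}
        # with half the peaks overlapping, any same-size control gives OR near 1
        res = celltype_enrichment(diff, robust, sets, seed=0)
        assert res.iloc[0]["pvalue"] > 0.05

    @pytest.mark.parametrize("seed", range(4))
    def test_fisher_p_equals_hypergeometric_tail_sum(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(1, 30, size=4)
        _, p = stats.fisher_exact([[a, b], [c, d]])
        # two-sided exact p = sum of hypergeometric pmfs <= pmf(observed)
        N, K, n = a + b + c + d, a + c, a + b
        pmf_obs = stats.hypergeom.pmf(a, N, K, n)
        total = sum(stats.hypergeom.pmf(x, N, K, n)
                    for x in range(max(0, n - (N - K)), min(K, n) + 1)
                    if stats.hypergeom.pmf(x, N, K, n) <= pmf_obs * (1 + 1e-9))
        assert abs(p - total) < 1e-9
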