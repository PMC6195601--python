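"""Permutation odds-ratio enrichment of trait-associated positions in peak
sets, and cell-type-specific enhancer enrichment.

The permutation test asks whether foreground positions (GWAS SNPs, DMLs)
overlap a region set more than background positions do, relative to
size-matched regions shuffled into the unmasked autosomal genome:

    OR_r = (observed_fore / observed_back) / (shuffled_fore_r / shuffled_back_r)

with the observed counts computed once and one shuffle per round.  The
reported 95% interval is mean +/- 1.96*sd over the per-round odds ratios
(percentile and standard-error variants are available), alongside a baseline
band obtained by running the same test on shuffled copies of the region set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import AnnotationCatalog
from .intervals import (GenomeModel, PositionSet, _FlatSpace, overlap_counts,
                        shuffle_regions)

logger = logging.getLogger("cartatac.enrichment")

DEFAULT_TIERS = (1e-4, 1e-3, 1e-2, 0.05, 0.1, 0.2, 0.5, 1.0)


@dataclass
class EnrichmentResult:
    label: str
    or_mean: float
    ci_low: float
    ci_high: float
    n_perm: int
    observed_fore: int
    observed_back: int
    n_regions: int
    n_continuity: int = 0
    baseline_low: float = np.nan
    baseline_high: float = np.nan

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def _autosomal(regions: pd.DataFrame, genome: GenomeModel) -> pd.DataFrame:
    keep = regions["chrom"].isin(set(genome.autosomes))
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d non-autosomal regions", dropped)
    return regions[keep].reset_index(drop=True)


def _round_ors(regions, fore_pos, back_pos, genome, n_perm, rng, space=None):
    space = space or _FlatSpace(genome)
    reg_start, reg_len = space.flatten_intervals(regions)
    fore_flat = space.flatten_positions(fore_pos)
    back_flat = space.flatten_positions(back_pos)
    of = space.count_in_union(fore_flat, reg_start, reg_len)
    ob = space.count_in_union(back_flat, reg_start, reg_len)
    if ob == 0:
        raise ValueError("no background positions fall in the region set; "
                         "the background must populate the regions")
    ors = np.empty(n_perm)
    n_cont = 0
    for r in range(n_perm):
        starts = space.shuffle_starts(reg_len, rng)
        sf = space.count_in_union(fore_flat, starts, reg_len)
        sb = space.count_in_union(back_flat, starts, reg_len)
        a, b, c, d = of, ob, sf, sb
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 1, b + 1, c + 1, d + 1
            n_cont += 1
        ors[r] = (a / b) / (c / d)
    if n_cont:
        logger.info("continuity substitution applied in %d/%d rounds", n_cont, n_perm)
    return ors, of, ob, n_cont


def _interval(ors: np.ndarray, ci: str):
    m = float(np.mean(ors))
    if len(ors) < 2:
        return m, m, m
    if ci == "percentile":
        lo, hi = np.percentile(ors, [2.5, 97.5])
        return m, float(lo), float(hi)
    sd = float(np.std(ors, ddof=1))
    if ci == "sem":
        sd = sd / np.sqrt(len(ors))
    elif ci != "sd":
        raise ValueError("ci must be 'sd', 'sem' or 'percentile'")
    return m, m - 1.96 * sd, m + 1.96 * sd


def permutation_or(regions: pd.DataFrame, fore: PositionSet, back: PositionSet,
                   genome: GenomeModel, n_perm: int = 100, seed=0,
                   label: str = "", ci: str = "sd") -> EnrichmentResult:
    """Permutation odds ratio of foreground-vs-background enrichment in
    ``regions``, with size-matched shuffles into the masked autosomal genome."""
    if len(fore) == 0 or len(back) == 0:
        raise ValueError("foreground and background position sets must be non-empty")
    regions = _autosomal(regions, genome)
    if len(regions) == 0:
        raise ValueError("empty region set after autosome restriction")
    fore_pos = fore.restrict(genome.autosomes).positions
    back_pos = back.restrict(genome.autosomes).positions
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ors, of, ob, n_cont = _round_ors(regions, fore_pos, back_pos, genome, n_perm, rng)
    m, lo, hi = _interval(ors, ci)
    return EnrichmentResult(label=label or "regions", or_mean=m, ci_low=lo, ci_high=hi,
                            n_perm=n_perm, observed_fore=of, observed_back=ob,
                            n_regions=len(regions), n_continuity=n_cont)


def baseline_band(regions: pd.DataFrame, fore: PositionSet, back: PositionSet,
                  genome: GenomeModel, n_draws: int = 20, n_perm: int = 100,
                  seed=0) -> tuple:
    """0.05-0.95 percentile band of or_mean when the region set itself is a
    shuffled copy (the no-signal reference drawn n_draws times)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    regions = _autosomal(regions, genome)
    fore_pos = fore.restrict(genome.autosomes).positions
    back_pos = back.restrict(genome.autosomes).positions
    means = []
    for _ in range(n_draws):
        fake = shuffle_regions(regions, genome, rng)
        ors, *_ = _round_ors(fake, fore_pos, back_pos, genome, n_perm, rng)
        means.append(float(np.mean(ors)))
    lo, hi = np.percentile(means, [5, 95])
    return float(lo), float(hi)


def tier_curves(diff_table: pd.DataFrame, peaks: pd.DataFrame, fore: PositionSet,
                back: PositionSet, genome: GenomeModel, tiers=DEFAULT_TIERS,
                annotation: pd.Series | None = None, n_perm: int = 100,
                seed=0, ci: str = "sd") -> pd.DataFrame:
    """Enrichment across FDR tiers (loosest tier = the full tested set), with
    the promoter/enhancer composition of each tier."""
    tiers = sorted(tiers)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    peaks = peaks.set_index("id", drop=False) if "id" in peaks.columns else peaks
    rows = []
    for t in tiers:
        sel_ids = diff_table.index[diff_table["fdr"].values <= t]
        sub = peaks.loc[peaks.index.intersection(sel_ids)].reset_index(drop=True)
        if len(sub) == 0:
            logger.info("tier %g: no peaks, skipped", t)
            continue
        res = permutation_or(sub, fore, back, genome, n_perm=n_perm, seed=rng,
                             label=f"fdr<={t:g}", ci=ci)
        row = {"tier": t, "n_peaks": len(sub), "or_mean": res.or_mean,
               "ci_low": res.ci_low, "ci_high": res.ci_high,
               "observed_fore": res.observed_fore, "observed_back": res.observed_back,
               "n_continuity": res.n_continuity}
        if annotation is not None:
            ann = annotation.reindex(sel_ids)
            row["frac_enhancer"] = float((ann == "enhancer").mean())
            row["frac_promoter"] = float((ann == "promoter").mean())
        rows.append(row)
    return pd.DataFrame(rows)


def celltype_specific(catalog: AnnotationCatalog, fold: float = 2.0) -> dict:
    """Per-cell-type pooled sets of specific enhancer clusters.

    A cluster is specific to cell type c when its density in c is at least
    ``fold`` times the cluster's mean density across all cell types.
    """
    types = catalog.cell_types
    if len(types) < 2:
        raise ValueError("need >= 2 cell types")
    dens = catalog.clusters[types].values.astype(float)
    mean = dens.mean(axis=1)
    out = {}
    for k, ct in enumerate(types):
        with np.errstate(invalid="ignore"):
            spec = dens[:, k] >= fold * mean
        spec &= mean > 0
        out[ct] = catalog.clusters.loc[spec, ["chrom", "start", "end"]].reset_index(drop=True)
    return out


def celltype_enrichment(diff_peaks: pd.DataFrame, robust_peaks: pd.DataFrame,
                        specific_sets: dict, seed=0, n_controls: int = 1) -> pd.DataFrame:
    """Fisher's exact enrichment of cell-type-specific enhancer clusters in
    differential peaks against an equally sized random control drawn from the
    robust peaks; cell types ranked by odds ratio."""
    if len(diff_peaks) > len(robust_peaks):
        raise ValueError("differential peak set larger than robust peak set")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    controls = [robust_peaks.iloc[rng.choice(len(robust_peaks), size=len(diff_peaks),
                                             replace=False)].reset_index(drop=True)
                for _ in range(n_controls)]
    for ct, clusters in specific_sets.items():
        d_hit = int((overlap_counts(diff_peaks, clusters) > 0).sum())
        c_hits = [int((overlap_counts(ctrl, clusters) > 0).sum()) for ctrl in controls]
        c_hit = float(np.mean(c_hits))
        a, b = d_hit, len(diff_peaks) - d_hit
        c, d = c_hit, len(diff_peaks) - c_hit
        table = np.array([[a, b], [c, d]])
        _, p = stats.fisher_exact(np.round(table).astype(int), alternative="two-sided")
        if (table == 0).any():
            table = table + 0.5  # Haldane correction
        oddsr = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
        se = np.sqrt((1 / table).sum())
        rows.append({"cell_type": ct, "odds_ratio": float(oddsr), "pvalue": float(p),
                     "ci_low": float(np.exp(np.log(oddsr) - 1.96 * se)),
                     "ci_high": float(np.exp(np.log(oddsr) + 1.96 * se)),
                     "n_diff_hit": a, "n_control_hit": c_hit})
    out = pd.DataFrame(rows).sort_values("odds_ratio", ascending=False, kind="mergesort")
    return out.reset_index(drop=True)
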