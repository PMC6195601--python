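"""Unified peak atlas: RLE normalization, robust filtering, regulatory
annotation and the DHS-enrichment library QC score.

The atlas starts from peaks called on the two pooled compartments, merged into
raw regions upstream (``merge_intervals`` with a 300 bp join distance).  Counts
per raw region and sample are consumed, not computed.  Normalization follows
the relative-log-expression (median-of-ratios) scheme; a region is *robust*
when it reaches >= 2 CPM in at least 6 samples of either compartment, and only
robust regions enter the differential analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .intervals import GenomeModel, overlap, shuffle_regions, count_positions_in_union

COMPARTMENTS = ("oLT", "iMT")
ANNOTATION_CLASSES = ("promoter", "enhancer", "other")
ELEMENT_LABELS = ("promoter", "proximal_enhancer", "distal_enhancer")


@dataclass
class AnnotationCatalog:
    """Reference regulatory elements and enhancer clusters.

    ``elements``: interval frame with a ``label`` column drawn from
    ``ELEMENT_LABELS``.  ``clusters``: interval frame whose remaining numeric
    columns are per-cell-type activity densities (one column per cell type).
    """

    elements: pd.DataFrame
    clusters: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        bad = set(self.elements["label"]) - set(ELEMENT_LABELS)
        if bad:
            raise ValueError(f"unknown element labels: {sorted(bad)}")
        if len(self.clusters):
            dens = self.clusters[self.cell_types]
            if (dens.values < 0).any():
                raise ValueError("cluster densities must be >= 0")

    @property
    def cell_types(self):
        return [c for c in self.clusters.columns if c not in ("chrom", "start", "end", "id")]


def rle_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Relative-log-expression (median-of-ratios) size factors.

    The per-feature reference is the geometric mean across samples, computed
    over features positive in every sample; each sample's factor is the median
    ratio to that reference, rescaled so the factors have geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples for RLE normalization")
    mat = counts.values.astype(float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no feature has positive counts in every sample; "
                         "prefilter features before RLE normalization")
    sub = mat[allpos]
    ref = np.exp(np.mean(np.log(sub), axis=1))
    ratios = sub / ref[:, None]
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def effective_library_size(counts: pd.DataFrame, size_factors: pd.Series) -> pd.Series:
    """Effective library size = size factor x geometric-mean raw library size.

    The median-of-ratios factor already carries each sample's sequencing
    depth, so it is anchored to the cohort's typical depth rather than
    multiplied onto the per-sample total (which would count depth twice).
    """
    lib = counts.sum(axis=0)
    return size_factors.reindex(counts.columns) * float(np.exp(np.mean(np.log(lib))))


def cpm_matrix(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """CPM on the effective library size."""
    return counts * 1e6 / effective_library_size(counts, size_factors)


def robust_filter(cpm: pd.DataFrame, meta: pd.DataFrame,
                  min_cpm: float = 2.0, min_samples: int = 6) -> pd.Series:
    """Boolean robust flag per peak: >= ``min_cpm`` CPM in at least
    ``min_samples`` samples of either compartment."""
    flags = {}
    for comp in COMPARTMENTS:
        samples = meta.loc[meta["compartment"] == comp, "sample"]
        if min_samples > len(samples):
            raise ValueError(f"min_samples={min_samples} exceeds {comp} group size {len(samples)}")
        flags[comp] = (cpm[list(samples)] >= min_cpm).sum(axis=1) >= min_samples
    return (flags["oLT"] | flags["iMT"]).rename("robust")


def annotate_peaks(peaks: pd.DataFrame, catalog: AnnotationCatalog):
    """Assign each peak one class: promoter > enhancer > other.

    A peak intersecting any promoter element is a promoter even if it also
    intersects enhancer elements (promoter-preferential rule); otherwise any
    enhancer-element overlap makes it an enhancer.  Returns the class Series
    and the number of dual peaks (intersecting both a promoter and a
    proximal-enhancer element).
    """
    el = catalog.elements.reset_index(drop=True)
    hits = overlap(peaks, el[["chrom", "start", "end"]])
    labels = el["label"].values
    is_prom = np.zeros(len(peaks), dtype=bool)
    is_prox = np.zeros(len(peaks), dtype=bool)
    is_enh = np.zeros(len(peaks), dtype=bool)
    if len(hits):
        hl = labels[hits["subject"].values]
        qi = hits["query"].values
        np.logical_or.at(is_prom, qi[hl == "promoter"], True)
        np.logical_or.at(is_prox, qi[hl == "proximal_enhancer"], True)
        np.logical_or.at(is_enh, qi[(hl == "proximal_enhancer") | (hl == "distal_enhancer")], True)
    cls = np.where(is_prom, "promoter", np.where(is_enh, "enhancer", "other"))
    n_dual = int((is_prom & is_prox).sum())
    index = peaks["id"] if "id" in peaks.columns else peaks.index
    return pd.Series(cls, index=index, name="annotation"), n_dual


def dhs_enrichment_score(read_positions: pd.DataFrame, dhs_regions: pd.DataFrame,
                         genome: GenomeModel, n_draws: int = 10, seed=0) -> float:
    """Library-quality score: reads inside the DHS catalog over the mean reads
    inside ``n_draws`` random region sets of the same sizes.

    ``read_positions`` are point loci (fragment midpoints), ``chrom``/``pos``.
    """
    obs = count_positions_in_union(read_positions, dhs_regions)
    rng = np.random.default_rng(seed)
    rand = []
    for _ in range(n_draws):
        shuf = shuffle_regions(dhs_regions, genome, rng)
        rand.append(count_positions_in_union(read_positions, shuf))
    denom = float(np.mean(rand))
    if denom == 0:
        raise ValueError("zero reads in every random region set; increase n_draws "
                         "or check the read positions")
    return obs / denom


def round_half_up(x, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, ndigits: int = 1) -> float:
    """100*count/total rounded half-up, matching reported printed precision."""
    if total <= 0:
        raise ValueError("total must be positive")
    frac = Decimal(count) * 100 / Decimal(total)
    return float(frac.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


def link_summary_fractions(n_one: int, n_two: int, n_three_plus: int):
    """Percentages of linked peaks with 1 / 2 / >=3 target genes, one decimal."""
    counts = (n_one, n_two, n_three_plus)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be >= 0")
    total = sum(counts)
    if total == 0:
        raise ValueError("at least one count must be positive")
    return tuple(percentage(c, total) for c in counts)


@dataclass
class PeakAtlas:
    """The unified peak set with counts, normalization and annotation."""

    peaks: pd.DataFrame                  # chrom/start/end/id, sorted, non-overlapping
    counts: pd.DataFrame                 # index = peak id, columns = samples
    meta: pd.DataFrame                   # sample / patient / compartment / dhs_score
    size_factors: pd.Series
    cpm: pd.DataFrame
    annotation: pd.Series                # promoter | enhancer | other, index = peak id
    robust: pd.Series
    n_dual: int = 0

    def robust_peaks(self) -> pd.DataFrame:
        return self.peaks[self.robust.reindex(self.peaks["id"]).values].reset_index(drop=True)

    def class_counts(self) -> dict:
        ann = self.annotation[self.robust.reindex(self.annotation.index)]
        n = len(ann)
        out = {"n_robust": n}
        for c in ANNOTATION_CLASSES:
            k = int((ann == c).sum())
            out[f"n_{c}"] = k
            out[f"pct_{c}"] = percentage(k, n) if n else 0.0
        out["n_dual"] = self.n_dual
        out["pct_dual"] = percentage(self.n_dual, n) if n else 0.0
        return out


def build_atlas(peaks: pd.DataFrame, counts: pd.DataFrame, meta: pd.DataFrame,
                catalog: AnnotationCatalog, min_cpm: float = 2.0,
                min_samples: int = 6) -> PeakAtlas:
    """Normalize, flag robust peaks and annotate, in the order the analysis
    expects (size factors computed once on the raw merged regions)."""
    if set(meta["compartment"]) - set(COMPARTMENTS):
        raise ValueError("compartment must be oLT or iMT")
    counts = counts.loc[peaks["id"].values, list(meta["sample"])]
    sf = rle_size_factors(counts)
    cpm = cpm_matrix(counts, sf)
    robust = robust_filter(cpm, meta, min_cpm=min_cpm, min_samples=min_samples)
    ann, n_dual = annotate_peaks(peaks, catalog)
    return PeakAtlas(peaks=peaks, counts=counts, meta=meta, size_factors=sf,
                     cpm=cpm, annotation=ann, robust=robust, n_dual=n_dual)
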