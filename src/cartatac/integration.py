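"""Cross-omics integration.

Combines differential expression with differential accessibility through the
peak-to-gene link table: a gene is *concordant* when it is differentially
expressed and at least one linked differential promoter or enhancer peak
changes accessibility in the same direction.  Methylation concordance follows
the opposite-sign rule (hypomethylation with increased accessibility, and vice
versa).  Also provides the supporting statistics: Welch t-tests of expression
fold changes stratified by regulator accessibility direction, and Fisher's
exact tests of gene-set overlaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import differential_table

logger = logging.getLogger("cartatac.integration")

CONCORDANCE_CLASSES = ("concordant", "discordant", "expression_only",
                       "accessibility_only", "ns")


def expression_de(gene_counts: pd.DataFrame, meta: pd.DataFrame,
                  threshold: float = 0.05, paired: bool = False) -> pd.DataFrame:
    """Differential expression iMT vs oLT; the peak model without the
    accessibility QC covariate."""
    return differential_table(gene_counts, meta, threshold=threshold,
                              covariates=(), kind="expression", paired=paired)


@dataclass
class ConcordanceReport:
    table: pd.DataFrame        # per-gene class and supporting-peak evidence
    summary: dict              # counts per class (+ conflicts)

    def genes(self, cls: str) -> list:
        return list(self.table.index[self.table["class"] == cls])


def concordant_genes(expr_table: pd.DataFrame, peak_table: pd.DataFrame,
                     promoter_links: pd.DataFrame, enhancer_links: pd.DataFrame,
                     threshold: float = 0.05) -> ConcordanceReport:
    """Classify genes by agreement between expression and accessibility.

    A gene is concordant when its expression FDR <= threshold and some linked
    promoter or enhancer peak has accessibility FDR <= threshold with the same
    fold-change sign; a DE gene whose differential linked peaks all change in
    the opposite direction is discordant.  A gene with both kinds of support
    is classed concordant (existence rule) and counted as a conflict.
    """
    links = pd.concat([promoter_links, enhancer_links], ignore_index=True) \
        if len(promoter_links) or len(enhancer_links) else pd.DataFrame(columns=["peak", "gene"])
    links = links.sort_values(["gene", "peak"], kind="mergesort")
    known = set(expr_table.index)
    skipped = set(links["gene"]) - known
    if skipped:
        logger.info("%d linked genes absent from the expression table; skipped", len(skipped))
    links = links[links["gene"].isin(known)]
    by_gene = {g: list(sub["peak"]) for g, sub in links.groupby("gene", sort=True)}

    peak_fdr = peak_table["fdr"]
    peak_fc = peak_table["log2fc"]
    rows = []
    n_conflict = 0
    for gene in expr_table.index:
        e_fdr = expr_table.at[gene, "fdr"]
        e_fc = expr_table.at[gene, "log2fc"]
        gene_de = np.isfinite(e_fdr) and e_fdr <= threshold and e_fc != 0
        same, oppo = [], []
        for pk in by_gene.get(gene, ()):
            if pk not in peak_fdr.index:
                continue
            f = peak_fdr[pk]
            fc = peak_fc[pk]
            if not (np.isfinite(f) and f <= threshold and fc != 0):
                continue
            (same if np.sign(fc) == np.sign(e_fc) else oppo).append(pk)
        if gene_de and same:
            cls = "concordant"
            if oppo:
                n_conflict += 1
        elif gene_de and oppo:
            cls = "discordant"
        elif gene_de:
            cls = "expression_only"
        elif same or oppo:
            cls = "accessibility_only"
        else:
            cls = "ns"
        rows.append({"gene": gene, "expr_log2fc": e_fc, "expr_fdr": e_fdr, "class": cls,
                     "supporting_peaks": ";".join(same), "opposing_peaks": ";".join(oppo)})
    table = pd.DataFrame(rows).set_index("gene")
    summary = {f"n_{c}": int((table["class"] == c).sum()) for c in CONCORDANCE_CLASSES}
    summary["n_conflict"] = n_conflict
    summary["n_genes"] = len(table)
    return ConcordanceReport(table=table, summary=summary)


def dml_concordance(rows: pd.DataFrame, delta_col: str = "delta_beta",
                    fc_col: str = "access_log2fc") -> tuple:
    """(n_concordant, n_total, fraction) under the opposite-sign rule.

    Positive delta beta means hypermethylation in the damaged compartment, so
    concordance is hypomethylation with increased accessibility or
    hypermethylation with decreased accessibility: sign(delta) != sign(fc).
    Rows where either quantity is exactly zero have no direction and are
    excluded from the denominator.
    """
    delta = rows[delta_col].values.astype(float)
    fc = rows[fc_col].values.astype(float)
    if not (np.isfinite(delta).all() and np.isfinite(fc).all()):
        raise ValueError("delta beta and fold change must be finite")
    usable = (delta != 0) & (fc != 0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("%d rows with zero delta beta or fold change excluded", n_dropped)
    conc = np.sign(delta[usable]) != np.sign(fc[usable])
    n_total = int(usable.sum())
    n_conc = int(conc.sum())
    return n_conc, n_total, (n_conc / n_total if n_total else float("nan"))


def fc_by_accessibility(expr_table: pd.DataFrame, gene_directions: pd.DataFrame) -> dict:
    """Welch t-test of expression log2 fold changes, genes with more- vs
    less-accessible regulators, separately per regulator class.

    ``gene_directions`` columns: gene, regulator_class (promoter|enhancer),
    direction (more_accessible|less_accessible).  Genes appearing in both
    direction groups of a class are excluded and counted.
    """
    out = {}
    for cls, sub in gene_directions.groupby("regulator_class", sort=True):
        more = set(sub.loc[sub["direction"] == "more_accessible", "gene"])
        less = set(sub.loc[sub["direction"] == "less_accessible", "gene"])
        both = more & less
        more, less = more - both, less - both
        x = expr_table.loc[expr_table.index.intersection(sorted(more)), "log2fc"].values
        y = expr_table.loc[expr_table.index.intersection(sorted(less)), "log2fc"].values
        if len(x) == 0 or len(y) == 0:
            raise ValueError(f"{cls}: both direction groups must be non-empty")
        if np.array_equal(np.sort(x), np.sort(y)):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(x, y, equal_var=False)
        out[cls] = {"mean_more": float(np.mean(x)), "mean_less": float(np.mean(y)),
                    "t": float(t), "pvalue": float(p),
                    "n_more": len(x), "n_less": len(y), "n_excluded_both": len(both)}
    return out


def overlap_significance(de_genes, genes_with_diff_promoters, genes_with_diff_enhancers,
                         universe) -> dict:
    """Two-sided Fisher's exact test of DE-gene overlap with the genes having
    differential promoters / enhancers, within the gene universe."""
    universe = set(universe)
    de = set(de_genes) & universe
    out = {}
    for cls, genes in (("promoter", genes_with_diff_promoters),
                       ("enhancer", genes_with_diff_enhancers)):
        gs = set(genes) & universe
        a = len(de & gs)
        b = len(de - gs)
        c = len(gs - de)
        d = len(universe) - a - b - c
        oddsr, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        out[cls] = {"n_overlap": a, "odds_ratio": float(oddsr), "pvalue": float(p),
                    "n_de": len(de), "n_class": len(gs), "n_universe": len(universe)}
    return out
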