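"""Assigning peaks to putative target genes.

Promoter peaks are assigned to the genes whose transcript TSS they contain.
Enhancer peaks are linked to a gene when they overlap an eQTL of that gene
(any tissue, p strictly below the cutoff) or fall inside a precomputed
enhancer-promoter linkage interval for that gene.  Links from both sources are
unioned and deduplicated per (peak, gene), keeping all evidence tags.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .atlas import link_summary_fractions
from .intervals import overlap

logger = logging.getLogger("cartatac.linking")

LINK_COLUMNS = ["peak", "gene", "evidence", "detail"]


def _empty_links() -> pd.DataFrame:
    return pd.DataFrame(columns=LINK_COLUMNS)


def assign_promoters(promoter_peaks: pd.DataFrame, tss_table: pd.DataFrame) -> pd.DataFrame:
    """Link rows (peak, gene, 'tss') for every gene with a transcript TSS
    inside the peak; multiple genes per peak allowed, duplicates collapsed."""
    if len(promoter_peaks) == 0 or len(tss_table) == 0:
        return _empty_links()
    peaks = promoter_peaks.reset_index(drop=True)
    hits = overlap(peaks, tss_table[["chrom", "pos"]])
    if len(hits) == 0:
        return _empty_links()
    rows = pd.DataFrame({
        "peak": peaks["id"].values[hits["query"].values],
        "gene": tss_table["gene"].values[hits["subject"].values],
        "evidence": "tss",
        "detail": tss_table["transcript"].astype(str).values[hits["subject"].values]
        if "transcript" in tss_table.columns else "",
    })
    rows = rows.sort_values(["peak", "gene", "detail"], kind="mergesort")
    rows = rows.groupby(["peak", "gene", "evidence"], as_index=False, sort=True).agg(
        detail=("detail", lambda s: ";".join(sorted(set(map(str, s))))))
    return rows[LINK_COLUMNS].reset_index(drop=True)


def _validate_pvalues(eqtl_table: pd.DataFrame) -> np.ndarray:
    p = pd.to_numeric(eqtl_table["p"], errors="coerce").values
    bad = np.isnan(p) | (p < 0) | (p > 1)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 1
        raise ValueError(f"malformed eQTL p-value at row {line}: {eqtl_table['p'].iloc[line-1]!r}")
    return p


def link_enhancers(enhancer_peaks: pd.DataFrame, eqtl_table: pd.DataFrame | None = None,
                   linkage_table: pd.DataFrame | None = None,
                   p_cut: float = 1e-5) -> pd.DataFrame:
    """Union of eQTL-supported (p < p_cut, any tissue) and precomputed-linkage
    links, one row per (peak, gene) carrying every supporting evidence tag."""
    peaks = enhancer_peaks.reset_index(drop=True)
    pieces = []
    if eqtl_table is not None and len(eqtl_table):
        p = _validate_pvalues(eqtl_table)
        keep = eqtl_table.reset_index(drop=True)[p < p_cut]
        pvals = p[p < p_cut]
        if len(keep):
            hits = overlap(peaks, keep[["chrom", "pos"]].reset_index(drop=True))
            if len(hits):
                sub = keep.reset_index(drop=True)
                detail = pvals[hits["subject"].values].astype(str)
                if "tissue" in sub.columns:
                    detail = sub["tissue"].astype(str).values[hits["subject"].values] + ":" + detail
                pieces.append(pd.DataFrame({
                    "peak": peaks["id"].values[hits["query"].values],
                    "gene": sub["gene"].values[hits["subject"].values],
                    "evidence": "eqtl", "detail": detail}))
    if linkage_table is not None and len(linkage_table):
        link = linkage_table.reset_index(drop=True)
        hits = overlap(peaks, link[["chrom", "start", "end"]])
        if len(hits):
            pieces.append(pd.DataFrame({
                "peak": peaks["id"].values[hits["query"].values],
                "gene": link["gene"].values[hits["subject"].values],
                "evidence": "linkage",
                "detail": link["score"].astype(str).values[hits["subject"].values]
                if "score" in link.columns else ""}))
    if not pieces:
        return _empty_links()
    rows = pd.concat(pieces, ignore_index=True)
    merged = rows.sort_values(["peak", "gene", "evidence"], kind="mergesort").groupby(
        ["peak", "gene"], as_index=False, sort=True).agg(
        evidence=("evidence", lambda s: ",".join(sorted(set(s)))),
        detail=("detail", lambda s: ";".join(x for x in map(str, s) if x)))
    return merged[LINK_COLUMNS].reset_index(drop=True)


def linkage_summary(link_table: pd.DataFrame, enhancer_peaks: pd.DataFrame) -> dict:
    """Arity summary: peaks linked to 0/1/2/>=3 distinct genes, with the
    1/2/3+ percentages over linked peaks."""
    peak_ids = enhancer_peaks["id"] if "id" in enhancer_peaks.columns else enhancer_peaks
    n_peaks = len(peak_ids)
    if len(link_table) == 0:
        logger.warning("empty link table; linkage percentages reported as 0")
        return {"n_peaks": n_peaks, "n_linked": 0, "n_zero": n_peaks,
                "n_one": 0, "n_two": 0, "n_three_plus": 0,
                "pct_one": 0.0, "pct_two": 0.0, "pct_three_plus": 0.0}
    arity = link_table.groupby("peak")["gene"].nunique()
    arity = arity.reindex(peak_ids, fill_value=0)
    n_one = int((arity == 1).sum())
    n_two = int((arity == 2).sum())
    n_three = int((arity >= 3).sum())
    n_linked = n_one + n_two + n_three
    pct = link_summary_fractions(n_one, n_two, n_three) if n_linked else (0.0, 0.0, 0.0)
    return {"n_peaks": n_peaks, "n_linked": n_linked, "n_zero": int((arity == 0).sum()),
            "n_one": n_one, "n_two": n_two, "n_three_plus": n_three,
            "pct_one": pct[0], "pct_two": pct[1], "pct_three_plus": pct[2]}


def distinct_loci(rows: pd.DataFrame, lead_col: str = "lead_snp") -> int:
    """Number of independent loci, grouped by distinct lead-SNP identifier."""
    if len(rows) == 0:
        return 0
    if lead_col not in rows.columns:
        raise ValueError(f"missing lead-SNP column {lead_col!r}")
    return int(rows[lead_col].nunique())
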