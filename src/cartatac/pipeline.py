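"""End-to-end orchestration: simulate -> atlas -> differential -> enrichment
-> linking -> integration, with per-stage seeds derived from one master seed
and a versioned machine-readable summary."""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import atlas as atlas_mod
from . import differential as diff_mod
from . import enrichment as enr_mod
from . import integration as int_mod
from . import linking as link_mod
from .intervals import overlap
from .simulate import SimConfig, SimDataset, simulate_dataset

logger = logging.getLogger("cartatac.pipeline")

SUMMARY_SCHEMA_VERSION = 1
_REQUIRED_SUMMARY_KEYS = ("schema_version", "seed", "atlas", "differential",
                          "enrichment", "linking", "integration")


@dataclass
class RunConfig:
    """Thresholds and scales for one pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    min_cpm: float = 2.0
    min_samples: int = 6
    fdr: float = 0.05
    eqtl_p_cut: float = 1e-5
    specificity_fold: float = 2.0
    n_perm: int = 100
    tiers: tuple = (0.01, 0.05, 0.2, 1.0)
    outdir: str | None = None

    def __post_init__(self):
        if not 0 < self.fdr <= 1:
            raise ValueError("fdr threshold must lie in (0, 1]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed (stage-name hash folded into the master)."""
    return (int(master) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("atlas")
def _run_atlas(data: SimDataset, cfg: RunConfig) -> atlas_mod.PeakAtlas:
    return atlas_mod.build_atlas(data.peaks, data.counts, data.meta, data.catalog,
                                 min_cpm=cfg.min_cpm, min_samples=cfg.min_samples)


@_stage("differential")
def _run_differential(atlas: atlas_mod.PeakAtlas, cfg: RunConfig) -> pd.DataFrame:
    robust_ids = atlas.robust.index[atlas.robust.values]
    counts = atlas.counts.loc[robust_ids]
    return diff_mod.differential_table(counts, atlas.meta, threshold=cfg.fdr,
                                      covariates=("dhs_score",),
                                      size_factors=atlas.size_factors)


@_stage("enrichment")
def _run_enrichment(data: SimDataset, atlas: atlas_mod.PeakAtlas,
                    diff_table: pd.DataFrame, cfg: RunConfig) -> dict:
    seed = stage_seed(cfg.seed, "enrichment")
    robust = atlas.robust_peaks()
    out = {"tiers": {}}
    sets = {"snp": (data.snp_fore, data.snp_back),
            "dml": (data.dml_fore, data.dml_back),
            "control": (data.ctl_fore, data.ctl_back)}
    for i, (name, (fore, back)) in enumerate(sets.items()):
        curves = enr_mod.tier_curves(diff_table, robust, fore, back, data.genome,
                                     tiers=cfg.tiers, annotation=atlas.annotation,
                                     n_perm=cfg.n_perm, seed=seed + i)
        out["tiers"][name] = curves.to_dict(orient="records")
    specific = enr_mod.celltype_specific(data.catalog, fold=cfg.specificity_fold)
    diff_ids = diff_table.index[(diff_table["fdr"] <= cfg.fdr).fillna(False)]
    diff_peaks = robust.set_index("id", drop=False).loc[
        robust.set_index("id").index.intersection(diff_ids)].reset_index(drop=True)
    ct = enr_mod.celltype_enrichment(diff_peaks, robust, specific,
                                     seed=stage_seed(cfg.seed, "celltype"))
    out["celltype"] = ct.to_dict(orient="records")
    out["n_specific_sets"] = {k: len(v) for k, v in specific.items()}
    return out


@_stage("linking")
def _run_linking(data: SimDataset, atlas: atlas_mod.PeakAtlas,
                 diff_table: pd.DataFrame, cfg: RunConfig) -> dict:
    robust = atlas.robust_peaks()
    ann = atlas.annotation.reindex(robust["id"])
    prom_peaks = robust[(ann == "promoter").values].reset_index(drop=True)
    enh_peaks = robust[(ann == "enhancer").values].reset_index(drop=True)
    prom_links = link_mod.assign_promoters(prom_peaks, data.tss_table)
    enh_links = link_mod.link_enhancers(enh_peaks, data.eqtl_table, data.linkage_table,
                                        p_cut=cfg.eqtl_p_cut)
    summary = link_mod.linkage_summary(enh_links, enh_peaks)
    # independent loci among GWAS-hit differential enhancers
    diff_enh = enh_peaks[
        (diff_table["fdr"].reindex(enh_peaks["id"]) <= cfg.fdr).fillna(False).values]
    hits = overlap(diff_enh.reset_index(drop=True), data.snp_fore.positions)
    snp_rows = data.snp_fore.positions.iloc[hits["subject"].values] if len(hits) else \
        data.snp_fore.positions.iloc[[]]
    n_loci = link_mod.distinct_loci(snp_rows, lead_col="lead_snp")
    return {"promoter_links": prom_links, "enhancer_links": enh_links,
            "summary": summary,
            "n_gwas_hit_diff_enhancers": int(hits["query"].nunique()) if len(hits) else 0,
            "n_independent_loci": n_loci}


@_stage("integration")
def _run_integration(data: SimDataset, atlas: atlas_mod.PeakAtlas,
                     diff_table: pd.DataFrame, links: dict, cfg: RunConfig) -> dict:
    expr = int_mod.expression_de(data.gene_counts, data.meta, threshold=cfg.fdr)
    report = int_mod.concordant_genes(expr, diff_table, links["promoter_links"],
                                      links["enhancer_links"], threshold=cfg.fdr)

    # methylation-direction concordance over differential peaks hit by a probe
    diff_ids = set(diff_table.index[(diff_table["fdr"] <= cfg.fdr).fillna(False)])
    robust = atlas.robust_peaks()
    diff_peaks = robust[robust["id"].isin(diff_ids)].reset_index(drop=True)
    hits = overlap(diff_peaks, data.dml_fore.positions)
    if len(hits):
        dml_rows = pd.DataFrame({
            "peak": diff_peaks["id"].values[hits["query"].values],
            "delta_beta": data.dml_fore.positions["delta_beta"].values[hits["subject"].values],
        })
        dml_rows["access_log2fc"] = diff_table["log2fc"].reindex(dml_rows["peak"]).values
        n_conc, n_tot, frac = int_mod.dml_concordance(dml_rows)
    else:
        n_conc, n_tot, frac = 0, 0, float("nan")

    # fold-change stratification and overlap tests
    all_links = {"promoter": links["promoter_links"], "enhancer": links["enhancer_links"]}
    gd_rows = []
    diff_dir = diff_table["direction"]
    for cls, tab in all_links.items():
        for _, r in tab.iterrows():
            d = diff_dir.get(r["peak"], "ns")
            if d in ("more_accessible", "less_accessible"):
                gd_rows.append({"gene": r["gene"], "regulator_class": cls, "direction": d})
    gene_dirs = pd.DataFrame(gd_rows, columns=["gene", "regulator_class", "direction"])
    try:
        fc_stats = int_mod.fc_by_accessibility(expr, gene_dirs) if len(gene_dirs) else {}
    except ValueError as exc:
        logger.warning("fold-change stratification skipped: %s", exc)
        fc_stats = {}
    de_genes = set(expr.index[expr["direction"] != "ns"])
    g_prom = set(gene_dirs.loc[gene_dirs["regulator_class"] == "promoter", "gene"])
    g_enh = set(gene_dirs.loc[gene_dirs["regulator_class"] == "enhancer", "gene"])
    overlap_stats = int_mod.overlap_significance(de_genes, g_prom, g_enh, set(expr.index))

    return {"expression": expr, "concordance": report,
            "dml": {"n_concordant": n_conc, "n_total": n_tot, "fraction": frac},
            "fc_by_accessibility": fc_stats, "overlap_significance": overlap_stats}


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating, float)):
        v = float(x)
        return None if not np.isfinite(v) else v
    return x


def validate_summary(summary: dict) -> None:
    missing = [k for k in _REQUIRED_SUMMARY_KEYS if k not in summary]
    if missing:
        raise ValueError(f"summary missing keys: {missing}")
    if summary["schema_version"] != SUMMARY_SCHEMA_VERSION:
        raise ValueError("unknown summary schema version")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and return the summary dict (also written to
    ``outdir/summary.json`` plus per-stage TSVs when ``outdir`` is set)."""
    data = simulate_dataset(cfg.sim, stage_seed(cfg.seed, "simulate"))
    atl = _run_atlas(data, cfg)
    diff_table = _run_differential(atl, cfg)
    enrich = _run_enrichment(data, atl, diff_table, cfg)
    links = _run_linking(data, atl, diff_table, cfg)
    integ = _run_integration(data, atl, diff_table, links, cfg)

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": cfg.seed,
        "atlas": atl.class_counts(),
        "differential": diff_mod.summarize_directions(diff_table),
        "enrichment": enrich,
        "linking": {"summary": links["summary"],
                    "n_gwas_hit_diff_enhancers": links["n_gwas_hit_diff_enhancers"],
                    "n_independent_loci": links["n_independent_loci"]},
        "integration": {
            "expression": diff_mod.summarize_directions(integ["expression"], kind="expression"),
            "concordance": integ["concordance"].summary,
            "dml": integ["dml"],
            "fc_by_accessibility": integ["fc_by_accessibility"],
            "overlap_significance": integ["overlap_significance"],
        },
    }
    summary = _jsonable(summary)
    validate_summary(summary)

    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        diff_table.to_csv(out / "differential_peaks.tsv", sep="\t")
        integ["expression"].to_csv(out / "differential_genes.tsv", sep="\t")
        integ["concordance"].table.to_csv(out / "concordance.tsv", sep="\t")
        links["promoter_links"].to_csv(out / "promoter_links.tsv", sep="\t", index=False)
        links["enhancer_links"].to_csv(out / "enhancer_links.tsv", sep="\t", index=False)
    return summary
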