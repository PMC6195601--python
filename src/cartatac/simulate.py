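"""Synthetic data emulating the paired-compartment cartilage study design.

Every input the pipeline consumes can be generated here with the statistical
structure the analysis assumes: a small multi-chromosome genome with masked
gaps; non-overlapping peaks; negative-binomial peak counts for 8 patients x 2
compartments (oLT intact / iMT damaged) with planted compartment effects,
patient effects, per-sample sequencing depth and a per-sample DHS-score
quality covariate acting on the counts; promoter/enhancer catalogs with
enhancer clusters carrying per-cell-type densities (one designated stem-cell
-like type boosted over planted differential enhancers); foreground/background
position sets (GWAS-SNP-like and methylation-probe-like) with configurable
enrichment in differential peaks; enhancer-gene link evidence tables; and gene
expression counts coupled to the planted accessibility effects.

Alongside each dataset a truth table records what was planted; recovery tests
read truth only from there.  All generators are pure functions of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .atlas import AnnotationCatalog
from .intervals import GenomeModel, PositionSet, as_intervals, interval_ids, sort_intervals


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the emulated study: 8 patients with one intact (oLT) and
    one damaged (iMT) sample each; NB counts with Var = mu + alpha*mu^2 at
    alpha = 0.1; patient effects Normal(0, 0.3^2) on the log scale; DHS
    quality scores Uniform(2, 4); ~10% of peaks carrying a planted
    compartment effect; foreground positions enriched 5-fold in differential
    peaks; 92% methylation-direction concordance.
    """

    n_patients: int = 8
    n_peaks: int = 2000
    # genome
    n_chroms: int = 4
    chrom_size: int = 10_000_000
    gap_fraction: float = 0.05
    gap_size: int = 50_000
    include_sex_chrom: bool = False
    # counts
    mean_low: float = 30.0
    mean_high: float = 300.0
    dispersion: float = 0.1
    patient_sd: float = 0.3
    depth_sd: float = 0.2
    dhs_score_range: tuple = (2.0, 4.0)
    dhs_gamma: float = 0.5
    dhs_gamma_sd: float = 0.5    # relative spread of per-peak covariate sensitivity
    effect_fraction: float = 0.1
    effect_log2fc_range: tuple = (0.5, 2.0)
    effect_positive_prob: float = 0.35
    # peak geometry
    peak_width_range: tuple = (300, 1500)
    # catalog
    promoter_prop: float = 0.17
    enhancer_prop: float = 0.71
    dual_fraction: float = 0.016
    n_celltypes: int = 8
    msc_celltype: str = "MSC"
    cluster_prob: float = 0.6
    specific_prob: float = 0.3
    msc_target_prob: float = 0.8
    specific_boost: float = 4.0
    # position sets
    n_foreground: int = 2000
    n_background: int = 10000
    fore_multiplier: float = 5.0
    dml_concordance: float = 0.92
    delta_beta_range: tuple = (0.15, 0.25)
    locus_size_range: tuple = (1, 5)
    # links
    link_prob: float = 0.47
    arity_probs: tuple = (0.425, 0.223, 0.235, 0.117)   # 1, 2, 3, 4 genes
    eqtl_prob: float = 0.5
    linkage_prob: float = 0.35
    eqtl_decoy_prob: float = 0.15
    # expression
    kappa: float = 0.8
    expr_noise_sd: float = 0.25
    n_extra_genes: int = 300
    gene_dispersion: float = 0.1

    def __post_init__(self):
        for name in ("gap_fraction", "effect_fraction", "promoter_prop", "enhancer_prop",
                     "dual_fraction", "cluster_prob", "specific_prob", "msc_target_prob",
                     "link_prob", "eqtl_prob", "linkage_prob", "eqtl_decoy_prob",
                     "dml_concordance"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.dispersion < 0 or self.gene_dispersion < 0:
            raise ValueError("dispersions must be >= 0")


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_genome(config: SimConfig, seed) -> GenomeModel:
    """Genome with evenly slotted, jittered gaps realizing the gap fraction."""
    rng = _rng(seed)
    names = [f"chr{i+1}" for i in range(config.n_chroms)]
    if config.include_sex_chrom:
        names.append("chrX")
    chroms = tuple((c, config.chrom_size) for c in names)
    gaps = []
    if config.gap_fraction > 0:
        per_chrom_gap = config.gap_fraction * config.chrom_size
        n_gaps = max(1, int(round(per_chrom_gap / config.gap_size)))
        gap_len = int(round(per_chrom_gap / n_gaps))
        slot = config.chrom_size // n_gaps
        for c in names:
            for k in range(n_gaps):
                jitter = int(rng.integers(0, max(slot - gap_len, 1)))
                start = k * slot + jitter
                gaps.append((c, start, start + gap_len))
    return GenomeModel(chromosomes=chroms, gaps=as_intervals(gaps))


def gen_peaks(genome: GenomeModel, config: SimConfig, seed) -> pd.DataFrame:
    """Non-overlapping peaks placed into the unmasked genome, widths uniform
    over the configured range, allocated to segments by length."""
    rng = _rng(seed)
    segs = genome.unmasked_segments()
    seg_len = (segs["end"] - segs["start"]).values
    alloc = rng.multinomial(config.n_peaks, seg_len / seg_len.sum())
    lo, hi = config.peak_width_range
    rows = []
    for (seg, n) in zip(segs.itertuples(index=False), alloc):
        n = int(n)
        if n == 0:
            continue
        widths = rng.integers(lo, hi + 1, size=n)
        free = (seg.end - seg.start) - int(widths.sum())
        while free < n:          # overfull segment: shed peaks
            n -= 1
            widths = widths[:-1]
            free = (seg.end - seg.start) - int(widths.sum())
        if n == 0:
            continue
        cuts = np.sort(rng.integers(0, free + 1, size=n))
        starts = seg.start + cuts + np.concatenate([[0], np.cumsum(widths[:-1])])
        for s, w in zip(starts, widths):
            rows.append((seg.chrom, int(s), int(s + w)))
    peaks = sort_intervals(as_intervals(rows))
    peaks["id"] = interval_ids(peaks)
    return peaks


def gen_meta(config: SimConfig, seed) -> pd.DataFrame:
    rng = _rng(seed)
    lo, hi = config.dhs_score_range
    rows = []
    for i in range(config.n_patients):
        patient = f"P{i+1:02d}"
        for comp in ("oLT", "iMT"):
            rows.append({"sample": f"{patient}_{comp}", "patient": patient,
                         "compartment": comp,
                         "dhs_score": float(rng.uniform(lo, hi))})
    return pd.DataFrame(rows)


def _nb_draw(rng, mu, alpha):
    if alpha <= 0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu))


def gen_counts(peaks: pd.DataFrame, meta: pd.DataFrame, config: SimConfig, seed):
    """NB peak-by-sample counts with planted compartment effects.

    log-mean = baseline + patient effect + compartment effect (planted peaks
    only) + gamma_p * centered log DHS score + log depth.  The library-quality
    sensitivity gamma_p varies across peaks (mean ``dhs_gamma``, relative sd
    ``dhs_gamma_sd``): a peak-independent sensitivity would be a pure depth
    shift that size-factor normalization absorbs entirely.  Returns the count
    frame (index = peak id) and the truth table with the planted log2 fold
    change per peak.
    """
    rng = _rng(seed)
    n = len(peaks)
    baseline = rng.uniform(np.log(config.mean_low), np.log(config.mean_high), size=n)
    n_eff = int(round(config.effect_fraction * n))
    planted = np.zeros(n)
    idx = rng.choice(n, size=n_eff, replace=False)
    lo, hi = config.effect_log2fc_range
    mag = rng.uniform(lo, hi, size=n_eff)
    sign = np.where(rng.random(n_eff) < config.effect_positive_prob, 1.0, -1.0)
    planted[idx] = mag * sign

    patients = pd.unique(meta["patient"])
    pat_eff = dict(zip(patients, rng.normal(0, config.patient_sd, size=len(patients))))
    depth = rng.lognormal(0, config.depth_sd, size=len(meta))
    logdhs = np.log(meta["dhs_score"].values)
    logdhs = logdhs - logdhs.mean()
    gamma = config.dhs_gamma * (1.0 + config.dhs_gamma_sd * rng.standard_normal(n))

    cols = {}
    for s, row in enumerate(meta.itertuples(index=False)):
        eta = baseline + pat_eff[row.patient] + np.log(depth[s]) \
            + gamma * logdhs[s]
        if row.compartment == "iMT":
            eta = eta + planted * np.log(2)
        cols[row.sample] = _nb_draw(rng, np.exp(eta), config.dispersion)
    counts = pd.DataFrame(cols, index=peaks["id"].values)
    truth = pd.DataFrame({"peak": peaks["id"].values, "planted_log2fc": planted,
                          "is_differential": planted != 0}).set_index("peak")
    return counts, truth


def gen_catalog(peaks: pd.DataFrame, truth: pd.DataFrame, config: SimConfig, seed):
    """Regulatory catalog covering the peaks plus enhancer clusters.

    Peak classes follow the configured promoter/enhancer proportions; a small
    fraction of promoter peaks also receives a proximal-enhancer element (the
    dual-annotation case).  Clusters sit over enhancer peaks; clusters over
    planted differential enhancers are made specific to the designated
    stem-cell-like type.  Returns (catalog, true class per peak id).
    """
    rng = _rng(seed)
    n = len(peaks)
    u = rng.random(n)
    cls = np.where(u < config.promoter_prop, "promoter",
                   np.where(u < config.promoter_prop + config.enhancer_prop,
                            "enhancer", "other"))
    elements = []
    centers = ((peaks["start"] + peaks["end"]) // 2).values
    chroms = peaks["chrom"].values
    dual_prob = min(config.dual_fraction / max(config.promoter_prop, 1e-9), 1.0)
    for i in range(n):
        c, mid = chroms[i], int(centers[i])
        if cls[i] == "promoter":
            elements.append((c, mid - 100, mid + 100, "promoter"))
            if rng.random() < dual_prob:
                elements.append((c, mid + 50, mid + 250, "proximal_enhancer"))
        elif cls[i] == "enhancer":
            lab = "proximal_enhancer" if rng.random() < 0.5 else "distal_enhancer"
            elements.append((c, mid - 100, mid + 100, lab))
    el = pd.DataFrame(elements, columns=["chrom", "start", "end", "label"])

    types = [config.msc_celltype] + [f"CT{k+1:02d}" for k in range(config.n_celltypes - 1)]
    is_diff = truth["is_differential"].reindex(peaks["id"]).values
    clusters = []
    for i in range(n):
        if cls[i] != "enhancer" or rng.random() >= config.cluster_prob:
            continue
        dens = rng.lognormal(0, 0.5, size=len(types))
        if rng.random() < config.specific_prob:
            if is_diff[i] and rng.random() < config.msc_target_prob:
                k = 0
            else:
                k = int(rng.integers(1, len(types)))
            others = np.delete(dens, k)
            dens[k] = config.specific_boost * others.mean()
        c, mid = chroms[i], int(centers[i])
        clusters.append((c, mid - 150, mid + 150, *dens))
    cl = pd.DataFrame(clusters, columns=["chrom", "start", "end", *types])
    catalog = AnnotationCatalog(elements=el, clusters=cl)
    classes = pd.Series(cls, index=peaks["id"].values, name="true_class")
    return catalog, classes


def _unmasked_sampler(genome: GenomeModel, chroms):
    segs = genome.unmasked_segments(chroms)
    seg_len = (segs["end"] - segs["start"]).values
    cum = np.cumsum(seg_len)

    def draw(rng, size):
        u = rng.integers(0, cum[-1], size=size)
        j = np.searchsorted(cum, u, side="right")
        off = u - np.where(j > 0, cum[j - 1], 0)
        return segs["chrom"].values[j], segs["start"].values[j] + off

    return draw, int(cum[-1])


def gen_position_sets(peaks: pd.DataFrame, truth: pd.DataFrame, genome: GenomeModel,
                      config: SimConfig, seed, kind: str = "snp",
                      multiplier: float | None = None):
    """Foreground/background point loci.

    Background is uniform over the unmasked autosomes.  Foreground positions
    are placed so that their density inside the planted differential peaks is
    ``multiplier`` times the outside density.  SNP-like foregrounds carry a
    lead-SNP grouping; DML-like foregrounds carry a delta beta whose sign
    opposes the host peak's planted fold change with probability
    ``dml_concordance``.
    """
    rng = _rng(seed)
    m = config.fore_multiplier if multiplier is None else multiplier
    draw, total_bp = _unmasked_sampler(genome, genome.autosomes)
    diff = peaks[truth["is_differential"].reindex(peaks["id"]).values]
    diff = diff[diff["chrom"].isin(set(genome.autosomes))].reset_index(drop=True)
    dlen = (diff["end"] - diff["start"]).values
    dcum = np.cumsum(dlen) if len(diff) else np.array([0])
    b = dcum[-1] / total_bp if len(diff) else 0.0
    # mixture weight chosen so P(foreground in differential peaks) = m*b,
    # making the permutation odds ratio converge to m as counts grow
    q = min(b * (m - 1) / (1 - b), 1.0) if len(diff) and m != 1 else 0.0

    planted_fc = truth["planted_log2fc"].reindex(diff["id"]).values if len(diff) else np.array([])

    n_f = config.n_foreground
    inside = rng.random(n_f) < q
    chrom_arr = np.empty(n_f, dtype=object)
    pos_arr = np.zeros(n_f, dtype=np.int64)
    host_fc = np.zeros(n_f)
    k_in = int(inside.sum())
    if k_in:
        u = rng.integers(0, dcum[-1], size=k_in)
        j = np.searchsorted(dcum, u, side="right")
        off = u - np.where(j > 0, dcum[j - 1], 0)
        chrom_arr[inside] = diff["chrom"].values[j]
        pos_arr[inside] = diff["start"].values[j] + off
        host_fc[inside] = planted_fc[j]
    if k_in < n_f:
        c, p = draw(rng, n_f - k_in)
        chrom_arr[~inside] = c
        pos_arr[~inside] = p
        # positions drawn outside may still land in a differential peak; their
        # delta-beta sign then follows the host like any other covered probe
        if len(diff):
            for t, (cc, pp) in enumerate(zip(c, p)):
                sub = diff[diff["chrom"] == cc]
                hit = (sub["start"].values <= pp) & (pp < sub["end"].values)
                if hit.any():
                    host_fc[np.flatnonzero(~inside)[t]] = planted_fc[sub.index.values[hit][0]]

    fore = pd.DataFrame({"chrom": chrom_arr, "pos": pos_arr})
    if kind == "snp":
        sizes = []
        lo, hi = config.locus_size_range
        while sum(sizes) < n_f:
            sizes.append(int(rng.integers(lo, hi + 1)))
        leads = np.repeat([f"lead{k+1:04d}" for k in range(len(sizes))], sizes)[:n_f]
        order = np.lexsort((pos_arr, chrom_arr.astype(str)))
        fore = fore.iloc[order].reset_index(drop=True)
        fore["lead_snp"] = leads
        fore["snp"] = [f"snp{k+1:05d}" for k in range(n_f)]
    elif kind == "dml":
        lo, hi = config.delta_beta_range
        mag = rng.uniform(lo, hi, size=n_f)
        opposite = rng.random(n_f) < config.dml_concordance
        sign = np.where(host_fc != 0,
                        np.where(opposite, -np.sign(host_fc), np.sign(host_fc)),
                        np.where(rng.random(n_f) < 0.5, 1.0, -1.0))
        fore["delta_beta"] = sign * mag
        fore["probe"] = [f"cg{k+1:06d}" for k in range(n_f)]
    else:
        raise ValueError("kind must be 'snp' or 'dml'")

    c, p = draw(rng, config.n_background)
    back = pd.DataFrame({"chrom": c, "pos": p}).drop_duplicates(["chrom", "pos"])
    back = back.reset_index(drop=True)
    return (PositionSet(fore, role="foreground", trait=kind),
            PositionSet(back, role="background", trait=kind))


def gen_links(peaks: pd.DataFrame, classes: pd.Series, config: SimConfig, seed):
    """TSS, eQTL and precomputed-linkage evidence tables.

    Each promoter peak hosts the TSS of one (occasionally two) genes.
    Enhancer peaks are linked with probability ``link_prob`` to 1-4 genes via
    eQTL positions (p below the cutoff), linkage intervals, or both; decoy
    eQTL rows above the cutoff are interspersed.  Returns (tss_table,
    eqtl_table, linkage_table, truth frame of intended peak-gene pairs).
    """
    rng = _rng(seed)
    peaks = peaks.reset_index(drop=True)
    cls = classes.reindex(peaks["id"]).values
    gene_counter = [0]

    def new_gene():
        gene_counter[0] += 1
        return f"G{gene_counter[0]:05d}"

    tss_rows, eqtl_rows, link_rows, truth_rows = [], [], [], []
    gene_pool = []
    for i in np.flatnonzero(cls == "promoter"):
        c = peaks["chrom"].values[i]
        s, e = int(peaks["start"].values[i]), int(peaks["end"].values[i])
        n_genes = 2 if rng.random() < 0.1 else 1
        for _ in range(n_genes):
            g = new_gene()
            gene_pool.append(g)
            pos = int(rng.integers(s, e))
            tss_rows.append({"gene": g, "transcript": f"{g}.1", "chrom": c, "pos": pos})
            truth_rows.append({"peak": peaks["id"].values[i], "gene": g, "source": "tss"})

    arity_vals = np.array([1, 2, 3, 4])
    for i in np.flatnonzero(cls == "enhancer"):
        pid = peaks["id"].values[i]
        c = peaks["chrom"].values[i]
        s, e = int(peaks["start"].values[i]), int(peaks["end"].values[i])
        if rng.random() < config.eqtl_decoy_prob:
            g = gene_pool[int(rng.integers(len(gene_pool)))] if gene_pool else new_gene()
            eqtl_rows.append({"chrom": c, "pos": int(rng.integers(s, e)), "gene": g,
                              "p": float(rng.uniform(1e-5, 1e-2)), "tissue": "cartilage"})
        if rng.random() >= config.link_prob:
            continue
        k = int(rng.choice(arity_vals, p=np.array(config.arity_probs) /
                           sum(config.arity_probs)))
        genes = set()
        while len(genes) < k:
            if gene_pool and rng.random() < 0.5:
                genes.add(gene_pool[int(rng.integers(len(gene_pool)))])
            else:
                g = new_gene()
                gene_pool.append(g)
                genes.add(g)
        for g in sorted(genes):
            u = rng.random()
            if u < config.eqtl_prob:
                via_eqtl, via_link = True, False
            elif u < config.eqtl_prob + config.linkage_prob:
                via_eqtl, via_link = False, True
            else:
                via_eqtl = via_link = True
            if via_eqtl:
                eqtl_rows.append({"chrom": c, "pos": int(rng.integers(s, e)), "gene": g,
                                  "p": float(10 ** rng.uniform(-12, -6)),
                                  "tissue": "cartilage"})
            if via_link:
                link_rows.append({"chrom": c, "start": max(s - 200, 0), "end": e + 200,
                                  "gene": g, "score": float(rng.uniform(0.5, 1.0))})
            truth_rows.append({"peak": pid, "gene": g, "source": "enhancer"})

    return (pd.DataFrame(tss_rows), pd.DataFrame(eqtl_rows), pd.DataFrame(link_rows),
            pd.DataFrame(truth_rows))


def gen_expression(link_truth: pd.DataFrame, peak_truth: pd.DataFrame,
                   meta: pd.DataFrame, config: SimConfig, seed):
    """Gene counts whose planted log2 fold change couples to the mean planted
    accessibility change of the gene's linked peaks (strength kappa)."""
    rng = _rng(seed)
    genes = sorted(set(link_truth["gene"])) if len(link_truth) else []
    genes = genes + [f"X{k+1:05d}" for k in range(config.n_extra_genes)]
    coupled = np.zeros(len(genes))
    if len(link_truth):
        fc_by_gene = link_truth.merge(
            peak_truth["planted_log2fc"], left_on="peak", right_index=True,
            how="left").groupby("gene")["planted_log2fc"].mean()
        coupled = fc_by_gene.reindex(genes).fillna(0.0).values
    gene_fc = config.kappa * coupled + rng.normal(0, config.expr_noise_sd, size=len(genes))

    baseline = rng.uniform(np.log(config.mean_low), np.log(config.mean_high), size=len(genes))
    patients = pd.unique(meta["patient"])
    pat_eff = dict(zip(patients, rng.normal(0, config.patient_sd, size=len(patients))))
    depth = rng.lognormal(0, config.depth_sd, size=len(meta))
    cols = {}
    for s, row in enumerate(meta.itertuples(index=False)):
        eta = baseline + pat_eff[row.patient] + np.log(depth[s])
        if row.compartment == "iMT":
            eta = eta + gene_fc * np.log(2)
        cols[row.sample] = _nb_draw(rng, np.exp(eta), config.gene_dispersion)
    counts = pd.DataFrame(cols, index=genes)
    truth = pd.DataFrame({"gene": genes, "planted_log2fc": gene_fc,
                          "coupled_access_log2fc": coupled}).set_index("gene")
    return counts, truth


@dataclass
class SimDataset:
    """Everything one end-to-end run consumes, plus the planted truth."""

    config: SimConfig
    genome: GenomeModel
    peaks: pd.DataFrame
    meta: pd.DataFrame
    counts: pd.DataFrame
    peak_truth: pd.DataFrame
    catalog: AnnotationCatalog
    true_classes: pd.Series
    snp_fore: PositionSet
    snp_back: PositionSet
    dml_fore: PositionSet
    dml_back: PositionSet
    ctl_fore: PositionSet
    ctl_back: PositionSet
    tss_table: pd.DataFrame
    eqtl_table: pd.DataFrame
    linkage_table: pd.DataFrame
    link_truth: pd.DataFrame
    gene_counts: pd.DataFrame
    gene_truth: pd.DataFrame


def simulate_dataset(config: SimConfig, seed: int) -> SimDataset:
    """Generate one complete synthetic study from a single master seed."""
    ss = np.random.SeedSequence(seed)
    keys = ["genome", "peaks", "meta", "counts", "catalog", "snp", "dml", "ctl",
            "links", "expression"]
    rngs = dict(zip(keys, (np.random.default_rng(s) for s in ss.spawn(len(keys)))))
    genome = gen_genome(config, rngs["genome"])
    peaks = gen_peaks(genome, config, rngs["peaks"])
    meta = gen_meta(config, rngs["meta"])
    counts, peak_truth = gen_counts(peaks, meta, config, rngs["counts"])
    catalog, classes = gen_catalog(peaks, peak_truth, config, rngs["catalog"])
    snp_f, snp_b = gen_position_sets(peaks, peak_truth, genome, config, rngs["snp"], kind="snp")
    dml_f, dml_b = gen_position_sets(peaks, peak_truth, genome, config, rngs["dml"], kind="dml")
    ctl_f, ctl_b = gen_position_sets(peaks, peak_truth, genome, config, rngs["ctl"],
                                     kind="snp", multiplier=1.0)
    ctl_f.trait = ctl_b.trait = "control"
    tss, eqtl, linkage, link_truth = gen_links(peaks, classes, config, rngs["links"])
    gene_counts, gene_truth = gen_expression(link_truth, peak_truth, meta, config,
                                             rngs["expression"])
    return SimDataset(config=config, genome=genome, peaks=peaks, meta=meta,
                      counts=counts, peak_truth=peak_truth, catalog=catalog,
                      true_classes=classes, snp_fore=snp_f, snp_back=snp_b,
                      dml_fore=dml_f, dml_back=dml_b, ctl_fore=ctl_f, ctl_back=ctl_b,
                      tss_table=tss, eqtl_table=eqtl, linkage_table=linkage,
                      link_truth=link_truth, gene_counts=gene_counts,
                      gene_truth=gene_truth)


def write_dataset(data: SimDataset, outdir) -> None:
    """Write every pipeline input (and the truth tables) as BED/TSV files."""
    from pathlib import Path

    from . import io as io_mod

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io_mod.write_genome(data.genome, out / "genome.tsv", out / "gaps.bed")
    io_mod.write_bed(data.peaks, out / "peaks.bed")
    io_mod.write_counts(data.counts, out / "peak_counts.tsv")
    io_mod.write_table(data.meta, out / "samples.tsv")
    io_mod.write_table(data.catalog.elements, out / "catalog_elements.tsv")
    io_mod.write_table(data.catalog.clusters, out / "catalog_clusters.tsv")
    for name in ("snp_fore", "snp_back", "dml_fore", "dml_back", "ctl_fore", "ctl_back"):
        io_mod.write_table(getattr(data, name).positions, out / f"{name}.tsv")
    io_mod.write_table(data.tss_table, out / "tss.tsv")
    io_mod.write_table(data.eqtl_table, out / "eqtl.tsv")
    io_mod.write_table(data.linkage_table, out / "linkage.tsv")
    io_mod.write_counts(data.gene_counts, out / "gene_counts.tsv")
    io_mod.write_table(data.peak_truth.reset_index(), out / "truth_peaks.tsv")
    io_mod.write_table(data.gene_truth.reset_index(), out / "truth_genes.tsv")
    io_mod.write_table(data.link_truth, out / "truth_links.tsv")


def null_config(config: SimConfig | None = None) -> SimConfig:
    """A copy of the config with every planted effect switched off."""
    base = config or SimConfig()
    return replace(base, effect_fraction=0.0, fore_multiplier=1.0, kappa=0.0)
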