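# cartatac

Chromatin-accessibility integration analysis for paired intact/damaged
osteoarthritic (OA) knee cartilage.

In the paired-compartment OA design, the outer lateral tibial cartilage
(oLT, macroscopically intact) is the within-patient control for the inner
medial tibial cartilage (iMT, damaged), giving 8 patients × 2 ATAC-seq
libraries. `cartatac` turns that design into a reusable pipeline for anyone
analysing regulatory change in paired clinical tissue:

* **Peak atlas** — union-merge of pooled-compartment peak calls
  (`merge -d 300` semantics), relative-log-expression (median-of-ratios)
  normalization, the robust-peak rule (≥ 2 CPM in ≥ 6 samples of either
  compartment), promoter-preferential annotation against a DHS catalog, and
  the DHS enrichment QC score (reads in DHS over reads in size-matched
  random regions).
* **Differential accessibility** — per-peak negative-binomial GLMs,
  log μ = β₀ + β·iMT + γ·DHS-score with offset log(effective library size),
  Var = μ + αμ² with moment-estimated, median-shrunk dispersion; Wald test,
  Benjamini–Hochberg FDR, direction classes at FDR ≤ 0.05.
* **Permutation enrichment** — for trait-associated positions (GWAS SNPs,
  differentially methylated loci):
  OR = (obs_fore/obs_back) / (shuf_fore/shuf_back) over 100 rounds of
  shuffling the peaks into the unmasked autosomal genome, with FDR-tier
  curves, baseline bands, and Fisher-exact enrichment of cell-type-specific
  enhancer clusters (≥ 2× cross-cell-type mean density).
* **Enhancer→gene linking** — promoter peaks via contained TSS; enhancer
  peaks via eQTL overlap (p < 1e-5, any tissue) or precomputed
  enhancer–promoter linkage; arity summaries and independent-locus counts.
* **Cross-omics integration** — expression DE with the same NB machinery,
  sign-concordant gene classification (DE gene + same-direction linked
  differential peak), methylation-direction concordance (hypomethylation
  with increased accessibility and vice versa), Welch and Fisher support
  statistics.
* **Synthetic cohorts** — a first-class generator producing every input with
  planted effects and truth tables, so the whole stack is testable offline.

## Worked example

Run the bundled demo (1,500 synthetic peaks, 8 patients × 2 compartments):

```sh
cartatac run --config configs/demo.json --seed 7 --out demo_out
```

or in Python:

```python
import json
import cartatac as ct
from cartatac.pipeline import RunConfig, run_pipeline

cfg = RunConfig(sim=ct.SimConfig(n_peaks=1500, n_foreground=1500,
                                 n_background=6000, n_extra_genes=150),
                seed=7, n_perm=50, tiers=(0.01, 0.05, 0.2, 1.0))
summary = run_pipeline(cfg)
print(summary["atlas"])
print(summary["differential"])
print(summary["integration"]["dml"])
```

prints (exactly, for seed 7):

```
{'n_robust': 1500, 'n_promoter': 252, 'pct_promoter': 16.8, 'n_enhancer': 1049,
 'pct_enhancer': 69.9, 'n_other': 199, 'pct_other': 13.3, 'n_dual': 23, 'pct_dual': 1.5}
{'n_significant': 132, 'n_more_accessible': 49, 'n_less_accessible': 83}
{'n_concordant': 13, 'n_total': 14, 'fraction': 0.9285714285714286}
```

Reading this: all 1,500 peaks pass the robust filter at this depth; 16.8% /
69.9% are annotated promoter / enhancer (the generator plants 17% / 71%);
132 peaks are differentially accessible at FDR ≤ 0.05, more of them losing
than gaining accessibility in the damaged compartment (the planted
imbalance); and 13 of the 14 differential peaks hit by a methylation probe
change in the direction opposite to methylation — recovering the ~92%
concordance rate the generator plants. The SNP enrichment tier curve in
`summary["enrichment"]["tiers"]["snp"]` rises toward small FDR cutoffs
(or_mean 1.41 over all peaks, ~6 at FDR ≤ 0.01) while the control trait
stays flat with intervals covering 1, and the planted stem-cell-like
cell type ranks first in `summary["enrichment"]["celltype"]`
(OR 9.6, p = 5e-4 here). Stage tables (differential peaks and genes, link
tables, per-gene concordance classes) and a versioned `summary.json` land in
`demo_out/`.

Each stage is also a subcommand on files (`simulate`, `atlas`, `diff`,
`enrich`, `link`, `integrate`) — see `cartatac --help`.

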