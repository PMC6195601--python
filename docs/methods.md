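# Methods

`cartatac` reimplements, as a tested library, the chromatin-accessibility
integration analysis used for paired osteoarthritic knee-cartilage
compartments: the intact outer lateral tibial region (oLT) serves as a
within-patient control for the damaged inner medial tibial region (iMT).
Every stage consumes plain-text inputs (BED intervals, TSV count matrices and
evidence tables), and a synthetic-data module generates all of them with the
statistical structure the analysis assumes, so the full stack is exercised
end-to-end without any external download.

## Peak atlas

Peaks called separately on the two pooled compartments are union-merged with
a 300 bp join distance (`merge_intervals`, `bedtools merge -d` semantics:
book-ended or up-to-300-bp-separated intervals collapse). Counts per merged
region and sample are inputs. Normalization is relative log expression
(median of ratios): the per-region reference is the geometric mean across
samples over regions positive everywhere; a sample's size factor is the
median ratio to that reference, rescaled to geometric mean 1. The effective
library size is the size factor times the geometric-mean raw library size —
the median-of-ratios factor already carries sequencing depth, so multiplying
the factor onto each sample's own total would count depth twice (this is the
same effective library size the edgeR RLE path produces). CPM is counts per
million on that effective size.

A region is **robust** when it reaches ≥ 2 CPM in at least 6 of 8 samples of
either compartment; only robust regions are analysed further. Size factors
are computed once on the raw merged regions and not recomputed after
filtering. Annotation against a DHS catalog is promoter-preferential: any
promoter-element overlap (≥ 1 shared bp; no minimum-fraction rule) makes the
peak a promoter even when enhancer elements also intersect it; otherwise any
enhancer-element overlap makes it an enhancer; otherwise it is "other". The
count of dual promoter+proximal-enhancer peaks is reported alongside.

The DHS enrichment score — the library-quality covariate — is the ratio of
reads falling inside the DHS catalog to the mean reads inside random region
sets of the same interval sizes (default 10 draws). Reads enter as fragment
midpoints to avoid double-counting read pairs; this is configurable.
Reported percentages are rounded half-up to one decimal, matching the
precision used downstream.

## Differential accessibility

Each region gets a negative-binomial log-linear model
(Var = μ + αμ²) with design intercept + iMT indicator + mean-centered
per-sample covariates (the DHS score by default, entering linearly; a
log-transform flag exists), and offset log(effective library size).
The dispersion α is a per-region method-of-moments estimate — pooled
within-compartment moments on normalized counts — shrunk 50/50 toward the
across-region median and floored at 1e-4. This moment/shrinkage scheme is
deliberately simple and is the main numerical divergence from
empirical-Bayes packages; tests assert its calibration rather than equality
with any external tool. Inference is a Wald z-test on the compartment
coefficient; log2FC = coefficient / ln 2. Regions with all-zero counts are
flagged and excluded from testing; non-converged fits report p = 1, log2FC =
0 and a flag. Benjamini–Hochberg step-up adjustment gives the FDR; direction
labels (more/less accessible, or up/down for genes) require FDR ≤ 0.05 and a
nonzero fold change.

Patient identity is *not* in the default design, mirroring the analysis this
package follows (compartment + DHS covariate only); `paired=True` adds
patient fixed effects. A consequence worth knowing: with shared patient
effects and an estimated covariate, all regions share one design
realization, so the dataset-level type-I error of the unpaired test
fluctuates between datasets (conservative on average because the
within-group dispersion absorbs patient variance that cancels in the paired
contrast). Calibration tests therefore measure type-I error under the
model-matched null (no patient effects), which isolates the estimator's own
behaviour; the paired-design effect is exercised separately as a directional
property (omitting a real covariate inflates null rejections).

## Permutation enrichment

For a region set and foreground/background point loci (GWAS lead+proxy SNPs
against common variants; methylation probes against the array universe), the
observed ratio observed_fore/observed_back is divided, per permutation
round, by the same ratio for regions of identical sizes shuffled uniformly
into the unmasked (gap-excluded) autosomal genome:

    OR_r = (observed_fore / observed_back) / (shuffled_fore_r / shuffled_back_r)

with 100 rounds by default. A position covered by several regions counts
once. Any zero cell in a round triggers a +1 substitution on all four counts
of that round (logged; n_perm stays fixed). The point estimate is the
arithmetic mean over rounds. The 95% interval is mean ± 1.96·sd over the
per-round odds ratios: the round-to-round spread has the same magnitude as
the sampling noise of the observed ratio, so this interval attains ~95%
null coverage (verified by simulation); a standard-error-of-the-mean
interval would be ~10× too narrow and cover a null OR of 1 in only ~15% of
datasets. Percentile and SEM variants are available via the `ci` argument.
The baseline band replaces the region set by a shuffled copy and repeats the
whole test (default 20 draws, 5th–95th percentiles of the resulting means).
Shuffled regions are placed independently and may overlap one another
(`no_self_overlap` disables this); shuffling is genome-wide over autosomes
by default with a chromosome-matched option.

Tier curves repeat the test on peaks at FDR ≤ t for a ladder of cutoffs and
report each tier's promoter/enhancer composition. Cell-type-specific
enhancers are clusters whose activity density in one cell type is at least
twice the cross-cell-type mean; enrichment of each type's pooled set in the
differential peaks is a two-sided Fisher's exact test against an equal-size
random control drawn from the robust peaks (one seeded draw by default,
averaging available), with Haldane correction on zero cells and types ranked
by odds ratio.

## Linking and integration

Promoter peaks link to every gene with a transcript TSS inside the peak.
Enhancer peaks link to a gene when they overlap an eQTL of that gene with
p strictly below 1e-5 in any tissue, or fall inside a precomputed
enhancer–promoter linkage interval for that gene; evidence from both sources
is unioned per (peak, gene) with all tags kept. Arity summaries report peaks
linked to 1 / 2 / ≥3 distinct genes as percentages of linked peaks.
Independent GWAS loci are counted as distinct lead-SNP identifiers — a
deliberate simplification of LD-block construction, which would need
population genotypes.

Expression differential testing reuses the NB machinery without the DHS
covariate. A gene is **concordant** when it is differentially expressed
(FDR ≤ 0.05) and at least one linked differential promoter or enhancer peak
changes accessibility in the same direction; genes whose differential linked
peaks all oppose the expression direction are discordant. A gene with both
kinds of support is classed concordant (existence rule) and counted as a
conflict. Methylation concordance follows the opposite-sign rule: a
probe/peak pair is concordant when the methylation delta beta (iMT − oLT)
and the accessibility log2FC have opposite signs; exact zeros have no
direction and leave the denominator (logged). Supporting statistics: Welch
t-tests comparing expression fold changes of genes with more- vs
less-accessible regulators (genes in both groups excluded and counted), and
two-sided Fisher tests of DE-gene overlap with genes having differential
promoters/enhancers within the expression universe.

## Synthetic cohorts

The generator emulates the study design: 8 patients × 2 compartments.
Peak counts are NB with Var = μ + αμ², α = 0.1 (typical ATAC biological
dispersion); log-mean = baseline (log-uniform mean 30–300) + patient effect
(Normal(0, 0.3²), the patient-to-patient axis of variation) + planted
compartment effect (10% of peaks; |log2FC| uniform 0.5–2; 35% positive,
matching the observed more/less-accessible imbalance) + per-peak
library-quality term + log depth (lognormal, sd 0.2). DHS scores are
Uniform(2, 4), the reported range for good libraries. The quality covariate
multiplies centered log score by a per-peak sensitivity
Normal(γ, (0.5γ)²): a peak-independent sensitivity would be exactly a depth
shift that normalization absorbs, leaving the covariate nothing to do.

Foreground positions are placed so their density inside planted differential
peaks is `fore_multiplier` (default 5) times the outside density, with the
mixture weight solved so the permutation OR converges to the multiplier;
background positions are uniform over unmasked autosomes. SNP-like
foregrounds carry lead-SNP groupings (locus sizes 1–5); probe-like
foregrounds carry delta betas opposing the host peak's planted direction
with probability 0.92, the concordance rate the integration stage should
recover. The catalog covers peaks at 17%/71% promoter/enhancer proportions
with 1.6% dual annotations; enhancer clusters carry lognormal per-cell-type
densities, and clusters over planted differential enhancers are made
specific to a designated stem-cell-like type ("MSC"). Link tables produce a
1/2/3/4-gene arity mix (42.5/22.3/23.5/11.7%) via eQTL rows (p log-uniform
1e-12–1e-6, plus decoys above the cutoff) and linkage intervals. Gene
expression couples each gene's planted log2FC to κ (default 0.8) times the
mean planted accessibility change of its linked peaks plus Normal(0, 0.25²)
noise.

What the generator does **not** emulate: read-level artefacts (GC and
mappability bias, duplicates), LD structure beyond the lead-SNP labels,
correlated peaks (counts are independent across peaks given the design),
tissue heterogeneity, and genuine genomic sequence. Passing recovery tests
therefore demonstrates the estimators are correct and calibrated under the
assumed model, not that the model captures every property of real ATAC
libraries.

## Scales, seeds and numerical choices

All generators are pure functions of (config, seed); the pipeline derives
per-stage seeds from the master seed by hashing the stage name, so stages
can be rerun in isolation and two runs with one seed produce byte-identical
summary JSON. Calibration and recovery checks run at deliberately desk-sized
scales — 1000–2000 peaks on a 40 Mb four-chromosome genome, 100
permutations, 100 null repetitions — chosen to keep the whole suite fast
while leaving comfortable statistical margins; the bundled demo
configuration (1500 peaks) completes in well under a minute. The hot
shuffle/count loop flattens the genome to one axis and works on sorted
arrays; it is tested for exact agreement with the reference interval
routines. Ties and degenerate inputs: merge treats separation equal to the
gap as joinable; a position at an interval's half-open end does not overlap;
identical groups give t = 0, p = 1 in the Welch comparison; empty link
tables report zero percentages with a warning rather than NaN.
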