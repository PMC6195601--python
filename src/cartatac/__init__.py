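"""cartatac: chromatin-accessibility integration analysis for paired
intact/damaged osteoarthritic knee cartilage.

Builds a unified robust ATAC-seq peak atlas, annotates peaks against
regulatory catalogs, tests covariate-adjusted differential accessibility with
negative-binomial GLMs, measures permutation odds-ratio enrichment of
trait-associated positions, links enhancer peaks to putative target genes,
and classifies cross-omics sign concordance — with a synthetic-data module
emulating the paired oLT/iMT study design for end-to-end testing.
"""

from importlib import resources as _resources

import pandas as _pd

from .atlas import (AnnotationCatalog, PeakAtlas, annotate_peaks, build_atlas,
                    dhs_enrichment_score, link_summary_fractions, percentage,
                    rle_size_factors, robust_filter)
from .differential import bh_fdr, classify, differential_table, fit_nb_glm
from .enrichment import (EnrichmentResult, baseline_band, celltype_enrichment,
                         celltype_specific, permutation_or, tier_curves)
from .integration import (ConcordanceReport, concordant_genes, dml_concordance,
                          expression_de, fc_by_accessibility, overlap_significance)
from .intervals import (GenomeModel, PositionSet, merge_intervals, overlap,
                        shuffle_regions)
from .linking import (assign_promoters, distinct_loci, link_enhancers,
                      linkage_summary)
from .pipeline import RunConfig, run_pipeline
from .simulate import SimConfig, SimDataset, simulate_dataset

__version__ = "0.1.0"


def load_reference_table(name: str) -> _pd.DataFrame:
    """Bundled worked-example tables.

    ``gwas_enhancers``: published differentially accessible enhancers
    overlapping OA GWAS SNPs (proxy/lead ids, fold changes, FDR).
    ``dml_enhancers``: published differentially accessible enhancers
    overlapping OA differentially methylated loci (delta beta, fold change).
    """
    path = _resources.files("cartatac.data").joinpath(f"{name}.tsv")
    with _resources.as_file(path) as p:
        return _pd.read_csv(p, sep="\t")
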