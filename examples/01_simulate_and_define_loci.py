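"""Simulate a GWAS with a planted causal variant and define its loci.

Walks the first stage of the pipeline: an LD panel with AR(1) blocks, a
seeded case-control GWAS, variant QC filters, and merged significance loci
with candidate genes.
"""

import pandas as pd

from locus2gene.summaries import (
    assign_candidate_genes,
    define_loci,
    filter_variants,
    make_dataset,
)
from locus2gene.synthetic import make_gene_models, simulate_gwas, simulate_ld_panel

# A 200-variant chromosome slice: blocks of 20 variants with r = 0.9^distance
panel = simulate_ld_panel(200, 20, 0.9, maf_range=(0.1, 0.5), seed=1)
print(f"panel: {panel.n_variants} variants on chr{panel.chrom}, "
      f"{len(panel.blocks)} LD blocks")

# Plant one causal variant (index 100, beta = 0.5 on the liability scale)
gwas_df, truth = simulate_gwas(
    panel, 100, 0.5, n=10_000, trait_type="binary", case_fraction=0.5, seed=11
)
gwas = make_dataset(gwas_df, trait_type="binary", study_id="EX01",
                    trait="example disease")
print(f"planted causal variant: {truth.causal_variants[0]}")

# QC: MAF >= 1e-4 and the extended HLA region excluded by default
gwas = filter_variants(gwas)

# Loci: p < 1e-6 variants, +/-250 kb windows, overlapping windows merged
loci = define_loci(gwas)
for locus in loci:
    print(f"locus {locus.id}: lead {locus.lead_variant} "
          f"(p = {locus.lead_pvalue:.2e}), {len(locus.members)} member variants")

# Candidate genes: any gene footprint within 250 kb of a member variant
genes = make_gene_models(panel, ["GENE_A", "GENE_B", "GENE_C"], 100)
candidates = assign_candidate_genes(loci[0], genes)
with pd.option_context("display.width", 120):
    print(candidates.genes)
print(f"nearest gene to the lead: {candidates.nearest}")
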