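"""Variant-consequence classification and enhancer (ABC) overlap features.

Coding variants are missense or "high"-impact consequences; pathogenic
variants are high-impact, or coding variants flagged pathogenic,
destabilizing or conserved by upstream predictors (the flags are consumed,
never computed here). ABC features link candidate genes to enhancers
overlapping the lead or any eligible associated variant, with ABCmax marking
the gene(s) holding the top score at a variant.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .summaries import GwasDataset, Locus, CandidateSet, parse_variant_id

logger = logging.getLogger(__name__)

__all__ = [
    "CONSEQUENCE_VOCABULARY",
    "HIGH_IMPACT_CONSEQUENCES",
    "classify_consequence",
    "eligible_associated_variants",
    "abc_features",
    "annotate_gene_locus",
]

CONSEQUENCE_VOCABULARY = frozenset(
    {
        "missense_variant",
        "synonymous_variant",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "splice_region_variant",
        "frameshift_variant",
        "transcript_ablation",
        "inframe_insertion",
        "inframe_deletion",
        "intron_variant",
        "intergenic_variant",
        "upstream_gene_variant",
        "downstream_gene_variant",
        "5_prime_UTR_variant",
        "3_prime_UTR_variant",
        "non_coding_transcript_variant",
    }
)

#: consequences conventionally annotated with "high" impact (stop gain,
#: splice-site and frameshift variants among them); configurable.
HIGH_IMPACT_CONSEQUENCES = frozenset(
    {
        "stop_gained",
        "stop_lost",
        "start_lost",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "frameshift_variant",
        "transcript_ablation",
    }
)

IMPACT_LEVELS = ("HIGH", "MODERATE", "LOW", "MODIFIER")

ANNOTATION_FLAGS = [
    "lead_coding",
    "lead_pathogenic",
    "assoc_coding",
    "assoc_pathogenic",
    "abcmax_lead",
    "abcmax_assoc",
    "abc_any_lead",
    "abc_any_assoc",
]


def classify_consequence(
    consequence: str,
    impact: str,
    pathogenic_flag: bool = False,
    destabilizing_flag: bool = False,
    conserved_flag: bool = False,
) -> tuple[bool, bool]:
    """Return ``(is_coding, is_pathogenic)`` for one consequence record.

    Coding = missense or high impact. Pathogenic = high impact, or a coding
    variant predicted pathogenic, destabilizing, or in a conserved region.
    """
    if consequence not in CONSEQUENCE_VOCABULARY:
        raise ValueError(
            f"unknown consequence term {consequence!r}; expected one of "
            f"{sorted(CONSEQUENCE_VOCABULARY)}"
        )
    if impact not in IMPACT_LEVELS:
        raise ValueError(f"unknown impact level {impact!r}; expected one of {IMPACT_LEVELS}")
    is_coding = consequence == "missense_variant" or impact == "HIGH"
    is_pathogenic = impact == "HIGH" or (
        is_coding and bool(pathogenic_flag or destabilizing_flag or conserved_flag)
    )
    return is_coding, is_pathogenic


def eligible_associated_variants(
    locus: Locus,
    gwas: GwasDataset,
    p_assoc: float = 1e-6,
    magnitude_window: float = 5.0,
) -> set[str]:
    """Associated variants eligible for annotation at a locus.

    A variant qualifies with p below ``p_assoc`` and within
    ``magnitude_window`` orders of magnitude of the lead p-value
    (inclusively: p <= p_lead * 10**magnitude_window).
    """
    rec = gwas.records
    in_region = (
        (rec["CHROM"] == locus.chrom)
        & rec["POS"].between(locus.start, locus.end)
    )
    sub = rec[in_region]
    p_lead = locus.lead_pvalue
    ok = (sub["PVAL"] < p_assoc) & (sub["PVAL"] <= p_lead * 10.0**magnitude_window)
    return set(sub.loc[ok, "VARIANT_ID"])


def _overlapping_abc(abc: pd.DataFrame, chrom: str, pos: int) -> pd.DataFrame:
    """ABC rows whose 0-based half-open enhancer contains 1-based ``pos``."""
    pos0 = pos - 1
    return abc[
        (abc["CHROM"].astype(str) == chrom)
        & (abc["START"] <= pos0)
        & (pos0 < abc["END"])
    ]


def abc_features(
    locus: Locus,
    eligible_variants: set[str],
    abc_records: pd.DataFrame,
    candidate_genes: list[str],
) -> pd.DataFrame:
    """Per-gene ABC flags at the lead and at eligible associated variants.

    At each variant, overlapping enhancers yield (gene, score) pairs; the per
    gene score is the max across cell types and the ABCmax gene(s) are the
    argmax across genes (all tied genes flagged). ``abc_any`` marks any
    overlap of any score.
    """
    genes = list(candidate_genes)
    flags = pd.DataFrame(
        False,
        index=pd.Index(genes, name="GENE_ID"),
        columns=["abcmax_lead", "abcmax_assoc", "abc_any_lead", "abc_any_assoc"],
    )
    if abc_records is None or abc_records.empty or not genes:
        return flags.reset_index()

    def _visit(vid: str, is_lead: bool) -> None:
        chrom, pos, _, _ = parse_variant_id(vid)
        hits = _overlapping_abc(abc_records, chrom, pos)
        hits = hits[hits["GENE_ID"].isin(genes)]
        if hits.empty:
            return
        per_gene = hits.groupby("GENE_ID")["ABC_SCORE"].max()
        top = per_gene.max()
        for gene, score in per_gene.items():
            if is_lead:
                flags.loc[gene, "abc_any_lead"] = True
                if score == top:
                    flags.loc[gene, "abcmax_lead"] = True
            flags.loc[gene, "abc_any_assoc"] = True
            if score == top:
                flags.loc[gene, "abcmax_assoc"] = True

    # the lead is itself an eligible associated variant
    _visit(locus.lead_variant, is_lead=True)
    for vid in sorted(eligible_variants - {locus.lead_variant}):
        _visit(vid, is_lead=False)
    return flags.reset_index()


def annotate_gene_locus(
    locus: Locus,
    gwas: GwasDataset,
    consequences: pd.DataFrame,
    abc_records: pd.DataFrame,
    candidates: CandidateSet,
    p_assoc: float = 1e-6,
    magnitude_window: float = 5.0,
) -> pd.DataFrame:
    """Assemble the per-gene evidence flags for one locus.

    Coding/pathogenic flags are computed only over eligible associated
    variants (the ``lead_*`` pair over the lead variant specifically);
    consequence rows for non-candidate genes are ignored with a logged count.
    """
    genes = candidates.gene_ids
    eligible = eligible_associated_variants(locus, gwas, p_assoc, magnitude_window)
    eligible.add(locus.lead_variant)

    out = pd.DataFrame(
        {
            "GENE_ID": genes,
            "LOCUS_ID": locus.id,
            "lead_coding": False,
            "lead_pathogenic": False,
            "assoc_coding": False,
            "assoc_pathogenic": False,
        }
    ).set_index("GENE_ID")

    if consequences is not None and not consequences.empty:
        sub = consequences[consequences["VARIANT_ID"].isin(eligible)]
        foreign = (~sub["GENE_ID"].isin(genes)).sum()
        if foreign:
            logger.info(
                "ignored %d consequence row(s) for non-candidate genes at %s",
                foreign,
                locus.id,
            )
        sub = sub[sub["GENE_ID"].isin(genes)]
        for _, row in sub.iterrows():
            coding, patho = classify_consequence(
                row["CONSEQUENCE"],
                row["IMPACT"],
                bool(row.get("PATHOGENIC", 0)),
                bool(row.get("DESTABILIZING", 0)),
                bool(row.get("CONSERVED", 0)),
            )
            g = row["GENE_ID"]
            if coding:
                out.loc[g, "assoc_coding"] = True
            if patho:
                out.loc[g, "assoc_pathogenic"] = True
            if row["VARIANT_ID"] == locus.lead_variant:
                if coding:
                    out.loc[g, "lead_coding"] = True
                if patho:
                    out.loc[g, "lead_pathogenic"] = True

    abc = abc_features(locus, eligible, abc_records, genes).set_index("GENE_ID")
    out = out.join(abc)
    return out.reset_index()[["GENE_ID", "LOCUS_ID"] + ANNOTATION_FLAGS]
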