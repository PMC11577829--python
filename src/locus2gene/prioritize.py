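"""Five-tier causal-gene ranking and per-locus prioritization.

The rank table, top tier first:

* Very high — lead pathogenic variant; or colocalization (H4 PP > 0.8) with
  the gene's molQTL in more than ``coloc_multi`` datasets together with the
  maximum ABC score at the lead variant.
* High — lead coding variant; or an associated (p < 1e-6) pathogenic
  variant; or multi-dataset colocalization together with ABCmax at an
  associated variant; or colocalization in at least one dataset together
  with ABCmax at the lead variant.
* Moderate — colocalization in at least one dataset; or significant MR with
  a protein QTL (q < 0.05); or ABCmax at the lead variant; or an associated
  coding variant.
* Weak — nearest gene to the lead variant; or ABCmax at an associated
  variant; or an any-score ABC link at the lead variant.
* Very weak — significant MR with an eQTL; or an any-score ABC link at an
  associated variant.

Within a locus the top-tier genes win; if the nearest gene is among them it
alone is prioritized, otherwise all top-tier genes are prioritized equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import pandas as pd

from .summaries import CandidateSet

__all__ = ["Tier", "EvidenceProfile", "Rank", "build_profiles", "assign_rank",
           "prioritize_locus", "prioritize_study"]


class Tier(IntEnum):
    NONE = 0
    VERY_WEAK = 1
    WEAK = 2
    MODERATE = 3
    HIGH = 4
    VERY_HIGH = 5


@dataclass
class EvidenceProfile:
    """Per gene x locus boolean evidence bundle feeding the rank table."""

    gene: str
    locus_id: str
    gwas_id: str = ""
    lead_pathogenic: bool = False
    lead_coding: bool = False
    assoc_pathogenic: bool = False
    assoc_coding: bool = False
    n_coloc: int = 0
    mr_pqtl_sig: bool = False
    mr_eqtl_sig: bool = False
    abcmax_lead: bool = False
    abcmax_assoc: bool = False
    abc_any_lead: bool = False
    abc_any_assoc: bool = False
    is_nearest: bool = False
    distance_to_lead: int = 0


@dataclass
class Rank:
    tier: Tier
    satisfied_criteria: list[str] = field(default_factory=list)


# (criterion label, tier, predicate) in top-down evaluation order
_CRITERIA = [
    ("lead_pathogenic", Tier.VERY_HIGH, lambda p, m: p.lead_pathogenic),
    ("coloc_multi+abcmax_lead", Tier.VERY_HIGH, lambda p, m: p.n_coloc > m and p.abcmax_lead),
    ("lead_coding", Tier.HIGH, lambda p, m: p.lead_coding),
    ("assoc_pathogenic", Tier.HIGH, lambda p, m: p.assoc_pathogenic),
    ("coloc_multi+abcmax_assoc", Tier.HIGH, lambda p, m: p.n_coloc > m and p.abcmax_assoc),
    ("coloc+abcmax_lead", Tier.HIGH, lambda p, m: p.n_coloc >= 1 and p.abcmax_lead),
    ("coloc", Tier.MODERATE, lambda p, m: p.n_coloc >= 1),
    ("mr_pqtl", Tier.MODERATE, lambda p, m: p.mr_pqtl_sig),
    ("abcmax_lead", Tier.MODERATE, lambda p, m: p.abcmax_lead),
    ("assoc_coding", Tier.MODERATE, lambda p, m: p.assoc_coding),
    ("nearest", Tier.WEAK, lambda p, m: p.is_nearest),
    ("abcmax_assoc", Tier.WEAK, lambda p, m: p.abcmax_assoc),
    ("abc_any_lead", Tier.WEAK, lambda p, m: p.abc_any_lead),
    ("mr_eqtl", Tier.VERY_WEAK, lambda p, m: p.mr_eqtl_sig),
    ("abc_any_assoc", Tier.VERY_WEAK, lambda p, m: p.abc_any_assoc),
]

#: criteria that count as coding or colocalization support
_CODING_OR_COLOC = {
    "lead_pathogenic",
    "coloc_multi+abcmax_lead",
    "lead_coding",
    "assoc_pathogenic",
    "coloc_multi+abcmax_assoc",
    "coloc+abcmax_lead",
    "coloc",
    "assoc_coding",
}


def assign_rank(profile: EvidenceProfile, coloc_multi: int = 2) -> Rank:
    """Assign the five-tier rank; ``coloc_multi`` is the strict lower bound
    on colocalizing dataset count for the multi-dataset criteria (the
    default 2 reads "in > 2 dataset" literally, i.e. at least 3)."""
    satisfied = [label for label, _, pred in _CRITERIA if pred(profile, coloc_multi)]
    tier = max(
        (t for label, t, pred in _CRITERIA if pred(profile, coloc_multi)),
        default=Tier.NONE,
    )
    return Rank(tier=tier, satisfied_criteria=satisfied)


def build_profiles(
    candidates: CandidateSet,
    annotations: pd.DataFrame,
    mr_results: pd.DataFrame,
    coloc_results: pd.DataFrame,
    gwas_id: str = "",
    h4_threshold: float = 0.8,
    mr_q: float = 0.05,
) -> list[EvidenceProfile]:
    """Join annotation, MR and colocalization evidence into per-gene profiles.

    ``n_coloc`` counts distinct molQTL dataset ids with PP_H4 strictly above
    ``h4_threshold``; the MR significance flags split by molecule type. A
    gene absent from a table simply has that evidence false.
    """
    for name, table in (
        ("annotations", annotations),
        ("mr_results", mr_results),
        ("coloc_results", coloc_results),
    ):
        if table is None:
            raise ValueError(f"missing upstream table: {name}")
    locus = candidates.locus
    ann = annotations.set_index("GENE_ID") if not annotations.empty else None
    profiles = []
    for _, row in candidates.genes.iterrows():
        gene = row["GENE_ID"]
        p = EvidenceProfile(
            gene=gene,
            locus_id=locus.id,
            gwas_id=gwas_id,
            is_nearest=gene == candidates.nearest,
            distance_to_lead=int(row["DISTANCE_TO_LEAD"]),
        )
        if ann is not None and gene in ann.index:
            a = ann.loc[gene]
            for flag in (
                "lead_pathogenic",
                "lead_coding",
                "assoc_pathogenic",
                "assoc_coding",
                "abcmax_lead",
                "abcmax_assoc",
                "abc_any_lead",
                "abc_any_assoc",
            ):
                setattr(p, flag, bool(a[flag]))
        if not coloc_results.empty:
            cc = coloc_results[
                (coloc_results["GENE_ID"] == gene)
                & (coloc_results.get("LOCUS_ID", locus.id) == locus.id)
                & (coloc_results["PP_H4"] > h4_threshold)
            ]
            p.n_coloc = int(cc["DATASET_ID"].nunique())
        if not mr_results.empty:
            mm = mr_results[
                (mr_results["GENE_ID"] == gene)
                & (mr_results.get("LOCUS_ID", locus.id) == locus.id)
                & (mr_results["QVAL"] < mr_q)
            ]
            types = set(mm["MOLECULE_TYPE"])
            p.mr_pqtl_sig = "pQTL" in types
            p.mr_eqtl_sig = "eQTL" in types
        profiles.append(p)
    return profiles


def prioritize_locus(
    profiles: list[EvidenceProfile], coloc_multi: int = 2
) -> tuple[list[str], pd.DataFrame]:
    """Pick the prioritized gene(s) of a locus from its evidence profiles.

    The nearest gene wins outright when it sits in the top-tier set;
    otherwise every top-tier gene is prioritized equally. If no criterion
    fires for any gene, the nearest candidate is prioritized as a fallback
    so the output stays total.
    """
    if not profiles:
        raise ValueError("prioritize_locus requires at least one profile")
    ranks = {p.gene: assign_rank(p, coloc_multi) for p in profiles}
    top = max(r.tier for r in ranks.values())
    nearest = next((p.gene for p in profiles if p.is_nearest), None)
    if top == Tier.NONE:
        prioritized = [nearest] if nearest is not None else []
    else:
        top_genes = sorted(g for g, r in ranks.items() if r.tier == top)
        prioritized = [nearest] if nearest in top_genes else top_genes
    rows = []
    for p in sorted(profiles, key=lambda q: q.gene):
        r = ranks[p.gene]
        rows.append(
            {
                "GWAS_ID": p.gwas_id,
                "LOCUS_ID": p.locus_id,
                "GENE_ID": p.gene,
                "TIER": r.tier.name,
                "CRITERIA": ",".join(r.satisfied_criteria),
                "IS_PRIORITIZED": p.gene in prioritized,
                "IS_NEAREST": p.is_nearest,
                "DISTANCE_TO_LEAD": p.distance_to_lead,
                "N_COLOC": p.n_coloc,
                "CODING_OR_COLOC": bool(set(r.satisfied_criteria) & _CODING_OR_COLOC),
            }
        )
    return prioritized, pd.DataFrame(rows)


def prioritize_study(
    gwas_id: str,
    candidate_sets: list[CandidateSet],
    annotations_by_locus: dict[str, pd.DataFrame],
    mr_results: pd.DataFrame,
    coloc_results: pd.DataFrame,
    h4_threshold: float = 0.8,
    mr_q: float = 0.05,
    coloc_multi: int = 2,
) -> pd.DataFrame:
    """Prioritize every locus of a study; one row per candidate gene."""
    tables = []
    for cs in candidate_sets:
        if cs.genes.empty:
            continue
        profiles = build_profiles(
            cs,
            annotations_by_locus[cs.locus.id],
            mr_results,
            coloc_results,
            gwas_id=gwas_id,
            h4_threshold=h4_threshold,
            mr_q=mr_q,
        )
        _, table = prioritize_locus(profiles, coloc_multi)
        table.insert(2, "LEAD_VARIANT", cs.locus.lead_variant)
        table.insert(3, "LEAD_PVAL", cs.locus.lead_pvalue)
        tables.append(table)
    if not tables:
        return pd.DataFrame()
    return pd.concat(tables, ignore_index=True)
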