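"""End-to-end study driver: simulate a multi-locus synthetic study with
per-locus evidence plans and run the full prioritization pipeline over it
(filtering, locus definition, annotation, MR scan, MR-gated colocalization,
tier assignment).

Each planted locus lives on its own chromosome with its own LD panel; the
disease GWAS concatenates all loci, molQTL datasets carry one gene slice per
locus, and a truth table records every planted causal variant and gene so
recovery is checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotation as ann_mod
from . import coloc as coloc_mod
from . import mr as mr_mod
from . import prioritize as prio_mod
from . import summaries as sums
from .ld import MultiPanelLd
from .synthetic import (
    MolQtlDataset,
    simulate_annotation_layers,
    simulate_gwas,
    simulate_ld_panel,
    simulate_molqtl,
)

__all__ = ["PipelineConfig", "LocusPlan", "StudyScenario", "SyntheticStudy",
           "StudyResults", "simulate_study", "run_study"]


@dataclass
class PipelineConfig:
    """Thresholds of the prioritization pipeline (defaults follow the
    biobank-GWAS conventions the package is built around)."""

    maf_min: float = 1e-4
    hla_region: tuple[str, int, int] = sums.DEFAULT_HLA_REGION
    p_locus: float = 1e-6
    p_genomewide: float = 5e-8
    window_bp: int = 250_000
    p_assoc: float = 1e-6
    magnitude_window: float = 5.0
    p_instrument: float = 1e-4
    clump_r2: float = 0.01
    clump_kb: int = 10_000
    molqtl_maf_min: float = 0.01
    mr_q: float = 0.05
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    prior_sd_quantitative: float = 0.15
    prior_sd_binary: float = 0.2
    h4_threshold: float = 0.8
    coloc_multi: int = 2


@dataclass
class LocusPlan:
    """One planted locus: its causal gene and the evidence to plant.

    ``evidence`` maps annotation features (see synthetic.EVIDENCE_FEATURES)
    to gene ids; ``n_shared_molqtl`` molQTL datasets share the GWAS causal
    variant for the causal gene (driving MR + colocalization evidence).
    """

    name: str
    causal_gene: str
    evidence: dict[str, str] = field(default_factory=dict)
    n_shared_molqtl: int = 0
    gwas_beta: float = 0.5
    molqtl_beta: float = 0.4
    n_decoys: int = 3
    expected_tier: str | None = None


@dataclass
class StudyScenario:
    plans: list[LocusPlan]
    n_gwas: int = 10_000
    n_molqtl: int = 5_000
    n_variants: int = 120
    block_size: int = 12
    rho: float = 0.8
    maf_range: tuple[float, float] = (0.1, 0.5)
    trait_type: str = "binary"
    case_fraction: float = 0.5
    datasets: tuple[tuple[str, str], ...] = (
        ("eqtl_blood", "eQTL"),
        ("eqtl_liver", "eQTL"),
        ("eqtl_brain", "eQTL"),
        ("pqtl_plasma", "pQTL"),
    )


@dataclass
class SyntheticStudy:
    gwas: sums.GwasDataset
    molqtl: list[MolQtlDataset]
    consequences: pd.DataFrame
    abc: pd.DataFrame
    gene_models: pd.DataFrame
    ld: MultiPanelLd
    truth: pd.DataFrame  # LOCUS_PLAN, CHROM, CAUSAL_GENE, CAUSAL_VARIANT, EXPECTED_TIER


@dataclass
class StudyResults:
    loci: list[sums.Locus]
    candidate_sets: list[sums.CandidateSet]
    annotations: dict[str, pd.DataFrame]
    mr: pd.DataFrame
    coloc: pd.DataFrame
    prioritization: pd.DataFrame


def simulate_study(scenario: StudyScenario, seed: int) -> SyntheticStudy:
    """Generate a full synthetic study from a scenario, deterministically."""
    root = np.random.default_rng(seed)
    gwas_frames, cons_frames, abc_frames, gene_frames = [], [], [], []
    molqtl_frames: dict[str, list[pd.DataFrame]] = {d: [] for d, _ in scenario.datasets}
    panels = {}
    truth_rows = []

    for li, plan in enumerate(scenario.plans):
        chrom = str(li + 1)
        seeds = root.integers(2**31, size=3 + len(scenario.datasets))
        panel = simulate_ld_panel(
            scenario.n_variants,
            scenario.block_size,
            scenario.rho,
            maf_range=scenario.maf_range,
            seed=int(seeds[0]),
            chrom=chrom,
        )
        panels[chrom] = panel
        # centre of the middle LD block, so the causal variant has strong
        # LD partners on both sides
        mid_block = panel.blocks[len(panel.blocks) // 2]
        causal_index = (mid_block[0] + mid_block[1]) // 2
        gwas_df, gwas_truth = simulate_gwas(
            panel,
            causal_index,
            plan.gwas_beta,
            scenario.n_gwas,
            trait_type=scenario.trait_type,
            case_fraction=scenario.case_fraction,
            seed=int(seeds[1]),
            trait_id=plan.name,
        )
        gwas_frames.append(gwas_df)

        genes = [plan.causal_gene] + [
            f"{plan.causal_gene}_DECOY{k + 1}" for k in range(plan.n_decoys)
        ]
        # lead-variant evidence goes to the realized lead (the causal
        # variant's strongest LD proxy can out-score it by sampling noise)
        lead_index = int(np.argmin(gwas_df["PVAL"].to_numpy()))
        cons, abc, models = simulate_annotation_layers(
            panel,
            genes,
            plan.causal_gene,
            plan.evidence,
            seed=int(seeds[2]),
            causal_index=lead_index,
            assoc_index=_pick_assoc_index(gwas_df, plan.evidence),
        )
        cons_frames.append(cons)
        abc_frames.append(abc)
        gene_frames.append(models)

        for di, (ds_id, _) in enumerate(scenario.datasets):
            mode = "shared" if di < plan.n_shared_molqtl else "null"
            qdf, _ = simulate_molqtl(
                panel,
                plan.causal_gene,
                mode,
                gwas_truth=gwas_truth,
                beta_true=plan.molqtl_beta,
                n=scenario.n_molqtl,
                dataset_id=ds_id,
                seed=int(seeds[3 + di]),
            )
            molqtl_frames[ds_id].append(qdf)

        truth_rows.append(
            (
                plan.name,
                chrom,
                plan.causal_gene,
                panel.variants[causal_index],
                plan.expected_tier,
            )
        )

    gwas = sums.make_dataset(
        pd.concat(gwas_frames, ignore_index=True),
        trait_type=scenario.trait_type,
        study_id="SYN_GWAS",
        trait="synthetic disease",
    )
    molqtl = [
        MolQtlDataset(ds_id, mol_type, pd.concat(frames, ignore_index=True).pipe(_clean_molqtl))
        for (ds_id, mol_type), frames in zip(scenario.datasets, molqtl_frames.values())
    ]
    truth = pd.DataFrame(
        truth_rows,
        columns=["LOCUS_PLAN", "CHROM", "CAUSAL_GENE", "CAUSAL_VARIANT", "EXPECTED_TIER"],
    )
    return SyntheticStudy(
        gwas=gwas,
        molqtl=molqtl,
        consequences=_concat_or_empty(cons_frames),
        abc=_concat_or_empty(abc_frames),
        gene_models=pd.concat(gene_frames, ignore_index=True),
        ld=MultiPanelLd(panels),
        truth=truth,
    )


_ASSOC_FEATURES = ("assoc_pathogenic", "assoc_coding", "abcmax_assoc", "abc_any_assoc")


def _pick_assoc_index(
    gwas_df: pd.DataFrame,
    evidence: dict[str, str],
    p_assoc: float = 1e-6,
    magnitude_window: float = 5.0,
) -> int | None:
    """Variant to carry planted associated-variant evidence.

    Associated-variant features only count downstream for variants that are
    eligible at the realized locus (p below the locus threshold and within
    the magnitude window of the lead), so the plant must land on one; the
    strongest eligible non-lead variant is used. Returns None (the
    neighbor-of-causal default) when no plan feature needs it or no eligible
    variant exists.
    """
    if not any(k in evidence for k in _ASSOC_FEATURES):
        return None
    pv = gwas_df["PVAL"].to_numpy()
    lead = int(np.argmin(pv))
    eligible = np.flatnonzero((pv < p_assoc) & (pv <= pv[lead] * 10.0**magnitude_window))
    eligible = eligible[eligible != lead]
    if eligible.size == 0:
        return None
    return int(eligible[np.argmin(pv[eligible])])


def _concat_or_empty(frames: list[pd.DataFrame]) -> pd.DataFrame:
    nonempty = [f for f in frames if not f.empty]
    return pd.concat(nonempty, ignore_index=True) if nonempty else frames[0]


def _clean_molqtl(df: pd.DataFrame) -> pd.DataFrame:
    keep = np.isfinite(df["SE"]) & (df["SE"] > 0) & (df["PVAL"] > 0)
    df = df[keep].copy()
    df["VARIANT_ID"] = (
        df["CHROM"].astype(str)
        + ":" + df["POS"].astype(str)
        + ":" + df["REF"] + ":" + df["ALT"]
    )
    df["MAF"] = np.minimum(df["EAF"], 1.0 - df["EAF"])
    return df


def run_study(study: SyntheticStudy, config: PipelineConfig | None = None) -> StudyResults:
    """Run the full prioritization pipeline on a (synthetic or real) study."""
    cfg = config or PipelineConfig()
    gwas = sums.filter_variants(study.gwas, cfg.maf_min, (cfg.hla_region,))
    loci = sums.define_loci(gwas, cfg.p_locus, cfg.window_bp)
    candidate_sets = [
        sums.assign_candidate_genes(locus, study.gene_models, cfg.window_bp)
        for locus in loci
    ]

    annotations: dict[str, pd.DataFrame] = {}
    for locus, cs in zip(loci, candidate_sets):
        annotations[locus.id] = ann_mod.annotate_gene_locus(
            locus,
            gwas,
            study.consequences,
            study.abc,
            cs,
            cfg.p_assoc,
            cfg.magnitude_window,
        )

    mr_table = mr_mod.mr_scan(
        gwas,
        study.molqtl,
        candidate_sets,
        study.ld,
        p_instrument=cfg.p_instrument,
        molqtl_maf_min=cfg.molqtl_maf_min,
        clump_r2=cfg.clump_r2,
        clump_kb=cfg.clump_kb,
    )

    # colocalization only where MR was significant (FDR gate)
    coloc_rows = []
    if not mr_table.empty:
        sig = mr_table[mr_table["QVAL"] < cfg.mr_q]
        locus_by_id = {locus.id: locus for locus in loci}
        ds_by_id = {ds.dataset_id: ds for ds in study.molqtl}
        for _, row in sig.iterrows():
            locus = locus_by_id[row["LOCUS_ID"]]
            ds = ds_by_id[row["DATASET_ID"]]
            slice_ = ds.records[ds.records["GENE_ID"] == row["GENE_ID"]]
            res = coloc_mod.coloc_region(
                gwas,
                locus,
                slice_,
                window=cfg.window_bp,
                p1=cfg.coloc_p1,
                p2=cfg.coloc_p2,
                p12=cfg.coloc_p12,
                prior_sd_quantitative=cfg.prior_sd_quantitative,
                prior_sd_binary=cfg.prior_sd_binary,
                gene=row["GENE_ID"],
                dataset_id=row["DATASET_ID"],
            )
            if res.status != "ok":
                continue
            d = res.as_dict()
            d["LOCUS_ID"] = locus.id
            coloc_rows.append(d)
    coloc_table = pd.DataFrame(coloc_rows)
    if coloc_table.empty:
        coloc_table = pd.DataFrame(
            columns=["GENE_ID", "DATASET_ID", "GWAS_ID", "NSNPS", "LOCUS_ID",
                     "PP_H0", "PP_H1", "PP_H2", "PP_H3", "PP_H4"]
        )

    prioritization = prio_mod.prioritize_study(
        gwas.study_id,
        candidate_sets,
        annotations,
        mr_table,
        coloc_table,
        h4_threshold=cfg.h4_threshold,
        mr_q=cfg.mr_q,
        coloc_multi=cfg.coloc_multi,
    )
    return StudyResults(
        loci=loci,
        candidate_sets=candidate_sets,
        annotations=annotations,
        mr=mr_table,
        coloc=coloc_table,
        prioritization=prioritization,
    )
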