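"""Two-sample Mendelian randomization: instrument selection by greedy LD
clumping, allele harmonization with palindromic-frequency inference, Wald
ratio and fixed-effect IVW estimation, and Benjamini-Hochberg FDR across the
transcriptome-wide scan.

Exposures are molecular traits (eQTL/pQTL per gene); outcomes are disease
GWAS. A single instrument routes to the Wald ratio, two or more to IVW.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .summaries import GwasDataset, CandidateSet

logger = logging.getLogger(__name__)

__all__ = [
    "HarmonizedPair",
    "clump",
    "select_instruments",
    "harmonize",
    "wald_ratio",
    "ivw",
    "bh_fdr",
    "mr_scan",
]

PALINDROMIC_SETS = ({"A", "T"}, {"C", "G"})

MR_COLUMNS = [
    "GWAS_ID",
    "LOCUS_ID",
    "GENE_ID",
    "DATASET_ID",
    "MOLECULE_TYPE",
    "METHOD",
    "BETA",
    "SE",
    "PVAL",
    "QVAL",
    "N_INSTRUMENTS",
]


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure/outcome effects expressed for the same effect allele."""

    variant: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float
    eaf_out: float
    flipped: bool


@dataclass(frozen=True)
class MrEstimate:
    method: str  # "wald_ratio" or "ivw"
    beta: float
    se: float
    pvalue: float
    n_instruments: int


def clump(
    records: pd.DataFrame,
    ld,
    r2_max: float = 0.01,
    kb_window: int = 10_000,
    p1: float = 1.0,
    p2: float = 1.0,
) -> list[str]:
    """Greedy LD clumping of association records.

    Repeatedly takes the smallest-p unassigned variant (p < ``p1``) as an
    index and assigns to it every unassigned variant within ``kb_window`` kb
    with r^2 > ``r2_max`` (and p < ``p2``). Variants not covered by the LD
    reference are dropped with a logged count. P-value ties break by variant
    id, so the output is independent of input row order. Returns index
    variant ids in selection order.
    """
    df = records[["VARIANT_ID", "PVAL", "CHROM", "POS"]].copy()
    covered = df["VARIANT_ID"].map(ld.covers)
    n_uncovered = int((~covered).sum())
    if n_uncovered:
        logger.info("clump: dropped %d variant(s) absent from the LD reference", n_uncovered)
        df = df[covered]
    df = df.sort_values(["PVAL", "VARIANT_ID"], kind="mergesort").reset_index(drop=True)
    assigned = np.zeros(len(df), dtype=bool)
    indices: list[str] = []
    window_bp = kb_window * 1_000
    vids = df["VARIANT_ID"].to_numpy()
    pvals = df["PVAL"].to_numpy()
    chroms = df["CHROM"].to_numpy()
    poss = df["POS"].to_numpy()
    for i in range(len(df)):
        if assigned[i] or pvals[i] >= p1:
            continue
        assigned[i] = True
        indices.append(vids[i])
        for j in range(len(df)):
            if assigned[j] or pvals[j] >= p2:
                continue
            if chroms[j] != chroms[i] or abs(int(poss[j]) - int(poss[i])) > window_bp:
                continue
            if ld.r2(vids[i], vids[j]) > r2_max:
                assigned[j] = True
    return indices


def select_instruments(
    records: pd.DataFrame,
    ld,
    p_instrument: float = 1e-4,
    maf_min: float = 0.01,
    r2_max: float = 0.01,
    kb_window: int = 10_000,
) -> list[str]:
    """Independent molQTL variants with p below the instrument threshold.

    Variants with MAF below ``maf_min`` are excluded before selection; the
    survivors are clumped. An empty result means MR is skipped for this
    gene x dataset (not an error).
    """
    sub = records[(records["MAF"] >= maf_min) & (records["PVAL"] < p_instrument)]
    if sub.empty:
        return []
    return clump(sub, ld, r2_max=r2_max, kb_window=kb_window)


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in PALINDROMIC_SETS


def harmonize(
    exp,
    out,
    palindromic_eaf_limit: float = 0.42,
) -> tuple[HarmonizedPair | None, str | None]:
    """Express exposure and outcome effects for the same effect allele.

    ``exp`` and ``out`` are mappings (e.g. pandas rows) with EFFECT_ALLELE,
    OTHER_ALLELE, EAF, BETA, SE and VARIANT_ID. If the effect alleles differ
    the outcome beta is sign-flipped and its frequency complemented.
    Palindromic (A/T, C/G) variants are retained only when both frequencies
    fall on the same side of 0.5 and outside
    ``[palindromic_eaf_limit, 1 - palindromic_eaf_limit]``; otherwise the
    pair is dropped with reason ``"palindromic_ambiguous"``. Incompatible
    allele sets drop with ``"allele_mismatch"``.
    """
    ea_e, oa_e = exp["EFFECT_ALLELE"], exp["OTHER_ALLELE"]
    ea_o, oa_o = out["EFFECT_ALLELE"], out["OTHER_ALLELE"]
    beta_out, eaf_out = float(out["BETA"]), float(out["EAF"])
    if (ea_o, oa_o) == (ea_e, oa_e):
        flipped = False
    elif (ea_o, oa_o) == (oa_e, ea_e):
        flipped = True
        beta_out = -beta_out
        eaf_out = 1.0 - eaf_out
    else:
        return None, "allele_mismatch"
    eaf_exp = float(exp["EAF"])
    if _is_palindromic(ea_e, oa_e):
        lo, hi = palindromic_eaf_limit, 1.0 - palindromic_eaf_limit
        same_side = (eaf_exp - 0.5) * (eaf_out - 0.5) > 0
        unambiguous = (
            same_side
            and not (lo <= eaf_exp <= hi)
            and not (lo <= eaf_out <= hi)
        )
        if not unambiguous:
            return None, "palindromic_ambiguous"
    pair = HarmonizedPair(
        variant=str(exp.get("VARIANT_ID", "")),
        beta_exp=float(exp["BETA"]),
        se_exp=float(exp["SE"]),
        beta_out=beta_out,
        se_out=float(out["SE"]),
        eaf_exp=eaf_exp,
        eaf_out=eaf_out,
        flipped=flipped,
    )
    return pair, None


def wald_ratio(pair: HarmonizedPair) -> MrEstimate:
    """Single-instrument causal estimate beta_out / beta_exp.

    The standard error uses the first-order delta method,
    se_out / |beta_exp|; the p-value is the two-sided normal approximation.
    """
    if pair.beta_exp == 0:
        raise ValueError("null exposure effect")
    beta = pair.beta_out / pair.beta_exp
    se = pair.se_out / abs(pair.beta_exp)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return MrEstimate("wald_ratio", beta, se, p, 1)


def ivw(pairs: list[HarmonizedPair]) -> MrEstimate:
    """Fixed-effect inverse-variance-weighted estimate across instruments.

    Equivalent to the slope of a zero-intercept regression of outcome on
    exposure effects with weights 1/se_out^2.
    """
    if len(pairs) < 2:
        raise ValueError("ivw requires >= 2 instruments; route single pairs to wald_ratio")
    be = np.array([p.beta_exp for p in pairs])
    bo = np.array([p.beta_out for p in pairs])
    so = np.array([p.se_out for p in pairs])
    if np.any(be == 0):
        raise ValueError("null exposure effect")
    w = be**2 / so**2
    beta = float(np.sum(be * bo / so**2) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return MrEstimate("ivw", beta, se, p, len(pairs))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mr_scan(
    gwas: GwasDataset,
    molqtl_datasets,
    candidate_sets: list[CandidateSet],
    ld,
    p_instrument: float = 1e-4,
    molqtl_maf_min: float = 0.01,
    clump_r2: float = 0.01,
    clump_kb: int = 10_000,
) -> pd.DataFrame:
    """Run MR for every candidate gene x molQTL dataset with instruments.

    Q-values are computed by BH across all tests for this GWAS. Gene x
    dataset pairs with no instruments or no harmonizable pairs are skipped
    with a logged reason.
    """
    gwas_by_vid = gwas.records.set_index("VARIANT_ID")
    rows = []
    for cs in candidate_sets:
        for gene in cs.gene_ids:
            for ds in molqtl_datasets:
                sub = ds.records[ds.records["GENE_ID"] == gene]
                if sub.empty:
                    continue
                instruments = select_instruments(
                    sub, ld, p_instrument, molqtl_maf_min, clump_r2, clump_kb
                )
                if not instruments:
                    logger.debug("mr_scan: no instruments for %s x %s", gene, ds.dataset_id)
                    continue
                exp_by_vid = sub.set_index("VARIANT_ID")
                pairs = []
                for vid in instruments:
                    if vid not in gwas_by_vid.index:
                        logger.debug("mr_scan: instrument %s absent from outcome", vid)
                        continue
                    exp_rec = exp_by_vid.loc[vid].copy()
                    exp_rec["VARIANT_ID"] = vid
                    pair, reason = harmonize(exp_rec, gwas_by_vid.loc[vid])
                    if pair is None:
                        logger.debug("mr_scan: dropped %s (%s)", vid, reason)
                        continue
                    if pair.beta_exp != 0:
                        pairs.append(pair)
                if not pairs:
                    logger.debug(
                        "mr_scan: no harmonizable instruments for %s x %s",
                        gene,
                        ds.dataset_id,
                    )
                    continue
                est = wald_ratio(pairs[0]) if len(pairs) == 1 else ivw(pairs)
                rows.append(
                    (
                        gwas.study_id,
                        cs.locus.id,
                        gene,
                        ds.dataset_id,
                        ds.molecule_type,
                        est.method,
                        est.beta,
                        est.se,
                        est.pvalue,
                        np.nan,
                        est.n_instruments,
                    )
                )
    out = pd.DataFrame(rows, columns=MR_COLUMNS)
    if not out.empty:
        out["QVAL"] = bh_fdr(out["PVAL"].to_numpy())
    return out
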