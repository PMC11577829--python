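"""Approximate-Bayes-factor colocalization of a GWAS locus against a molQTL
gene signal, yielding posterior probabilities for the five causal
configurations: H0 no association, H1/H2 one trait only, H3 two distinct
causal variants, H4 a shared causal variant.

Per-variant Wakefield log approximate Bayes factors are combined on the log
scale with log-sum-exp accumulation, since at biobank z-scores the raw ABFs
overflow double precision. Priors default to the canonical per-variant values
p1 = p2 = 1e-4 and p12 = 1e-5; the effect-scale prior SD defaults to 0.15 for
quantitative traits and 0.2 for binary (log-odds) traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .summaries import GwasDataset, Locus

__all__ = ["ColocResult", "log_abf", "coloc_abf", "coloc_region"]

HYPOTHESES = ("PP_H0", "PP_H1", "PP_H2", "PP_H3", "PP_H4")


@dataclass
class ColocResult:
    """H0-H4 posteriors for one gene x dataset x locus comparison."""

    pp: np.ndarray  # five posteriors, summing to 1
    n_snps: int
    gene: str | None = None
    dataset_id: str | None = None
    gwas_id: str | None = None
    status: str = "ok"  # "ok" or "no_overlap"

    @property
    def pp_h4(self) -> float:
        return float(self.pp[4])

    def as_dict(self) -> dict:
        d = {
            "GENE_ID": self.gene,
            "DATASET_ID": self.dataset_id,
            "GWAS_ID": self.gwas_id,
            "NSNPS": self.n_snps,
        }
        d.update({h: float(v) for h, v in zip(HYPOTHESES, self.pp)})
        return d


def log_abf(beta, se, prior_sd: float):
    """Wakefield log approximate Bayes factor for one association.

    With V = se^2, W = prior_sd^2, r = W / (V + W) and z = beta / se:
    ``log ABF = 0.5 * (log(1 - r) + r * z**2)``.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(se))):
        raise ValueError("beta and se must be finite")
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    v = se**2
    w = prior_sd**2
    r = w / (v + w)
    z = beta / se
    return 0.5 * (np.log1p(-r) + r * z**2)


def coloc_abf(
    beta1,
    se1,
    beta2,
    se2,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd1: float = 0.15,
    prior_sd2: float = 0.15,
) -> ColocResult:
    """Colocalize two traits over their shared variants.

    Hypothesis weights are accumulated in log space:
    L1 = p1 * sum_i ABF1_i, L2 = p2 * sum_i ABF2_i,
    L3 = p1 p2 * sum_{i != j} ABF1_i ABF2_j,
    L4 = p12 * sum_i ABF1_i ABF2_i, L0 = 1;
    posteriors are the normalized weights. A single shared variant leaves H3
    an empty sum (pp3 exactly 0).
    """
    if min(p1, p2, p12) <= 0 or p1 + p2 + p12 >= 1:
        raise ValueError("priors must be positive with p1 + p2 + p12 < 1")
    lbf1 = np.atleast_1d(log_abf(beta1, se1, prior_sd1))
    lbf2 = np.atleast_1d(log_abf(beta2, se2, prior_sd2))
    if lbf1.shape != lbf2.shape:
        raise ValueError("trait 1 and trait 2 must cover the same variants")
    m = lbf1.size
    if m < 1:
        raise ValueError("at least one shared variant is required")

    l1 = logsumexp(lbf1)
    l2 = logsumexp(lbf2)
    l4 = logsumexp(lbf1 + lbf2)
    if m == 1:
        l3 = -np.inf
    else:
        # exact off-diagonal sum; m is locus-sized so the m^2 grid is cheap
        grid = lbf1[:, None] + lbf2[None, :]
        np.fill_diagonal(grid, -np.inf)
        l3 = logsumexp(grid)

    log_weights = np.array(
        [
            0.0,
            np.log(p1) + l1,
            np.log(p2) + l2,
            np.log(p1) + np.log(p2) + l3,
            np.log(p12) + l4,
        ]
    )
    pp = np.exp(log_weights - logsumexp(log_weights))
    pp /= pp.sum()
    return ColocResult(pp=pp, n_snps=m)


def coloc_region(
    gwas: GwasDataset,
    locus: Locus,
    molqtl_records,
    window: int = 250_000,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd_quantitative: float = 0.15,
    prior_sd_binary: float = 0.2,
    gene: str | None = None,
    dataset_id: str | None = None,
) -> ColocResult:
    """Colocalize a molQTL gene slice against a GWAS locus.

    Variants of both datasets within ``window`` bp of the locus lead variant
    are intersected on their canonical ids; zero overlap returns a result
    flagged ``no_overlap`` that downstream evidence building excludes.
    The GWAS prior SD follows its trait type (log-odds scale for binary).
    """
    lo, hi = locus.lead_pos - window, locus.lead_pos + window
    grec = gwas.records
    g = grec[(grec["CHROM"] == locus.chrom) & grec["POS"].between(lo, hi)]
    q = molqtl_records[
        (molqtl_records["CHROM"] == locus.chrom)
        & molqtl_records["POS"].between(lo, hi)
    ]
    shared = g[g["VARIANT_ID"].isin(set(q["VARIANT_ID"]))]
    if shared.empty:
        return ColocResult(
            pp=np.full(5, np.nan),
            n_snps=0,
            gene=gene,
            dataset_id=dataset_id,
            gwas_id=gwas.study_id,
            status="no_overlap",
        )
    g = shared.sort_values("POS", kind="mergesort")
    q = q.set_index("VARIANT_ID").loc[g["VARIANT_ID"]]
    sd1 = prior_sd_binary if gwas.trait_type == "binary" else prior_sd_quantitative
    res = coloc_abf(
        g["BETA"].to_numpy(),
        g["SE"].to_numpy(),
        q["BETA"].to_numpy(),
        q["SE"].to_numpy(),
        p1=p1,
        p2=p2,
        p12=p12,
        prior_sd1=sd1,
        prior_sd2=prior_sd_quantitative,
    )
    res.gene = gene
    res.dataset_id = dataset_id
    res.gwas_id = gwas.study_id
    return res
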