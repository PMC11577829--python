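"""Synthetic GWAS / molQTL study generator with machine-readable ground truth.

This module emulates the statistical structure of the real inputs of a
locus-to-gene prioritization study: LD-correlated marginal association
statistics arising from planted causal variants, molecular-QTL datasets that
do or do not share the disease causal variant, per-gene consequence and
enhancer (ABC) evidence, and toy drug / gold-standard / ontology tables.
Every generator is deterministic for a fixed ``(seed, parameters)`` pair and
returns a :class:`TruthRecord` so downstream recovery can be asserted.

Haplotypes are drawn as stationary binary Markov chains within LD blocks:
each variant copies the previous allele with probability ``rho`` and
otherwise redraws a fresh Bernoulli(maf) allele. This makes the allelic
correlation exactly ``rho ** |i - j|`` within a block (zero between blocks),
so the panel correlation matrix is the realized LD, not a latent-scale
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .ld import LdPanel

__all__ = [
    "TruthRecord",
    "MolQtlDataset",
    "simulate_ld_panel",
    "simulate_haplotypes",
    "simulate_genotypes",
    "simulate_gwas",
    "simulate_molqtl",
    "simulate_annotation_layers",
    "simulate_translation_tables",
]

SUMMARY_COLUMNS = [
    "CHROM",
    "POS",
    "REF",
    "ALT",
    "EFFECT_ALLELE",
    "OTHER_ALLELE",
    "EAF",
    "BETA",
    "SE",
    "PVAL",
    "N",
]

# non-palindromic ref/alt pairs cycled along the panel
_ALLELE_PAIRS = [("A", "G"), ("G", "A"), ("C", "A"), ("T", "C")]


@dataclass
class TruthRecord:
    """Ground truth for one simulated trait (disease GWAS or molQTL gene)."""

    trait_id: str
    causal_variants: tuple[str, ...]
    causal_indices: tuple[int, ...]
    betas: tuple[float, ...]
    seed: int
    causal_gene: str | None = None
    shared_with_gwas: bool | None = None


@dataclass
class MolQtlDataset:
    """One molQTL dataset (e.g. an eQTL cell type or a pQTL study)."""

    dataset_id: str
    molecule_type: str  # "eQTL" or "pQTL"
    records: pd.DataFrame  # summary columns + GENE_ID + DATASET_ID


def simulate_ld_panel(
    n_variants: int,
    block_size: int,
    rho: float,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    chrom: str = "1",
    pos_start: int = 1_000_000,
    pos_spacing: int = 2_000,
) -> LdPanel:
    """Build an AR(1)-block LD panel.

    Within a block the allelic correlation of variants ``i`` and ``j`` is
    exactly ``rho ** |i - j|``; variants in different blocks are independent.
    Allele frequency is drawn once per block from ``maf_range`` (the Markov
    construction requires a common stationary frequency within a block).
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must satisfy 0 <= rho < 1 (rho >= 1 is degenerate)")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")

    rng = np.random.default_rng(seed)
    blocks: list[tuple[int, int]] = []
    maf = np.empty(n_variants)
    start = 0
    while start < n_variants:
        stop = min(start + block_size, n_variants)
        maf[start:stop] = rng.uniform(lo, hi)
        blocks.append((start, stop))
        start = stop

    corr = np.eye(n_variants)
    if block_size > 1 and rho > 0.0:
        for bstart, bstop in blocks:
            idx = np.arange(bstart, bstop)
            lag = np.abs(idx[:, None] - idx[None, :])
            corr[bstart:bstop, bstart:bstop] = rho ** lag

    positions = pos_start + pos_spacing * np.arange(n_variants, dtype=np.int64)
    variants = []
    for i, pos in enumerate(positions):
        ref, alt = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
        variants.append(f"{chrom}:{pos}:{ref}:{alt}")
    return LdPanel(
        chrom=chrom,
        variants=variants,
        positions=positions,
        maf=maf,
        corr=corr,
        blocks=blocks,
        rho=rho,
    )


def simulate_haplotypes(panel: LdPanel, n_hap: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_hap`` haplotypes (0/1 alternate-allele indicators).

    Within each block the chain keeps the previous allele with probability
    ``rho`` and otherwise redraws Bernoulli(maf); the stationary frequency is
    therefore the block maf and lag-k correlation is ``rho**k``.
    """
    out = np.empty((n_hap, panel.n_variants), dtype=np.int8)
    rho = panel.rho
    for bstart, bstop in panel.blocks:
        f = panel.maf[bstart]
        col = (rng.random(n_hap) < f).astype(np.int8)
        out[:, bstart] = col
        for j in range(bstart + 1, bstop):
            keep = rng.random(n_hap) < rho
            fresh = (rng.random(n_hap) < f).astype(np.int8)
            col = np.where(keep, col, fresh)
            out[:, j] = col
    return out


def simulate_genotypes(panel: LdPanel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Diploid genotypes as the sum of two independent haplotypes."""
    return simulate_haplotypes(panel, n, rng) + simulate_haplotypes(panel, n, rng)


def _as_tuple(x) -> tuple:
    if np.isscalar(x):
        return (x,)
    return tuple(x)


def _marginal_linear(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant simple linear regression of y on genotype."""
    g = g.astype(np.float64, copy=False)
    n, _ = g.shape
    gm = g.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", g, g) - n * gm**2
    sxy = g.T @ yc
    syy = float(yc @ yc)
    poly = sxx > 0
    beta = np.zeros_like(sxx)
    se = np.full_like(sxx, np.inf)
    pval = np.ones_like(sxx)
    np.divide(sxy, sxx, out=beta, where=poly)
    resid = np.maximum(syy - beta * sxy, 0.0)
    sigma2 = resid / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_ok = np.sqrt(sigma2 / np.where(poly, sxx, 1.0))
    se[poly] = se_ok[poly]
    z = np.zeros_like(beta)
    np.divide(beta, se, out=z, where=poly & (se > 0))
    pval[poly] = 2.0 * stats.t.sf(np.abs(z[poly]), n - 2)
    return beta, se, pval


def _marginal_logistic_score(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant logistic score test with one-step log-odds estimate.

    Under the intercept-only null, the score is U = g'(y - p0) with variance
    V = p0 (1 - p0) Sxx; the one-step estimate U/V is the standard fast-GWAS
    log-odds effect with se = V^{-1/2}.
    """
    g = g.astype(np.float64, copy=False)
    n, _ = g.shape
    p0 = y.mean()
    gm = g.mean(axis=0)
    sxx = np.einsum("ij,ij->j", g, g) - n * gm**2
    u = g.T @ (y - p0)
    v = p0 * (1.0 - p0) * sxx
    poly = v > 0
    beta = np.zeros_like(u, dtype=float)
    se = np.full(u.shape, np.inf)
    pval = np.ones(u.shape)
    np.divide(u, v, out=beta, where=poly)
    se[poly] = 1.0 / np.sqrt(v[poly])
    zsq = np.zeros_like(beta)
    np.divide(u * u, v, out=zsq, where=poly)
    pval[poly] = stats.chi2.sf(zsq[poly], 1)
    return beta, se, pval


def _records_frame(panel: LdPanel, g: np.ndarray, beta, se, pval, n: int) -> pd.DataFrame:
    eaf = g.mean(axis=0) / 2.0
    refs = [v.split(":")[2] for v in panel.variants]
    alts = [v.split(":")[3] for v in panel.variants]
    return pd.DataFrame(
        {
            "CHROM": panel.chrom,
            "POS": panel.positions,
            "REF": refs,
            "ALT": alts,
            "EFFECT_ALLELE": alts,
            "OTHER_ALLELE": refs,
            "EAF": eaf,
            "BETA": beta,
            "SE": se,
            "PVAL": pval,
            "N": n,
        }
    )


def simulate_gwas(
    panel: LdPanel,
    causal_index,
    beta_true,
    n: int,
    trait_type: str = "quantitative",
    case_fraction: float = 0.5,
    seed: int = 0,
    trait_id: str = "trait",
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate marginal GWAS summary statistics with planted causal variants.

    Individual-level genotypes are drawn consistent with the panel; the
    phenotype is an additive genetic effect plus noise (logistic link for
    binary traits) and every variant is tested marginally. Monomorphic
    variants are emitted with ``SE = inf`` so the filtering path downstream
    is exercised rather than silently skipped.

    ``causal_index`` / ``beta_true`` may be scalars or parallel sequences;
    quantitative betas are in units of the residual SD, binary betas are
    log-odds per allele.
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    if trait_type not in ("binary", "quantitative"):
        raise ValueError("trait_type must be 'binary' or 'quantitative'")
    idx = tuple(int(i) for i in _as_tuple(causal_index))
    betas = tuple(float(b) for b in _as_tuple(beta_true))
    if len(idx) != len(betas):
        raise ValueError("causal_index and beta_true lengths differ")
    for i in idx:
        if not 0 <= i < panel.n_variants:
            raise ValueError(f"causal index {i} out of range")
    rng = np.random.default_rng(seed)
    g = simulate_genotypes(panel, n, rng)
    genetic = g[:, list(idx)].astype(float) @ np.array(betas) if idx else np.zeros(n)

    if trait_type == "quantitative":
        y = genetic + rng.standard_normal(n)
        beta, se, pval = _marginal_linear(g, y)
    else:
        if not 0.0 < case_fraction < 1.0:
            raise ValueError("case_fraction must be in (0, 1)")

        def mean_prev(alpha: float) -> float:
            return float(special.expit(alpha + genetic).mean()) - case_fraction

        alpha = optimize.brentq(mean_prev, -30.0, 30.0)
        y = (rng.random(n) < special.expit(alpha + genetic)).astype(float)
        beta, se, pval = _marginal_logistic_score(g, y)

    df = _records_frame(panel, g, beta, se, pval, n)
    truth = TruthRecord(
        trait_id=trait_id,
        causal_variants=tuple(panel.variants[i] for i in idx),
        causal_indices=idx,
        betas=betas,
        seed=seed,
    )
    return df, truth


def simulate_molqtl(
    panel: LdPanel,
    gene: str,
    mode: str,
    gwas_truth: TruthRecord | None = None,
    beta_true: float = 0.4,
    n: int = 5_000,
    dataset_id: str = "molqtl",
    seed: int = 0,
    distinct_r_max: float = 0.1,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate one gene's molQTL summary statistics.

    ``mode`` selects how the molecular causal variant relates to the GWAS:
    ``shared`` reuses the GWAS causal variant, ``distinct`` picks a variant
    with ``|r| < distinct_r_max`` to it, and ``null`` plants no effect.
    """
    if mode not in ("shared", "distinct", "null"):
        raise ValueError("mode must be one of 'shared', 'distinct', 'null'")
    rng = np.random.default_rng(seed)
    if mode == "null":
        idx: tuple[int, ...] = ()
        betas: tuple[float, ...] = ()
    else:
        if gwas_truth is None or not gwas_truth.causal_indices:
            raise ValueError(f"mode={mode!r} requires a GWAS truth record")
        gwas_idx = gwas_truth.causal_indices[0]
        if mode == "shared":
            idx = (gwas_idx,)
        else:
            eligible = np.flatnonzero(np.abs(panel.corr[gwas_idx]) < distinct_r_max)
            if eligible.size == 0:
                raise ValueError(
                    f"no panel variant has |r| < {distinct_r_max} with the GWAS "
                    "causal variant; enlarge the panel or relax distinct_r_max"
                )
            idx = (int(rng.choice(eligible)),)
        betas = (float(beta_true),)

    df, truth = simulate_gwas(
        panel,
        idx,
        betas,
        n,
        trait_type="quantitative",
        seed=int(rng.integers(2**31)),
        trait_id=f"{dataset_id}:{gene}",
    )
    df = df.copy()
    df["GENE_ID"] = gene
    df["DATASET_ID"] = dataset_id
    truth.causal_gene = gene
    truth.shared_with_gwas = mode == "shared"
    truth.seed = seed
    return df, truth


# ---------------------------------------------------------------------------
# annotation layers (consequence table, ABC map, gene models)
# ---------------------------------------------------------------------------

CONSEQUENCE_COLUMNS = [
    "VARIANT_ID",
    "GENE_ID",
    "CONSEQUENCE",
    "IMPACT",
    "PATHOGENIC",
    "DESTABILIZING",
    "CONSERVED",
]
ABC_COLUMNS = ["CHROM", "START", "END", "GENE_ID", "CELL_TYPE", "ABC_SCORE"]
GENE_MODEL_COLUMNS = ["GENE_ID", "SYMBOL", "CHROM", "START", "END", "STRAND"]

#: evidence-plan keys the generator understands
EVIDENCE_FEATURES = (
    "lead_pathogenic",
    "lead_coding",
    "assoc_pathogenic",
    "assoc_coding",
    "abcmax_lead",
    "abcmax_assoc",
    "abc_any_lead",
    "abc_any_assoc",
    "nearest",
)


def make_gene_models(
    panel: LdPanel,
    genes: list[str],
    causal_index: int,
    nearest_gene: str | None = None,
    footprint: int = 20_000,
) -> pd.DataFrame:
    """Place gene footprints around the causal variant.

    The first offset is the closest to the causal (lead) variant; pass
    ``nearest_gene`` to choose which gene takes it. By default the nearest
    slot goes to the second listed gene (a decoy, by the generator's
    convention of listing the causal gene first), so recovering the causal
    gene genuinely requires evidence rather than proximity.
    """
    pos = int(panel.positions[causal_index])
    offsets = [6_000 + 45_000 * k for k in range(len(genes))]
    order = list(genes)
    if nearest_gene is None and len(order) > 1:
        nearest_gene = order[1]
    if nearest_gene is not None:
        if nearest_gene not in order:
            raise ValueError(f"nearest_gene {nearest_gene!r} not among genes")
        order.remove(nearest_gene)
        order.insert(0, nearest_gene)
    rows = []
    for gene, off in zip(order, offsets):
        start = pos + off
        rows.append((gene, gene, panel.chrom, start, start + footprint, "+"))
    return pd.DataFrame(rows, columns=GENE_MODEL_COLUMNS)


def simulate_annotation_layers(
    panel: LdPanel,
    genes: list[str],
    causal_gene: str,
    evidence_plan: dict[str, str],
    seed: int = 0,
    causal_index: int | None = None,
    assoc_index: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Plant consequence / ABC evidence so it is literally detectable.

    ``evidence_plan`` maps a feature key (see :data:`EVIDENCE_FEATURES`) to
    the gene that should carry it; genes not named receive no planted
    evidence. ``causal_index`` is the GWAS causal variant (defaults to the
    panel midpoint) and ``assoc_index`` an LD neighbour used for the
    ``assoc_*`` features (defaults to the adjacent variant in the same
    block). Returns ``(consequences, abc, gene_models)``.
    """
    for key, gene in evidence_plan.items():
        if key not in EVIDENCE_FEATURES:
            raise ValueError(f"unknown evidence feature {key!r}")
        if gene not in genes:
            raise ValueError(f"evidence plan references absent gene {gene!r}")
    if causal_gene not in genes:
        raise ValueError(f"causal gene {causal_gene!r} not among genes")
    if causal_index is None:
        causal_index = panel.n_variants // 2
    if assoc_index is None:
        assoc_index = causal_index + 1 if causal_index + 1 < panel.n_variants else causal_index - 1

    gene_models = make_gene_models(
        panel, genes, causal_index, nearest_gene=evidence_plan.get("nearest")
    )
    lead_v = panel.variants[causal_index]
    assoc_v = panel.variants[assoc_index]

    cons_rows = []
    if "lead_coding" in evidence_plan:
        cons_rows.append((lead_v, evidence_plan["lead_coding"], "missense_variant", "MODERATE", 0, 0, 0))
    if "lead_pathogenic" in evidence_plan:
        cons_rows.append((lead_v, evidence_plan["lead_pathogenic"], "missense_variant", "MODERATE", 1, 0, 0))
    if "assoc_coding" in evidence_plan:
        cons_rows.append((assoc_v, evidence_plan["assoc_coding"], "missense_variant", "MODERATE", 0, 0, 0))
    if "assoc_pathogenic" in evidence_plan:
        cons_rows.append((assoc_v, evidence_plan["assoc_pathogenic"], "missense_variant", "MODERATE", 1, 0, 0))
    consequences = pd.DataFrame(cons_rows, columns=CONSEQUENCE_COLUMNS)

    decoy = next((g for g in genes if g != causal_gene), None)
    abc_rows = []

    def _enhancer(index: int) -> tuple[int, int]:
        pos0 = int(panel.positions[index]) - 1  # 0-based
        return pos0 - 500, pos0 + 500

    if "abcmax_lead" in evidence_plan:
        s, e = _enhancer(causal_index)
        abc_rows.append((panel.chrom, s, e, evidence_plan["abcmax_lead"], "cell_a", 0.50))
        if decoy is not None and decoy != evidence_plan["abcmax_lead"]:
            abc_rows.append((panel.chrom, s, e, decoy, "cell_a", 0.05))
    if "abcmax_assoc" in evidence_plan:
        s, e = _enhancer(assoc_index)
        abc_rows.append((panel.chrom, s, e, evidence_plan["abcmax_assoc"], "cell_b", 0.45))
    if "abc_any_lead" in evidence_plan:
        s, e = _enhancer(causal_index)
        abc_rows.append((panel.chrom, s, e, evidence_plan["abc_any_lead"], "cell_c", 0.04))
    if "abc_any_assoc" in evidence_plan:
        s, e = _enhancer(assoc_index)
        abc_rows.append((panel.chrom, s, e, evidence_plan["abc_any_assoc"], "cell_c", 0.03))
    abc = pd.DataFrame(abc_rows, columns=ABC_COLUMNS)
    return consequences, abc, gene_models


# ---------------------------------------------------------------------------
# translational stand-ins (drugs, gold standards, ontology)
# ---------------------------------------------------------------------------

DRUG_COLUMNS = ["DRUG_ID", "TARGET_GENE", "INDICATION_EFO", "PHASE", "MOA"]
GOLD_COLUMNS = ["GENE_ID", "EFO_ID"]

_INHIBITION_KEYWORDS = ("inhibitor", "antagonist", "degrader")
_ACTIVATION_KEYWORDS = ("agonist", "activator")
PHASES = ("1", "2", "3", "approved")


@dataclass
class TranslationTables:
    """Synthetic drug, gold-standard and ontology tables (Citeline-like
    stand-ins; no licensed content)."""

    drugs: pd.DataFrame
    gold_standards: pd.DataFrame
    ontology_edges: pd.DataFrame  # CHILD, PARENT
    term_usage: dict[str, int]
    disease_terms: dict[str, str]  # disease label -> ontology term
    truth: dict = field(default_factory=dict)


def _build_ontology(n_leaves: int, depth: int, branching: int = 3) -> tuple[pd.DataFrame, list[str]]:
    """Rooted is-a DAG: a balanced tree deep enough for >= n_leaves leaves,
    plus one cross edge to make it a genuine DAG rather than a tree."""
    edges: list[tuple[str, str]] = []
    level = ["EFO:ROOT"]
    counter = 0
    for _ in range(depth):
        nxt = []
        for parent in level:
            for _ in range(branching):
                counter += 1
                child = f"EFO:{counter:04d}"
                edges.append((child, parent))
                nxt.append(child)
        level = nxt
        if len(level) >= n_leaves:
            break
    leaves = level
    if len(leaves) < n_leaves:
        raise ValueError("ontology_depth too small for the requested diseases")
    if len(leaves) >= 2:
        # cross edge: second leaf also is-a first leaf's parent's sibling branch
        edges.append((leaves[1], edges[0][1]))
    return pd.DataFrame(edges, columns=["CHILD", "PARENT"]), leaves


def simulate_translation_tables(
    genes: list[str],
    diseases: list[str],
    n_drugs: int,
    ontology_depth: int = 3,
    seed: int = 0,
    gold_pairs: list[tuple[str, str]] | None = None,
    supported_pairs: set[tuple[str, str]] | None = None,
    advance_rr: float = 2.0,
    base_phase2_rate: float = 0.3,
    moa_predictions: dict[tuple[str, str], str] | None = None,
    concordance_rate: float = 1.0,
) -> TranslationTables:
    """Generate toy drug / gold-standard / ontology tables.

    ``supported_pairs`` are (gene, disease-term) pairs treated as genetically
    supported: their drugs advance past phase 1 at ``advance_rr`` times the
    base rate (later transitions share a common conditional rate, so the
    risk ratio is ``advance_rr`` at every cumulative phase cut).
    ``moa_predictions`` maps (gene, disease-term) to the genetically
    beneficial direction ("inhibition"/"activation"); drug MoA keywords are
    then drawn concordant with probability ``concordance_rate``.
    """
    if ontology_depth < 2:
        raise ValueError("ontology_depth must be >= 2")
    if n_drugs < 0:
        raise ValueError("n_drugs must be >= 0")
    rng = np.random.default_rng(seed)
    edges, leaves = _build_ontology(len(diseases), ontology_depth)
    disease_terms = {d: leaves[i] for i, d in enumerate(diseases)}
    usage = {t: 1 for t in leaves[: len(diseases)]}

    if gold_pairs is None:
        gold_pairs = [(genes[0], disease_terms[diseases[0]])] if genes and diseases else []
    gold = pd.DataFrame(gold_pairs, columns=GOLD_COLUMNS)

    supported = supported_pairs or set()
    terms = [disease_terms[d] for d in diseases]
    rows = []
    for k in range(n_drugs):
        gene = genes[int(rng.integers(len(genes)))]
        term = terms[int(rng.integers(len(terms)))]
        is_supported = (gene, term) in supported
        p2 = min(1.0, base_phase2_rate * (advance_rr if is_supported else 1.0))
        phase = 1
        if rng.random() < p2:
            phase = 2
            if rng.random() < 0.5:
                phase = 3
                if rng.random() < 0.5:
                    phase = 4
        phase_label = PHASES[phase - 1]
        pred = (moa_predictions or {}).get((gene, term))
        if pred is None:
            moa = str(rng.choice(list(_INHIBITION_KEYWORDS + _ACTIVATION_KEYWORDS + ("other",))))
        else:
            concordant = rng.random() < concordance_rate
            pool = (
                _INHIBITION_KEYWORDS
                if (pred == "inhibition") == concordant
                else _ACTIVATION_KEYWORDS
            )
            moa = str(rng.choice(list(pool)))
        rows.append((f"DRUG{k:04d}", gene, term, phase_label, moa))
    drugs = pd.DataFrame(rows, columns=DRUG_COLUMNS)
    return TranslationTables(
        drugs=drugs,
        gold_standards=gold,
        ontology_edges=edges,
        term_usage=usage,
        disease_terms=disease_terms,
        truth={"supported_pairs": supported, "advance_rr": advance_rr},
    )
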