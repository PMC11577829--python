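"""Downstream translational analytics.

Covers: gold-standard benchmarking of the prioritizer (Fisher enrichment plus
precision / recall / F1 per evidence selector), the three contingency-cube
enrichments (gene x cell type, gene x disease category, disease category x
cell type), information-content semantic similarity over a disease ontology
DAG for linking genetics to drug indications, clinical-phase risk ratios for
genetically supported target-indication pairs, and drug mechanism-of-action
directionality predicted from low-frequency coding variants or from the MR
consensus sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .mr import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "OntologyGraph",
    "MoaPrediction",
    "fisher_exact",
    "evaluate_gold_standards",
    "build_cube",
    "gene_celltype_enrichment",
    "gene_disease_category_enrichment",
    "category_celltype_enrichment",
    "group_dataset_axis",
    "semantic_similarity",
    "pairwise_similarity",
    "link_genetics_to_drugs",
    "clinical_phase_risk_ratios",
    "moa_direction_from_coding",
    "moa_direction_from_mr",
    "moa_concordance",
]

PHASE_ORDER = {"1": 1, "2": 2, "3": 3, "approved": 4}
INHIBITION_KEYWORDS = frozenset({"antagonist", "inhibitor", "degrader"})
ACTIVATION_KEYWORDS = frozenset({"agonist", "activator"})


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table; ``a`` is the focal co-occurrence (top-left) cell."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact(table: ContingencyTable, sidedness: str = "two_sided") -> tuple[float, float]:
    """Fisher exact test on a 2x2 table.

    Returns ``(odds_ratio, pvalue)``. The odds ratio is the sample
    cross-product ratio, with a Haldane-Anscombe 0.5 correction applied only
    when a zero cell occurs; a zero margin yields an NaN odds ratio and
    p-value 1.
    """
    if sidedness not in ("two_sided", "greater"):
        raise ValueError("sidedness must be 'two_sided' or 'greater'")
    arr = table.as_array()
    if min(arr.sum(axis=0).min(), arr.sum(axis=1).min()) == 0:
        return float("nan"), 1.0
    alternative = "two-sided" if sidedness == "two_sided" else "greater"
    _, p = stats.fisher_exact(arr, alternative=alternative)
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c), float(p)


# ---------------------------------------------------------------------------
# gold-standard evaluation
# ---------------------------------------------------------------------------

@dataclass
class GoldStandardResult:
    selector: str
    table: ContingencyTable
    odds_ratio: float
    pvalue: float
    precision: float
    recall: float
    f1: float


def _prf(a: int, b: int, c: int) -> tuple[float, float, float]:
    precision = a / (a + b) if (a + b) else float("nan")
    recall = a / (a + c) if (a + c) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (a + b) and (precision + recall) > 0
        else 0.0
    )
    return precision, recall, f1


def evaluate_gold_standards(
    candidates: pd.DataFrame,
    gold: pd.DataFrame,
    selectors: dict[str, object],
    p_genomewide: float = 5e-8,
) -> pd.DataFrame:
    """Benchmark evidence selectors against gold-standard gene-disease pairs.

    ``candidates`` has one row per (GWAS, locus, gene) with at least GWAS_ID,
    EFO_ID, LOCUS_ID, GENE_ID, LEAD_PVAL plus whatever columns the selectors
    read; ``gold`` has GENE_ID, EFO_ID. Only loci with a genome-wide
    significant lead (p < ``p_genomewide``) enter; per indication, the
    universe is restricted to genes in loci where a gold-standard gene for
    that indication is located. Each selector is a callable mapping the
    restricted frame to a boolean "prioritized" series.
    """
    df = candidates[candidates["LEAD_PVAL"] < p_genomewide].copy()
    gold_pairs = set(zip(gold["GENE_ID"], gold["EFO_ID"]))
    gold_genes_by_term: dict[str, set] = {}
    for g, t in gold_pairs:
        gold_genes_by_term.setdefault(t, set()).add(g)

    universes = []
    for term, sub in df.groupby("EFO_ID"):
        gold_genes = gold_genes_by_term.get(term, set())
        loci_with_gold = set(sub.loc[sub["GENE_ID"].isin(gold_genes), "LOCUS_ID"])
        keep = sub[sub["LOCUS_ID"].isin(loci_with_gold)].copy()
        if keep.empty:
            continue
        keep["IS_GOLD"] = [
            (g, term) in gold_pairs for g in keep["GENE_ID"]
        ]
        universes.append(keep)
    if not universes:
        raise ValueError("no locus contains a gold-standard gene after restriction")
    uni = pd.concat(universes, ignore_index=True)

    rows = []
    for name, selector in selectors.items():
        pred = np.asarray(selector(uni), dtype=bool)
        is_gold = uni["IS_GOLD"].to_numpy()
        a = int((pred & is_gold).sum())
        b = int((pred & ~is_gold).sum())
        c = int((~pred & is_gold).sum())
        d = int((~pred & ~is_gold).sum())
        if a + b == 0:
            logger.info("selector %r matched nothing", name)
        table = ContingencyTable(a, b, c, d)
        odds, p = fisher_exact(table)
        precision, recall, f1 = _prf(a, b, c)
        rows.append(
            (name, a, b, c, d, odds, p, precision, recall, f1)
        )
    return pd.DataFrame(
        rows,
        columns=["SELECTOR", "A", "B", "C", "D", "OR", "PVAL", "PRECISION", "RECALL", "F1"],
    )


# ---------------------------------------------------------------------------
# contingency-cube enrichments
# ---------------------------------------------------------------------------

def build_cube(
    df: pd.DataFrame, axes: tuple[str, str, str]
) -> tuple[np.ndarray, list, list, list]:
    """Binary 3-D indicator cube from a tidy evidence frame.

    ``axes`` names the three columns; cube[i, j, k] = 1 iff the combination
    occurs at least once.
    """
    labels = [sorted(df[c].unique()) for c in axes]
    lookup = [{v: i for i, v in enumerate(lab)} for lab in labels]
    cube = np.zeros([len(lab) for lab in labels], dtype=bool)
    for vals in df[list(axes)].itertuples(index=False):
        cube[tuple(lu[v] for lu, v in zip(lookup, vals))] = True
    return cube, labels[0], labels[1], labels[2]


def _enrich_rows(rows: list[dict]) -> pd.DataFrame:
    out = pd.DataFrame(rows)
    if not out.empty:
        out["QVAL"] = bh_fdr(out["PVAL"].to_numpy())
    return out


def gene_celltype_enrichment(
    cube: np.ndarray, diseases: list, genes: list, datasets: list
) -> pd.DataFrame:
    """Cell-type enrichment of colocalizing molQTL at single genes.

    ``cube[i, j, k] = 1`` if disease i colocalizes with prioritized gene j in
    dataset k (diseases collapsed to unique ontology terms upstream, so a
    gene counts once per indication). For a focal (gene J, dataset K):
    a = sum_i C[i,J,K]; b = sum_i sum_{k!=K} C[i,J,k];
    c = sum_i sum_{j!=J} C[i,j,K]; d = the remainder. Genes never prioritized
    are skipped; q-values are BH across all tested (J, K) pairs.
    """
    total = int(cube.sum())
    rows = []
    for j, gene in enumerate(genes):
        row_j = int(cube[:, j, :].sum())
        if row_j == 0:
            continue
        for k, ds in enumerate(datasets):
            col_k = int(cube[:, :, k].sum())
            a = int(cube[:, j, k].sum())
            b = row_j - a
            c = col_k - a
            d = total - row_j - col_k + a
            table = ContingencyTable(a, b, c, d)
            odds, p = fisher_exact(table)
            rows.append(
                {"GENE_ID": gene, "DATASET_ID": ds, "A": a, "B": b, "C": c,
                 "D": d, "OR": odds, "PVAL": p}
            )
    return _enrich_rows(rows)


def gene_disease_category_enrichment(
    cube: np.ndarray, gwas_list: list, genes: list, categories: list
) -> pd.DataFrame:
    """Disease-category enrichment for single genes.

    ``cube[i, j, c] = 1`` if GWAS i is prioritized for gene j and belongs to
    category c. For focal (gene J, category C): a = sum_i D[i,J,C];
    b = sum_i sum_{c!=C} D[i,J,c]; c = sum_i sum_{j!=J} D[i,j,C]; d = rest.
    """
    total = int(cube.sum())
    rows = []
    for j, gene in enumerate(genes):
        row_j = int(cube[:, j, :].sum())
        if row_j == 0:
            continue
        for ci, cat in enumerate(categories):
            col_c = int(cube[:, :, ci].sum())
            a = int(cube[:, j, ci].sum())
            b = row_j - a
            c = col_c - a
            d = total - row_j - col_c + a
            table = ContingencyTable(a, b, c, d)
            odds, p = fisher_exact(table)
            rows.append(
                {"GENE_ID": gene, "CATEGORY": cat, "A": a, "B": b, "C": c,
                 "D": d, "OR": odds, "PVAL": p}
            )
    return _enrich_rows(rows)


def category_celltype_enrichment(
    cube: np.ndarray, categories: list, genes: list, datasets: list
) -> pd.DataFrame:
    """Cell-type enrichment of colocalizing molQTL per disease category.

    ``cube[i, j, k] = 1`` if at least one GWAS of category i colocalizes with
    gene j in dataset k. For focal (category I, dataset K):
    a = sum_j C[I,j,K]; b = sum_j sum_{k!=K} C[I,j,k];
    c = sum_j sum_{i!=I} C[i,j,K]; d = rest.
    """
    total = int(cube.sum())
    rows = []
    for i, cat in enumerate(categories):
        row_i = int(cube[i, :, :].sum())
        if row_i == 0:
            continue
        for k, ds in enumerate(datasets):
            col_k = int(cube[:, :, k].sum())
            a = int(cube[i, :, k].sum())
            b = row_i - a
            c = col_k - a
            d = total - row_i - col_k + a
            table = ContingencyTable(a, b, c, d)
            odds, p = fisher_exact(table)
            rows.append(
                {"CATEGORY": cat, "DATASET_ID": ds, "A": a, "B": b, "C": c,
                 "D": d, "OR": odds, "PVAL": p}
            )
    return _enrich_rows(rows)


def group_dataset_axis(
    cube: np.ndarray, datasets: list, grouping: dict[str, str]
) -> tuple[np.ndarray, list]:
    """Collapse the dataset axis into broader tissue groups (logical OR)."""
    groups = sorted({grouping.get(d, d) for d in datasets})
    gi = {g: i for i, g in enumerate(groups)}
    out = np.zeros(cube.shape[:2] + (len(groups),), dtype=bool)
    for k, d in enumerate(datasets):
        out[:, :, gi[grouping.get(d, d)]] |= cube[:, :, k]
    return out, groups


# ---------------------------------------------------------------------------
# ontology and semantic similarity
# ---------------------------------------------------------------------------

class OntologyGraph:
    """A rooted is-a DAG of disease terms with usage-based information content.

    ``edges`` is an iterable of (child, parent) pairs or a DataFrame with
    CHILD / PARENT columns; ``usage`` counts how often each term annotates a
    disease, feeding IC(t) = -log(cumulative usage of t and its descendants /
    total usage).
    """

    def __init__(self, edges, usage: dict[str, int] | None = None):
        if isinstance(edges, pd.DataFrame):
            edges = list(zip(edges["CHILD"], edges["PARENT"]))
        self.graph = nx.DiGraph()  # child -> parent
        self.graph.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology contains a directed cycle")
        roots = [t for t in self.graph.nodes if self.graph.out_degree(t) == 0]
        if len(roots) != 1:
            raise ValueError(f"ontology must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self.usage = dict(usage or {t: 1 for t in self.graph.nodes})
        self._counts: dict[str, int] = {}
        total = 0
        for term, n in self.usage.items():
            if term not in self.graph:
                raise ValueError(f"usage references unknown term {term!r}")
            total += n
            for anc in self.ancestors(term):
                self._counts[anc] = self._counts.get(anc, 0) + n
        self._total = total
        self._max_ic = max(
            (self.ic(t) for t in self.graph.nodes if self._counts.get(t, 0) > 0),
            default=0.0,
        )

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def ancestors(self, term: str) -> set[str]:
        """The term and all its is-a ancestors up to the root."""
        if term not in self.graph:
            raise KeyError(f"unknown ontology term {term!r}")
        return {term} | nx.descendants(self.graph, term)

    def term_descendants(self, term: str) -> set[str]:
        if term not in self.graph:
            raise KeyError(f"unknown ontology term {term!r}")
        return {term} | nx.ancestors(self.graph, term)

    def ic(self, term: str) -> float:
        count = self._counts.get(term, 0)
        if count == 0 or self._total == 0:
            return float("inf")
        return float(-np.log(count / self._total))

    def mica_ic(self, a: str, b: str) -> float:
        """IC of the most informative common ancestor (0 if only the root)."""
        common = self.ancestors(a) & self.ancestors(b)
        ics = [self.ic(t) for t in common if np.isfinite(self.ic(t))]
        return max(ics) if ics else 0.0


def semantic_similarity(term_a: str, term_b: str, ontology: OntologyGraph) -> float:
    """Raw semantic similarity in [0, 1]: the mean of max-IC-scaled Resnik
    and Lin similarity of the most informative common ancestor. Terms whose
    only common ancestor carries zero information score 0."""
    if term_a not in ontology or term_b not in ontology:
        raise KeyError("unknown ontology term")
    mica = ontology.mica_ic(term_a, term_b)
    resnik = mica / ontology._max_ic if ontology._max_ic > 0 else 0.0
    ia, ib = ontology.ic(term_a), ontology.ic(term_b)
    if np.isfinite(ia) and np.isfinite(ib) and (ia + ib) > 0:
        lin = 2.0 * mica / (ia + ib)
    else:
        lin = 0.0
    return 0.5 * (resnik + lin)


def pairwise_similarity(
    row_terms: list[str],
    col_terms: list[str],
    ontology: OntologyGraph,
    standardize: bool = True,
) -> pd.DataFrame:
    """All-pairs similarity matrix, optionally standardized per row.

    Standardization divides each row by its maximum over the union of row and
    column terms (self-similarity included), so every disease's best match -
    in particular the self-match - scores exactly 1.
    """
    universe = list(dict.fromkeys(list(col_terms) + list(row_terms)))
    raw = pd.DataFrame(
        [[semantic_similarity(a, b, ontology) for b in universe] for a in row_terms],
        index=row_terms,
        columns=universe,
    )
    if standardize:
        row_max = raw.max(axis=1)
        raw = raw.div(row_max.where(row_max > 0, 1.0), axis=0)
    return raw[list(dict.fromkeys(col_terms))]


# ---------------------------------------------------------------------------
# drugs: linkage, clinical-phase risk ratios, MoA directionality
# ---------------------------------------------------------------------------

def link_genetics_to_drugs(
    prioritized: pd.DataFrame,
    drugs: pd.DataFrame,
    ontology: OntologyGraph,
    threshold: float = 0.7,
    cancer_terms: frozenset | set = frozenset(),
) -> pd.DataFrame:
    """Genetically supported target-indication pairs.

    ``prioritized`` has GENE_ID, EFO_ID, GWAS_ID, LEAD_PVAL rows (prioritized
    gene-disease pairs); ``drugs`` has TARGET_GENE and INDICATION_EFO. A pair
    is supported iff some prioritized disease for the target reaches
    standardized similarity >= ``threshold`` with the indication; among
    multiple supporting GWAS the one with the smallest locus lead p-value is
    kept. Indications in ``cancer_terms`` (or below them in the ontology) are
    excluded beforehand.
    """
    excluded: set[str] = set()
    for t in cancer_terms:
        excluded |= ontology.term_descendants(t)
    pairs = drugs[["TARGET_GENE", "INDICATION_EFO"]].drop_duplicates()
    pairs = pairs[~pairs["INDICATION_EFO"].isin(excluded)]
    diseases = sorted(prioritized["EFO_ID"].unique())
    indications = sorted(pairs["INDICATION_EFO"].unique())
    if not diseases or not indications:
        return pd.DataFrame(
            columns=["TARGET_GENE", "INDICATION_EFO", "GWAS_ID", "EFO_ID",
                     "SIMILARITY", "LEAD_PVAL"]
        )
    sim = pairwise_similarity(diseases, indications, ontology)
    rows = []
    for target, indication in pairs.itertuples(index=False):
        support = prioritized[prioritized["GENE_ID"] == target]
        if support.empty:
            continue
        sims = support["EFO_ID"].map(lambda d: sim.loc[d, indication])
        hits = support[sims >= threshold].copy()
        if hits.empty:
            continue
        hits["SIMILARITY"] = sims[sims >= threshold]
        best = hits.sort_values(["LEAD_PVAL", "GWAS_ID"], kind="mergesort").iloc[0]
        rows.append(
            (target, indication, best["GWAS_ID"], best["EFO_ID"],
             float(best["SIMILARITY"]), float(best["LEAD_PVAL"]))
        )
    return pd.DataFrame(
        rows,
        columns=["TARGET_GENE", "INDICATION_EFO", "GWAS_ID", "EFO_ID",
                 "SIMILARITY", "LEAD_PVAL"],
    )


def clinical_phase_risk_ratios(
    drugs: pd.DataFrame,
    supported_pairs: set[tuple[str, str]],
    phases: tuple[str, ...] = ("1", "2", "3", "approved"),
) -> pd.DataFrame:
    """Risk ratio of reaching each cumulative clinical phase given genetic
    support, over the universe of unique drug-table target-indication pairs.

    RR = P(phase >= X | supported) / P(phase >= X | unsupported); the Fisher
    p-value comes from the corresponding 2x2. An empty stratum yields an NaN
    sentinel.
    """
    uni = drugs[["TARGET_GENE", "INDICATION_EFO", "PHASE"]].copy()
    uni["PHASE_NUM"] = uni["PHASE"].map(PHASE_ORDER)
    if uni["PHASE_NUM"].isna().any():
        raise ValueError("unknown phase label in drug table")
    best = uni.groupby(["TARGET_GENE", "INDICATION_EFO"])["PHASE_NUM"].max()
    supported = np.array(
        [pair in supported_pairs for pair in best.index], dtype=bool
    )
    rows = []
    for phase in phases:
        cut = PHASE_ORDER[phase]
        reach = best.to_numpy() >= cut
        a = int((reach & supported).sum())
        b = int((~reach & supported).sum())
        c = int((reach & ~supported).sum())
        d = int((~reach & ~supported).sum())
        n_sup, n_unsup = a + b, c + d
        if n_sup == 0 or n_unsup == 0 or c == 0:
            rr = float("nan")
        else:
            rr = (a / n_sup) / (c / n_unsup)
        _, p = fisher_exact(ContingencyTable(a, b, c, d))
        rows.append((phase, a, b, c, d, rr, p))
    return pd.DataFrame(
        rows, columns=["PHASE", "A", "B", "C", "D", "RR", "PVAL"]
    )


@dataclass
class MoaPrediction:
    """Genetically predicted beneficial drug directionality for a gene-disease
    pair: "inhibition" (antagonist / inhibitor / degrader beneficial) or
    "activation" (agonist / activator beneficial)."""

    gene: str
    disease: str
    source: str  # "coding_variant" or "mr_consensus"
    predicted_beneficial_moa: str
    basis_sign: str  # "+" or "-"


def moa_direction_from_coding(
    gene: str,
    disease: str,
    beta: float,
    eaf: float,
    maf_limit: float = 0.05,
) -> MoaPrediction | None:
    """Directionality from a low-frequency lead coding variant.

    The variant is assumed disruptive (LoF); the effect is re-expressed for
    the minor allele. A risk-increasing minor allele implies activation would
    be beneficial; a protective one implies inhibition. Variants at or above
    the MAF limit, or with a null effect, yield no prediction.
    """
    maf = min(eaf, 1.0 - eaf)
    if maf >= maf_limit:
        return None
    beta_minor = beta if eaf <= 0.5 else -beta
    if beta_minor == 0:
        return None
    if beta_minor > 0:
        return MoaPrediction(gene, disease, "coding_variant", "activation", "+")
    return MoaPrediction(gene, disease, "coding_variant", "inhibition", "-")


def moa_direction_from_mr(
    gene: str,
    disease: str,
    mr_with_coloc: pd.DataFrame,
    h4_threshold: float = 0.8,
    q_threshold: float = 0.05,
    consensus_frac: float = 0.75,
) -> MoaPrediction | None:
    """Directionality from the MR consensus sign across colocalizing molQTL.

    Only datasets with MR q below ``q_threshold`` and PP_H4 strictly above
    ``h4_threshold`` qualify (columns QVAL, PP_H4, BETA). A consensus needs
    the same sign across strictly more than ``consensus_frac`` of qualifying
    datasets; a negative consensus (more expression, less risk) predicts
    activation, a positive one inhibition.
    """
    q = mr_with_coloc[
        (mr_with_coloc["QVAL"] < q_threshold)
        & (mr_with_coloc["PP_H4"] > h4_threshold)
        & (mr_with_coloc["BETA"] != 0)
    ]
    if q.empty:
        return None
    signs = np.sign(q["BETA"].to_numpy())
    frac_pos = float((signs > 0).mean())
    frac_neg = float((signs < 0).mean())
    if max(frac_pos, frac_neg) <= consensus_frac:
        return None
    if frac_neg > frac_pos:
        return MoaPrediction(gene, disease, "mr_consensus", "activation", "-")
    return MoaPrediction(gene, disease, "mr_consensus", "inhibition", "+")


@dataclass
class MoaConcordance:
    table: pd.DataFrame  # predicted x actual cross-tabulation
    concordance: float
    pvalue: float
    n_pairs: int
    n_excluded: int = 0


def classify_moa_keyword(moa: str) -> str | None:
    """Map a MoA keyword to its direction class, None if outside both."""
    kw = moa.strip().lower()
    if kw in INHIBITION_KEYWORDS:
        return "inhibition"
    if kw in ACTIVATION_KEYWORDS:
        return "activation"
    return None


def moa_concordance(
    joined: pd.DataFrame,
    min_phase: int = 2,
) -> MoaConcordance:
    """Concordance between predicted directionality and actual drug MoA.

    ``joined`` has one row per linked prediction-drug pair with columns
    PREDICTED ("inhibition"/"activation"), MOA (keyword) and PHASE. Drugs
    below ``min_phase`` or with keywords outside both direction classes are
    excluded, not counted discordant. The p-value is a Fisher exact test on
    the predicted x actual 2x2.
    """
    df = joined.copy()
    df["PHASE_NUM"] = df["PHASE"].map(PHASE_ORDER)
    df = df[df["PHASE_NUM"] >= min_phase]
    df["ACTUAL"] = df["MOA"].map(classify_moa_keyword)
    n_excluded = int(df["ACTUAL"].isna().sum())
    df = df.dropna(subset=["ACTUAL"])
    if df.empty:
        return MoaConcordance(pd.DataFrame(), float("nan"), 1.0, 0, n_excluded)
    classes = ["inhibition", "activation"]
    tab = pd.crosstab(df["PREDICTED"], df["ACTUAL"]).reindex(
        index=classes, columns=classes, fill_value=0
    )
    a, b = int(tab.iloc[0, 0]), int(tab.iloc[0, 1])
    c, d = int(tab.iloc[1, 0]), int(tab.iloc[1, 1])
    concordance = (a + d) / (a + b + c + d)
    _, p = fisher_exact(ContingencyTable(a, b, c, d))
    return MoaConcordance(tab, concordance, p, a + b + c + d, n_excluded)
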