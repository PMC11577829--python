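"""Translational analytics: Fisher exact arithmetic, contingency cubes,
ontology semantic similarity, drug linkage, phase risk ratios and MoA
directionality."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from locus2gene.translation import (
    ContingencyTable,
    OntologyGraph,
    build_cube,
    category_celltype_enrichment,
    classify_moa_keyword,
    clinical_phase_risk_ratios,
    evaluate_gold_standards,
    fisher_exact,
    gene_celltype_enrichment,
    gene_disease_category_enrichment,
    group_dataset_axis,
    link_genetics_to_drugs,
    moa_concordance,
    moa_direction_from_coding,
    moa_direction_from_mr,
    pairwise_similarity,
    semantic_similarity,
)


def _hypergeom_pvalues(a, b, c, d):
    """Enumeration oracle: exact hypergeometric tail sums."""
    n = a + b + c + d
    row, col = a + b, a + c
    rv = stats.hypergeom(n, col, row)
    lo, hi = max(0, row + col - n), min(row, col)
    pmf_a = rv.pmf(a)
    two = sum(rv.pmf(k) for k in range(lo, hi + 1) if rv.pmf(k) <= pmf_a * (1 + 1e-7))
    greater = sum(rv.pmf(k) for k in range(a, hi + 1))
    return min(two, 1.0), min(greater, 1.0)


class TestFisherExact:
    def test_perfect_separation_one_sided(self):
        # choosing the 5 successes out of 10 in one draw of 5: p = 1/252
        _, p = fisher_exact(ContingencyTable(5, 0, 0, 5), "greater")
        assert p == pytest.approx(1 / 252, rel=1e-12)

    def test_balanced_table_is_null(self):
        odds, p = fisher_exact(ContingencyTable(1, 1, 1, 1))
        assert odds == pytest.approx(1.0) and p == pytest.approx(1.0)

    def test_zero_margin_sentinel(self):
        odds, p = fisher_exact(ContingencyTable(0, 0, 3, 4))
        assert math.isnan(odds) and p == 1.0

    def test_haldane_correction_only_on_zero_cells(self):
        odds, _ = fisher_exact(ContingencyTable(3, 0, 1, 4))
        assert odds == pytest.approx((3.5 * 4.5) / (0.5 * 1.5))
        odds2, _ = fisher_exact(ContingencyTable(6, 2, 1, 4))
        assert odds2 == pytest.approx(24 / 2)

    def test_matches_hypergeometric_enumeration(self):
        """All tables with cells <= 5 (margins <= 10), both sidedness."""
        for a, b, c, d in itertools.product(range(6), repeat=4):
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            want_two, want_gr = _hypergeom_pvalues(a, b, c, d)
            _, got_two = fisher_exact(ContingencyTable(a, b, c, d), "two_sided")
            _, got_gr = fisher_exact(ContingencyTable(a, b, c, d), "greater")
            assert got_two == pytest.approx(want_two, abs=1e-9)
            assert got_gr == pytest.approx(want_gr, abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)
        with pytest.raises(ValueError):
            fisher_exact(ContingencyTable(1, 1, 1, 1), "less")


def _random_tidy(seed, n=60):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "DISEASE": rng.choice([f"d{i}" for i in range(5)], n),
            "GENE_ID": rng.choice([f"g{i}" for i in range(6)], n),
            "DATASET_ID": rng.choice([f"t{i}" for i in range(4)], n),
        }
    )


class TestCubes:
    def test_build_cube_indicator_semantics(self):
        df = _random_tidy(1)
        cube, dis, genes, ds = build_cube(df, ("DISEASE", "GENE_ID", "DATASET_ID"))
        seen = set(map(tuple, df.to_numpy()))
        for i, d in enumerate(dis):
            for j, g in enumerate(genes):
                for k, t in enumerate(ds):
                    assert cube[i, j, k] == ((d, g, t) in seen)

    def test_gene_celltype_against_cell_arithmetic_oracle(self):
        for seed in range(5):
            df = _random_tidy(seed)
            cube, dis, genes, ds = build_cube(df, ("DISEASE", "GENE_ID", "DATASET_ID"))
            out = gene_celltype_enrichment(cube, dis, genes, ds)
            total = int(cube.sum())
            for _, row in out.iterrows():
                j = genes.index(row["GENE_ID"])
                k = ds.index(row["DATASET_ID"])
                a = int(cube[:, j, k].sum())
                assert row["A"] == a
                assert row["B"] == int(cube[:, j, :].sum()) - a
                assert row["C"] == int(cube[:, :, k].sum()) - a
                assert row["D"] == total - int(cube[:, j, :].sum()) - int(cube[:, :, k].sum()) + a
                _, p = fisher_exact(
                    ContingencyTable(int(row["A"]), int(row["B"]), int(row["C"]), int(row["D"]))
                )
                assert row["PVAL"] == pytest.approx(p)

    def test_category_celltype_focal_axis_is_first(self):
        df = _random_tidy(11).rename(columns={"DISEASE": "CATEGORY"})
        cube, cats, genes, ds = build_cube(df, ("CATEGORY", "GENE_ID", "DATASET_ID"))
        out = category_celltype_enrichment(cube, cats, genes, ds)
        total = int(cube.sum())
        for _, row in out.iterrows():
            i = cats.index(row["CATEGORY"])
            k = ds.index(row["DATASET_ID"])
            a = int(cube[i, :, k].sum())
            assert row["A"] == a
            assert row["B"] == int(cube[i, :, :].sum()) - a

    def test_gene_disease_category_rows_skip_unused_genes(self):
        df = _random_tidy(12).rename(columns={"DATASET_ID": "CATEGORY"})
        cube, gwas, genes, cats = build_cube(df, ("DISEASE", "GENE_ID", "CATEGORY"))
        cube[:, 2, :] = False  # gene g2 never prioritized
        out = gene_disease_category_enrichment(cube, gwas, genes, cats)
        assert genes[2] not in set(out["GENE_ID"])

    def test_qvalues_are_bh_of_pvalues(self):
        df = _random_tidy(13)
        cube, dis, genes, ds = build_cube(df, ("DISEASE", "GENE_ID", "DATASET_ID"))
        out = gene_celltype_enrichment(cube, dis, genes, ds)
        p = out["PVAL"].to_numpy()
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        q_sorted = p[order] * m / (np.arange(m) + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        want = np.empty(m)
        want[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(out["QVAL"].to_numpy(), want)

    def test_group_dataset_axis_is_logical_or(self):
        df = _random_tidy(14)
        cube, dis, genes, ds = build_cube(df, ("DISEASE", "GENE_ID", "DATASET_ID"))
        grouping = {"t0": "blood", "t1": "blood", "t2": "brain", "t3": "brain"}
        out, groups = group_dataset_axis(cube, ds, grouping)
        assert groups == ["blood", "brain"]
        assert np.array_equal(out[:, :, 0], cube[:, :, 0] | cube[:, :, 1])
        assert np.array_equal(out[:, :, 1], cube[:, :, 2] | cube[:, :, 3])


# Hand-worked 7-term DAG:
#          R
#        /   \
#       A     B
#      / \     \
#    A1   A2    B1
#    |
#   A1a
EDGES = [("A", "R"), ("B", "R"), ("A1", "A"), ("A2", "A"), ("B1", "B"), ("A1a", "A1")]
USAGE = {"A1": 2, "A2": 1, "B1": 1}


@pytest.fixture(scope="module")
def ontology():
    return OntologyGraph(EDGES, USAGE)


class TestOntology:
    def test_information_content_hand_worked(self, ontology):
        # cumulative usage: A1=2, A=3, R=4 of total 4
        assert ontology.ic("A1") == pytest.approx(math.log(2))
        assert ontology.ic("A") == pytest.approx(-math.log(3 / 4))
        assert ontology.ic("R") == 0.0
        assert math.isinf(ontology.ic("A1a"))  # never used

    def test_sibling_similarity_hand_worked(self, ontology):
        # MICA of A1, A2 is A; max IC in the DAG is log 4 (A2 / B1)
        mica = -math.log(3 / 4)
        resnik = mica / math.log(4)
        lin = 2 * mica / (math.log(2) + math.log(4))
        want = 0.5 * (resnik + lin)
        assert semantic_similarity("A1", "A2", ontology) == pytest.approx(want)

    def test_identical_terms_score_one(self, ontology):
        assert semantic_similarity("A2", "A2", ontology) == pytest.approx(1.0)

    def test_root_only_common_ancestor_scores_zero(self, ontology):
        assert semantic_similarity("A1", "B1", ontology) == 0.0

    def test_similarity_is_symmetric(self, ontology):
        for a, b in itertools.combinations(["A1", "A2", "B1", "A"], 2):
            assert semantic_similarity(a, b, ontology) == pytest.approx(
                semantic_similarity(b, a, ontology)
            )

    def test_standardized_self_similarity_is_one(self, ontology):
        sim = pairwise_similarity(["A1", "B1"], ["A1", "A2", "B1"], ontology)
        assert sim.loc["A1", "A1"] == pytest.approx(1.0)
        assert sim.loc["B1", "B1"] == pytest.approx(1.0)

    def test_multiple_roots_rejected(self):
        with pytest.raises(ValueError, match="root"):
            OntologyGraph([("A", "R1"), ("B", "R2")])

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            OntologyGraph([("A", "B"), ("B", "A")])


def _prioritized(rows):
    return pd.DataFrame(rows, columns=["GENE_ID", "EFO_ID", "GWAS_ID", "LEAD_PVAL"])


class TestDrugLinkage:
    def test_threshold_is_inclusive_boundary(self, ontology):
        prior = _prioritized([("G1", "A1", "S1", 1e-9)])
        drugs = pd.DataFrame({"TARGET_GENE": ["G1"], "INDICATION_EFO": ["A2"]})
        sim = pairwise_similarity(["A1"], ["A2"], ontology).loc["A1", "A2"]
        linked = link_genetics_to_drugs(prior, drugs, ontology, threshold=sim)
        assert len(linked) == 1
        not_linked = link_genetics_to_drugs(prior, drugs, ontology, threshold=sim + 1e-9)
        assert not_linked.empty

    def test_best_supporting_gwas_kept(self, ontology):
        prior = _prioritized(
            [("G1", "A1", "S_weak", 1e-8), ("G1", "A1", "S_strong", 1e-12)]
        )
        drugs = pd.DataFrame({"TARGET_GENE": ["G1"], "INDICATION_EFO": ["A1"]})
        linked = link_genetics_to_drugs(prior, drugs, ontology, threshold=0.7)
        assert linked.iloc[0]["GWAS_ID"] == "S_strong"
        assert linked.iloc[0]["LEAD_PVAL"] == 1e-12

    def test_cancer_indications_excluded_with_descendants(self, ontology):
        prior = _prioritized([("G1", "A1", "S1", 1e-9), ("G1", "B1", "S1", 1e-9)])
        drugs = pd.DataFrame(
            {"TARGET_GENE": ["G1", "G1"], "INDICATION_EFO": ["A1", "B1"]}
        )
        linked = link_genetics_to_drugs(
            prior, drugs, ontology, threshold=0.7, cancer_terms={"B"}
        )
        assert set(linked["INDICATION_EFO"]) == {"A1"}


class TestPhaseRiskRatios:
    def test_hand_worked_risk_ratio(self):
        # supported: 2 pairs, 1 reaching phase >= 2 (P = 0.5)
        # unsupported: 8 pairs, 1 reaching phase >= 2 (P = 0.125) -> RR = 4
        rows = [("G1", "d1", "2"), ("G2", "d1", "1")]
        rows += [(f"U{i}", "d1", "1") for i in range(7)] + [("U7b", "d1", "2")]
        drugs = pd.DataFrame(rows, columns=["TARGET_GENE", "INDICATION_EFO", "PHASE"])
        supported = {("G1", "d1"), ("G2", "d1")}
        out = clinical_phase_risk_ratios(drugs, supported).set_index("PHASE")
        assert out.loc["2", "RR"] == pytest.approx(4.0)
        assert out.loc["1", "RR"] == pytest.approx(1.0)  # everyone reaches phase 1

    def test_max_phase_per_pair(self):
        drugs = pd.DataFrame(
            [("G1", "d1", "1"), ("G1", "d1", "approved")],
            columns=["TARGET_GENE", "INDICATION_EFO", "PHASE"],
        )
        out = clinical_phase_risk_ratios(drugs, set()).set_index("PHASE")
        assert out.loc["approved", "C"] == 1  # the pair counts once, at its max

    def test_empty_stratum_gives_nan(self):
        drugs = pd.DataFrame(
            [("G1", "d1", "2")], columns=["TARGET_GENE", "INDICATION_EFO", "PHASE"]
        )
        out = clinical_phase_risk_ratios(drugs, {("G1", "d1")})
        assert out["RR"].isna().all()  # no unsupported pairs

    def test_unknown_phase_rejected(self):
        drugs = pd.DataFrame(
            [("G1", "d1", "phase IV")], columns=["TARGET_GENE", "INDICATION_EFO", "PHASE"]
        )
        with pytest.raises(ValueError):
            clinical_phase_risk_ratios(drugs, set())


class TestGoldStandards:
    def test_hand_worked_precision_recall(self):
        candidates = pd.DataFrame(
            {
                "GWAS_ID": ["S"] * 4,
                "EFO_ID": ["d1"] * 4,
                "LOCUS_ID": ["L1"] * 4,
                "GENE_ID": ["GOLD", "GX", "GY", "GZ"],
                "LEAD_PVAL": [1e-10] * 4,
                "PICK": [True, True, False, False],
            }
        )
        gold = pd.DataFrame({"GENE_ID": ["GOLD"], "EFO_ID": ["d1"]})
        out = evaluate_gold_standards(
            candidates, gold, {"pick": lambda df: df["PICK"]}
        ).iloc[0]
        assert out["PRECISION"] == pytest.approx(0.5)
        assert out["RECALL"] == pytest.approx(1.0)
        assert out["F1"] == pytest.approx(2 / 3)

    def test_subsignificant_loci_excluded(self):
        candidates = pd.DataFrame(
            {
                "GWAS_ID": ["S", "S"],
                "EFO_ID": ["d1", "d1"],
                "LOCUS_ID": ["L1", "L2"],
                "GENE_ID": ["GOLD", "GOLD"],
                "LEAD_PVAL": [1e-10, 1e-7],  # L2 below genome-wide significance
            }
        )
        gold = pd.DataFrame({"GENE_ID": ["GOLD"], "EFO_ID": ["d1"]})
        out = evaluate_gold_standards(
            candidates, gold, {"all": lambda df: pd.Series(True, index=df.index)}
        ).iloc[0]
        assert out["A"] + out["B"] + out["C"] + out["D"] == 1

    def test_loci_without_gold_gene_excluded_from_universe(self):
        candidates = pd.DataFrame(
            {
                "GWAS_ID": ["S"] * 3,
                "EFO_ID": ["d1"] * 3,
                "LOCUS_ID": ["L1", "L1", "L2"],
                "GENE_ID": ["GOLD", "GX", "GY"],
                "LEAD_PVAL": [1e-10] * 3,
            }
        )
        gold = pd.DataFrame({"GENE_ID": ["GOLD"], "EFO_ID": ["d1"]})
        out = evaluate_gold_standards(
            candidates, gold, {"all": lambda df: pd.Series(True, index=df.index)}
        ).iloc[0]
        assert out["A"] + out["B"] == 2  # GY's locus has no gold gene


class TestMoaDirection:
    def test_common_variant_yields_no_prediction(self):
        assert moa_direction_from_coding("G", "d", 0.4, 0.10) is None

    def test_rare_risk_minor_allele_predicts_activation(self):
        pred = moa_direction_from_coding("G", "d", 0.4, 0.02)
        assert pred.predicted_beneficial_moa == "activation"

    def test_effect_reexpressed_for_minor_allele(self):
        # EAF 0.98: the minor allele is the other allele, so beta flips
        pred = moa_direction_from_coding("G", "d", 0.4, 0.98)
        assert pred.predicted_beneficial_moa == "inhibition"

    def test_sign_negation_flips_prediction(self):
        a = moa_direction_from_coding("G", "d", 0.4, 0.02)
        b = moa_direction_from_coding("G", "d", -0.4, 0.02)
        assert {a.predicted_beneficial_moa, b.predicted_beneficial_moa} == {
            "activation",
            "inhibition",
        }

    @staticmethod
    def _mr_frame(betas, q=0.01, h4=0.95):
        return pd.DataFrame({"BETA": betas, "QVAL": q, "PP_H4": h4})

    def test_three_of_four_is_no_consensus(self):
        out = moa_direction_from_mr("G", "d", self._mr_frame([-1, -1, -1, 1.0]))
        assert out is None  # 0.75 is not strictly above 0.75

    def test_four_of_five_negative_predicts_activation(self):
        out = moa_direction_from_mr("G", "d", self._mr_frame([-1, -1, -1, -1, 1.0]))
        assert out.predicted_beneficial_moa == "activation"

    def test_single_positive_dataset_predicts_inhibition(self):
        out = moa_direction_from_mr("G", "d", self._mr_frame([0.3]))
        assert out.predicted_beneficial_moa == "inhibition"

    def test_unqualified_rows_ignored(self):
        df = pd.DataFrame(
            {
                "BETA": [0.3, -1.0, -1.0],
                "QVAL": [0.01, 0.50, 0.01],   # second fails FDR
                "PP_H4": [0.95, 0.95, 0.50],  # third fails coloc
            }
        )
        out = moa_direction_from_mr("G", "d", df)
        assert out.predicted_beneficial_moa == "inhibition"

    def test_mr_sign_negation_equivariance(self):
        betas = [-0.4, -0.2, -0.5, -0.3, 0.1]
        a = moa_direction_from_mr("G", "d", self._mr_frame(betas))
        b = moa_direction_from_mr("G", "d", self._mr_frame([-x for x in betas]))
        assert a.predicted_beneficial_moa != b.predicted_beneficial_moa


class TestMoaConcordance:
    def test_keyword_classes(self):
        assert classify_moa_keyword("Inhibitor") == "inhibition"
        assert classify_moa_keyword("agonist") == "activation"
        assert classify_moa_keyword("degrader") == "inhibition"
        assert classify_moa_keyword("modulator") is None

    def test_perfectly_concordant_pairs(self):
        joined = pd.DataFrame(
            {
                "PREDICTED": ["inhibition", "activation", "inhibition"],
                "MOA": ["inhibitor", "agonist", "antagonist"],
                "PHASE": ["2", "3", "approved"],
            }
        )
        out = moa_concordance(joined)
        assert out.concordance == pytest.approx(1.0)
        assert out.n_pairs == 3 and out.n_excluded == 0

    def test_unknown_keywords_excluded_not_discordant(self):
        joined = pd.DataFrame(
            {
                "PREDICTED": ["inhibition", "inhibition"],
                "MOA": ["inhibitor", "modulator"],
                "PHASE": ["2", "2"],
            }
        )
        out = moa_concordance(joined)
        assert out.concordance == pytest.approx(1.0)
        assert out.n_pairs == 1 and out.n_excluded == 1

    def test_early_phase_drugs_dropped(self):
        joined = pd.DataFrame(
            {
                "PREDICTED": ["inhibition", "activation"],
                "MOA": ["inhibitor", "inhibitor"],
                "PHASE": ["2", "1"],  # the discordant pair is pre-phase-2
            }
        )
        out = moa_concordance(joined, min_phase=2)
        assert out.concordance == pytest.approx(1.0)
        assert out.n_pairs == 1
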