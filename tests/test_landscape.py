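"""Cohort landscape statistics: loads, spectrum, frequencies, tests, tiers."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hnsomatic.landscape import (
    CohortTable, KBRule, KnowledgeBase, annotate_actionability, bh_fdr,
    cnv_frequency, default_knowledge_base, default_pathway_map,
    export_landscape, gene_frequency, mutation_spectrum, mutual_exclusivity,
    pathway_alteration_frequency, proportion_test_cc, summarize_mutation_load,
    wilcoxon_rank_sum, PathwayMap,
)

# Frozen statistics oracle values (closed-form evaluation, cross-checked
# against R prop.test / fisher.test before freezing).
YATES_9_83_VS_4_207 = 2.693361401135e-03
KSAMPLE_TP53_P = 5.401150203279e-18
FISHER_0_20_9_54 = 1.052700246706e-01


def build_table(n_samples, mutated=(), cnvs=(), fusions=(), msi=(),
                site="larynx", sites=None):
    """Indicator-level cohort table: 'mutated' etc. name (sample idx, gene)."""
    ids = [f"S{i:03d}" for i in range(n_samples)]
    if sites is None:
        sites = [site] * n_samples
    samples = pd.DataFrame({"sample_id": ids, "anatomic_site": sites})
    variants = pd.DataFrame(
        [{"sample_id": ids[i], "gene": g, "variant_class": "missense",
          "ref": "C", "alt": "T"} for i, g in mutated],
        columns=["sample_id", "gene", "variant_class", "ref", "alt"])
    cnv_df = pd.DataFrame(
        [{"sample_id": ids[i], "gene": g, "cnv_type": t} for i, g, t in cnvs],
        columns=["sample_id", "gene", "cnv_type"])
    fus_df = pd.DataFrame(
        [{"sample_id": ids[i], "gene5": a, "gene3": b} for i, a, b in fusions],
        columns=["sample_id", "gene5", "gene3"])
    return CohortTable(samples=samples, variants=variants, cnvs=cnv_df,
                       fusions=fus_df, msi={ids[i]: s for i, s in msi})


class TestMutationLoad:
    def test_cohort_totals_from_snv_and_indel_records(self):
        rows = (
            [{"sample_id": "S000", "gene": "TP53", "variant_class": "missense",
              "ref": "C", "alt": "T"}] * 1864
            + [{"sample_id": "S000", "gene": "TP53",
                "variant_class": "frameshift_del", "ref": "CA", "alt": "C"}] * 292
        )
        table = build_table(1)
        table.variants = pd.DataFrame(rows)
        load = summarize_mutation_load(table)
        assert load["n_snv"] == 1864
        assert load["n_indel"] == 292
        assert load["n_total"] == 2156

    def test_mean_and_median_of_two_samples(self):
        mutated = [(0, f"G{k}") for k in range(3)] + [(1, f"G{k}") for k in range(7)]
        load = summarize_mutation_load(build_table(2, mutated))
        site = load["per_site"].loc["larynx"]
        assert site["mean"] == 5 and site["median"] == 5

    def test_empty_sample_included_in_median(self):
        mutated = [(0, "A"), (0, "B"), (1, "C")]
        load = summarize_mutation_load(build_table(3, mutated))
        assert list(load["per_sample"]) == [2, 1, 0]
        assert load["per_site"].loc["larynx", "median"] == 1


class TestSpectrum:
    def test_purine_substitution_complemented(self):
        table = build_table(1)
        table.variants = pd.DataFrame([
            {"sample_id": "S000", "gene": "X", "variant_class": "missense",
             "ref": "G", "alt": "A"}])
        assert mutation_spectrum(table)["C>T"] == 1.0

    def test_fraction_arithmetic(self):
        rows = [{"sample_id": "S000", "gene": "X", "variant_class": "missense",
                 "ref": "C", "alt": "T"}] * 42
        for ref, alt, k in [("C", "A", 20), ("C", "G", 10), ("T", "A", 10),
                            ("T", "C", 10), ("T", "G", 8)]:
            rows += [{"sample_id": "S000", "gene": "X",
                      "variant_class": "missense", "ref": ref, "alt": alt}] * k
        table = build_table(1)
        table.variants = pd.DataFrame(rows)
        assert mutation_spectrum(table)["C>T"] == pytest.approx(0.42)

    def test_uniform_input_uniform_output(self):
        rows = []
        for ref, alt in [("C", "A"), ("C", "G"), ("C", "T"),
                         ("T", "A"), ("T", "C"), ("T", "G")]:
            rows.append({"sample_id": "S000", "gene": "X",
                         "variant_class": "missense", "ref": ref, "alt": alt})
        table = build_table(1)
        table.variants = pd.DataFrame(rows)
        assert all(v == pytest.approx(1 / 6) for v in mutation_spectrum(table).values())


class TestFrequencies:
    def test_cyld_npc_frequency(self):
        table = build_table(83, [(i, "CYLD") for i in range(9)], site="nasopharynx")
        assert gene_frequency(table, "CYLD", "nasopharynx") == (9, 83, 10.8)

    def test_cyld_other_sites_frequency(self):
        table = build_table(207, [(i, "CYLD") for i in range(4)])
        assert gene_frequency(table, "CYLD") == (4, 207, 1.9)

    def test_unknown_gene_zero(self):
        table = build_table(50)
        assert gene_frequency(table, "NOSUCH") == (0, 50, 0.0)

    def test_sample_with_two_mutations_counted_once(self):
        table = build_table(10, [(0, "TP53"), (0, "TP53")])
        assert gene_frequency(table, "TP53")[0] == 1

    def test_ccnd1_cnv_frequency(self):
        cnvs = [(i, "CCND1", "gain") for i in range(80)] + [(80, "CCND1", "loss")]
        table = build_table(317, cnvs=cnvs)
        assert cnv_frequency(table, "CCND1") == (81, 80, 1, 25.6)

    def test_cdkn2a_cnv_frequency(self):
        cnvs = [(i, "CDKN2A", "gain") for i in range(3)] + [
            (3 + i, "CDKN2A", "loss") for i in range(74)]
        table = build_table(317, cnvs=cnvs)
        assert cnv_frequency(table, "CDKN2A") == (77, 3, 74, 24.3)

    def test_no_cnv_records(self):
        table = build_table(10)
        assert cnv_frequency(table, "CCND1") == (0, 0, 0, 0.0)


class TestProportionTest:
    def test_identical_proportions_p_one(self):
        assert proportion_test_cc([5, 5], [100, 100]) == pytest.approx(1.0)

    def test_two_sample_yates_matches_closed_form(self):
        assert proportion_test_cc([9, 4], [83, 207]) == pytest.approx(
            YATES_9_83_VS_4_207, abs=1e-12)

    def test_k_sample_matches_closed_form(self):
        assert proportion_test_cc([31, 54, 20, 78], [36, 60, 83, 111]) == pytest.approx(
            KSAMPLE_TP53_P, rel=1e-9)

    def test_group_order_invariance(self):
        p1 = proportion_test_cc([9, 4], [83, 207])
        p2 = proportion_test_cc([4, 9], [207, 83])
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_zero_size_group_raises(self):
        with pytest.raises(ValueError):
            proportion_test_cc([0, 1], [0, 10])


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.037]) == pytest.approx([0.037])

    def test_hand_evaluated_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_empty_vector(self):
        assert len(bh_fdr([])) == 0

    def test_monotone_in_order_statistics(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=20)
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12)


class TestWilcoxon:
    def test_extreme_separation_exact_enumeration(self):
        # most extreme labeling among C(6,3) = 20 -> two-sided p = 2/20
        assert wilcoxon_rank_sum([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        assert wilcoxon_rank_sum([5, 5, 5, 5], [5, 5, 5, 5]) >= 0.99

    def test_order_invariance(self):
        a = [3.0, 9.0, 1.0, 7.0]
        b = [2.0, 8.0, 4.0]
        assert wilcoxon_rank_sum(a, b) == pytest.approx(
            wilcoxon_rank_sum(a[::-1], b[::-1]))

    def test_exact_matches_full_enumeration(self):
        a = [0.3, 2.1, 3.7, 5.2]
        b = [1.1, 4.4, 6.6]
        pooled = sorted(a + b)
        ranks = {v: i + 1 for i, v in enumerate(pooled)}
        obs = sum(ranks[v] for v in a)
        n = len(a)
        stats = [sum(combo) for combo in itertools.combinations(
            [ranks[v] for v in pooled], n)]
        mean = np.mean(stats)
        extreme = sum(1 for s in stats if abs(s - mean) >= abs(obs - mean) - 1e-9)
        expected = extreme / len(stats)
        assert wilcoxon_rank_sum(a, b) == pytest.approx(expected, rel=1e-9)


class TestMutualExclusivity:
    def test_npc_fixture_matches_hypergeometric_oracle(self):
        mutated = [(i, "TP53") for i in range(20)] + [
            (20 + i, "CYLD") for i in range(9)]
        table = build_table(83, mutated, site="nasopharynx")
        overlap, p = mutual_exclusivity(table, "TP53", "CYLD", "nasopharynx")
        assert overlap == 0
        assert p == pytest.approx(FISHER_0_20_9_54, rel=1e-9)

    def test_symmetric_in_gene_order(self):
        mutated = [(0, "A"), (1, "A"), (1, "B"), (2, "B"), (3, "A")]
        table = build_table(10, mutated)
        assert mutual_exclusivity(table, "A", "B") == mutual_exclusivity(table, "B", "A")

    def test_identical_sets_cooccurrence(self):
        mutated = [(i, g) for i in range(5) for g in ("A", "B")]
        table = build_table(30, mutated)
        overlap, p = mutual_exclusivity(table, "A", "B")
        assert overlap == 5
        assert p < 0.01

    def test_absent_gene(self):
        table = build_table(4, [(0, "A")])
        overlap, p = mutual_exclusivity(table, "NOPE", "ALSO_NOPE")
        assert overlap == 0
        assert p == pytest.approx(1.0)


class TestPathways:
    def test_cell_cycle_percentage(self):
        mutated = [(i, "TP53") for i in range(50)] + [(i, "CDKN2A") for i in range(50, 80)]
        cnvs = [(i, "CCND1", "gain") for i in range(80, 97)]
        table = build_table(100, mutated, cnvs=cnvs)
        out = pathway_alteration_frequency(table, default_pathway_map())
        assert out["cell_cycle"]["pathway_pct"] == 97

    def test_two_alterations_one_pathway_counted_once(self):
        table = build_table(10, [(0, "TP53"), (0, "CDKN2A")])
        out = pathway_alteration_frequency(table, default_pathway_map())
        assert out["cell_cycle"]["altered_samples"] == 1

    def test_empty_pathway_zero(self):
        table = build_table(10, [(0, "TP53")])
        pmap = PathwayMap({"custom": {"UNSEEN_GENE": "oncogene"}})
        out = pathway_alteration_frequency(table, pmap)
        assert out["custom"]["pathway_pct"] == 0


class TestActionability:
    def test_ntrk2_fusion_is_level_1(self):
        table = build_table(3, fusions=[(0, "TEX10", "NTRK2")])
        out = annotate_actionability(table)
        assert out["per_sample_level"]["S000"] == "1"

    def test_msi_high_is_level_1(self):
        table = build_table(3, msi=[(1, "MSI-H")])
        out = annotate_actionability(table)
        assert out["per_sample_level"]["S001"] == "1"

    def test_unmatched_sample_has_no_level(self):
        table = build_table(2, [(0, "GENE_NOT_IN_KB")])
        out = annotate_actionability(table)
        assert out["per_sample_level"]["S000"] is None
        assert out["n_actionable"] == 0

    def test_cohort_fixture_fractions(self):
        # 141/317 actionable (CDKN2A deletions), 271/317 with >= 1 oncogenic
        cnvs = [(i, "CDKN2A", "loss") for i in range(141)]
        mutated = [(i, "TP53") for i in range(141, 271)]
        table = build_table(317, mutated, cnvs=cnvs)
        out = annotate_actionability(table)
        assert (out["n_actionable"], out["actionable_pct"]) == (141, 44.5)
        assert (out["n_oncogenic"], out["oncogenic_pct"]) == (271, 85.5)

    def test_highest_priority_level_wins(self):
        table = build_table(1, [(0, "PIK3CA")], fusions=[(0, "TEX10", "NTRK2")])
        out = annotate_actionability(table)
        assert out["per_sample_level"]["S000"] == "1"

    def test_malformed_rule_rejected(self):
        with pytest.raises(ValueError):
            KBRule("TP53", "snv_indel", "5")
        with pytest.raises(ValueError):
            KBRule("TP53", "weird_type", "1")


class TestExport:
    def test_matrix_sorted_by_recurrence_then_alphabetical(self, tmp_path):
        mutated = [(0, "BBB"), (1, "BBB"), (0, "AAA"), (1, "AAA"), (2, "CCC")]
        table = build_table(3, mutated)
        export_landscape(table, tmp_path)
        freq = pd.read_csv(tmp_path / "gene_frequencies.tsv", sep="\t")
        assert list(freq["gene"]) == ["AAA", "BBB", "CCC"]

    def test_empty_table_writes_headers(self, tmp_path):
        table = build_table(0)
        export_landscape(table, tmp_path)
        maf = pd.read_csv(tmp_path / "variants.maf.tsv", sep="\t")
        assert list(maf.columns) == ["sample_id", "gene", "variant_class",
                                     "ref", "alt"]
        assert maf.empty


class TestValidation:
    def test_unknown_variant_class_rejected(self):
        table = build_table(2)
        bad = pd.DataFrame([
            {"sample_id": "S000", "gene": "X", "variant_class": "weird",
             "ref": "C", "alt": "T"}])
        with pytest.raises(ValueError, match="variant class"):
            CohortTable(samples=table.samples, variants=bad,
                        cnvs=table.cnvs, fusions=table.fusions)

    def test_orphan_sample_rejected(self):
        table = build_table(2)
        orphan = pd.DataFrame([
            {"sample_id": "GHOST", "gene": "X", "variant_class": "missense",
             "ref": "C", "alt": "T"}])
        with pytest.raises(ValueError, match="missing"):
            CohortTable(samples=table.samples, variants=orphan,
                        cnvs=table.cnvs, fusions=table.fusions)
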