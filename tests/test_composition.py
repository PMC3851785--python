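"""GC metrics, RSCU/CAI closed forms, ANOVA+Tukey calibration and oracles,
strata classification, contig screen, genome summaries."""

import math

import numpy as np
import pytest
from scipy import stats

from genomedecay import composition as C
from genomedecay.seqio import GeneFeature, GenomeRecord
from genomedecay.synthetic_data import simulate_contig_profiles


class TestGCMetrics:
    def test_gc_percent_counts_n_as_non_gc(self):
        assert C.gc_percent("ATGC") == 50.0
        assert C.gc_percent("GGNN") == 50.0
        assert C.gc_percent("") == 0.0

    def test_gc2_uses_second_codon_positions(self):
        assert C.gc2("ATGAAA") == 0.0          # T, A
        assert C.gc2("AGGACG") == 100.0        # G, C

    def test_gc4_uses_fourfold_families_only(self):
        assert C.gc4("GCTGCG") == 50.0         # two GCN codons, thirds T and G
        # AAA (Lys) is not fourfold-degenerate: contributes nothing
        assert C.gc4("AAAGCG") == 100.0

    def test_frame_errors(self):
        for fn in (C.gc2, C.gc3, C.gc4):
            with pytest.raises(ValueError):
                fn("ATGA")

    def test_gc_metrics_agree_on_annotated_strand(self, small_pair):
        genome = small_pair["genome_a"]
        for f in genome.cds_features()[:5]:
            cds = f.sequence(genome)
            cds = cds[:3 * (len(cds) // 3)]
            # reverse-complementing the genome and flipping the strand
            # reproduces the same reading-frame metrics
            from Bio.Seq import Seq
            rc = str(Seq(cds).reverse_complement())
            rc_back = str(Seq(rc).reverse_complement())
            assert C.gc2(cds) == C.gc2(rc_back)
            assert C.gc4(cds) == C.gc4(rc_back)


class TestRSCUandCAI:
    def test_uniform_usage_gives_unit_rscu_and_cai(self):
        # one gene using every sense codon exactly once
        gene = "".join(c for c in C.CODONS if c not in ("TAA", "TAG", "TGA"))
        table = C.rscu([gene])
        for fam in C.FAMILIES.values():
            for c in fam:
                assert table.rscu[c] == pytest.approx(1.0)
                assert table.w[c] == pytest.approx(1.0)
        assert C.cai(gene, table) == pytest.approx(1.0)

    def test_two_codon_family_closed_form(self):
        # GAA x30 + GAG x10: RSCU 1.5/0.5, w 1/0.3333; CAI of one each = sqrt(1/3)
        ref = ["GAA" * 30 + "GAG" * 10]
        table = C.rscu(ref)
        assert table.rscu["GAA"] == pytest.approx(1.5)
        assert table.rscu["GAG"] == pytest.approx(0.5)
        assert table.w["GAA"] == pytest.approx(1.0)
        assert table.w["GAG"] == pytest.approx(1 / 3)
        assert C.cai("GAAGAG", table) == pytest.approx(math.sqrt(1 / 3))

    def test_family_maximal_codons_give_cai_one(self):
        ref = ["GAA" * 30 + "GAG" * 10]
        table = C.rscu(ref)
        assert C.cai("GAA" * 7, table) == pytest.approx(1.0)

    def test_cai_invariant_under_gene_duplication(self, small_pair):
        genome = small_pair["genome_a"]
        genes = []
        for f in genome.cds_features()[:10]:
            s = f.sequence(genome)
            genes.append(s[:3 * (len(s) // 3)])
        table = C.rscu(genes)
        g = genes[0]
        assert C.cai(g + g, table) == pytest.approx(C.cai(g, table))

    def test_rscu_family_means_are_one_for_observed_families(self, small_pair):
        genome = small_pair["genome_a"]
        genes = [f.sequence(genome) for f in genome.cds_features()]
        table = C.rscu([g[:3 * (len(g) // 3)] for g in genes])
        for fam in C.FAMILIES.values():
            if all(table.counts[c] > 0.5 for c in fam):  # fully observed family
                assert np.mean([table.rscu[c] for c in fam]) == pytest.approx(1.0)

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            C.rscu([])


class TestAnovaTukey:
    def test_matches_statsmodels_and_scipy_oracles(self):
        """Adjusted p-values agree with two independent implementations to 1e-6
        on 20 random balanced and unbalanced datasets."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        for seed in range(20):
            rng = np.random.default_rng(seed)
            k = int(rng.integers(3, 6))
            groups = {}
            values, labels = [], []
            for i in range(k):
                n = int(rng.integers(5, 30))
                g = rng.normal(rng.uniform(-1, 1), 1.0, n)
                groups[f"g{i}"] = g
                values.extend(g)
                labels.extend([f"g{i}"] * n)
            res = C.group_anova_tukey(groups)
            sm = pairwise_tukeyhsd(np.array(values), np.array(labels))
            ours = res.comparisons.sort_values(["group_i", "group_j"])["p_adj"].values
            assert np.allclose(ours, sm.pvalues, atol=1e-6)
            if len({len(g) for g in groups.values()}) == 1:
                sp = stats.tukey_hsd(*groups.values())
                names = sorted(groups)
                for row in res.comparisons.itertuples():
                    i, j = names.index(row.group_i), names.index(row.group_j)
                    assert row.p_adj == pytest.approx(sp.pvalue[i, j], abs=1e-6)

    def test_identical_distributions_rarely_reject(self):
        rejections = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            groups = {"a": rng.normal(0, 1, 40), "b": rng.normal(0, 1, 40)}
            res = C.group_anova_tukey(groups)
            rejections += res.anova_p < 0.05
        assert rejections <= 1  # >= 9/10 seeds accept the null

    def test_large_separation_is_detected_with_certainty(self):
        rng = np.random.default_rng(0)
        groups = {"hi": rng.normal(40, 1, 50), "lo": rng.normal(25, 1, 50)}
        res = C.group_anova_tukey(groups)
        assert res.comparisons["p_adj"].iloc[0] < 1e-6

    def test_three_equal_mean_groups_match_oracle_near_one(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        rng = np.random.default_rng(7)
        groups = {f"g{i}": rng.normal(5, 1, 30) for i in range(3)}
        res = C.group_anova_tukey(groups)
        values = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), [30, 30, 30])
        sm = pairwise_tukeyhsd(values, labels)
        assert np.allclose(res.comparisons["p_adj"].values, sm.pvalues, atol=1e-6)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            C.group_anova_tukey({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            C.group_anova_tukey({"a": [1.0, 2.0], "b": [3.0]})
        with pytest.raises(ValueError):
            C.group_anova_tukey({"a": [1.0, 1.0], "b": [1.0, 1.0]})


class TestStrata:
    @staticmethod
    def _strata(seed, coding=41.0, pseudo=33.0, inter=25.0, n=25, sd=3.0):
        rng = np.random.default_rng(seed)
        return {
            "coding": {"L2": list(rng.normal(coding, sd, n)),
                       "L5": list(rng.normal(coding, sd, n))},
            "pseudogene": {"L2": list(rng.normal(pseudo, sd, n)),
                           "L5": list(rng.normal(pseudo, sd, n))},
            "intergenic": {"L2": list(rng.normal(inter, sd, n)),
                           "L5": list(rng.normal(inter, sd, n))},
        }

    def test_distinct_strata_all_significant_with_expected_ordering(self):
        stage1, stage2 = C.classify_gc_strata(self._strata(0))
        assert set(stage2.comparisons["p_adj"] < 0.05) == {True}
        means = {}
        for g, vals in (("coding", 41), ("pseudogene", 33), ("intergenic", 25)):
            means[g] = vals
        for row in stage2.comparisons.itertuples():
            sign = means[row.group_j] - means[row.group_i]
            assert np.sign(row.mean_diff) == np.sign(sign)

    def test_single_distribution_merges_without_significance(self):
        strata = self._strata(1, coding=30.0, pseudo=30.0, inter=30.0)
        _, stage2 = C.classify_gc_strata(strata)
        assert set(stage2.comparisons["group_i"]) | set(stage2.comparisons["group_j"]) \
            == {"coding", "pseudogene", "intergenic"}  # merged labels
        assert not (stage2.comparisons["p_adj"] < 0.01).any()

    def test_single_member_group_propagates_anova_error(self):
        strata = self._strata(2)
        strata["pseudogene"] = {"L2": [33.0]}
        with pytest.raises(ValueError):
            C.classify_gc_strata(strata)


class TestContigScreen:
    def test_shifted_contig_is_flagged_exactly(self):
        prof = simulate_contig_profiles(seed=3, shifted_contig="Contig9")
        flagged, results = C.contig_screen(prof)
        assert flagged == ["Contig9"]
        assert set(results) == {"gc", "gc2", "gc4", "cai"}

    def test_null_contigs_rarely_flagged(self):
        clean = sum(len(C.contig_screen(simulate_contig_profiles(seed=s))[0]) == 0
                    for s in range(100, 110))
        assert clean >= 9

    def test_single_contig_has_nothing_to_compare(self):
        prof = simulate_contig_profiles(seed=0, n_contigs=1)
        flagged, results = C.contig_screen(prof)
        assert flagged == [] and results == {}


class TestGenomeSummaries:
    def test_coding_density_union_not_sum(self):
        g = GenomeRecord("g", "A" * 1000, "linear",
                         [GeneFeature("a", 0, 100, "+"), GeneFeature("b", 50, 150, "+")])
        assert C.coding_density(g) == pytest.approx(15.0)

    def test_coding_density_simple_fraction(self):
        g = GenomeRecord("g", "A" * 1000, "linear", [GeneFeature("a", 0, 570, "+")])
        assert C.coding_density(g) == pytest.approx(57.0)

    def test_all_genes_definition_includes_rna(self):
        g = GenomeRecord("g", "A" * 1000, "linear",
                         [GeneFeature("a", 0, 100, "+", "CDS"),
                          GeneFeature("r", 200, 300, "+", "rRNA")])
        assert C.coding_density(g, "cds-only") == pytest.approx(10.0)
        assert C.coding_density(g, "all-genes") == pytest.approx(20.0)

    def test_variant_rate(self):
        assert C.variant_rate(0, 1000) == 0.0
        assert C.variant_rate(1, 100) == 1.0
        assert C.variant_rate(34, 1_480_000) == pytest.approx(0.0023, abs=1e-4)
        with pytest.raises(ValueError):
            C.variant_rate(1, 0)
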