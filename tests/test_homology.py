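"""Homolog pairing, synteny model, screens, inventory."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genomedecay import homology as hom
from genomedecay.seqio import GeneFeature, GenomeRecord, Hit


def mkhit(q, s, e, bits=50.0, ident=90.0):
    return Hit(q, s, ident, 100, 10, 0, 1, 100, 1, 100, e, bits)


def genes(tags, length=300, spacing=1000, strand="+"):
    return [GeneFeature(t, i * spacing, i * spacing + length, strand)
            for i, t in enumerate(tags)]


class TestPairHomologs:
    A = genes(["q1", "q2", "q3"])
    B = genes(["s1", "s2", "s3"])

    def test_unambiguous_hits_pair_everything(self):
        hits = [mkhit("q1", "s1", 1e-50), mkhit("q2", "s2", 1e-40),
                mkhit("q3", "s3", 1e-5)]
        omap = hom.pair_homologs(hits, self.A, self.B)
        assert [(p.gene_a.locus_tag, p.gene_b.locus_tag) for p in omap.pairs] == \
            [("q1", "s1"), ("q2", "s2"), ("q3", "s3")]
        assert omap.orphans_a == [] and omap.orphans_b == []

    def test_duplicate_subject_keeps_best_and_orphans_the_rest(self):
        hits = [mkhit("q1", "s1", 1e-50), mkhit("q2", "s1", 1e-20)]
        omap = hom.pair_homologs(hits, self.A, self.B)
        assert [(p.gene_a.locus_tag, p.gene_b.locus_tag) for p in omap.pairs] == \
            [("q1", "s1")]
        assert [g.locus_tag for g in omap.orphans_a] == ["q2", "q3"]
        assert [g.locus_tag for g in omap.orphans_b] == ["s2", "s3"]

    def test_empty_hit_list_orphans_everyone(self):
        omap = hom.pair_homologs([], self.A, self.B)
        assert omap.pairs == []
        assert len(omap.orphans_a) == 3 and len(omap.orphans_b) == 3

    def test_unknown_gene_id_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            hom.pair_homologs([mkhit("nope", "s1", 1e-5)], self.A, self.B)

    @given(st.lists(st.tuples(st.integers(0, 8), st.integers(0, 8),
                              st.floats(1e-60, 1.0)), max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_one_to_one_property_on_random_hit_tables(self, raw):
        A = genes([f"q{i}" for i in range(9)])
        B = genes([f"s{i}" for i in range(9)])
        hits = [mkhit(f"q{a}", f"s{b}", e) for a, b, e in raw]
        omap = hom.pair_homologs(hits, A, B)
        pa = [p.gene_a.locus_tag for p in omap.pairs]
        pb = [p.gene_b.locus_tag for p in omap.pairs]
        assert len(set(pa)) == len(pa) and len(set(pb)) == len(pb)
        assert len(omap.pairs) + len(omap.orphans_a) == len(A)
        assert len(omap.pairs) + len(omap.orphans_b) == len(B)
        # determinism under stable tie-breaking
        omap2 = hom.pair_homologs(list(reversed(hits)), A, B)
        assert [(p.gene_a.locus_tag, p.gene_b.locus_tag) for p in omap2.pairs] == \
            [(p.gene_a.locus_tag, p.gene_b.locus_tag) for p in omap.pairs]


def syntenic_toy(n=50, spacing=2000, length=400):
    L = n * spacing
    ga = GenomeRecord("A", "ACGT" * (L // 4), "circular",
                      genes([f"a{i}" for i in range(n)], length, spacing))
    gb = GenomeRecord("B", "ACGT" * (L // 4), "circular",
                      genes([f"b{i}" for i in range(n)], length, spacing))
    pairs = [hom.HomologPair(fa, fb, 1e-30, 90.0)
             for fa, fb in zip(ga.features, gb.features)]
    return ga, gb, pairs


class TestSynteny:
    def test_perfect_synteny_has_zero_discrepancy(self):
        ga, gb, pairs = syntenic_toy()
        omap = hom.OrthologMap(pairs, [], [])
        omap, model = hom.synteny_discrepancy(omap, ga, gb)
        assert all(p.discrepancy == 0 for p in omap.pairs)
        assert model is not None and model.sign == 1

    def test_transposed_gene_gets_maximal_discrepancy_and_flag(self):
        ga, gb, pairs = syntenic_toy()
        moved = pairs[10]
        far = GeneFeature(moved.gene_b.locus_tag,
                          (moved.gene_b.start + 50_000) % 100_000,
                          (moved.gene_b.start + 50_000) % 100_000 + 400, "+")
        pairs[10] = hom.HomologPair(moved.gene_a, far, moved.e_value, 90.0)
        omap, _ = hom.synteny_discrepancy(hom.OrthologMap(pairs, [], []), ga, gb)
        worst = max(omap.pairs, key=lambda p: p.discrepancy)
        assert worst.gene_a.locus_tag == "a10"
        assert "manual-review" in worst.flags

    def test_too_few_pairs_flags_everything(self):
        ga, gb, pairs = syntenic_toy(n=2)
        omap, model = hom.synteny_discrepancy(hom.OrthologMap(pairs, [], []), ga, gb)
        assert model is None
        assert all("manual-review" in p.flags for p in omap.pairs)

    def test_inversion_discrepancies_bounded_by_span(self):
        ga, gb, pairs = syntenic_toy()
        # invert a 10-gene block in B (order reversed, strands flipped)
        lo, hi = 20, 30
        block = [p.gene_b for p in pairs[lo:hi]]
        for k, gb_feat in enumerate(reversed(block)):
            src = pairs[lo + k]
            flipped = GeneFeature(gb_feat.locus_tag, gb_feat.start, gb_feat.end, "-")
            pairs[lo + k] = hom.HomologPair(src.gene_a, flipped, src.e_value, 90.0)
        omap, _ = hom.synteny_discrepancy(hom.OrthologMap(pairs, [], []), ga, gb)
        span = (hi - lo) * 2000
        for p in omap.pairs[lo:hi]:
            assert p.discrepancy <= span
        segs = hom.reversed_segments(omap)
        assert len(segs) == 1 and segs[0]["n_genes"] == 10


class TestScreens:
    def test_hitlist_similarity_examples(self):
        assert hom.hitlist_similarity(list("abcde"), list("abcde"), k=5) == 1.0
        assert hom.hitlist_similarity(list("abcde"), list("fghij"), k=5) == 0.0
        # top-10 overlap of 5: |A∩B|=5, |A∪B|=15
        a = [f"x{i}" for i in range(10)]
        b = a[:5] + [f"y{i}" for i in range(5)]
        assert hom.hitlist_similarity(a, b, k=10) == pytest.approx(5 / 15)
        with pytest.raises(ValueError):
            hom.hitlist_similarity(a, b, k=0)

    def test_length_screen_boundary_is_strict(self):
        df = hom.length_screen([("a", 100, "b", 79), ("c", 100, "d", 80)])
        assert df.loc[0, "pct_difference"] == pytest.approx(-21.0)
        assert bool(df.loc[0, "flagged"])
        assert df.loc[1, "pct_difference"] == pytest.approx(-20.0)
        assert not df.loc[1, "flagged"]

    def test_length_screen_zero_length_is_an_error(self):
        with pytest.raises(ValueError, match="zero length"):
            hom.length_screen([("a", 0, "b", 10)])

    def test_three_way_check_fires_only_on_conflicting_evidence(self):
        A = genes(["q1", "q2", "q3"])
        B = genes(["s1", "s2", "s3"])
        omap = hom.pair_homologs([mkhit("q1", "s1", 1e-9), mkhit("q2", "s2", 1e-9),
                                  mkhit("q3", "s3", 1e-9)], A, B)
        out_a = [mkhit("q1", "o1", 1e-8), mkhit("q2", "o2", 1e-8)]
        out_b = [mkhit("s1", "o1", 1e-8), mkhit("s2", "oX", 1e-8)]
        bad = hom.three_way_check(omap, out_a, out_b)
        # q1/s1 agree; q2/s2 conflict; q3/s3 have no outgroup evidence
        assert [p.gene_a.locus_tag for p in bad] == ["q2"]


class TestExtendStart:
    def _pair_with_clipped_start(self, clip_codons=30):
        rng = np.random.default_rng(5)
        codons = ["ATG"] + ["".join(c) for c in
                            rng.choice(list("ACGT"), size=(97, 3))]
        codons = ["GAA" if c in ("TAA", "TAG", "TGA", "ATG") else c for c in codons]
        codons[0] = "ATG"
        cds = "".join(codons) + "TAA"
        flank = "CCCCCC"
        seq_a = flank + cds + flank
        ga = GenomeRecord("A", seq_a, "linear",
                          [GeneFeature("ga", 6, 6 + len(cds), "+", "CDS")])
        # genome B identical but annotated start clipped by clip_codons
        clip = 3 * clip_codons
        gb = GenomeRecord("B", seq_a, "linear",
                          [GeneFeature("gb", 6 + clip, 6 + len(cds), "+", "CDS")])
        pair = hom.HomologPair(ga.features[0], gb.features[0], 1e-40, 95.0)
        return pair, ga, gb, clip

    def test_clipped_annotation_is_extended_back_to_upstream_atg(self):
        pair, ga, gb, clip = self._pair_with_clipped_start()
        fixed = hom.extend_start(pair, ga, gb)
        assert "start-extended" in fixed.flags
        assert fixed.gene_b.start == pair.gene_b.start - clip

    def test_equal_length_pair_is_untouched(self):
        pair, ga, gb, _ = self._pair_with_clipped_start()
        same = hom.HomologPair(pair.gene_a, pair.gene_a, 1e-40, 100.0)
        assert hom.extend_start(same, ga, ga) is same

    def test_intervening_stop_blocks_extension(self):
        pair, ga, gb, clip = self._pair_with_clipped_start()
        # plant a TAA immediately upstream of the clipped start, in frame
        s = gb.sequence
        pos = pair.gene_b.start - 3
        gb2 = GenomeRecord("B", s[:pos] + "TAA" + s[pos + 3:], "linear",
                           list(gb.features))
        fixed = hom.extend_start(pair, ga, gb2)
        assert "start-extended" not in fixed.flags


class TestInventory:
    def test_annotated_product_match_and_absence(self):
        g1 = GenomeRecord("g1", "ACGT" * 300, "linear",
                          [GeneFeature("ftsZ_1", 0, 300, "+", "CDS",
                                       product="cell division protein FtsZ")])
        g2 = GenomeRecord("g2", "ACGT" * 300, "linear",
                          [GeneFeature("x", 0, 300, "+", "CDS", product="unrelated")])
        table = hom.inventory_matrix({"g1": g1, "g2": g2}, ["ftsZ", "dnaA"])
        assert bool(table.loc["g1", "ftsZ"]) is True
        assert bool(table.loc["g2", "ftsZ"]) is False
        assert not table["dnaA"].any()

    def test_empty_marker_list_gives_empty_table(self):
        g = GenomeRecord("g", "ACGT" * 10, "linear", [])
        assert hom.inventory_matrix({"g": g}, []).shape[1] == 0

    def test_sequence_level_rescue_of_unannotated_marker(self, small_pair):
        genome = small_pair["genome_a"]
        target = genome.cds_features()[0]
        marker_seq = target.translation
        table = hom.inventory_matrix({"A": genome}, ["mysteryGene"],
                                     marker_seqs={"mysteryGene": marker_seq})
        assert bool(table.loc["A", "mysteryGene"]) is True
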