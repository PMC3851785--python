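"""Pseudogene calling rules, weighted-identity aggregation, stop-frame maps,
intergenic synteny contrast."""

import numpy as np
import pytest

from genomedecay import decay as D
from genomedecay.homology import SyntenyModel
from genomedecay.seqio import GeneFeature, GenomeRecord, Hit, IntergenicRegion
from genomedecay.synthetic_data import simulate_eroded_intergenic


def thit(q, s, e, s_start, s_end, frame_s, aln=50, ident=70.0):
    return Hit(q, s, ident, aln, 5, 0, 1, aln, s_start, s_end, e, 60.0,
               frame_q=0, frame_s=frame_s)


@pytest.fixture()
def orphan_setup():
    orphan = GeneFeature("orph", 10_000, 11_000, "+", "CDS", product="demo enzyme")
    region = IntergenicRegion("B", 9_800, 12_300, "A" * 2500)
    genome_b = GenomeRecord("B", "A" * 50_000, "circular", [])
    # model predicting the same coordinate in B as in A
    model = SyntenyModel(scale=1.0, offset=0.0, length_b=50_000)
    regions = {region.region_id: region}
    return orphan, region, regions, genome_b, model


class TestOrphanRoute:
    def test_grouped_frameshifted_hits_yield_call(self, orphan_setup):
        orphan, region, regions, genome_b, model = orphan_setup
        rid = region.region_id
        hits = [thit("orph", rid, 1e-30, 201, 500, 1),
                thit("orph", rid, 1e-25, 502, 800, 2),
                thit("orph", rid, 1e-20, 810, 1100, 1)]
        call = D.call_pseudogene_from_orphan(orphan, hits, regions, genome_b, model)
        assert call is not None
        assert call.evidence == "orphan-tblastn"
        assert call.frameshift_count == 1  # frames {1, 2}
        assert call.locus_end - call.locus_start <= orphan.length

    def test_span_larger_than_query_blocks_call(self, orphan_setup):
        orphan, region, regions, genome_b, model = orphan_setup
        rid = region.region_id
        hits = [thit("orph", rid, 1e-30, 1, 500, 1),
                thit("orph", rid, 1e-25, 2000, 2500, 2)]
        assert D.call_pseudogene_from_orphan(orphan, hits, regions,
                                             genome_b, model) is None

    def test_offsynteny_locus_blocks_call(self, orphan_setup):
        orphan, region, regions, genome_b, _ = orphan_setup
        rid = region.region_id
        hits = [thit("orph", rid, 1e-30, 201, 900, 1)]
        far_model = SyntenyModel(scale=1.0, offset=25_000.0, length_b=50_000)
        assert D.call_pseudogene_from_orphan(orphan, hits, regions,
                                             genome_b, far_model) is None

    def test_no_hits_no_call(self, orphan_setup):
        orphan, _, regions, genome_b, model = orphan_setup
        assert D.call_pseudogene_from_orphan(orphan, [], regions,
                                             genome_b, model) is None


class TestIntergenicRoute:
    REGION = IntergenicRegion("A", 1000, 1400, "ACGT" * 100)

    def test_strong_named_hit_yields_call(self):
        hits = [thit("r", "P1", 1e-5, 1, 300, 0)]
        titles = {"P1": "UTP-glucose-1-phosphate uridylyltransferase"}
        call = D.call_pseudogene_from_intergenic(self.REGION, hits, titles=titles)
        assert call is not None
        assert call.nearest_homolog.startswith("UTP-glucose")

    def test_weak_evalue_blocks_call(self):
        hits = [thit("r", "P1", 0.01, 1, 300, 0)]
        assert D.call_pseudogene_from_intergenic(self.REGION, hits,
                                                 titles={"P1": "real enzyme"}) is None

    def test_hypothetical_titles_block_call(self):
        hits = [thit("r", "P1", 1e-20, 1, 300, 0)]
        titles = {"P1": "Hypothetical protein XY_123"}
        assert D.call_pseudogene_from_intergenic(self.REGION, hits,
                                                 titles=titles) is None


class TestAggregation:
    def test_weighted_identity_formula(self):
        hits = [thit("q", "s", 1e-9, 1, 100, 1, aln=100, ident=80.0),
                thit("q", "s", 1e-9, 101, 150, 1, aln=50, ident=90.0)]
        assert D.aggregate_translated_hits(hits) == pytest.approx(83.333, abs=1e-3)

    def test_single_hit_returns_its_identity(self):
        hits = [thit("q", "s", 1e-9, 1, 100, 1, ident=72.5)]
        assert D.aggregate_translated_hits(hits) == 72.5

    def test_order_invariance_and_bounds(self, rng):
        hits = [thit("q", "s", 1e-9, 1, 100, 1, aln=int(l), ident=float(i))
                for l, i in zip(rng.integers(10, 200, 8), rng.uniform(40, 100, 8))]
        forward = D.aggregate_translated_hits(hits)
        shuffled = list(hits)
        rng.shuffle(shuffled)
        assert D.aggregate_translated_hits(shuffled) == pytest.approx(forward)
        idents = [h.pct_identity for h in hits]
        assert min(idents) <= forward <= max(idents)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            D.aggregate_translated_hits([])


class TestIntergenicSynteny:
    def test_identical_sets_give_full_identity_diagonal(self):
        rng = np.random.default_rng(0)
        regions = []
        pos = 200
        for i in range(5):
            seq = "".join(rng.choice(list("ACGT"), p=[0.2, 0.3, 0.3, 0.2], size=400))
            regions.append(IntergenicRegion("G", pos, pos + 400, seq))
            pos += 600
        points = D.intergenic_synteny(regions, regions, pos, pos, mode="nucleotide")
        assert len(points) == 5
        for p in points:
            assert p.midpoint_a == p.midpoint_b
            assert p.weighted_identity == 100.0

    def test_disjoint_random_sequences_give_no_points(self):
        rng = np.random.default_rng(1)
        ra = [IntergenicRegion("A", 100, 500, "".join(rng.choice(list("ACGT"), 400)))]
        rb = [IntergenicRegion("B", 100, 500, "".join(rng.choice(list("ACGT"), 400)))]
        assert D.intergenic_synteny(ra, rb, 1000, 1000, mode="nucleotide") == []
        assert D.intergenic_synteny(ra, rb, 1000, 1000, mode="translated") == []

    def test_translated_mode_retains_signal_nucleotide_mode_lost(self):
        """Once-coding DNA eroded ~35% keeps a syntenic translated signal
        after nucleotide similarity has decayed (the decayed-gene regime)."""
        ra, rb, la, lb = simulate_eroded_intergenic(seed=7)
        pts_nt = D.intergenic_synteny(ra, rb, la, lb, mode="nucleotide")
        pts_tx = D.intergenic_synteny(ra, rb, la, lb, mode="translated")
        assert len(pts_tx) >= 3 * max(len(pts_nt), 1)
        # the translated points are overwhelmingly syntenic (matched order)
        syntenic = sum(1 for p in pts_tx
                       if abs(p.midpoint_a / la - p.midpoint_b / lb) < 0.05)
        assert syntenic >= 0.8 * len(pts_tx)

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError):
            D.intergenic_synteny([], [], 10, 10, mode="nope")


class TestStopFrameMap:
    def test_tandem_stops_land_in_frame_zero(self):
        m = D.stop_frame_map("TAATAGTGA")
        assert m.stops[0] == [0, 3, 6]
        assert m.stops[1] == [] and m.stops[2] == []

    def test_all_gc_sequence_has_no_stops_and_full_gc(self):
        m = D.stop_frame_map("GC" * 200, window=100)
        assert m.stops == {0: [], 1: [], 2: []}
        assert all(gc == 100.0 for _, gc in m.gc_windows)

    def test_random_sequence_stop_density_near_binomial_expectation(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 3000))
        m = D.stop_frame_map(seq)
        for frame in (0, 1, 2):
            n_codons = len([i for i in range(frame, 3000 - 2, 3)])
            expected = n_codons * 3 / 64
            sigma = (n_codons * (3 / 64) * (61 / 64)) ** 0.5
            assert abs(len(m.stops[frame]) - expected) <= 3 * sigma
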