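"""Synteny-aware one-to-one homolog pairing between two strains.

The pairing procedure is a greedy best-hit chain: keep each query's best
(lowest e-value) subject, order the retained pairs by ascending e-value and
drop any pair whose subject has already been claimed.  Genes left unpaired
on either side are orphans.  A global circular offset model then scores each
pair's departure from genome-wide synteny; the most discrepant fraction is
flagged for review rather than dropped, and a length screen plus a three-way
outgroup consistency check provide additional evidence for annotation
artifacts and truncation/pseudogenization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import aligner as al
from .seqio import GeneFeature, GenomeRecord, Hit, circular_distance

__all__ = [
    "HomologPair",
    "OrthologMap",
    "SyntenyModel",
    "pair_homologs",
    "fit_synteny_model",
    "synteny_discrepancy",
    "hitlist_similarity",
    "extend_start",
    "length_screen",
    "three_way_check",
    "inventory_matrix",
    "reversed_segments",
    "all_vs_all_protein_hits",
    "pairs_table",
]


@dataclass
class HomologPair:
    gene_a: GeneFeature
    gene_b: GeneFeature
    e_value: float
    pct_identity: float
    expected_b_coord: int | None = None
    discrepancy: int | None = None
    flags: set = field(default_factory=set)


@dataclass
class OrthologMap:
    pairs: list[HomologPair]
    orphans_a: list[GeneFeature]
    orphans_b: list[GeneFeature]

    def __post_init__(self):
        pa = [p.gene_a.locus_tag for p in self.pairs]
        pb = [p.gene_b.locus_tag for p in self.pairs]
        if len(set(pa)) != len(pa) or len(set(pb)) != len(pb):
            raise ValueError("ortholog map is not one-to-one")


@dataclass
class SyntenyModel:
    """Expected partner coordinate: ``(scale * coord_a * sign + offset) mod L_b``."""

    scale: float
    offset: float
    length_b: int
    sign: int = 1

    def expected(self, coord_a: int) -> int:
        return int(round(self.sign * self.scale * coord_a + self.offset)) % self.length_b


def _feature_index(genes: list[GeneFeature]) -> dict[str, GeneFeature]:
    idx = {}
    for g in genes:
        if g.locus_tag in idx:
            raise ValueError(f"duplicate locus_tag {g.locus_tag}")
        idx[g.locus_tag] = g
    return idx


def pair_homologs(hits_ab: list[Hit], genes_a: list[GeneFeature],
                  genes_b: list[GeneFeature]) -> OrthologMap:
    """Greedy one-to-one pairing from an A-proteins-vs-B-proteins hit table.

    Per query keep only the best (lowest e-value) hit; sort retained hits by
    ascending e-value; walking down that list, discard a hit whose subject
    was already taken by an earlier (better) hit.  Ties on e-value break by
    higher bit score, then query id, then subject id, for determinism.
    """
    idx_a = _feature_index(genes_a)
    idx_b = _feature_index(genes_b)
    for h in hits_ab:
        if h.query_id not in idx_a:
            raise ValueError(f"hit references unknown query gene {h.query_id}")
        if h.subject_id not in idx_b:
            raise ValueError(f"hit references unknown subject gene {h.subject_id}")

    best: dict[str, Hit] = {}
    for h in hits_ab:
        cur = best.get(h.query_id)
        if cur is None or (h.e_value, -h.bit_score, h.subject_id) < \
                (cur.e_value, -cur.bit_score, cur.subject_id):
            best[h.query_id] = h
    ordered = sorted(best.values(),
                     key=lambda h: (h.e_value, -h.bit_score, h.query_id, h.subject_id))
    taken_b: set[str] = set()
    pairs: list[HomologPair] = []
    for h in ordered:
        if h.subject_id in taken_b:
            continue
        taken_b.add(h.subject_id)
        pairs.append(HomologPair(idx_a[h.query_id], idx_b[h.subject_id],
                                 h.e_value, h.pct_identity))
    paired_a = {p.gene_a.locus_tag for p in pairs}
    paired_b = {p.gene_b.locus_tag for p in pairs}
    return OrthologMap(pairs,
                       [g for g in genes_a if g.locus_tag not in paired_a],
                       [g for g in genes_b if g.locus_tag not in paired_b])


# ---------------------------------------------------------------------------
# Synteny model
# ---------------------------------------------------------------------------

def fit_synteny_model(coords_a: np.ndarray, coords_b: np.ndarray,
                      length_a: int, length_b: int) -> SyntenyModel:
    """Robust global circular offset fit between paired gene coordinates.

    The scale is fixed at ``L_b / L_a``; the offset (and overall orientation)
    is chosen to minimize the median absolute circular residual over all
    pairs, evaluating every per-pair residual as an offset candidate.  The
    median makes the fit robust to a minority of rearranged genes (e.g. a
    couple of inversions).
    """
    scale = length_b / length_a
    best = None
    for sign in (1, -1):
        res = (coords_b - sign * scale * coords_a) % length_b
        for cand in res:
            d = np.abs(res - cand)
            d = np.minimum(d, length_b - d)
            med = float(np.median(d))
            if best is None or med < best[0]:
                best = (med, sign, float(cand))
    _, sign, offset = best
    return SyntenyModel(scale=scale, offset=offset, length_b=length_b, sign=sign)


def synteny_discrepancy(omap: OrthologMap, g_a: GenomeRecord, g_b: GenomeRecord,
                        review_fraction: float = 0.10) -> tuple[OrthologMap, SyntenyModel | None]:
    """Fill per-pair synteny discrepancies and flag the most discrepant pairs.

    With fewer than 3 pairs no model can be fit: every pair is flagged
    ``manual-review``.  Otherwise the top ``review_fraction`` (default 10%)
    of pairs by circular discrepancy from the fitted model are flagged, in
    the spirit of a manual re-examination list, without dropping them.
    Coordinates are the genes' start coordinates on the forward strand.
    """
    if len(omap.pairs) < 3:
        for p in omap.pairs:
            p.flags.add("manual-review")
        return omap, None
    ca = np.array([p.gene_a.start for p in omap.pairs], dtype=float)
    cb = np.array([p.gene_b.start for p in omap.pairs], dtype=float)
    model = fit_synteny_model(ca, cb, g_a.length, g_b.length)
    for p in omap.pairs:
        exp = model.expected(p.gene_a.start)
        p.expected_b_coord = exp
        p.discrepancy = circular_distance(p.gene_b.start, exp, g_b.length)
    n_flag = max(1, int(math.floor(review_fraction * len(omap.pairs))))
    for p in sorted(omap.pairs, key=lambda p: -p.discrepancy)[:n_flag]:
        p.flags.add("manual-review")
    return omap, model


def reversed_segments(omap: OrthologMap, min_run: int = 3) -> list[dict]:
    """Contiguous runs of pairs whose partner order runs backwards (inversions).

    Pairs are walked in order of their coordinate in genome A; a maximal run
    of at least ``min_run`` consecutive pairs whose genome-B coordinates
    decrease while the relative strand is flipped is reported as one
    reversed segment with its coordinate spans in both genomes.
    """
    pairs = sorted(omap.pairs, key=lambda p: p.gene_a.start)
    if len(pairs) < min_run:
        return []
    flipped = [p.gene_a.strand != p.gene_b.strand for p in pairs]
    segments = []
    i = 0
    while i < len(pairs):
        if not flipped[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(pairs) and flipped[j + 1] and \
                pairs[j + 1].gene_b.start < pairs[j].gene_b.start:
            j += 1
        run = pairs[i:j + 1]
        if len(run) >= min_run:
            segments.append({
                "n_genes": len(run),
                "a_start": run[0].gene_a.start, "a_end": run[-1].gene_a.end,
                "b_start": min(p.gene_b.start for p in run),
                "b_end": max(p.gene_b.end for p in run),
                "loci_a": [p.gene_a.locus_tag for p in run],
            })
        i = j + 1
    return segments


# ---------------------------------------------------------------------------
# Secondary screens
# ---------------------------------------------------------------------------

def hitlist_similarity(query_hits: list[str], subject_hits: list[str], k: int = 10) -> float:
    """Jaccard index of the top-k hit-id sets of the two ranked lists."""
    if k <= 0:
        raise ValueError("k must be positive")
    qa, sb = set(query_hits[:k]), set(subject_hits[:k])
    if not qa and not sb:
        return 1.0
    return len(qa & sb) / len(qa | sb)


def extend_start(pair: HomologPair, g_a: GenomeRecord, g_b: GenomeRecord,
                 scheme: al.ScoringScheme | None = None,
                 max_extra_codons: int = 10, min_identity: float = 50.0
                 ) -> HomologPair:
    """Move the shorter gene's start upstream when homology reaches an earlier start.

    Walks upstream of the shorter gene codon-by-codon in frame, stopping at
    the first in-frame stop codon, collecting candidate ATG starts out to
    the partner-length deficit (plus a small slack).  The farthest candidate
    whose translated extension aligns to the longer protein's N-terminal
    overhang at >= ``min_identity`` % identity becomes the new start and the
    pair is flagged ``start-extended``; otherwise the pair is returned
    unchanged.
    """
    scheme = scheme or al.protein_scheme()
    la, lb = pair.gene_a.length, pair.gene_b.length
    if la == lb:
        return pair
    if la > lb:
        short, short_genome, side = pair.gene_b, g_b, "b"
        long_prot = _protein_of(pair.gene_a, g_a)
    else:
        short, short_genome, side = pair.gene_a, g_a, "a"
        long_prot = _protein_of(pair.gene_b, g_b)
    deficit_codons = (max(la, lb) - min(la, lb)) // 3 + max_extra_codons
    L = short_genome.length

    def codon_upstream(i: int) -> str:  # i-th codon upstream of the annotated start
        if short.strand == "+":
            s = (short.start - 3 * i) % L
            return short_genome.slice(s, s + 3)
        s = (short.end + 3 * (i - 1)) % L
        codon = short_genome.slice(s, s + 3)
        from Bio.Seq import Seq
        return str(Seq(codon).reverse_complement())

    candidates = []
    for i in range(1, deficit_codons + 1):
        codon = codon_upstream(i)
        if codon in ("TAA", "TAG", "TGA"):
            break
        if codon == "ATG":
            candidates.append(i)
    for i in sorted(candidates, reverse=True):  # farthest upstream first
        ext = "".join(codon_upstream(j) for j in range(i, 0, -1))
        from Bio.Seq import Seq
        ext_prot = str(Seq(ext).translate(table=11))
        overhang = long_prot[: i + 5]
        hits = al.local_align(ext_prot, overhang, scheme)
        if hits and hits[0].pct_identity >= min_identity and \
                hits[0].aln_length >= 0.6 * len(ext_prot):
            if short.strand == "+":
                new = replace(short, start=(short.start - 3 * i) % L)
            else:
                new = replace(short, end=short.end + 3 * i)
            if side == "b":
                newpair = HomologPair(pair.gene_a, new, pair.e_value, pair.pct_identity,
                                      pair.expected_b_coord, pair.discrepancy,
                                      set(pair.flags))
            else:
                newpair = HomologPair(new, pair.gene_b, pair.e_value, pair.pct_identity,
                                      pair.expected_b_coord, pair.discrepancy,
                                      set(pair.flags))
            newpair.flags.add("start-extended")
            return newpair
    return pair


def _protein_of(gene: GeneFeature, genome: GenomeRecord) -> str:
    if gene.translation:
        return gene.translation
    from Bio.Seq import Seq
    nt = gene.sequence(genome)
    return str(Seq(nt[: 3 * (len(nt) // 3)]).translate(table=11)).rstrip("*")


def length_screen(pairs: list[tuple[str, int, str, int]] | list[HomologPair],
                  threshold: float = 0.20) -> pd.DataFrame:
    """Flag pairs whose lengths differ by more than ``threshold`` (strict >).

    Accepts either :class:`HomologPair` objects or ``(id_a, len_a, id_b,
    len_b)`` tuples.  The signed percent difference is reported relative to
    the longer member (shorter second member gives a negative sign).
    """
    rows = []
    for p in pairs:
        if isinstance(p, HomologPair):
            ida, la = p.gene_a.locus_tag, p.gene_a.length
            idb, lb = p.gene_b.locus_tag, p.gene_b.length
        else:
            ida, la, idb, lb = p
        if la <= 0 or lb <= 0:
            raise ValueError(f"zero length in pair ({ida}, {idb})")
        diff = abs(la - lb) / max(la, lb)
        signed = -100.0 * diff if lb < la else (100.0 * diff if lb > la else 0.0)
        rows.append({"id_a": ida, "id_b": idb, "len_a": la, "len_b": lb,
                     "pct_difference": signed, "flagged": diff > threshold})
    return pd.DataFrame(rows, columns=["id_a", "id_b", "len_a", "len_b",
                                       "pct_difference", "flagged"])


def three_way_check(omap: OrthologMap, hits_a_out: list[Hit],
                    hits_b_out: list[Hit]) -> list[HomologPair]:
    """Pairs whose members have *different* best hits in an outgroup.

    A pair is inconsistent only on conflicting evidence: both members must
    have an outgroup best hit and those hits must disagree.  A member with
    no outgroup hit never renders its pair inconsistent.
    """
    def best_map(hits: list[Hit]) -> dict[str, str]:
        best: dict[str, Hit] = {}
        for h in hits:
            cur = best.get(h.query_id)
            if cur is None or (h.e_value, -h.bit_score) < (cur.e_value, -cur.bit_score):
                best[h.query_id] = h
        return {q: h.subject_id for q, h in best.items()}

    ba, bb = best_map(hits_a_out), best_map(hits_b_out)
    bad = []
    for p in omap.pairs:
        oa = ba.get(p.gene_a.locus_tag)
        ob = bb.get(p.gene_b.locus_tag)
        if oa is not None and ob is not None and oa != ob:
            p.flags.add("outgroup-conflict")
            bad.append(p)
    return bad


def inventory_matrix(genomes: dict[str, GenomeRecord], marker_genes: list[str],
                     marker_seqs: dict[str, str] | None = None,
                     scheme: al.ScoringScheme | None = None,
                     min_identity: float = 50.0) -> pd.DataFrame:
    """Presence/absence of marker genes across annotated genomes.

    A marker is present when its name matches a feature product or locus tag
    (case-insensitive substring), or — when a marker protein sequence is
    supplied — when some annotated protein aligns to it at
    >= ``min_identity`` % identity.
    """
    scheme = scheme or al.protein_scheme()
    table = {}
    for gid, genome in genomes.items():
        col = {}
        for marker in marker_genes:
            m = marker.lower()
            present = any(m in f.product.lower() or m in f.locus_tag.lower()
                          for f in genome.features)
            if not present and marker_seqs and marker in marker_seqs:
                ref = marker_seqs[marker]
                for f in genome.cds_features():
                    prot = _protein_of(f, genome)
                    if al.quick_distance(ref, prot) > 0.8:
                        continue
                    hits = al.local_align(ref, prot, scheme)
                    if hits and hits[0].pct_identity >= min_identity and \
                            hits[0].aln_length >= 0.5 * len(ref):
                        present = True
                        break
            col[marker] = present
        table[gid] = col
    return pd.DataFrame(table).T if table else pd.DataFrame(columns=marker_genes)


# ---------------------------------------------------------------------------
# Search driver + export
# ---------------------------------------------------------------------------

def all_vs_all_protein_hits(genes_a: list[GeneFeature], genes_b: list[GeneFeature],
                            g_a: GenomeRecord, g_b: GenomeRecord,
                            scheme: al.ScoringScheme | None = None,
                            prescreen: float = 0.60) -> list[Hit]:
    """Hit table of every A protein against every B protein.

    A fast edit-distance prescreen (infix mode, normalized distance above
    ``prescreen`` skips the pair) keeps the all-vs-all search tractable;
    every reported hit is still scored by the exact local aligner.
    """
    scheme = scheme or al.protein_scheme()
    prots_b = [(g.locus_tag, _protein_of(g, g_b)) for g in genes_b]
    hits: list[Hit] = []
    for ga in genes_a:
        pa = _protein_of(ga, g_a)
        for tag_b, pb in prots_b:
            short, long_ = (pa, pb) if len(pa) <= len(pb) else (pb, pa)
            if al.quick_distance(short, long_) > prescreen:
                continue
            hits.extend(al.local_align(pa, pb, scheme, query_id=ga.locus_tag,
                                       subject_id=tag_b, max_hsps=1))
    return hits


def pairs_table(omap: OrthologMap) -> pd.DataFrame:
    """Flat TSV-ready view of an ortholog map (dot-plot ready coordinates)."""
    rows = [{
        "locus_a": p.gene_a.locus_tag, "locus_b": p.gene_b.locus_tag,
        "start_a": p.gene_a.start, "start_b": p.gene_b.start,
        "strand_a": p.gene_a.strand, "strand_b": p.gene_b.strand,
        "pct_identity": p.pct_identity, "e_value": p.e_value,
        "expected_b_coord": p.expected_b_coord, "discrepancy": p.discrepancy,
        "flags": ",".join(sorted(p.flags)),
    } for p in omap.pairs]
    return pd.DataFrame(rows, columns=["locus_a", "locus_b", "start_a", "start_b",
                                       "strand_a", "strand_b", "pct_identity",
                                       "e_value", "expected_b_coord", "discrepancy",
                                       "flags"])
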