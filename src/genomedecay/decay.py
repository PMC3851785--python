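"""Pseudogene detection and intergenic-decay synteny analysis.

Two complementary detection routes:

* **orphan route** — an annotated gene in one strain with no partner is
  searched (translated, six-frame) against the other strain's intergenic
  DNA.  A pseudogene is called when the grouped hits stay within a locus no
  larger than the query gene, at a position consistent with genome-wide
  synteny.  Distinct reading frames among the grouped hits witness
  frameshifts; stop codons in the best frame witness nonsense mutations.
* **intergenic route** — intergenic regions of either strain searched
  (translated) against a protein database; a region whose best
  non-"hypothetical" hit clears an e-value cutoff is a pseudogene degraded
  in both strains.

The intergenic synteny analysis contrasts nucleotide-level and
translated-level searches of the intergenic complements of the two strains:
in heavily eroded once-coding DNA the translated search retains a syntenic
signal long after nucleotide similarity has decayed away.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import aligner as al
from .homology import SyntenyModel
from .seqio import (GeneFeature, GenomeRecord, Hit, IntergenicRegion,
                    circular_distance)

__all__ = [
    "PseudogeneCall",
    "SyntenyPoint",
    "StopFrameMap",
    "call_pseudogene_from_orphan",
    "call_pseudogene_from_intergenic",
    "aggregate_translated_hits",
    "intergenic_synteny",
    "stop_frame_map",
    "find_pseudogenes_from_orphans",
    "calls_table",
]

_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class PseudogeneCall:
    region: IntergenicRegion
    evidence: str                      # "orphan-tblastn" | "intergenic-blastx"
    supporting_hits: list[Hit]
    nearest_homolog: str
    frameshift_count: int = 0
    inframe_stop_count: int = 0
    gc_pct: float = 0.0
    strand: str = "+"
    locus_start: int = 0               # genome coordinates of the hit locus
    locus_end: int = 0

    def __post_init__(self):
        if not self.supporting_hits:
            raise ValueError("a pseudogene call requires supporting hits")


@dataclass(frozen=True)
class SyntenyPoint:
    midpoint_a: int
    midpoint_b: int
    weighted_identity: float
    region_a: str = ""
    region_b: str = ""


@dataclass
class StopFrameMap:
    """Per-frame stop-codon positions plus a windowed GC histogram."""

    stops: dict[int, list[int]]            # frame 0/1/2 -> codon start positions
    gc_windows: list[tuple[int, float]]    # (window start, GC %)
    window: int


def _gc(seq: str) -> float:
    if not seq:
        return 0.0
    return 100.0 * sum(1 for c in seq if c in "GC") / len(seq)


# ---------------------------------------------------------------------------
# Pseudogene calls
# ---------------------------------------------------------------------------

def call_pseudogene_from_orphan(orphan: GeneFeature, hits: list[Hit],
                                regions: dict[str, IntergenicRegion],
                                genome_b: GenomeRecord,
                                synteny_model: SyntenyModel | None,
                                span_tolerance: float = 1.0,
                                synteny_window: int = 20_000) -> PseudogeneCall | None:
    """Call a decayed copy of an orphan gene inside the partner's intergenic DNA.

    ``hits`` are translated-search hits of the orphan protein against the
    partner strain's intergenic regions (subject ids are region ids).  The
    call requires (i) at least one hit, (ii) the genome-coordinate span of
    the grouped hits not exceeding the orphan's nucleotide length times
    ``span_tolerance``, and (iii) the locus lying within ``synteny_window``
    of the coordinate the genome-wide synteny model predicts.  Returns
    ``None`` when any criterion fails.
    """
    if not hits:
        return None
    spans = []
    for h in hits:
        r = regions[h.subject_id]
        lo, hi = h.s_span
        spans.append((r.start + lo, r.start + hi, h))
    # group on the dominant region cluster: use all hits, span over genome coords
    lo = min(s for s, _, _ in spans)
    hi = max(e for _, e, _ in spans)
    if (hi - lo) > span_tolerance * orphan.length:
        return None
    if synteny_model is not None:
        expected = synteny_model.expected(orphan.start)
        mid = (lo + hi) // 2
        if circular_distance(mid, expected, genome_b.length) > synteny_window:
            return None
    frames = {h.frame_s for h in hits}
    frameshifts = max(0, len(frames) - 1)
    best = min(hits, key=lambda h: (h.e_value, -h.bit_score))
    region = regions[best.subject_id]
    stops = _stops_in_best_frame(region, best, lo, hi)
    locus_seq = genome_b.slice(lo, hi) if hi <= genome_b.length else region.sequence
    return PseudogeneCall(
        region=region, evidence="orphan-tblastn", supporting_hits=list(hits),
        nearest_homolog=f"{orphan.locus_tag} {orphan.product}".strip(),
        frameshift_count=frameshifts, inframe_stop_count=stops,
        gc_pct=_gc(locus_seq), strand="+" if best.frame_s >= 0 else "-",
        locus_start=lo, locus_end=hi)


def _stops_in_best_frame(region: IntergenicRegion, best: Hit,
                         locus_lo: int, locus_hi: int) -> int:
    """In-frame stops across the grouped locus, read in the best hit's frame.

    Individual HSPs are stop-free by construction (translation segments are
    split at stops), so disruptive nonsense codons show up *between* the
    grouped HSPs; the count is taken over the whole locus span in the frame
    phase of the best hit.
    """
    lo = max(locus_lo - region.start, 0)
    hi = min(locus_hi - region.start, len(region.sequence))
    seq = region.sequence[lo:hi]
    if best.frame_s < 0:
        seq = str(Seq(seq).reverse_complement())
        anchor = (abs(best.frame_s) - 1 - (len(region.sequence) - hi)) % 3
    else:
        # phase of the best hit's frame relative to the locus start
        anchor = (min(best.s_start, best.s_end) - 1 - lo) % 3
    return sum(1 for i in range(anchor, len(seq) - 2, 3) if seq[i:i + 3] in _STOPS)


def call_pseudogene_from_intergenic(region: IntergenicRegion, hits: list[Hit],
                                    e_cutoff: float = 1e-3,
                                    titles: dict[str, str] | None = None
                                    ) -> PseudogeneCall | None:
    """Call a doubly-degraded pseudogene from translated hits of an intergenic region.

    The best qualifying hit must clear ``e_cutoff`` (strict <) and its
    subject title must not contain "hypothetical" (case-insensitive).
    ``titles`` maps subject ids to descriptive titles; absent a mapping the
    subject id itself is the title.
    """
    titles = titles or {}
    qualifying = [h for h in hits
                  if h.e_value < e_cutoff
                  and "hypothetical" not in titles.get(h.subject_id, h.subject_id).lower()]
    if not qualifying:
        return None
    best = min(qualifying, key=lambda h: (h.e_value, -h.bit_score))
    return PseudogeneCall(
        region=region, evidence="intergenic-blastx", supporting_hits=qualifying,
        nearest_homolog=titles.get(best.subject_id, best.subject_id),
        frameshift_count=max(0, len({h.frame_q for h in qualifying
                                     if h.subject_id == best.subject_id}) - 1),
        inframe_stop_count=0, gc_pct=_gc(region.sequence),
        strand="+" if best.frame_q >= 0 else "-",
        locus_start=region.start, locus_end=region.end)


def find_pseudogenes_from_orphans(orphans: list[GeneFeature], genome_a: GenomeRecord,
                                  regions_b: list[IntergenicRegion],
                                  genome_b: GenomeRecord,
                                  synteny_model: SyntenyModel | None,
                                  scheme: al.ScoringScheme | None = None,
                                  span_tolerance: float = 1.0,
                                  synteny_window: int = 20_000,
                                  prescreen: float = 0.55,
                                  min_aa: int = 15,
                                  group_e_cutoff: float = 1e-3) -> list[PseudogeneCall]:
    """Run the orphan route for every orphan of strain A against strain B.

    Searches each orphan protein against every intergenic region of the
    partner (translated, six frames; edit-distance prescreen on the
    translated segments keeps this tractable), keeps hits clearing
    ``group_e_cutoff`` as evidence, groups them per region neighborhood and
    applies :func:`call_pseudogene_from_orphan`.  The evidence cutoff keeps
    short chance HSPs — which a seeded search would never report — from
    inflating the hit group's span or frame count.
    """
    scheme = scheme or al.protein_scheme()
    regions = {r.region_id: r for r in regions_b}
    seg_cache = {r.region_id: al.six_frame_segments(r.sequence, min_aa=min_aa)
                 for r in regions_b}
    calls = []
    for orphan in orphans:
        prot = orphan.translation
        if not prot:
            nt = orphan.sequence(genome_a)
            prot = str(Seq(nt[:3 * (len(nt) // 3)]).translate(table=11)).rstrip("*")
        if len(prot) < min_aa:
            continue
        hits: list[Hit] = []
        for r in regions_b:
            segs = seg_cache[r.region_id]
            if not segs:
                continue
            if min(al.quick_distance(pep, prot) for _, pep, _, _ in segs) > prescreen:
                continue
            hits.extend(h for h in
                        al.translated_search(prot, r.sequence, scheme,
                                             mode="tblastn", query_id=orphan.locus_tag,
                                             subject_id=r.region_id, min_aa=min_aa)
                        if h.e_value <= group_e_cutoff)
        if not hits:
            continue
        # group hits by region, keep the region cluster with the best evidence
        by_region = defaultdict(list)
        for h in hits:
            by_region[h.subject_id].append(h)
        best_region = min(by_region, key=lambda k: min(h.e_value for h in by_region[k]))
        call = call_pseudogene_from_orphan(orphan, by_region[best_region], regions,
                                           genome_b, synteny_model,
                                           span_tolerance, synteny_window)
        if call is not None:
            calls.append(call)
    return calls


# ---------------------------------------------------------------------------
# Intergenic synteny
# ---------------------------------------------------------------------------

def aggregate_translated_hits(hits: list[Hit]) -> float:
    """Average percent identity weighted by alignment length over grouped HSPs."""
    if not hits:
        raise ValueError("empty hit group")
    total = sum(h.aln_length for h in hits)
    return sum(h.pct_identity * h.aln_length for h in hits) / total


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def intergenic_synteny(regions_a: list[IntergenicRegion],
                       regions_b: list[IntergenicRegion],
                       length_a: int, length_b: int,
                       mode: str = "translated",
                       scheme: al.ScoringScheme | None = None,
                       min_aa: int = 15, kmer: int = 16, min_shared_kmers: int = 1,
                       hit_e_cutoff: float = 1e-3,
                       min_nt_aln: int = 40) -> list[SyntenyPoint]:
    """Dot-plot points relating the intergenic complements of two strains.

    ``nucleotide`` mode keeps the single best hit per query region
    (shared-nucleotide-k-mer prescreen, exact local alignment, hits shorter
    than ``min_nt_aln`` bases ignored — a word-seeded search would not
    report them); ``translated`` mode groups the six-frame HSPs clearing
    ``hit_e_cutoff`` per region pair and reports the length-weighted
    average identity, prescreening pairs by shared translated 7-mers.
    Points carry the region midpoints in their respective genomes.
    """
    if mode == "nucleotide":
        nscheme = scheme or al.nucleotide_scheme()
        kmers_b = [(r, _kmer_set(r.sequence, kmer)) for r in regions_b]
        points = []
        for ra in regions_a:
            ka = _kmer_set(ra.sequence, kmer)
            best_hit, best_rb = None, None
            for rb, kb in kmers_b:
                if len(ka & kb) < min_shared_kmers:
                    continue
                hits = [h for h in
                        al.local_align(ra.sequence, rb.sequence, nscheme,
                                       query_id=ra.region_id, subject_id=rb.region_id,
                                       max_hsps=1)
                        if h.aln_length >= min_nt_aln]
                if hits and (best_hit is None or hits[0].e_value < best_hit.e_value):
                    best_hit, best_rb = hits[0], rb
            if best_hit is not None:
                points.append(SyntenyPoint(ra.midpoint(length_a), best_rb.midpoint(length_b),
                                           best_hit.pct_identity,
                                           ra.region_id, best_rb.region_id))
        return points

    if mode != "translated":
        raise ValueError(f"unknown mode {mode!r}")
    pscheme = scheme or al.protein_scheme()
    aa_k = 7  # shared-peptide-k-mer prescreen for the translated all-vs-all

    def aa_kmers(segs) -> set[str]:
        out: set[str] = set()
        for _, pep, _, _ in segs:
            out.update(pep[i:i + aa_k] for i in range(len(pep) - aa_k + 1))
        return out

    segs_b = {r.region_id: al.six_frame_segments(r.sequence, min_aa=min_aa)
              for r in regions_b}
    kmers_b = {rid: aa_kmers(s) for rid, s in segs_b.items()}
    points = []
    for ra in regions_a:
        segs_a = al.six_frame_segments(ra.sequence, min_aa=min_aa)
        if not segs_a:
            continue
        ka = aa_kmers(segs_a)
        for rb in regions_b:
            sb = segs_b[rb.region_id]
            if not sb:
                continue
            if len(ka & kmers_b[rb.region_id]) < 2:
                continue
            hits = [h for h in
                    al.translated_search(ra.sequence, rb.sequence, pscheme,
                                         mode="tblastx", query_id=ra.region_id,
                                         subject_id=rb.region_id, min_aa=min_aa)
                    if h.e_value <= hit_e_cutoff]
            if hits:
                points.append(SyntenyPoint(ra.midpoint(length_a), rb.midpoint(length_b),
                                           aggregate_translated_hits(hits),
                                           ra.region_id, rb.region_id))
    return points


# ---------------------------------------------------------------------------
# Stop-codon frame maps
# ---------------------------------------------------------------------------

def stop_frame_map(seq: str, window: int = 100) -> StopFrameMap:
    """Stop-codon positions in the three forward frames plus windowed GC%."""
    seq = seq.upper()
    stops: dict[int, list[int]] = {0: [], 1: [], 2: []}
    for i in range(len(seq) - 2):
        if seq[i:i + 3] in _STOPS:
            stops[i % 3].append(i)
    gc_windows = [(i, _gc(seq[i:i + window])) for i in range(0, len(seq), window)]
    return StopFrameMap(stops=stops, gc_windows=gc_windows, window=window)


def calls_table(calls: list[PseudogeneCall]) -> pd.DataFrame:
    """Flat TSV-ready view of pseudogene calls (per-strain coordinate schema)."""
    rows = [{
        "genome": c.region.genome_id,
        "start": c.locus_start, "end": c.locus_end, "strand": c.strand,
        "evidence": c.evidence, "nearest_homolog": c.nearest_homolog,
        "frameshifts": c.frameshift_count, "inframe_stops": c.inframe_stop_count,
        "gc_pct": c.gc_pct, "n_hits": len(c.supporting_hits),
    } for c in calls]
    return pd.DataFrame(rows, columns=["genome", "start", "end", "strand", "evidence",
                                       "nearest_homolog", "frameshifts",
                                       "inframe_stops", "gc_pct", "n_hits"])
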