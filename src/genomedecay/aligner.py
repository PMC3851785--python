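"""Self-contained local similarity search (protein, nucleotide, translated).

This module stands in for an external BLAST installation so the whole
pipeline runs hermetically; externally produced tabular hit files can be
imported through :mod:`genomedecay.seqio` instead at any step.

The dynamic-programming engine is Smith-Waterman / Needleman-Wunsch with
affine gaps (``Bio.Align.PairwiseAligner``).  Multiple HSPs per pair are
enumerated greedily: take the best local alignment, remove the covered
subject stretch, and repeat until the e-value cutoff is reached.  Statistics
follow raw Karlin-Altschul, ``E = K m n exp(-lambda S)``, with fixed
calibration constants; they are used for ordering and loose cutoffs, not for
bit-exact parity with any particular BLAST release.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import edlib
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .seqio import Hit

__all__ = [
    "ScoringScheme",
    "protein_scheme",
    "nucleotide_scheme",
    "local_align",
    "translated_search",
    "six_frame_segments",
    "global_alignment",
    "quick_distance",
]

_STOP = "*"


def _nucleotide_matrix(match: float = 2.0, mismatch: float = -3.0):
    """Match/mismatch matrix over ACGTN in which N never matches anything."""
    mat = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            mat[a, b] = match if (a == b and a != "N") else mismatch
    return mat


@dataclass
class ScoringScheme:
    """Scoring parameters for one search mode plus Karlin-Altschul constants."""

    mode: Literal["protein", "nucleotide"] = "protein"
    matrix: object = None
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_K: float = 0.134
    karlin_lambda: float = 0.317
    e_cutoff: float = 10.0

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.karlin_lambda <= 0:
            raise ValueError("lambda must be positive")
        if self.matrix is None:
            self.matrix = (substitution_matrices.load("BLOSUM62")
                           if self.mode == "protein" else _nucleotide_matrix())

    def make_aligner(self, mode: str = "local") -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.mode = mode
        al.substitution_matrix = self.matrix
        al.open_gap_score = -(self.gap_open + self.gap_extend)
        al.extend_gap_score = -self.gap_extend
        return al

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.karlin_K * m * n * math.exp(-self.karlin_lambda * score)

    def bits(self, score: float) -> float:
        return (self.karlin_lambda * score - math.log(self.karlin_K)) / math.log(2.0)


def protein_scheme(**kw) -> ScoringScheme:
    """BLOSUM62, gap open 11 / extend 1, gapped K=0.134 lambda=0.317."""
    return ScoringScheme(mode="protein", **kw)


def nucleotide_scheme(**kw) -> ScoringScheme:
    """Match +2 / mismatch -3, gap open 5 / extend 2; ungapped-style constants."""
    kw.setdefault("gap_open", 5.0)
    kw.setdefault("gap_extend", 2.0)
    kw.setdefault("karlin_K", 0.41)
    kw.setdefault("karlin_lambda", 0.625)
    return ScoringScheme(mode="nucleotide", **kw)


_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZXU*")
_DNA_ALPHABET = set("ACGTN")


def _check_alphabet(seq: str, scheme: ScoringScheme, label: str) -> str:
    seq = seq.upper()
    if scheme.mode == "nucleotide":
        if not set(seq) <= _DNA_ALPHABET:
            raise ValueError(f"{label}: non-DNA characters for nucleotide search")
    else:
        if not set(seq) <= _PROTEIN_ALPHABET:
            raise ValueError(f"{label}: non-protein characters for protein search")
        seq = seq.replace("U", "X")
    return seq


def _alignment_stats(alignment) -> tuple[int, int, int, int]:
    """(columns, identities, mismatches, gap_opens) of a biopython alignment."""
    c = alignment.counts()
    columns = c.identities + c.mismatches + c.gaps
    qb, sb = alignment.aligned
    gap_opens = 0
    for (qprev, qnext), (sprev, snext) in zip(zip(qb[:-1], qb[1:]), zip(sb[:-1], sb[1:])):
        if qnext[0] > qprev[1]:
            gap_opens += 1
        if snext[0] > sprev[1]:
            gap_opens += 1
    return columns, c.identities, c.mismatches, gap_opens


def local_align(query: str, subject: str, scheme: ScoringScheme | None = None,
                query_id: str = "query", subject_id: str = "subject",
                max_hsps: int = 25, min_segment: int = 8,
                _m: int | None = None, _n: int | None = None) -> list[Hit]:
    """Greedy multi-HSP Smith-Waterman search of ``query`` against ``subject``.

    Returns non-overlapping (in the subject) HSPs with e-value at most the
    scheme's cutoff, best first.  Coordinates in the returned hits are
    1-based inclusive, plus strand.
    """
    scheme = scheme or protein_scheme()
    query = _check_alphabet(query, scheme, "query")
    subject = _check_alphabet(subject, scheme, "subject")
    if not query or not subject:
        raise ValueError("empty sequence")
    m = _m if _m is not None else len(query)
    n = _n if _n is not None else len(subject)
    aligner = scheme.make_aligner("local")

    hits: list[Hit] = []

    def search(sub: str, offset: int) -> None:
        if len(hits) >= max_hsps or len(sub) < min_segment:
            return
        try:
            alignments = aligner.align(query, sub)
            alignment = alignments[0]
        except (ValueError, IndexError):
            return
        score = alignment.score
        if score <= 0:
            return
        ev = scheme.evalue(score, m, n)
        if ev > scheme.e_cutoff:
            return
        columns, ident, mism, gap_opens = _alignment_stats(alignment)
        if columns == 0:
            return
        coords = alignment.coordinates
        q0, q1 = int(coords[0][0]), int(coords[0][-1])
        s0, s1 = int(coords[1][0]), int(coords[1][-1])
        hits.append(Hit(
            query_id=query_id, subject_id=subject_id,
            pct_identity=100.0 * ident / columns, aln_length=columns,
            mismatches=mism, gap_opens=gap_opens,
            q_start=q0 + 1, q_end=q1,
            s_start=offset + s0 + 1, s_end=offset + s1,
            e_value=ev, bit_score=scheme.bits(score)))
        # mask the covered subject stretch and search both flanks
        search(sub[:s0], offset)
        search(sub[s1:], offset + s1)

    search(subject, 0)
    hits.sort(key=lambda h: (h.e_value, -h.bit_score))
    return hits


# ---------------------------------------------------------------------------
# Translated search
# ---------------------------------------------------------------------------

def six_frame_segments(dna: str, min_aa: int = 15) -> list[tuple[int, str, int, int]]:
    """Stop-free translated segments of all six reading frames.

    Returns ``(frame, peptide, dna_start, dna_end)`` with frame in
    {+1,+2,+3,-1,-2,-3} and DNA coordinates 0-based half-open on the forward
    strand.  Internal stop codons split a frame into segments; segments
    shorter than ``min_aa`` residues are dropped.  Bacterial genetic code
    (translation table 11).
    """
    dna = dna.upper()
    L = len(dna)
    out: list[tuple[int, str, int, int]] = []
    for strand, seq in ((1, dna), (-1, str(Seq(dna).reverse_complement()))):
        for off in range(3):
            n_codons = (len(seq) - off) // 3
            if n_codons < 1:
                continue
            aa = str(Seq(seq[off:off + 3 * n_codons]).translate(table=11))
            start = 0
            for chunk in aa.split(_STOP):
                if len(chunk) >= min_aa:
                    a0, a1 = start, start + len(chunk)
                    if strand == 1:
                        d0, d1 = off + 3 * a0, off + 3 * a1
                    else:
                        d0, d1 = L - (off + 3 * a1), L - (off + 3 * a0)
                    out.append((strand * (off + 1), chunk, d0, d1))
                start += len(chunk) + 1
    return out


def _segment_hit(h: Hit, frame: int, d0: int, d1: int, side: str) -> Hit:
    """Re-express one protein-level hit's coordinates on the segment's DNA."""
    if side == "q":
        a0, a1 = h.q_start - 1, h.q_end
    else:
        a0, a1 = h.s_start - 1, h.s_end
    if frame > 0:
        lo, hi = d0 + 3 * a0, d0 + 3 * a1          # forward: [lo, hi)
        start, end = lo + 1, hi
    else:
        lo, hi = d1 - 3 * a1, d1 - 3 * a0
        start, end = hi, lo + 1                     # minus: start > end
    kw = dict(query_id=h.query_id, subject_id=h.subject_id,
              pct_identity=h.pct_identity, aln_length=h.aln_length,
              mismatches=h.mismatches, gap_opens=h.gap_opens,
              q_start=h.q_start, q_end=h.q_end, s_start=h.s_start, s_end=h.s_end,
              e_value=h.e_value, bit_score=h.bit_score,
              frame_q=h.frame_q, frame_s=h.frame_s)
    if side == "q":
        kw.update(q_start=start, q_end=end, frame_q=frame)
    else:
        kw.update(s_start=start, s_end=end, frame_s=frame)
    return Hit(**kw)


def translated_search(query: str, subject: str, scheme: ScoringScheme | None = None,
                      mode: Literal["tblastn", "tblastx"] = "tblastn",
                      query_id: str = "query", subject_id: str = "subject",
                      min_aa: int = 15) -> list[Hit]:
    """Protein-level search against the six-frame translation of DNA.

    ``tblastn`` mode takes a protein query against a translated DNA subject;
    ``tblastx`` translates both sides.  Hit coordinates on any translated
    side are on the DNA (1-based inclusive, start > end for minus frames)
    and carry the reading frame.
    """
    scheme = scheme or protein_scheme()
    if scheme.mode != "protein":
        raise ValueError("translated search requires a protein scoring scheme")
    sub_segments = six_frame_segments(subject, min_aa=min_aa)
    if mode == "tblastn":
        q_segments = [(0, query.upper(), 0, 3 * len(query))]
        m = len(query)
    elif mode == "tblastx":
        q_segments = six_frame_segments(query, min_aa=min_aa)
        m = len(query) // 3
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n = len(subject) // 3
    hits: list[Hit] = []
    for fq, qpep, qd0, qd1 in q_segments:
        for fs, spep, sd0, sd1 in sub_segments:
            for h in local_align(qpep, spep, scheme, query_id, subject_id,
                                 _m=max(m, 1), _n=max(n, 1)):
                h = _segment_hit(h, fs, sd0, sd1, "s")
                if fq != 0:
                    h = _segment_hit(h, fq, qd0, qd1, "q")
                hits.append(h)
    hits.sort(key=lambda h: (h.e_value, -h.bit_score))
    return hits


# ---------------------------------------------------------------------------
# Helpers shared by the pipeline stages
# ---------------------------------------------------------------------------

def global_alignment(a: str, b: str, scheme: ScoringScheme | None = None):
    """Best global (Needleman-Wunsch, affine) alignment of two sequences."""
    scheme = scheme or protein_scheme()
    aligner = scheme.make_aligner("global")
    return aligner.align(a.upper(), b.upper())[0]


def quick_distance(a: str, b: str, mode: str = "HW") -> float:
    """Normalized edit distance (fast prescreen for all-vs-all searches).

    ``HW`` (infix) mode finds the best placement of ``a`` inside ``b``;
    distance is normalized by ``len(a)``.  Exact scoring of every reported
    hit is still done by the dynamic-programming engine; this only decides
    which pairs are worth aligning.
    """
    if not a or not b:
        return 1.0
    d = edlib.align(a, b, mode=mode, task="distance")["editDistance"]
    if d < 0:
        return 1.0
    return d / len(a)
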