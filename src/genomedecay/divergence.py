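"""Per-gene and genome-wide divergence metrics.

Gene pairs are compared by aligning the proteins globally first and then
inducing the nucleotide alignment codon-wise from the protein alignment
(each aligned residue pair expands to its three source bases, a residue gap
to a codon gap).  Identity denominators exclude columns with a gap in
either sequence by default (pairwise deletion); the include-gaps alternative
is exposed.  Amplicon reads are classified by best local-alignment identity
against a reference sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import aligner as al
from Bio.Seq import Seq

__all__ = [
    "GenePairIdentity",
    "pair_identity",
    "identity_distribution",
    "trim_alignment",
    "identity_matrix",
    "classify_amplicons",
    "divergence_time_range",
]


@dataclass(frozen=True)
class GenePairIdentity:
    name: str
    alignment_length: int          # bases, includes codon gap columns
    protein_identity: float        # %
    nucleotide_identity: float     # %
    aligned_protein: tuple[str, str] = ("", "")
    aligned_nucleotide: tuple[str, str] = ("", "")


def _translate_cds(cds: str, name: str) -> str:
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"{name}: CDS length {len(cds)} not divisible by 3")
    prot = str(Seq(cds).translate(table=11))
    if prot.endswith("*"):
        prot = prot[:-1]
        cds = cds[:-3]
    if "*" in prot:
        raise ValueError(f"{name}: internal stop codon in translation")
    return prot


def _identity(a: str, b: str, include_gaps: bool = False) -> float:
    matches = cols = 0
    for x, y in zip(a, b):
        if x == "-" and y == "-":
            continue
        if x == "-" or y == "-":
            if include_gaps:
                cols += 1
            continue
        cols += 1
        if x == y and x != "N":
            matches += 1
    return 100.0 * matches / cols if cols else 0.0


def pair_identity(cds_a: str, cds_b: str, name: str = "",
                  scheme: al.ScoringScheme | None = None,
                  include_gaps: bool = False) -> GenePairIdentity:
    """Protein and codon-induced nucleotide identity of two CDSs.

    The protein alignment is global (whole genes are being compared); the
    nucleotide alignment is read off it codon by codon, so its length is
    exactly three times the protein alignment length.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    prot_a = _translate_cds(cds_a, name or "cds_a")
    prot_b = _translate_cds(cds_b, name or "cds_b")
    cds_a, cds_b = cds_a[:3 * len(prot_a)], cds_b[:3 * len(prot_b)]
    alignment = al.global_alignment(prot_a, prot_b, scheme or al.protein_scheme())
    row_a, row_b = str(alignment[0]), str(alignment[1])
    nt_a = []
    nt_b = []
    ia = ib = 0
    for x, y in zip(row_a, row_b):
        if x == "-":
            nt_a.append("---")
        else:
            nt_a.append(cds_a[3 * ia:3 * ia + 3])
            ia += 1
        if y == "-":
            nt_b.append("---")
        else:
            nt_b.append(cds_b[3 * ib:3 * ib + 3])
            ib += 1
    nta, ntb = "".join(nt_a), "".join(nt_b)
    return GenePairIdentity(
        name=name, alignment_length=len(nta),
        protein_identity=_identity(row_a, row_b, include_gaps),
        nucleotide_identity=_identity(nta, ntb, include_gaps),
        aligned_protein=(row_a, row_b), aligned_nucleotide=(nta, ntb))


def identity_distribution(identities: "list[float] | np.ndarray",
                          grid: int = 256) -> dict:
    """Median and kernel-density export of a set of pairwise identities."""
    vals = np.asarray(identities, dtype=float)
    if vals.size == 0:
        raise ValueError("no identities given")
    out = {"median": float(np.median(vals)), "n": int(vals.size),
           "values": vals}
    if vals.size >= 3 and np.ptp(vals) > 0:
        kde = stats.gaussian_kde(vals)
        xs = np.linspace(vals.min() - 5, min(vals.max() + 5, 100.0), grid)
        out["density_x"] = xs
        out["density_y"] = kde(xs)
    return out


# ---------------------------------------------------------------------------
# MSA utilities
# ---------------------------------------------------------------------------

def trim_alignment(msa: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Trim ragged alignment ends.

    Leading columns are removed up to the first column in which every
    sequence has a residue; trailing columns likewise from the other end.
    Interior columns are untouched.  Idempotent.
    """
    if not msa:
        return []
    names, rows = zip(*msa)
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise ValueError("alignment rows have unequal lengths")
    full = [all(r[i] != "-" for r in rows) for i in range(L)]
    try:
        first = full.index(True)
        last = L - 1 - full[::-1].index(True)
    except ValueError:
        return [(n, "") for n in names]
    return [(n, r[first:last + 1]) for n, r in msa]


def identity_matrix(msa: list[tuple[str, str]], include_gaps: bool = False) -> pd.DataFrame:
    """Symmetric pairwise percent-identity matrix from an alignment.

    By default columns with a gap in either member of a pair are excluded
    from that pair's denominator (pairwise deletion).
    """
    names = [n for n, _ in msa]
    mat = pd.DataFrame(np.full((len(msa), len(msa)), 100.0), index=names, columns=names)
    for i in range(len(msa)):
        for j in range(i + 1, len(msa)):
            v = _identity(msa[i][1], msa[j][1], include_gaps)
            mat.iat[i, j] = mat.iat[j, i] = v
    return mat


# ---------------------------------------------------------------------------
# Amplicon classification
# ---------------------------------------------------------------------------

def classify_amplicons(reads: list[tuple[str, str]], ref: str,
                       threshold: float = 98.0,
                       scheme: al.ScoringScheme | None = None) -> dict:
    """Count reads matching a reference at >= ``threshold`` % local identity.

    Reads are sequencing fragments, so the alignment is local.  Returns the
    matching read ids, their count and their fraction of all reads.
    """
    scheme = scheme or al.nucleotide_scheme()
    matched = []
    for rid, seq in reads:
        hits = al.local_align(seq, ref, scheme, query_id=rid, subject_id="ref",
                              max_hsps=1)
        if hits and hits[0].pct_identity >= threshold and \
                hits[0].aln_length >= 0.5 * len(seq):
            matched.append(rid)
    n = len(reads)
    return {"matched_ids": matched, "count": len(matched),
            "fraction": len(matched) / n if n else 0.0}


def divergence_time_range(divergence_pct: float, rate_low: float,
                          rate_high: float) -> tuple[float, float]:
    """Divergence time window (Myr) from a % divergence and per-Myr rate bounds."""
    if rate_low <= 0 or rate_high <= 0:
        raise ValueError("rates must be positive")
    return divergence_pct / rate_high, divergence_pct / rate_low
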