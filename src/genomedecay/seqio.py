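"""Data model and readers/writers for genomes, features, intergenic regions and hit tables.

All internal coordinates are 0-based half-open on the forward strand.  File
dialects keep their native conventions and are converted at the boundary:
GenBank locations are 1-based inclusive, the 12-column tabular hit format is
1-based inclusive with start > end signalling the reverse strand/frame.

A circular replicon is a first-class citizen here: a feature or intergenic
region may wrap through the origin, in which case ``end`` exceeds the genome
length and coordinates are interpreted modulo ``length``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, CompoundLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneFeature",
    "GenomeRecord",
    "IntergenicRegion",
    "Hit",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "extract_intergenic",
    "read_hits",
    "write_hits",
    "circular_distance",
]

_RNA_KINDS = {"rRNA": "rRNA", "tRNA": "tRNA", "ncRNA": "other-RNA", "tmRNA": "other-RNA",
              "misc_RNA": "other-RNA"}
FEATURE_KINDS = ("CDS", "rRNA", "tRNA", "other-RNA", "pseudo")


class GenomeIOError(ValueError):
    """Raised for malformed genome files or features outside the sequence."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on a replicon, 0-based half-open.

    ``end > genome length`` together with ``wraps=True`` denotes a feature
    running through the origin of a circular replicon.
    """

    locus_tag: str
    start: int
    end: int
    strand: str  # '+' or '-'
    kind: str = "CDS"
    product: str = ""
    translation: str | None = None
    wraps: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end}) for {self.locus_tag}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sequence(self, genome: "GenomeRecord") -> str:
        """Feature nucleotide sequence in reading orientation."""
        raw = genome.slice(self.start, self.end)
        if self.strand == "-":
            return str(Seq(raw).reverse_complement())
        return raw


@dataclass
class GenomeRecord:
    """An annotated replicon: sequence plus an ordered list of gene features."""

    id: str
    sequence: str
    topology: str = "circular"  # or "linear"
    features: list[GeneFeature] = field(default_factory=list)
    description: str = ""

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if len(self.sequence) == 0:
            raise GenomeIOError(f"{self.id}: empty sequence")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"bad topology {self.topology!r}")
        self.features.sort(key=lambda f: (f.start, f.end))
        for f in self.features:
            limit = self.length * 2 if (f.wraps and self.topology == "circular") else self.length
            if f.end > limit:
                raise GenomeIOError(f"{self.id}: feature {f.locus_tag} outside sequence "
                                    f"([{f.start},{f.end}) vs length {self.length})")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Subsequence [start, end); wraps through the origin when end > length."""
        if end <= self.length:
            return self.sequence[start:end]
        if self.topology != "circular":
            raise GenomeIOError(f"{self.id}: slice beyond end of linear sequence")
        return self.sequence[start:] + self.sequence[: end - self.length]

    def cds_features(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "CDS"]


@dataclass(frozen=True)
class IntergenicRegion:
    """Genomic DNA not covered by any annotated gene feature."""

    genome_id: str
    start: int
    end: int  # may exceed genome length for the wrap-around region
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start

    def midpoint(self, genome_length: int) -> int:
        return ((self.start + self.end) // 2) % genome_length

    @property
    def region_id(self) -> str:
        return f"{self.genome_id}|ig|{self.start}-{self.end}"


@dataclass(frozen=True)
class Hit:
    """One local-similarity HSP in 12-column tabular semantics.

    Coordinates are 1-based inclusive as on disk; ``q_start > q_end`` (or the
    subject equivalent) marks a minus-strand/minus-frame coordinate pair.
    ``frame_q``/``frame_s`` are 0 for untranslated searches.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float
    frame_q: int = 0
    frame_s: int = 0

    def __post_init__(self):
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity outside [0, 100]")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")

    # subject coordinates on the forward strand, 0-based half-open
    @property
    def s_span(self) -> tuple[int, int]:
        lo, hi = sorted((self.s_start, self.s_end))
        return lo - 1, hi

    @property
    def q_span(self) -> tuple[int, int]:
        lo, hi = sorted((self.q_start, self.q_end))
        return lo - 1, hi


def circular_distance(a: int, b: int, length: int) -> int:
    """Shortest distance between two coordinates on a circle of given length."""
    d = abs(a - b) % length
    return min(d, length - d)


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

def _feature_kind(ftype: str, qualifiers: dict) -> str | None:
    if "pseudo" in qualifiers or "pseudogene" in qualifiers:
        return "pseudo"
    if ftype == "CDS":
        return "CDS"
    return _RNA_KINDS.get(ftype)


def read_genbank(path: str | Path) -> GenomeRecord:
    """Read one GenBank flat file into a :class:`GenomeRecord`.

    GenBank 1-based inclusive locations become 0-based half-open; a
    ``join`` spanning the origin of a circular record becomes a wrapped
    feature.  Features typed other than CDS/RNA (``gene``, ``source`` ...)
    are ignored; ``/pseudo`` qualified features are kept with kind
    ``pseudo``.
    """
    rec = SeqIO.read(str(path), "genbank")
    seq = str(rec.seq)
    if not seq or set(seq) == {"N"} and len(seq) < 1:
        raise GenomeIOError(f"{path}: record has no sequence")
    topology = rec.annotations.get("topology", "linear")
    length = len(seq)
    feats: list[GeneFeature] = []
    errors: list[str] = []
    for f in rec.features:
        kind = _feature_kind(f.type, f.qualifiers)
        if kind is None:
            continue
        locus = f.qualifiers.get("locus_tag", [f.qualifiers.get("gene", ["?"])[0]])[0]
        product = f.qualifiers.get("product", [""])[0]
        translation = f.qualifiers.get("translation", [None])[0]
        strand = "-" if f.location.strand == -1 else "+"
        parts = sorted(f.location.parts, key=lambda p: int(p.start))
        start = int(parts[0].start)
        end = int(parts[-1].end)
        wraps = False
        if len(parts) == 2 and topology == "circular" and int(parts[-1].end) == length \
                and int(parts[0].start) == 0:
            # origin-spanning join: [x, L) + [0, y)
            start = int(parts[-1].start)
            end = length + int(parts[0].end)
            wraps = True
        if end > (2 * length if wraps else length) or start >= length:
            errors.append(locus)
            continue
        feats.append(GeneFeature(locus, start, end, strand, kind, product, translation, wraps))
    if errors:
        raise GenomeIOError(f"{path}: features outside sequence: {', '.join(errors)}")
    return GenomeRecord(rec.id or rec.name, seq, topology, feats,
                        description=rec.description or "")


def write_genbank(genome: GenomeRecord, path: str | Path) -> None:
    """Write a :class:`GenomeRecord` as a GenBank flat file (inverse of read)."""
    seqrec = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                       description=genome.description)
    seqrec.annotations["molecule_type"] = "DNA"
    seqrec.annotations["topology"] = genome.topology
    L = genome.length
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        if f.wraps:
            loc = CompoundLocation([FeatureLocation(f.start, L, strand),
                                    FeatureLocation(0, f.end - L, strand)])
        else:
            loc = FeatureLocation(f.start, f.end, strand)
        ftype = "CDS" if f.kind in ("CDS", "pseudo") else \
            ("misc_RNA" if f.kind == "other-RNA" else f.kind)
        quals: dict[str, list[str]] = {"locus_tag": [f.locus_tag]}
        if f.product:
            quals["product"] = [f.product]
        if f.translation:
            quals["translation"] = [f.translation]
        if f.kind == "pseudo":
            quals["pseudo"] = [""]
        seqrec.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    SeqIO.write([seqrec], str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# Intergenic extraction
# ---------------------------------------------------------------------------

def extract_intergenic(genome: GenomeRecord, min_len: int = 100) -> list[IntergenicRegion]:
    """Complement of the union of all annotated features, dropping short gaps.

    Every feature kind counts as covered (RNA genes included).  On a circular
    replicon the gap through the origin is emitted once, as a wrapped region.
    Regions shorter than ``min_len`` (default 100 bp) are discarded.
    """
    L = genome.length
    intervals: list[tuple[int, int]] = []
    for f in genome.features:
        if f.wraps or f.end > L:
            intervals.append((f.start, L))
            intervals.append((0, f.end - L))
        else:
            intervals.append((f.start, f.end))
    if not intervals:
        regions = [IntergenicRegion(genome.id, 0, L, genome.sequence)]
        return [r for r in regions if r.length >= min_len]
    intervals.sort()
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    gaps: list[tuple[int, int]] = []
    for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
        gaps.append((e1, s2))
    head = (0, merged[0][0])          # before the first feature
    tail = (merged[-1][1], L)         # after the last feature
    if genome.topology == "circular":
        if head[1] > 0 or tail[0] < L:
            # single wrap-around gap from the last feature end to the first start
            gaps.append((tail[0], L + head[1]))
    else:
        if head[1] > head[0]:
            gaps.append(head)
        if tail[1] > tail[0]:
            gaps.append(tail)

    out = []
    for s, e in sorted(gaps):
        if e - s >= min_len:
            out.append(IntergenicRegion(genome.id, s, e, genome.slice(s, e)))
    return out


# ---------------------------------------------------------------------------
# Tabular hits (12-column dialect, optional 2 frame columns appended)
# ---------------------------------------------------------------------------

def read_hits(path: str | Path) -> list[Hit]:
    """Read a 12-column tab-separated hit table (frames in columns 13-14 if present)."""
    hits: list[Hit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) not in (12, 14):
                raise GenomeIOError(f"{path}:{lineno}: expected 12 (or 14) columns, "
                                    f"got {len(cols)}")
            try:
                hit = Hit(
                    query_id=cols[0], subject_id=cols[1],
                    pct_identity=float(cols[2]), aln_length=int(cols[3]),
                    mismatches=int(cols[4]), gap_opens=int(cols[5]),
                    q_start=int(cols[6]), q_end=int(cols[7]),
                    s_start=int(cols[8]), s_end=int(cols[9]),
                    e_value=float(cols[10]), bit_score=float(cols[11]),
                    frame_q=int(cols[12]) if len(cols) == 14 else 0,
                    frame_s=int(cols[13]) if len(cols) == 14 else 0,
                )
            except ValueError as exc:
                raise GenomeIOError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_hits(hits: Sequence[Hit], path: str | Path, frames: bool | None = None) -> None:
    """Write hits in the tabular dialect; frame columns written when any are translated."""
    if frames is None:
        frames = any(h.frame_q or h.frame_s for h in hits)
    with open(path, "w") as fh:
        for h in hits:
            # shortest round-trip float repr so read(write(h)) == h exactly
            row = [h.query_id, h.subject_id, repr(h.pct_identity), str(h.aln_length),
                   str(h.mismatches), str(h.gap_opens), str(h.q_start), str(h.q_end),
                   str(h.s_start), str(h.s_end), repr(h.e_value), repr(h.bit_score)]
            if frames:
                row += [str(h.frame_q), str(h.frame_s)]
            fh.write("\t".join(row) + "\n")
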