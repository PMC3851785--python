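"""Ground-truthed simulator of an ancestor genome and two eroding descendants.

The generator emulates the statistical regime of a vertically transmitted
intracellular symbiont pair diverging in isolation:

* a circular ancestor of protein-coding genes (ATG-started, stop-free,
  stop-terminated ORFs at a coding GC target) separated by AT-poorer
  neutral spacers, plus a few conserved RNA genes;
* two descendants evolved independently to a per-branch protein divergence
  target under a purifying-selection proxy (synonymous point mutations
  always accepted, nonsynonymous accepted with a small probability,
  nonsense never);
* nonfunctional DNA (spacers, and genes after pseudogenization) drifting
  neutrally with an AT-biased substitution process;
* a small fraction of genes pseudogenized per branch (frameshifts and
  in-frame stops, then neutral drift) and left deliberately unannotated,
  so the analysis pipeline must rediscover them;
* a small fraction of genes deleted outright;
* an exactly controlled number of large in-place inversions with recorded
  breakpoints.

All randomness flows through one ``numpy.random.Generator`` seeded from
``EvolutionParams.seed``; a fixed seed reproduces the genomes byte for
byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .seqio import GeneFeature, GenomeRecord, write_fasta, write_genbank

__all__ = ["EvolutionParams", "TruthTable", "simulate_ancestor",
           "evolve_descendant", "simulate_pair", "simulate_contig_profiles",
           "simulate_eroded_intergenic", "emit"]

_STOPS = ("TAA", "TAG", "TGA")
_BASES = np.array(list("ACGT"))


@dataclass
class EvolutionParams:
    """Scenario parameters; defaults are the package's standard study conditions."""

    n_genes: int = 300
    gene_len_mean: float = 300.0       # codons
    gene_len_sd: float = 80.0
    gene_len_min: int = 60
    spacer_len_mean: float = 600.0     # bases
    spacer_len_sd: float = 200.0
    spacer_len_min: int = 120
    coding_gc: float = 0.41
    spacer_gc: float = 0.30            # ancestral; drifts down under AT bias
    rna_genes: int = 6
    rna_gc: float = 0.45
    protein_divergence: float = 0.075  # per branch, fraction of residues changed
    nonsyn_acceptance: float = 0.15    # synonymous acceptance is 1, nonsense 0
    neutral_divergence: float = 0.35   # per branch, fraction of sites substituted
    at_bias: float = 0.85              # P(new base is A or T) in neutral drift
    pseudogenization: float = 0.05     # per branch, fraction of genes disrupted
    disruptions_min: int = 2
    disruptions_max: int = 4
    deletion: float = 0.02             # per branch, fraction of genes deleted
    n_inversions: int = 2
    inversion_span: int = 50_000       # bases
    seed: int = 0

    def __post_init__(self):
        for name in ("protein_divergence", "nonsyn_acceptance", "neutral_divergence",
                     "at_bias", "pseudogenization", "deletion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class _Element:
    """One unit of the genome mosaic: a gene, RNA gene, or spacer."""

    kind: str                  # "gene" | "rna" | "spacer"
    name: str
    seq: str
    strand: str = "+"
    ancestor: str | None = None
    state: str = "intact"      # "intact" | "pseudogene" | "never-coding"
    events: list = field(default_factory=list)


@dataclass
class TruthTable:
    """Ground truth linking every descendant element to its ancestral source."""

    gene_fate: pd.DataFrame          # ancestor_gene, fate, n_disruptions
    events: pd.DataFrame             # ancestor_gene, type, detail
    inversions: pd.DataFrame         # start, end (genome coordinates)
    element_coords: pd.DataFrame     # name, kind, state, start, end, strand


# ---------------------------------------------------------------------------
# Ancestor
# ---------------------------------------------------------------------------

def _random_codon(rng: np.random.Generator, gc: float) -> str:
    while True:
        c = "".join("GC"[rng.integers(0, 2)] if rng.random() < gc else
                    "AT"[rng.integers(0, 2)] for _ in range(3))
        if c not in _STOPS:
            return c


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    gc_draw = rng.random(n) < gc
    halves = rng.integers(0, 2, n)
    out = np.where(gc_draw, np.where(halves == 0, "G", "C"),
                   np.where(halves == 0, "A", "T"))
    return "".join(out)


def _random_gene(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    body = "".join(_random_codon(rng, gc) for _ in range(n_codons - 2))
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + body + stop


def simulate_ancestor(p: EvolutionParams) -> tuple[GenomeRecord, list[_Element]]:
    """Circular ancestor genome: alternating genes and spacers, a few RNA genes."""
    rng = np.random.default_rng(p.seed)
    elements: list[_Element] = []
    rna_slots = set()
    if p.rna_genes and p.n_genes:
        rna_slots = set(np.linspace(0, p.n_genes - 1, p.rna_genes, dtype=int))
    for i in range(p.n_genes):
        n_codons = max(p.gene_len_min,
                       int(round(rng.normal(p.gene_len_mean, p.gene_len_sd))))
        strand = "+" if rng.random() < 0.5 else "-"
        cds = _random_gene(rng, n_codons, p.coding_gc)
        # element sequences are stored in forward genomic orientation
        fwd = cds if strand == "+" else str(Seq(cds).reverse_complement())
        elements.append(_Element("gene", f"anc_{i:04d}", fwd, strand,
                                 ancestor=f"anc_{i:04d}"))
        if i in rna_slots:
            ln = int(rng.integers(90, 1500))
            elements.append(_Element("rna", f"rna_{i:04d}",
                                     _random_dna(rng, ln, p.rna_gc), "+",
                                     ancestor=f"rna_{i:04d}", state="never-coding"))
        ln = max(p.spacer_len_min,
                 int(round(rng.normal(p.spacer_len_mean, p.spacer_len_sd))))
        elements.append(_Element("spacer", f"sp_{i:04d}",
                                 _random_dna(rng, ln, p.spacer_gc), "+",
                                 ancestor=f"sp_{i:04d}", state="never-coding"))
    if not elements:  # geneless scenario: a single pure spacer replicon
        ln = max(p.spacer_len_min, int(round(p.spacer_len_mean)))
        elements.append(_Element("spacer", "sp_0000",
                                 _random_dna(rng, ln, p.spacer_gc), "+",
                                 ancestor="sp_0000", state="never-coding"))
    genome = _assemble("ancestor", elements)
    return genome, elements


# ---------------------------------------------------------------------------
# Evolution
# ---------------------------------------------------------------------------

def _translate(seq: str) -> str:
    return str(Seq(seq).translate(table=11))


def _evolve_protein(rng: np.random.Generator, seq: str, target: float,
                    q_nonsyn: float) -> tuple[str, int]:
    """Point-mutate a CDS until the protein differs at ~target fraction of residues.

    Candidate mutations hit a random non-start, non-stop position; they are
    accepted with probability 1 if synonymous, ``q_nonsyn`` if
    nonsynonymous (missense), and never if they create or destroy a stop or
    the start.  Returns the evolved CDS and the realized count of changed
    residues.
    """
    seq = list(seq)
    n_codons = len(seq) // 3
    aa0 = _translate("".join(seq))
    target_changes = int(round(target * (n_codons - 2)))
    changed: set[int] = set()
    guard = 0
    while len(changed) < target_changes and guard < 200 * max(target_changes, 1):
        guard += 1
        pos = int(rng.integers(3, 3 * (n_codons - 1)))  # skip start and stop codons
        ci = pos // 3
        old_codon = "".join(seq[3 * ci:3 * ci + 3])
        new_base = "ACGT"[rng.integers(0, 4)]
        if new_base == seq[pos]:
            continue
        new_codon = old_codon[:pos % 3] + new_base + old_codon[pos % 3 + 1:]
        if new_codon in _STOPS:
            continue
        old_aa, new_aa = _translate(old_codon), _translate(new_codon)
        if old_aa == new_aa:
            seq[pos] = new_base          # synonymous: accepted
        elif rng.random() < q_nonsyn:
            seq[pos] = new_base
            if new_aa != aa0[ci]:
                changed.add(ci)
            else:
                changed.discard(ci)
    return "".join(seq), len(changed)


def _drift(rng: np.random.Generator, seq: str, rate: float, at_bias: float) -> str:
    """AT-biased neutral substitution of ~rate of all sites."""
    arr = np.array(list(seq))
    n = len(arr)
    k = rng.binomial(n, rate)
    if k == 0:
        return seq
    sites = rng.choice(n, size=k, replace=False)
    at = rng.random(k) < at_bias
    halves = rng.integers(0, 2, k)
    newb = np.where(at, np.where(halves == 0, "A", "T"),
                    np.where(halves == 0, "G", "C"))
    arr[sites] = newb
    return "".join(arr)


def _disrupt(rng: np.random.Generator, seq: str, n_events: int) -> tuple[str, list]:
    """Apply frameshifts (1-2 bp indels) and in-frame premature stops."""
    events = []
    s = seq
    for _ in range(n_events):
        kind = "frameshift" if rng.random() < 0.5 else "stop"
        # keep events inside the middle 80% so hits can still bracket them
        lo, hi = int(0.1 * len(s)), int(0.9 * len(s))
        pos = int(rng.integers(lo, max(hi, lo + 1)))
        if kind == "frameshift":
            if rng.random() < 0.5:
                nb = int(rng.integers(1, 3))
                s = s[:pos] + _random_dna(rng, nb, 0.3) + s[pos:]
                events.append(("frameshift", f"+{nb}bp@{pos}"))
            else:
                nb = int(rng.integers(1, 3))
                s = s[:pos] + s[pos + nb:]
                events.append(("frameshift", f"-{nb}bp@{pos}"))
        else:
            ci = (pos // 3) * 3
            stop = _STOPS[rng.integers(0, 3)]
            s = s[:ci] + stop + s[ci + 3:]
            events.append(("stop", f"{stop}@{ci}"))
    return s, events


def evolve_descendant(elements: list[_Element], p: EvolutionParams,
                      branch: str, seed: int) -> tuple[GenomeRecord, TruthTable]:
    """Evolve one descendant from the ancestor's element list.

    Order of operations: per-gene fate draw (deleted / pseudogenized /
    intact), sequence evolution, inversions (recorded breakpoints),
    assembly.  Pseudogenes drift at half the branch's neutral rate
    (disruption happens, on average, midway through the branch) and are
    left unannotated.
    """
    rng = np.random.default_rng(seed)
    out: list[_Element] = []
    fates = []
    all_events = []
    genes = [e for e in elements if e.kind == "gene"]
    n = len(genes)
    n_del = int(round(p.deletion * n))
    n_pseudo = int(round(p.pseudogenization * n))
    order = rng.permutation(n)
    deleted = {genes[i].name for i in order[:n_del]}
    pseudo = {genes[i].name for i in order[n_del:n_del + n_pseudo]}

    for e in elements:
        if e.kind == "gene":
            if e.name in deleted:
                fates.append({"ancestor_gene": e.name, "fate": "deleted",
                              "n_disruptions": 0})
                continue
            ori = e.seq if e.strand == "+" else str(Seq(e.seq).reverse_complement())
            if e.name in pseudo:
                n_events = int(rng.integers(p.disruptions_min, p.disruptions_max + 1))
                s, events = _disrupt(rng, ori, n_events)
                s = _drift(rng, s, p.neutral_divergence * 0.5, p.at_bias)
                if e.strand == "-":
                    s = str(Seq(s).reverse_complement())
                out.append(replace(e, seq=s, state="pseudogene",
                                   name=f"{branch}_{e.name}", events=events))
                fates.append({"ancestor_gene": e.name, "fate": "pseudogene",
                              "n_disruptions": n_events})
                all_events += [{"ancestor_gene": e.name, "type": t, "detail": d}
                               for t, d in events]
                continue
            s, _ = _evolve_protein(rng, ori, p.protein_divergence, p.nonsyn_acceptance)
            if e.strand == "-":
                s = str(Seq(s).reverse_complement())
            out.append(replace(e, seq=s, name=f"{branch}_{e.name}"))
            fates.append({"ancestor_gene": e.name, "fate": "intact", "n_disruptions": 0})
        elif e.kind == "rna":
            s = _drift(rng, e.seq, 0.02, 0.5)
            out.append(replace(e, seq=s, name=f"{branch}_{e.name}"))
        else:
            s = _drift(rng, e.seq, p.neutral_divergence, p.at_bias)
            out.append(replace(e, seq=s, name=f"{branch}_{e.name}"))

    inversions = _apply_inversions(rng, out, p) if p.n_inversions else []
    genome = _assemble(branch, out)
    coords = _coords_table(out)
    truth = TruthTable(
        gene_fate=pd.DataFrame(fates, columns=["ancestor_gene", "fate", "n_disruptions"]),
        events=pd.DataFrame(all_events, columns=["ancestor_gene", "type", "detail"]),
        inversions=pd.DataFrame(inversions, columns=["start", "end", "n_elements"]),
        element_coords=coords)
    return genome, truth


def _apply_inversions(rng: np.random.Generator, elements: list[_Element],
                      p: EvolutionParams) -> list[dict]:
    """In-place inversions of contiguous element runs of ~inversion_span bases."""
    lengths = np.array([len(e.seq) for e in elements])
    records = []
    used: set[int] = set()
    for _ in range(p.n_inversions):
        for _attempt in range(100):
            i = int(rng.integers(0, len(elements)))
            j = i
            span = lengths[i]
            while j + 1 < len(elements) and span < p.inversion_span:
                j += 1
                span += lengths[j]
            if used & set(range(i, j + 1)) or j >= len(elements):
                continue
            used |= set(range(i, j + 1))
            start = int(lengths[:i].sum())
            seg = elements[i:j + 1]
            inverted = []
            for e in reversed(seg):
                flipped = replace(e, seq=str(Seq(e.seq).reverse_complement()),
                                  strand="-" if e.strand == "+" else "+")
                inverted.append(flipped)
            elements[i:j + 1] = inverted
            records.append({"start": start, "end": start + int(span),
                            "n_elements": j - i + 1})
            break
    return records


def _assemble(name: str, elements: list[_Element]) -> GenomeRecord:
    seq_parts = []
    feats = []
    pos = 0
    for e in elements:
        seq_parts.append(e.seq)
        end = pos + len(e.seq)
        if e.kind == "gene" and e.state == "intact":
            nt = e.seq if e.strand == "+" else str(Seq(e.seq).reverse_complement())
            feats.append(GeneFeature(e.name, pos, end, e.strand, "CDS",
                                     product=f"simulated enzyme {e.name.split('_')[-1]}",
                                     translation=_translate(nt)[:-1]))
        elif e.kind == "rna":
            feats.append(GeneFeature(e.name, pos, end, e.strand, "rRNA",
                                     product="simulated structural RNA"))
        # pseudogenes and spacers are deliberately unannotated
        pos = end
    return GenomeRecord(name, "".join(seq_parts), "circular", feats)


def _coords_table(elements: list[_Element]) -> pd.DataFrame:
    rows = []
    pos = 0
    for e in elements:
        rows.append({"name": e.name, "kind": e.kind, "state": e.state,
                     "ancestor": e.ancestor, "start": pos, "end": pos + len(e.seq),
                     "strand": e.strand})
        pos += len(e.seq)
    return pd.DataFrame(rows, columns=["name", "kind", "state", "ancestor",
                                       "start", "end", "strand"])


def simulate_pair(p: EvolutionParams | None = None
                  ) -> tuple[GenomeRecord, GenomeRecord, GenomeRecord,
                             TruthTable, TruthTable]:
    """Ancestor plus two independently evolved descendants A and B."""
    p = p or EvolutionParams()
    ancestor, elements = simulate_ancestor(p)
    # descendant seeds derived from the scenario seed; kept below 2**31
    pa = replace(p, n_inversions=0)
    genome_a, truth_a = evolve_descendant(elements, pa, "A", (p.seed * 7919 + 1) % (2**31))
    genome_b, truth_b = evolve_descendant(elements, p, "B", (p.seed * 7919 + 2) % (2**31))
    return ancestor, genome_a, genome_b, truth_a, truth_b


def simulate_eroded_intergenic(seed: int, n_regions: int = 40, codons: int = 160,
                               coding_gc: float = 0.41,
                               protein_divergence: float = 0.20,
                               nonsyn_acceptance: float = 0.15,
                               extra_drift: float = 0.08, at_bias: float = 0.85,
                               spacing: int = 200):
    """Paired once-coding intergenic sets eroded past nucleotide recognition.

    Each region pair descends from one ancestral ORF evolved independently
    on both branches under the synonymous-favored acceptance rule, then
    neutrally drifted with AT bias — the regime of decayed former genes in
    which translated searches keep a syntenic signal that nucleotide
    searches have lost.  Returns ``(regions_a, regions_b, length_a,
    length_b)`` with regions laid out in matching order.
    """
    from .seqio import IntergenicRegion

    rng = np.random.default_rng(seed)
    regions_a, regions_b = [], []
    pos_a = pos_b = spacing
    for i in range(n_regions):
        g = _random_gene(rng, codons, coding_gc)
        sa, _ = _evolve_protein(rng, g, protein_divergence, nonsyn_acceptance)
        sb, _ = _evolve_protein(rng, g, protein_divergence, nonsyn_acceptance)
        sa = _drift(rng, sa, extra_drift, at_bias)
        sb = _drift(rng, sb, extra_drift, at_bias)
        regions_a.append(IntergenicRegion("A", pos_a, pos_a + len(sa), sa))
        regions_b.append(IntergenicRegion("B", pos_b, pos_b + len(sb), sb))
        pos_a += len(sa) + spacing
        pos_b += len(sb) + spacing
    return regions_a, regions_b, pos_a, pos_b


def simulate_contig_profiles(seed: int, n_contigs: int = 10,
                             orfs_per_contig: int = 40, orf_codons: int = 250,
                             gc: float = 0.41, shifted_contig: str | None = None,
                             gc_shift: float = 0.08):
    """Per-ORF composition profiles for a simulated multi-contig bin.

    Emulates validating a metagenomic bin by nucleotide composition: every
    contig's ORFs are drawn from one composition model, except an optional
    ``shifted_contig`` whose GC target is displaced by ``gc_shift`` (a
    contaminating contig).  CAI is referenced to the first contig's genes.
    Returns a DataFrame with columns contig/gc/gc2/gc4/cai.
    """
    from . import composition as comp

    rng = np.random.default_rng(seed)
    genes: dict[str, list[str]] = {}
    for i in range(n_contigs):
        cid = f"Contig{i + 1}"
        target = gc + (gc_shift if cid == shifted_contig else 0.0)
        genes[cid] = [_random_gene(rng, orf_codons, target)
                      for _ in range(orfs_per_contig)]
    table = comp.rscu(genes["Contig1"])
    rows = []
    for cid, gs in genes.items():
        for g in gs:
            rows.append({"contig": cid, "gc": comp.gc_percent(g),
                         "gc2": comp.gc2(g), "gc4": comp.gc4(g),
                         "cai": comp.cai(g, table)})
    return pd.DataFrame(rows)


def emit(genomes: list[GenomeRecord], truths: dict[str, TruthTable],
         outdir: str | Path) -> None:
    """Write GenBank + FASTA per genome and the truth tables as TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for g in genomes:
        write_genbank(g, outdir / f"{g.id}.gbk")
        write_fasta([(g.id, g.sequence)], outdir / f"{g.id}.fasta")
    for branch, t in truths.items():
        t.gene_fate.to_csv(outdir / f"{branch}_gene_fate.tsv", sep="\t", index=False)
        t.events.to_csv(outdir / f"{branch}_events.tsv", sep="\t", index=False)
        t.inversions.to_csv(outdir / f"{branch}_inversions.tsv", sep="\t", index=False)
        t.element_coords.to_csv(outdir / f"{branch}_elements.tsv", sep="\t", index=False)
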