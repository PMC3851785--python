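"""Orchestration: run the full comparative analysis over a strain pair.

Stages: homolog pairing -> synteny model + review flags -> inversion
segments -> length screen / start extension -> orphans -> pseudogene
detection (both routes) -> intergenic synteny (nucleotide and translated)
-> composition strata -> divergence statistics.  Every numeric threshold
lives in :class:`AnalysisConfig`, which is serialized into the report so a
result is never separable from the settings that produced it.  Nothing is
dropped silently: every filtered gene, hit or region is counted in the
report's ``counts`` section.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aligner as al
from . import composition as comp
from . import decay
from . import divergence as dv
from . import homology as hom
from .seqio import GenomeRecord, extract_intergenic

logger = logging.getLogger("genomedecay")

__all__ = ["AnalysisConfig", "run_comparative", "run_contig_screen",
           "evaluate_against_truth"]


@dataclass
class AnalysisConfig:
    """Every numeric threshold of the comparative analysis, in one place."""

    min_intergenic_len: int = 100          # bp; shorter regions are discarded
    length_screen_threshold: float = 0.20  # fractional length difference (strict >)
    pseudogene_e_cutoff: float = 1e-3      # intergenic-route best-hit e-value
    amplicon_identity: float = 98.0        # % identity for read classification
    orphan_min_len: int = 300              # bp; shorter unsupported orphans removable
    hit_e_ceiling: float = 10.0            # search-wide e-value ceiling
    read_recruitment_e: float = 1e-30      # import-only, kept for provenance
    review_fraction: float = 0.10          # top synteny discrepancies flagged
    span_tolerance: float = 1.0            # pseudogene locus span vs query length
    synteny_window: int = 20_000           # bp; pseudogene locus vs synteny model
    drop_short_orphans: bool = False
    run_translated_intergenic: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("min_intergenic_len", "pseudogene_e_cutoff", "amplicon_identity",
                     "orphan_min_len", "hit_e_ceiling", "review_fraction",
                     "length_screen_threshold", "span_tolerance", "synteny_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _digest(genome: GenomeRecord) -> str:
    return hashlib.sha256(genome.sequence.encode()).hexdigest()[:12]


def run_comparative(genome_a: GenomeRecord, genome_b: GenomeRecord,
                    outgroup: GenomeRecord | None = None,
                    cfg: AnalysisConfig | None = None,
                    hits_ab: list | None = None,
                    outdir: str | Path | None = None) -> dict:
    """Full comparative degradation analysis of two strains.

    ``hits_ab`` substitutes an externally produced protein hit table for
    the internal all-vs-all search.  Returns a report dict of DataFrames
    and scalars; with ``outdir`` set, also writes the TSV bundle.
    """
    cfg = cfg or AnalysisConfig()
    report: dict = {"config": dataclasses.asdict(cfg),
                    "inputs": {genome_a.id: _digest(genome_a),
                               genome_b.id: _digest(genome_b)},
                    "counts": {}}
    counts = report["counts"]

    stage = "homolog pairing"
    try:
        genes_a, genes_b = genome_a.cds_features(), genome_b.cds_features()
        scheme = al.protein_scheme(e_cutoff=cfg.hit_e_ceiling)
        if hits_ab is None:
            logger.info("all-vs-all protein search (%d x %d genes)",
                        len(genes_a), len(genes_b))
            hits_ab = hom.all_vs_all_protein_hits(genes_a, genes_b,
                                                  genome_a, genome_b, scheme)
        counts["protein_hits"] = len(hits_ab)
        omap = hom.pair_homologs(hits_ab, genes_a, genes_b)

        stage = "synteny"
        omap, model = hom.synteny_discrepancy(omap, genome_a, genome_b,
                                              cfg.review_fraction)
        inversions = hom.reversed_segments(omap)
        counts.update(pairs=len(omap.pairs), orphans_a=len(omap.orphans_a),
                      orphans_b=len(omap.orphans_b), flagged_review=sum(
                          1 for p in omap.pairs if "manual-review" in p.flags))

        stage = "length screen"
        screen = hom.length_screen(omap.pairs, cfg.length_screen_threshold)
        counts["length_flagged"] = int(screen["flagged"].sum())

        stage = "orphans"
        orphans_a, orphans_b = omap.orphans_a, omap.orphans_b
        if cfg.drop_short_orphans:
            keep_a = [o for o in orphans_a if o.length >= cfg.orphan_min_len]
            keep_b = [o for o in orphans_b if o.length >= cfg.orphan_min_len]
            counts["short_orphans_dropped"] = (len(orphans_a) - len(keep_a)
                                               + len(orphans_b) - len(keep_b))
            orphans_a, orphans_b = keep_a, keep_b

        stage = "intergenic extraction"
        ig_a = extract_intergenic(genome_a, cfg.min_intergenic_len)
        ig_b = extract_intergenic(genome_b, cfg.min_intergenic_len)
        counts.update(intergenic_a=len(ig_a), intergenic_b=len(ig_b))

        stage = "pseudogene detection"
        # orphans of A against B's intergenic DNA find pseudogenes *in B*
        model_ab = model
        calls_b = decay.find_pseudogenes_from_orphans(
            orphans_a, genome_a, ig_b, genome_b, model_ab,
            scheme, cfg.span_tolerance, cfg.synteny_window)
        model_ba = None
        if model is not None:
            # inverse model maps B coordinates onto A
            model_ba = hom.fit_synteny_model(
                np.array([p.gene_b.start for p in omap.pairs], float),
                np.array([p.gene_a.start for p in omap.pairs], float),
                genome_b.length, genome_a.length)
        calls_a = decay.find_pseudogenes_from_orphans(
            orphans_b, genome_b, ig_a, genome_a, model_ba,
            scheme, cfg.span_tolerance, cfg.synteny_window)
        counts.update(pseudogenes_a=len(calls_a), pseudogenes_b=len(calls_b))

        stage = "intergenic synteny"
        pseudo_regions_a = {c.region.region_id for c in calls_a}
        pseudo_regions_b = {c.region.region_id for c in calls_b}
        points_nt = decay.intergenic_synteny(ig_a, ig_b, genome_a.length,
                                             genome_b.length, mode="nucleotide")
        points_tx = []
        if cfg.run_translated_intergenic:
            points_tx = decay.intergenic_synteny(ig_a, ig_b, genome_a.length,
                                                 genome_b.length, mode="translated")
        counts.update(intergenic_points_nucleotide=len(points_nt),
                      intergenic_points_translated=len(points_tx))

        stage = "composition strata"
        # pseudogene-bearing regions leave the intergenic set before statistics
        clean_ig_a = [r for r in ig_a if r.region_id not in pseudo_regions_a]
        clean_ig_b = [r for r in ig_b if r.region_id not in pseudo_regions_b]
        counts["pseudogene_regions_removed"] = (len(ig_a) - len(clean_ig_a)
                                                + len(ig_b) - len(clean_ig_b))
        strata = {
            "coding": {genome_a.id: [comp.gc_percent(f.sequence(genome_a))
                                     for f in genome_a.cds_features()],
                       genome_b.id: [comp.gc_percent(f.sequence(genome_b))
                                     for f in genome_b.cds_features()]},
            "intergenic": {genome_a.id: [comp.gc_percent(r.sequence) for r in clean_ig_a],
                           genome_b.id: [comp.gc_percent(r.sequence) for r in clean_ig_b]},
            "pseudogene": {genome_a.id: [c.gc_pct for c in calls_a],
                           genome_b.id: [c.gc_pct for c in calls_b]},
        }
        rna_a = [comp.gc_percent(f.sequence(genome_a))
                 for f in genome_a.features if f.kind in ("rRNA", "tRNA", "other-RNA")]
        rna_b = [comp.gc_percent(f.sequence(genome_b))
                 for f in genome_b.features if f.kind in ("rRNA", "tRNA", "other-RNA")]
        if len(rna_a) + len(rna_b) >= 4:
            strata["rna"] = {genome_a.id: rna_a, genome_b.id: rna_b}
        strata_result = None
        if all(sum(len(v) for v in g.values()) >= 3 for g in strata.values()):
            try:
                strata_result = comp.classify_gc_strata(strata)
            except ValueError as exc:
                logger.warning("GC strata statistics skipped: %s", exc)

        stage = "divergence"
        identities = [p.pct_identity for p in omap.pairs]
        dist = dv.identity_distribution(identities) if identities else None

        stage = "summary"
        summary = pd.DataFrame({
            g.id: {
                "length_bp": g.length,
                "protein_coding_genes": len(g.cds_features()),
                "pct_coding_cds_only": comp.coding_density(g, "cds-only"),
                "pct_coding_all_genes": comp.coding_density(g, "all-genes"),
                "gc_coding": _mean([comp.gc_percent(f.sequence(g))
                                    for f in g.cds_features()]),
                "gc_noncoding": _mean([comp.gc_percent(r.sequence) for r in ig]),
            }
            for g, ig in ((genome_a, ig_a), (genome_b, ig_b))
        })

        three_way = None
        if outgroup is not None:
            stage = "three-way outgroup check"
            hits_ao = hom.all_vs_all_protein_hits(genes_a, outgroup.cds_features(),
                                                  genome_a, outgroup, scheme)
            hits_bo = hom.all_vs_all_protein_hits(genes_b, outgroup.cds_features(),
                                                  genome_b, outgroup, scheme)
            bad = hom.three_way_check(omap, hits_ao, hits_bo)
            three_way = hom.pairs_table(hom.OrthologMap(bad, [], [])) if bad \
                else pd.DataFrame()
            counts["outgroup_conflicts"] = len(bad)
        else:
            logger.info("no outgroup supplied; three-way check skipped")

    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed on inputs "
                           f"{report['inputs']}: {exc}") from exc

    report.update(
        ortholog_map=omap, synteny_model=model,
        pairs=hom.pairs_table(omap),
        orphans_a=[o.locus_tag for o in orphans_a],
        orphans_b=[o.locus_tag for o in orphans_b],
        inversions=pd.DataFrame(inversions),
        length_screen=screen,
        pseudogenes=decay.calls_table(calls_a + calls_b),
        pseudogene_calls=(calls_a, calls_b),
        intergenic_points_nucleotide=_points_table(points_nt),
        intergenic_points_translated=_points_table(points_tx),
        gc_strata=strata, gc_strata_result=strata_result,
        median_protein_identity=(dist["median"] if dist else float("nan")),
        identity_distribution=dist,
        summary=summary, three_way=three_way,
    )
    if outdir is not None:
        _write_bundle(report, Path(outdir))
    return report


def _mean(vals: list[float]) -> float:
    return float(np.mean(vals)) if vals else float("nan")


def _points_table(points) -> pd.DataFrame:
    return pd.DataFrame([{"midpoint_a": p.midpoint_a, "midpoint_b": p.midpoint_b,
                          "weighted_identity": p.weighted_identity,
                          "region_a": p.region_a, "region_b": p.region_b}
                         for p in points],
                        columns=["midpoint_a", "midpoint_b", "weighted_identity",
                                 "region_a", "region_b"])


def _write_bundle(report: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(report["config"]))
    for key in ("pairs", "length_screen", "pseudogenes",
                "intergenic_points_nucleotide", "intergenic_points_translated",
                "inversions"):
        df = report[key]
        if isinstance(df, pd.DataFrame):
            df.to_csv(outdir / f"{key}.tsv", sep="\t", index=False)
    report["summary"].to_csv(outdir / "summary.tsv", sep="\t")
    if report["gc_strata_result"] is not None:
        report["gc_strata_result"][1].comparisons.to_csv(
            outdir / "gc_strata_tukey.tsv", sep="\t", index=False)
    counts = pd.Series(report["counts"], name="count")
    counts.to_csv(outdir / "counts.tsv", sep="\t")


def evaluate_against_truth(report: dict, truth_a, truth_b,
                           genome_a: GenomeRecord, genome_b: GenomeRecord) -> dict:
    """Score a comparative report against a simulator's ground truth.

    Returns ortholog-pair recovery and false-pairing rates, pseudogene
    sensitivity (over true pseudogenes with >= 2 disruptions) and
    specificity (over never-coding spacer regions), the number of true
    inversions recovered as reversed segments, and the median protein
    identity of the recovered pairs.
    """
    fate_a = truth_a.gene_fate.set_index("ancestor_gene")
    fate_b = truth_b.gene_fate.set_index("ancestor_gene")
    true_orthologs = {g for g in fate_a.index
                      if fate_a.loc[g, "fate"] == "intact"
                      and fate_b.loc[g, "fate"] == "intact"}

    def anc_of(tag: str) -> str:
        return tag.split("_", 1)[1]  # "A_anc_0001" -> "anc_0001"

    omap = report["ortholog_map"]
    got = {(anc_of(p.gene_a.locus_tag), anc_of(p.gene_b.locus_tag))
           for p in omap.pairs}
    correct = {a for a, b in got if a == b and a in true_orthologs}
    recovery = len(correct) / len(true_orthologs) if true_orthologs else float("nan")
    false_rate = (len(got) - len(correct)) / len(got) if got else 0.0

    # pseudogene detection: calls name the orphan they decayed from
    calls_a, calls_b = report["pseudogene_calls"]
    found_b = {anc_of(c.nearest_homolog.split()[0]) for c in calls_b}
    found_a = {anc_of(c.nearest_homolog.split()[0]) for c in calls_a}
    tp = fn = 0
    for fate, found in ((fate_a, found_a), (fate_b, found_b)):
        for g in fate.index:
            if fate.loc[g, "fate"] == "pseudogene" and fate.loc[g, "n_disruptions"] >= 2:
                if g in found:
                    tp += 1
                else:
                    fn += 1
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")

    # specificity over never-coding spacers: a call localized to a region
    # holding no true pseudogene is a false positive
    fp = 0
    n_spacers = 0
    for truth, calls, genome in ((truth_a, calls_a, genome_a),
                                 (truth_b, calls_b, genome_b)):
        ec = truth.element_coords
        pseudo_spans = [(r.start, r.end) for r in
                        ec[ec.state == "pseudogene"].itertuples()]
        n_spacers += int((ec.kind == "spacer").sum())
        for c in calls:
            hit_true = any(c.locus_start < e and s < c.locus_end
                           for s, e in pseudo_spans)
            if not hit_true:
                fp += 1
    specificity = 1.0 - fp / n_spacers if n_spacers else float("nan")

    inv_truth = truth_b.inversions
    detected = report["inversions"]
    recovered_inv = 0
    for t in inv_truth.itertuples():
        for d in (detected.itertuples() if not detected.empty else []):
            overlap = min(t.end, d.b_end) - max(t.start, d.b_start)
            if overlap > 0.5 * (t.end - t.start):
                recovered_inv += 1
                break
    return {
        "ortholog_recovery": recovery, "false_pair_rate": false_rate,
        "pseudogene_sensitivity": sensitivity, "pseudogene_specificity": specificity,
        "inversions_true": len(inv_truth), "inversions_recovered": recovered_inv,
        "median_protein_identity": report["median_protein_identity"],
        "n_true_orthologs": len(true_orthologs), "n_pairs": len(got),
    }


def run_contig_screen(profiles: pd.DataFrame, cfg: AnalysisConfig | None = None,
                      alpha: float = 0.05) -> dict:
    """Composition-based contig screen (per-ORF GC/GC2/GC4/CAI vs contig).

    ``profiles`` needs a ``contig`` column plus metric columns.  Returns
    the flagged outlier contigs and the pairwise Tukey p matrices per
    metric.
    """
    if profiles.empty:
        raise ValueError("empty contig profile table")
    flagged, results = comp.contig_screen(profiles, alpha=alpha)
    matrices = {}
    for metric, res in results.items():
        piv = res.comparisons.pivot(index="group_i", columns="group_j", values="p_adj")
        matrices[metric] = piv
    return {"outliers": flagged, "tukey": results, "p_matrices": matrices}
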