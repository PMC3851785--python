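"""Nucleotide-composition analytics and group statistics.

Per-ORF metrics: GC%, GC2 (G+C at second codon positions), GC4 (G+C at
third positions of the eight fourfold-degenerate codon families), RSCU
(relative synonymous codon usage) and CAI (codon adaptation index, Sharp &
Li: geometric mean of per-codon relative adaptiveness ``w`` excluding ATG,
TGG and stops).  Group comparisons use one-way fixed-effects ANOVA followed
by Tukey's HSD with adjusted p-values from the studentized-range
distribution (Tukey-Kramer for unequal group sizes, matching R's
``aov``/``TukeyHSD``).

Ambiguity handling: ``N`` counts as non-GC everywhere.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import GenomeRecord

__all__ = [
    "CodonUsageTable",
    "TukeyResult",
    "gc_percent",
    "gc2",
    "gc3",
    "gc4",
    "rscu",
    "cai",
    "group_anova_tukey",
    "classify_gc_strata",
    "contig_screen",
    "coding_density",
    "variant_rate",
    "composition_profile",
]

_BASES = "TCAG"
CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_STOPS = {"TAA", "TAG", "TGA"}

# synonymous families of the standard/bacterial code (stops excluded)
_CODON_AA = {}
_TABLE11 = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
for _c, _a in zip(CODONS, _TABLE11):
    _CODON_AA[_c] = _a
FAMILIES: dict[str, list[str]] = {}
for _c, _a in _CODON_AA.items():
    if _a != "*":
        FAMILIES.setdefault(_a, []).append(_c)

# fourfold-degenerate codon families (third position is free)
FOURFOLD_PREFIXES = ("CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG")


def _check_cds(cds: str, what: str) -> str:
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError(f"{what} requires an in-frame CDS (length divisible by 3), "
                         f"got length {len(cds)}")
    return cds


def gc_percent(seq: str) -> float:
    """G+C percentage of a sequence; N and other ambiguity codes count as non-GC."""
    seq = seq.upper()
    if not seq:
        return 0.0
    return 100.0 * sum(1 for c in seq if c in "GC") / len(seq)


def gc2(cds: str) -> float:
    """G+C percentage at second codon positions."""
    cds = _check_cds(cds, "gc2")
    return gc_percent(cds[1::3])


def gc3(cds: str) -> float:
    """G+C percentage at all third codon positions (alternative to GC4)."""
    cds = _check_cds(cds, "gc3")
    return gc_percent(cds[2::3])


def gc4(cds: str) -> float:
    """G+C percentage at third positions of fourfold-degenerate codons only."""
    cds = _check_cds(cds, "gc4")
    thirds = [cds[i + 2] for i in range(0, len(cds), 3)
              if cds[i:i + 2] in FOURFOLD_PREFIXES]
    if not thirds:
        return 0.0
    return gc_percent("".join(thirds))


# ---------------------------------------------------------------------------
# RSCU / CAI
# ---------------------------------------------------------------------------

@dataclass
class CodonUsageTable:
    counts: dict[str, float]
    rscu: dict[str, float]
    w: dict[str, float]


def _codons(cds: str):
    return (cds[i:i + 3] for i in range(0, len(cds), 3))


def rscu(genes: list[str], pseudocount: float = 0.5) -> CodonUsageTable:
    """Reference codon-usage table (RSCU and relative adaptiveness w).

    ``RSCU_c = count_c / mean(count over the synonymous family)`` and
    ``w_c = RSCU_c / max(RSCU within the family)``.  Codons absent from the
    reference set receive a 0.5 pseudo-count first, so that CAI of a gene
    using a rare codon is penalized rather than undefined.
    """
    if not genes:
        raise ValueError("empty reference gene set")
    counts = {c: 0.0 for c in CODONS}
    for g in genes:
        g = _check_cds(g, "rscu")
        for c in _codons(g):
            if c in counts:
                counts[c] += 1.0
    for c in counts:
        if counts[c] == 0 and c not in _STOPS:
            counts[c] = pseudocount
    rscu_vals = {}
    w_vals = {}
    for fam in FAMILIES.values():
        mean = sum(counts[c] for c in fam) / len(fam)
        for c in fam:
            rscu_vals[c] = counts[c] / mean if mean > 0 else 0.0
        mx = max(rscu_vals[c] for c in fam)
        for c in fam:
            w_vals[c] = rscu_vals[c] / mx if mx > 0 else 0.0
    return CodonUsageTable(counts=counts, rscu=rscu_vals, w=w_vals)


def cai(cds: str, table: CodonUsageTable) -> float:
    """Codon adaptation index: geometric mean of w over the gene's codons.

    ATG and TGG (the single-codon families) and stop codons are excluded,
    as in Sharp & Li.
    """
    cds = _check_cds(cds, "cai")
    logs = []
    for c in _codons(cds):
        if c in _STOPS or c in ("ATG", "TGG") or c not in table.w:
            continue
        w = table.w[c]
        logs.append(math.log(max(w, 1e-12)))
    if not logs:
        raise ValueError("gene contributes no codons to CAI")
    return math.exp(sum(logs) / len(logs))


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD
# ---------------------------------------------------------------------------

@dataclass
class TukeyResult:
    anova_F: float
    anova_p: float
    comparisons: pd.DataFrame  # group_i, group_j, mean_diff, p_adj

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        sig = self.comparisons[self.comparisons["p_adj"] < alpha]
        return list(zip(sig["group_i"], sig["group_j"]))


def group_anova_tukey(groups: dict[str, "np.ndarray | list[float]"]) -> TukeyResult:
    """One-way fixed-effects ANOVA followed by Tukey's HSD.

    Adjusted p-values come from the studentized-range distribution with the
    Tukey-Kramer standard error for unequal group sizes — the behavior of
    R's ``aov`` + ``TukeyHSD``.  Degenerate inputs (fewer than 2 groups,
    any group below 2 values, zero pooled variance) raise rather than
    returning a silent p of 0.
    """
    names = sorted(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    if len(data) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(d) < 2 for d in data):
        raise ValueError("every group needs at least 2 values")
    ns = np.array([len(d) for d in data])
    means = np.array([d.mean() for d in data])
    N, k = int(ns.sum()), len(data)
    grand = np.concatenate(data).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((d - m) ** 2).sum() for d, m in zip(data, means)))
    df_b, df_w = k - 1, N - k
    if ss_within <= 0 or df_w <= 0:
        raise ValueError("degenerate within-group variance")
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    F = ms_b / ms_w
    p = float(stats.f.sf(F, df_b, df_w))

    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[j] - means[i]
        se = math.sqrt(ms_w / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        q = abs(diff) / se
        p_adj = float(stats.studentized_range.sf(q, k, df_w))
        rows.append({"group_i": names[i], "group_j": names[j],
                     "mean_diff": float(diff), "p_adj": min(max(p_adj, 0.0), 1.0)})
    return TukeyResult(anova_F=float(F), anova_p=p,
                       comparisons=pd.DataFrame(rows, columns=["group_i", "group_j",
                                                               "mean_diff", "p_adj"]))


def classify_gc_strata(per_strain_groups: dict[str, dict[str, list[float]]],
                       alpha: float = 0.05) -> tuple[TukeyResult, TukeyResult]:
    """Two-stage GC stratification across two strains.

    ``per_strain_groups`` maps a category (``coding``, ``pseudogene``,
    ``intergenic``, ``rna`` ...) to ``{strain: values}``.  Stage one tests
    all per-strain groups jointly; a category whose two strains are *not*
    significantly different is merged across strains (categories with a
    single strain, or too few values per strain to test alone, are merged
    unconditionally — the small-sample pooling used for pseudogenes).
    Stage two reruns ANOVA + Tukey on the merged groups.  Returns the
    (stage-one, stage-two) results.
    """
    stage1_groups = {}
    for cat, strains in per_strain_groups.items():
        for strain, vals in strains.items():
            if len(vals) >= 2:
                stage1_groups[f"{cat}:{strain}"] = vals
    stage1 = group_anova_tukey(stage1_groups)
    sig = set(stage1.significant_pairs(alpha)) | \
        {(b, a) for a, b in stage1.significant_pairs(alpha)}

    merged: dict[str, list[float]] = {}
    for cat, strains in per_strain_groups.items():
        labels = [f"{cat}:{s}" for s in strains if f"{cat}:{s}" in stage1_groups]
        differ = any((la, lb) in sig for la, lb in itertools.combinations(labels, 2))
        if differ and len(labels) > 1:
            # strains of this category differ: keep them separate
            for s, vals in strains.items():
                merged[f"{cat}:{s}"] = list(vals)
        else:
            merged[cat] = [v for vals in strains.values() for v in vals]
    stage2 = group_anova_tukey(merged)
    return stage1, stage2


def contig_screen(metrics: dict[str, pd.DataFrame] | pd.DataFrame,
                  alpha: float = 0.05) -> tuple[list[str], dict[str, TukeyResult]]:
    """Flag contigs whose composition differs from any other contig.

    Input is a per-ORF table with a ``contig`` column and one column per
    metric (``gc``, ``gc2``, ``gc4``, ``cai``), or a dict of such tables.
    A contig is an outlier when, for at least one metric, at least one
    pairwise Tukey-adjusted p-value against another contig clears the
    screen-wise level ``alpha``.  Tukey HSD controls the family-wise error
    within one metric; because the four metrics are four views of the same
    question, ``alpha`` is Bonferroni-split across the metrics tested so
    the screen as a whole keeps its nominal error rate.  Returns the
    outliers and the full per-metric results (a pairwise p matrix can be
    pivoted from them).
    """
    if isinstance(metrics, dict):
        frames = metrics
    else:
        frames = {m: metrics[["contig", m]].rename(columns={m: "value"})
                  for m in ("gc", "gc2", "gc4", "cai") if m in metrics.columns}
    results: dict[str, TukeyResult] = {}
    per_metric_alpha = alpha / max(len(frames), 1)
    sig_pairs: list[tuple[str, str]] = []
    for metric, df in frames.items():
        col = "value" if "value" in df.columns else metric
        groups = {c: sub[col].to_list() for c, sub in df.groupby("contig")
                  if len(sub) >= 2}
        if len(groups) < 2:
            continue
        res = group_anova_tukey(groups)
        results[metric] = res
        sig_pairs.extend(res.significant_pairs(per_metric_alpha))
    # attribute significance: a contig with >= 2 distinct significant partners
    # is an outlier in its own right; a contig whose only significant partner
    # is itself an outlier is considered dragged in by it and kept
    partners: dict[str, set[str]] = {}
    for gi, gj in sig_pairs:
        partners.setdefault(gi, set()).add(gj)
        partners.setdefault(gj, set()).add(gi)
    if not partners:
        return [], results
    strong = {c for c, ps in partners.items() if len(ps) >= 2}
    if strong:
        return sorted(strong), results
    return sorted(partners), results  # a single significant pair: flag both


# ---------------------------------------------------------------------------
# Genome summaries
# ---------------------------------------------------------------------------

def coding_density(genome: GenomeRecord, definition: str = "cds-only") -> float:
    """Percent of the genome covered by the union of selected features.

    ``cds-only`` counts CDS features; ``all-genes`` counts every annotated
    feature (RNA genes included).
    """
    if definition == "cds-only":
        feats = [f for f in genome.features if f.kind == "CDS"]
    elif definition == "all-genes":
        feats = list(genome.features)
    else:
        raise ValueError(f"unknown definition {definition!r}")
    L = genome.length
    covered = np.zeros(L, dtype=bool)
    for f in feats:
        if f.end <= L:
            covered[f.start:f.end] = True
        else:
            covered[f.start:] = True
            covered[:f.end - L] = True
    return 100.0 * float(covered.sum()) / L


def variant_rate(n_variants: int, genome_length: int) -> float:
    """Variant sites per genome length as a percentage (assembly error rate)."""
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    return 100.0 * n_variants / genome_length


def composition_profile(genome: GenomeRecord, table: CodonUsageTable | None = None,
                        group: str = "coding") -> pd.DataFrame:
    """Per-CDS GC/GC2/GC4 (+ CAI when a reference table is given)."""
    rows = []
    for f in genome.cds_features():
        nt = f.sequence(genome)
        nt = nt[: 3 * (len(nt) // 3)]
        row = {"locus_tag": f.locus_tag, "group": group, "gc": gc_percent(nt),
               "gc2": gc2(nt), "gc4": gc4(nt)}
        if table is not None:
            row["cai"] = cai(nt, table)
        rows.append(row)
    return pd.DataFrame(rows)
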