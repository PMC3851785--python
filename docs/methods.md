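# Methods

`genomedecay` analyses genome degradation in pairs of closely related
bacterial endosymbiont strains — the regime of a vertically transmitted,
host-restricted symbiont whose two descendant lineages have been diverging
in isolation: near-total conservation of gene order, moderate protein
divergence, a small crop of recent pseudogenes hidden in unannotated DNA,
and strongly AT-shifted nonfunctional sequence. This note records the
models, the parameter choices, and the numerical decisions behind each
stage, and what the bundled simulator does and does not capture.

## Coordinates and sequence model

All internal coordinates are 0-based half-open on the forward strand; the
GenBank (1-based inclusive) and tabular-hit (1-based inclusive, start > end
on the minus strand/frame) dialects are converted at the file boundary.
Replicons are circular by default: a feature or intergenic region may wrap
through the origin (`end > length`, interpreted modulo the genome length),
the wrap-around intergenic gap is emitted exactly once, and every
"difference between coordinates" in the synteny machinery is a circular
distance. `N` counts as non-GC in every composition metric and never
matches in any identity computation.

## Similarity search

The search engine is exact Smith–Waterman (local) and Needleman–Wunsch
(global) with affine gaps, using `Bio.Align.PairwiseAligner` as the
dynamic-programming core. Default scoring: BLOSUM62 with gap open 11 /
extend 1 for protein; match +2 / mismatch −3 with gap open 5 / extend 2 for
nucleotide. Multiple HSPs per sequence pair are enumerated greedily: take
the best local alignment, remove the covered subject stretch, recurse on
the flanks. E-values follow raw Karlin–Altschul, `E = K·m·n·e^(−λS)`, with
fixed constants (protein K = 0.134, λ = 0.317; nucleotide K = 0.41,
λ = 0.625) and no edge-effect or composition corrections: e-values are used
for ordering and loose cutoffs (10, 10⁻³), not for parity with any specific
BLAST release. Externally produced 12-column tabular hit files can be
substituted for any internal search step.

Translated searches split each of the six reading frames at stop codons
(bacterial code, table 11) and align the resulting stop-free peptide
segments; hits report DNA coordinates and the reading frame. Segments
shorter than 15 residues are ignored — shorter peptides carry no usable
signal at the identity levels involved.

Because the engine is exact rather than word-seeded, two guards replace
what a seeded search would do implicitly. First, all-vs-all searches
prescreen pairs cheaply before the DP runs: a normalized edit-distance
bound (edlib, infix mode) for protein all-vs-all, shared nucleotide
16-mers for nucleotide intergenic search (the specificity of a
megablast-era word seed), and shared translated 7-mers for the translated
intergenic search. Every reported hit is still scored by the exact
aligner; the prescreens only decide which pairs are worth aligning.
Second, grouped-evidence analyses (pseudogene calling, translated
intergenic points) only admit hits with E ≤ 10⁻³, because an exact local
aligner at E ≤ 10 reports 4–6-residue chance matches that a word-seeded
tool would never emit, and those would otherwise inflate hit-group spans
and frame counts.

## Homolog pairing and synteny

Pairing is the greedy best-hit chain: keep each query's best (lowest
e-value) subject; sort retained hits by ascending e-value; walking down,
drop any hit whose subject is already taken; leftovers on either side are
orphans. E-value ties break by higher bit score, then query id, then
subject id — the procedure is deterministic. The mechanized counterpart of
comparing two genes' ranked database-hit lists is a top-k Jaccard index
(default k = 10, flag below 0.1, never auto-drop).

The synteny model is deliberately the simplest thing that fits two
near-collinear circular chromosomes: expected partner coordinate =
`(scale·x + offset) mod L_b`, with scale fixed to the length ratio and the
offset (and overall orientation sign) minimizing the median absolute
circular residual, each per-pair residual serving as an offset candidate.
The median keeps the fit robust to the minority of genes inside
rearrangements. Per-pair discrepancies are circular distances from this
model; the top 10% are flagged `manual-review` rather than removed,
mirroring a curator's re-examination list. Gene positions are start
coordinates of the forward-strand representation. Inversions are read out
of the pairing as maximal runs (≥ 3 pairs) in which partner order reverses
while relative strand flips.

Start-site extension handles annotation truncation: when one member of a
pair is shorter, the shorter gene's upstream DNA is walked codon-by-codon
in frame (stopping at the first in-frame stop), and the farthest upstream
ATG whose translated extension aligns to the longer protein's N-terminal
overhang at ≥ 50% identity becomes the new start (`start-extended` flag).
The length screen flags pairs differing by strictly more than 20% of the
longer length. The three-way outgroup check marks a pair inconsistent only
on conflicting evidence: both members have an outgroup best hit and the
hits differ.

## Pseudogene detection

Two routes, matching the two ways a decayed gene can survive annotation:

* **Orphan route.** Each orphan's protein is searched (translated,
  six-frame) against the partner strain's intergenic regions. A call
  requires the grouped hits to span no more than the orphan's nucleotide
  length (`span_tolerance` = 1.0 — the literal "no larger than the query"
  rule, configurable because real erosion includes deletions) at a locus
  within 20 kb of the synteny model's prediction (the conservation-of-
  synteny requirement, quantified; configurable). Frameshifts are counted
  as distinct subject reading frames among the grouped hits minus one;
  in-frame stops are counted across the grouped locus in the best hit's
  frame phase (individual HSPs are stop-free by construction, so the
  nonsense codons sit between them).
* **Intergenic route.** Intergenic regions searched (translated) against a
  protein database; a region calls as a pseudogene when its best hit has
  E < 10⁻³ and a subject title not containing "hypothetical"
  (case-insensitive). Taxonomic filtering of an imported database is the
  caller's responsibility.

The reported strand of a call is the strand of the best-hit frame.
Pseudogene-bearing regions are removed from the intergenic set before any
composition statistics.

## Intergenic decay and synteny

Intergenic complements of the two strains are compared in two modes:
nucleotide (best hit per query region, alignments shorter than 40 bp
ignored) and translated (all six-frame HSPs at E ≤ 10⁻³ per region pair,
summarized as the length-weighted mean percent identity,
`Σ(identity·length)/Σ(length)`). Points carry region midpoints for dot
plots. In once-coding DNA eroded under synonymous-biased substitution the
translated mode retains a syntenic diagonal long after the nucleotide mode
has gone blank — the package's acceptance checks assert exactly this
contrast on simulated decayed genes. Stop-codon frame maps (per-frame stop
positions plus windowed GC%) render the same degradation per locus.

## Composition statistics

GC2 is G+C at second codon positions; GC4 is G+C at third positions of the
eight fourfold-degenerate codon families (CTN, GTN, TCN, CCN, ACN, GCN,
CGN, GGN) — the standard GC4 reading; a GC3 (all third positions)
alternative is exposed. RSCU is the codon count over its synonymous-family
mean; relative adaptiveness w is RSCU over the family maximum; CAI is the
geometric mean of w over a gene's codons excluding ATG, TGG and stops, with
a 0.5 pseudo-count for codons absent from the reference set (the reference
is typically one contig's genes, so rare codons will be missing).

Group comparisons are one-way fixed-effects ANOVA followed by Tukey's HSD
with adjusted p-values from the studentized-range distribution and the
Tukey–Kramer standard error for unequal group sizes — the behavior of R's
`aov`/`TukeyHSD`, verified against two independent implementations to
1e-6. Degenerate inputs (one group, singleton groups, zero within-group
variance) raise instead of returning p = 0.

GC stratification is two-stage: per-strain groups (coding, pseudogene,
intergenic, RNA per strain) are tested jointly; categories whose strains do
not differ are merged across strains (singleton-strain categories such as
small pseudogene sets merge unconditionally — the small-sample pooling);
ANOVA + Tukey is rerun on the merged groups.

The contig screen flags a contig as an outlier when, for at least one of
GC/GC2/GC4/CAI, a Tukey-adjusted p-value against another contig clears the
screen-wise α = 0.05. Tukey controls the family-wise error within one
metric; since the four metrics are four views of one question, α is
Bonferroni-split across the metrics so the screen keeps its nominal error
rate. A contig with at least two distinct significant partners is an
outlier in its own right; a contig whose only significant partner is such
an outlier is treated as dragged in and not flagged.

Genome summaries: coding density is the union length of selected features
over genome length (`cds-only` default, `all-genes` alternative including
RNA genes — the definition is exposed because either convention is
defensible); noncoding GC is reported from the intergenic set. The variant
rate helper is `100·n/L`.

## Divergence metrics

Gene pairs align at the protein level first (global, whole genes), and the
nucleotide alignment is induced codon-wise from the protein alignment, so
its length is exactly three times the protein alignment's. Identity
denominators exclude columns with a gap in either sequence (pairwise
deletion) by default; the include-gaps alternative is exposed. Identity
distributions export a median and a Gaussian KDE. Multiple alignments are
trimmed by removing ragged ends (leading/trailing columns up to the first
column where every sequence has a residue); the operation is idempotent.
Identity matrices are symmetric with a unit diagonal. Amplicon reads
classify against a reference by best local alignment at ≥ 98% identity
covering at least half the read — local, because reads are fragments.

## The simulator

`synthetic_data` generates a circular ancestor (ATG-started, stop-free,
stop-terminated ORFs at a coding GC target, alternating with neutral
spacers, plus a few conserved RNA genes) and evolves two descendants
independently. Functional genes accumulate proposed point mutations
accepted with probability 1 if synonymous, 0.15 if missense, 0 if nonsense
— a minimal purifying-selection proxy that produces the synonymous-biased
substitution signature without a full codon model — until a per-branch
protein-divergence target is met. Pseudogenized genes receive 2–4 recorded
disruptions (1–2 bp frameshifts and in-frame stops), then drift neutrally;
spacers drift neutrally throughout; neutral drift replaces a fixed fraction
of sites with AT-biased draws. Pseudogenes drift at half the branch's
neutral rate, since disruption falls, on average, midway along the branch.
Inversions reverse-complement contiguous element runs of a target span,
with breakpoints recorded. Deletions remove whole genes. Pseudogenes are
deliberately left unannotated in the emitted GenBank so the pipeline must
rediscover them from intergenic DNA. All randomness flows through one
`numpy.random.Generator`; a fixed seed reproduces the genomes byte for
byte.

Default scenario (the package's standard study conditions): 300 genes of
300 ± 80 codons, spacers 600 ± 200 bp (min 120), coding GC 41%, ancestral
spacer GC 30%, 6 RNA genes at GC 45%, per-branch protein divergence 7.5%
(cross-strain identity ≈ 85%), neutral divergence 35% per branch with
P(A/T) = 0.85 (spacers land near 25% GC, pseudogenes intermediate near
36–37% — the coding > pseudogene > intergenic stratification), 5%
pseudogenization and 2% deletion per branch, two ~50 kb inversions on one
branch. These sizes keep a full pipeline run in the low minutes on one
core while leaving every effect far clearer than its sampling noise.

What the simulator does **not** emulate: realistic indel length spectra,
horizontal transfer, mobile elements, rearrangements beyond in-place
inversions, transcription-related strand asymmetries, and annotation noise
other than clipped start codons. Passing tests therefore demonstrate that
the implementation recovers the statistical structure it targets — not
that it is robust to every artifact of real assemblies and annotations.

Two auxiliary generators serve the statistical analyses: a multi-contig
ORF-profile simulator (one composition model, optionally one contig with a
shifted GC target, CAI referenced to the first contig's genes) and a
decayed-intergenic generator (once-coding region pairs evolved under the
synonymous-favored rule, then AT-drifted, ~35% total nucleotide
divergence) for the translated-vs-nucleotide contrast.

## Known limitations

* Karlin–Altschul constants are fixed per scoring scheme, not derived per
  composition; e-values are rank-faithful but not BLAST-calibrated.
  Imported hit tables are the route to exact parity with external tools.
* The greedy HSP enumerator never reports subject-overlapping HSPs, so
  tandem duplications inside one subject can be under-reported.
* The synteny model is a single global circular offset; genomes related by
  many large rearrangements would need a piecewise model, and the
  inversion read-out assumes inversions are in-place and gene-dense.
* The orphan route cannot see a pseudogene whose partner gene is itself
  lost in the other strain (no query exists); the intergenic route needs
  an informative protein database to catch those.
* CAI with an internal reference is mildly biased upward for the reference
  contig's own genes; with reference sets of a few thousand codons this is
  visible to a well-powered Tukey test, which is one reason the contig
  screen splits its α across metrics.
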