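# Methods

This note documents the models and procedures `genefam` implements, the
parameters that matter, the design choices made where the design was open,
and what the synthetic fixtures do and do not demonstrate.

## Membership decision model

Two homology signals are combined per subfamily.

*Threshold determination.* The ranked per-target output of a subfamily
profile-HMM search is scanned for previously validated reference members
(anchor-species genes). Each reference gene is represented by its
**first-occurring** transcript variant (smallest rank), and the inclusion
cutoff is the **largest** E-value among those representatives — i.e. the last
reference member one encounters walking down the ranked list. Comparison
against the cutoff is inclusive (`E <= E*`), so the anchor itself always
passes. Ties on the cutoff value break toward the later-ranked hit, then the
lexicographically smaller id, making the threshold deterministic. Genes, not
transcripts, are the decision unit: a gene is above threshold if any of its
variants is.

*Cluster assessment.* Orthogroups are typed after collapsing transcript
variants to genes: a **singleton** has exactly one member gene (even if it
contributes several variants), a **complete** cluster has all genes above
threshold, a **partial** cluster straddles the threshold, an **absent**
cluster has none above. A cluster is **known** if it contains at least one
previously identified member. The completion ratio is the fraction of member
genes above threshold.

*Decision policy.* A gene is kept iff it is above threshold and its cluster
is known, or a singleton, or reaches the completion cutoff (default 0.50,
configurable); reference-species members are force-included regardless of
score. Reason codes (`KNOWN_ABOVE`, `SINGLETON_ABOVE`, `PARTIAL_GE50`,
`FORCED`, `BELOW_THRESHOLD`, `PARTIAL_LT50`, `NO_HIT`) make every verdict
auditable. Two deliberately resolved ambiguities:

1. Whether below-threshold members of a cluster that reaches the completion
   cutoff should ride along. The default is **no** (keeps the soundness
   invariant that every non-forced kept gene is above threshold); the
   `partial_keep_below` flag flips it.
2. Whether the completion-ratio rule applies to known clusters. Above-
   threshold hits in known clusters are kept unconditionally (the known-
   cluster rule takes precedence); below-threshold members of known clusters
   are rejected like any others.

A gene hit by several subfamily models receives one decision per subfamily,
all flagged ambiguous — nothing is silently dropped.

## Motif scanning

Patterns are degenerate consensus strings (`G`, `(T/S)`, `x`). Compilation
assigns each column's allowed residues the probability mass
`1 − 20·pseudocount` uniformly plus `pseudocount` everywhere (default
pseudocount 0); wildcards equal the background exactly. Scores are
`log2(p/background)` with disallowed residues floored at −30 bits — the floor
keeps the dynamic programming free of sentinel values while still making a
single mismatch at a specific column effectively disqualifying.

The null distribution of window scores under i.i.d. background residues is
exact: each column's 20 scores are discretized onto 1000 bins spanning that
column's range (configurable granularity), and the integer window score's
distribution is the convolution over columns. Observed windows are scored on
the *same* integer grid, so a reported p-value is the exact tail probability
of the observed discretized score; per-column rounding is shared between
observation and null, and the tail is reported at the upper side of the bin.
A consensus window always attains the maximum score by construction.

Background defaults to uniform 1/20; proteome-derived frequencies can be
passed instead. "One hit per protein" is interpreted as best-window-per-
protein (leftmost on ties), and a gene's best variant represents it in the
conservation report. Unknown residues (X) score at the column minimum, which
is conservative. Proteins shorter than the motif yield no hit.

## Collinearity and duplication typing

Anchors (homolog pairs with both genes placed on chromosomes) are grouped per
chromosome pair and chained by DP in both orientations: a chain must be
strictly monotone in gene order on both chromosomes, with at most `max_gap`
(default 25) intervening gene ranks between consecutive anchors on either
side; chain score = `anchor_score` (1.0) per anchor minus `gap_penalty`
(0.25) per intervening rank. The best chain is extracted, its anchors
removed, and the DP repeated until no chain reaches `min_block_size`
(default 5) anchors — so blocks on one chromosome pair never share anchors.
These defaults mirror common collinearity-scanner conventions; none of them
is dictated by theory, and all are configurable. The gap constraint is
re-asserted on every emitted block.

Typing precedence: any block anchor is WGD/segmental; otherwise a homolog at
adjacent rank (`tandem_rank` 1) on the same chromosome makes both genes
tandem; within `proximal_rank` (10) ranks, proximal; any remaining homolog,
dispersed; no homolog, singleton. Gene *rank* along the chromosome, not base
pairs, drives all proximity rules, which makes the classification robust to
assembly-scale coordinate differences.

## Ka/Ks

Nei–Gojobori counting: per codon, each position contributes the fraction of
its three possible changes that are synonymous (summing to 3 sites per
codon); mutations creating a stop codon count as nonsynonymous sites. Site
counts are averaged between the two sequences. Differences at multi-hit
codons are averaged over all minimal mutational pathways with equal weights,
skipping pathways through stop codons (if every ordering is blocked, all are
used). Proportions are corrected with Jukes–Cantor; `p >= 3/4` flags the
result saturated. The ratio is undefined — reported as NA, never 0 or
infinity — when Ks = 0 or either distance is saturated. The estimator is
deliberately the simple counting one: it is transparent, exactly testable
against enumeration, and adequate for the moderately diverged duplicate
pairs the toolkit targets; likelihood estimators (GY94-style) are out of
scope but the result type would accommodate one.

## Expression labels

`log2FC = log2(FPKM_t + 1) − log2(FPKM_c + 1)`. The +1 offset handles zero
FPKM. Bounds are strict as stated: significant iff FC > 1.5 or FC < 0.5,
moderate iff FC > 1.2 or FC < 0.8 and not significant; FC exactly 1.5 or 0.5
is therefore moderate, not significant. Upregulation is positive under the
default direction; a `control_minus_treatment` switch exists for workflows
defined with the opposite sign, and its use is logged. One FPKM value per
condition is assumed (no replicate handling).

## Synthetic fixtures: what they emulate

The generator's defaults define the study conditions the tests run under:

* **Families.** Three species (first one anchors the references), subfamily
  sizes 9/12/15 (ZIK/MEKK/RAF), 40 decoys, backbones of 250–350 uniform
  random residues with one consensus realization of the subfamily motif
  embedded per member. Member E-values are log-uniform in 1e-120..1e-70;
  the worst member value is always assigned to an anchor-species reference
  so the threshold rule recovers exactly the planted boundary; decoys start
  `evalue_separation` (default 10) orders of magnitude above the member
  band. Orthogroups hold ~3 member genes each plus one singleton member per
  subfamily. With contamination rate c, `round(c·n_members)` decoys move
  into family clusters, filling the last cluster past majority-decoy first —
  a deterministic guarantee that c ≥ ~0.25 produces partial clusters below
  the 50% completion mark.
* **Genomes.** Four chromosomes (two per subgenome, A/D naming) of 80 gene
  slots; 2 segmental blocks of 6 paired genes (orientation alternating),
  4 tandem, 4 proximal (gap 2–10), 6 dispersed pairs; remaining genes are
  singletons. Noise pairs are uniform random gene pairs added at
  `noise_pair_rate` times the planted pair count.
* **Codon pairs.** 300 sense codons from a uniform ancestral draw; each
  branch receives Poisson(3·L·Ks/2) proposed point mutations (default Ks
  depth 0.3 — diverged enough to estimate, far from saturation), accepted
  always if synonymous, with probability ω (default 0.2) if nonsynonymous,
  never into a stop. The realized dN/dS is therefore ≈ ω.
* **Expression.** Control FPKM log-normal (median ≈ 4.5) floored at 2 so the
  strongest planted down-class stays representable; treatments are
  `fc·(control+1) − 1` for fc cycling through {2.0, 1.3, 1.0, 0.7, 0.4} —
  one planted class per label — with optional multiplicative noise (default
  off).

Every file type draws from its own stream (master seed + stream name), so
outputs are individually reproducible and adding a fixture type never
perturbs existing ones.

**What passing tests do not show.** Real hit tables come from actual HMM
searches whose E-values are not band-separated by construction; real
orthogroups carry correlated contamination, fragmented gene models, and
transcript-variant noise far richer than the swap model here; synthetic
backbones have no shared kinase scaffold, so motif specificity against
*related* non-members is untested; the codon model has no indels, no codon
usage bias, and no rate heterogeneity. The fixtures validate the decision
logic, the exactness of the numerics, and the plumbing — not the biological
error rates one would see on a real proteome.

## Numerical and degenerate-input choices

* E-value comparison inclusive; threshold ties break positionally (later
  rank), then lexicographically.
* Out-of-order E-values in a hit table are tolerated with a warning; ranks
  always follow file order, because the threshold rule is positional.
* Motif DP granularity 1000 bins/column; p-values exact for the discretized
  score and conservative at bin edges; log-odds floor −30 bits.
* Chain DP tie-breaks prefer the earlier starting anchor; block extraction
  is greedy best-first.
* Ka/Ks: empty pathway sets fall back to all orderings; gapped codons are
  dropped pairwise before counting; a trailing stop codon is trimmed.
* Writers sort all output rows (reports by subfamily then gene id, loci by
  chromosome then start) and the run manifest contains no timestamps, so
  identical inputs give byte-identical outputs.

## Known limitations

* The completion-ratio rule counts genes, not transcripts; if variants of
  one gene straddle the threshold the gene counts as above.
* Multi-subfamily hits are flagged, not resolved; downstream consumers (the
  pipeline's kept-gene map) take the first subfamily in sorted order.
* Collinearity reports blocks and anchors; transposed-duplicate
  subclassification and inter-species synteny are not implemented.
* The acceptance metrics quantify recovery of *planted* structure under the
  generator's assumptions; they are not error rates on real genomes.
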