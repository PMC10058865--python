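# Methods

This note documents the models, parameter choices and numerical conventions
behind the package, and what the synthetic-data experiments do and do not
demonstrate.

## Coordinate and sequence conventions

All in-memory intervals are 0-based half-open; GFF3 at the package boundary
is 1-based inclusive, converted by a tested bijection. Sequences are
uppercase DNA over {A, C, G, T, N}; U is normalized to T and any other
ambiguity code is rejected at parse time. N is carried through but never
matches in k-mer seeding and is excluded from substitution counts —
a conservative choice that can only lose signal, never invent it.

## Synthetic repeatome model

The generator builds what the downstream analysis assumes to exist:

* **Background** — i.i.d. nucleotides at GC 0.38 (a typical plant nuclear
  value; the choice only affects chance k-mer collisions).
* **Elements** — each repeat family has one consensus built as
  LTR–internal–LTR with identical LTRs starting `TG`/ending `CA` and an
  internal region carrying the family's domain peptides (drawn from the
  bundled reference library and reverse-translated with uniformly random
  codons) as ordered ORF blocks between random spacers. Each genomic copy
  ages independently: every site of each LTR receives a Poisson(rT) number
  of substitution events (r = 2×10⁻⁸ /site/yr; T the copy's age in years),
  each event a transition with probability κ/(κ+2) (κ = 2 by default), and
  multiple hits are applied sequentially. The internal region mutates at the
  same rate. Expected inter-LTR divergence is therefore 2rT, and saturation
  and back-mutation occur naturally — which is the point: the K2P correction
  used for dating is actually exercised, not just approximated by a
  single-hit model.
* **Insertion** — each element insertion duplicates the 5-bp target site on
  both flanks; TSD copies then mutate according to the element's age
  (`mutate_tsd` switch). With probability `nesting_probability` an element
  lands inside a previously placed element's internal region; the host is
  recorded as interrupted and the guest carries a parent link. Tandem
  satellite and rDNA tracts are monomer arrays placed the same way (no TSD).
* **Reads** — uniform fragment positions, Normal(300, 30) insert length,
  inward-facing 100-bp mates, random strand, optional per-base error rate
  (0 by default), expected pair count coverage·L/(2·100).

Every planted feature goes into a ground-truth registry (coordinates, age,
realized divergence and transition/transversion counts, TSD/motif
intactness, nesting, strand) used as the oracle in tests.

**What the generator does not model:** solo-LTR formation and element
removal by recombination, indels (off by default — the dating model is a
substitution clock), organellar contamination, realistic sequencing-error
profiles, and sequence heterogeneity within a family beyond the age process.
Detector recall and classification accuracy measured here are therefore
upper bounds relative to real genomes, where decayed and recombined copies
blur every boundary this generator keeps sharp.

## Read clustering

Edges require a local alignment (either strand) at ≥90 % identity over
≥55 % of the shorter read — the published defaults of graph-based repeat
clustering from reads. Identity is measured on the best-scoring local
alignment under +1/−1 match/mismatch and −2 gaps; with these weights a
passing pair's optimal score is at least C·(3f−2) (C the minimum overlap
columns, f the identity fraction), which gives a cheap score bound that
skips tracebacks for hopeless pairs. The shared-k-mer prefilter uses k = 9
because ≥50 matching columns interrupted by ≤5 non-matches must contain an
exact run of length ⌈50/6⌉ = 9 — so at default thresholds prefiltering is
provably lossless, and the test suite additionally verifies exact partition
equality against brute-force all-pairs alignment. Clusters are connected
components with ≥2 reads (no community splitting — subfamily resolution
finer than connectivity is out of scope), superclusters connect clusters
sharing ≥1 mate pair, and the top-cluster rule is >0.01 % of analyzed
reads. Inputs beyond 50 000 reads are deterministically subsampled.

## LTR-RE detection

Exact 20-mer seed matches at the same separation are chained (runs with ≥2
seeds, gaps ≤500 bp) and extended outward by ungapped X-drop (match +1,
mismatch −2, X = 15); extension is capped so the two repeats cannot overlap.
A pair is kept iff repeat lengths are in [100, 10 000] bp, the element span
in [1 500, 25 000] bp, and global-alignment identity (match +5, mismatch −4,
gap open −16, extend −4; gaps count against identity) is ≥85 %. The 85 %
floor is a visible parameter (`min_ltr_identity`): the structural constraint
set this mirrors does not pin it down, and 85 % corresponds to roughly
4 MY of divergence at the default rate. Sub-threshold repeat pairs are
logged, not silently dropped, to support decayed-element accounting.

Boundary refinement searches every shift within ±10 bp of the provisional
element start/end for a placement with `TG…CA` termini and identical 5-bp
flanking TSDs, preferring the smallest total shift (ties toward the start
shift). No valid placement discards the candidate. Overlap resolution keeps
the higher-identity candidate among pairs overlapping ≥50 % mutually
(ties: longer, then leftmost); containment nesting is deliberately left to
the annotation stage. Only the forward strand is scanned — direct-repeat
structure is strand-symmetric, and strand is later assigned from domain
orientation.

Ungapped extension means heavily indel-mutated LTR pairs (not generated by
default) may be under-extended; the TSD/motif refinement step is indel-free
by construction.

## Domain annotation, classification, filtering

The internal region is translated in all six frames and locally aligned
(BLOSUM62, gap open −11, extend −1) against every library peptide; hits
above the score threshold are selected greedily by score with no overlap,
so duplicated domains yield duplicated hits. The threshold default is 80:
measured on 3-kb random internal regions the best chance score against the
bundled library is ~54, while true domain hits score ≥240 even at 15 MY of
divergence, so 80 separates the two regimes with wide margins on both
sides (it remains configurable for real, distant libraries). Hit intervals
are mapped back to genome coordinates; element strand is the majority hit
strand.

Superfamily follows the INT-position rule: the detected order (read 5'→3'
on the element strand) must contain both INT and RT and be a subsequence of
exactly one canonical order — Copia GAG·PR·INT·RT·RH or Gypsy
GAG·PR·RT·RH·INT(·CHD). Lineage is the label of the best-scoring RT hit;
elements without RT stay lineage-unclassified.

Filtering removes: (a) nested configurations — if A's internal region fully
contains B's span, A is removed and B kept (the insertion interrupted A;
the host is no longer a clean full-length template), reversible via
`nested_policy="keep_outer"`; (b) elements with >1 hit of any domain type;
(c) elements whose order contradicts their assigned superfamily, or — when
unclassified — contradicts the superfamily their own domain hits' labels
point to by majority (an element built of Copia-labeled domains in a
non-Copia layout is malformed, not merely unclassifiable); (d) elements
with no domain hits at all. Partial domain sets in a consistent order are
retained as "LTR-RE unclassified", matching how unclassified rows appear in
published count tables. The filter is idempotent.

The bundled reference library is synthetic: one independently drawn 120-aa
peptide per (domain, lineage) for five Copia and three Gypsy lineages
(Tekay carries a CHD). Independent draws make lineages mutually distant,
which guarantees a unique best RT hit for planted elements — so the 100 %
classification accuracy shown on synthetic data reflects that construction,
not performance on a real, phylogenetically structured library (users load
their own via `ReferenceDomainLibrary.from_fasta`).

## Insertion dating

LTR pairs are aligned end-to-end (match +5, mismatch −4, gap open −16,
extend −4; configurable); transitions and transversions
are counted over columns where both symbols are unambiguous bases, and gap
columns are excluded from the site count. K2P distance
K = −½ ln((1−2P−Q)√(1−2Q)); observed proportions outside the domain
(2P+Q ≥ 1 or 2Q ≥ 1) are flagged saturated and excluded from profiles with
a count, rather than truncated into the last bin (which would fabricate a
boundary peak). Age is T = K/(2r): each LTR accumulates substitutions
independently after insertion, so inter-LTR divergence grows at 2r per
year. The default r = 2×10⁻⁸/site/yr is exposed as `--rate`; note the
factor-of-two convention (rate per LTR vs. per pair) differs between
published analyses, and anyone replacing the default should check which
convention their rate was calibrated under. Profiles are histograms over
[0, 15] MYA in 0.5-MY bins by default.

A subtlety in the evaluation: the benchmark cohort ages (0.5, 1, 2, 5, 10
MYA) sit exactly on bin edges, where the mode of an unbiased estimator is a
coin flip between the two adjacent bins. The mode check therefore accepts
a mode bin whose *closure* contains the truth — both adjacent bins qualify,
any other bin fails.

## Phylogeny

RT nucleotide sequences (reverse-complemented to element strand, ids
`species|lineage|element`) are aligned progressively: inputs are sorted by
id (making the result input-order invariant), a UPGMA guide tree is built
on pairwise shared-6-mer distances, and profiles are merged by affine-gap
Gotoh alignment (match +2, mismatch −1, new gaps −5/−1, existing gap
columns neutral) with deterministic tie-breaking. Distances are K2P over
ungapped column pairs; for tree building near-saturated pairs are clamped
to a large finite distance so NJ stays defined (the bundled synthetic RT
cohorts never reach the clamp).

Neighbor joining is the standard Saitou–Nei agglomeration (minimize
Q = (n−2)d − Rᵢ − Rⱼ, two-point branch lengths, ties broken by index
order); negative branch lengths are clamped to zero with the excess moved
to the sister branch, preserving path lengths. On additive matrices the
generating tree is recovered exactly (tested over random trees, n ≤ 12,
against both path-distance reconstruction and scikit-bio's independent NJ).
Bootstrap resamples alignment columns with replacement, rebuilds the tree,
and scores each internal branch of the reference tree by the percentage of
replicates containing the same bipartition; 100 replicates by default, and
supports ≥60 are the annotation convention for "well supported" here.

## Comparative statistics

Genome proportion = clustered/total reads ×100 (2 decimals, the precision
of published tables); Gypsy/Copia ratio and per-row max−min differences are
exact arithmetic on the abundance matrix, also at 2 decimals. Reproducing a
published maximum-difference column from its printed cells is asserted at
±0.01, because printed cells are themselves rounded (two rows of the
bundled survey differ from their printed derived value by exactly one unit
in the last place). Hierarchical clustering defaults to average linkage on
Euclidean row profiles (both are flags — published dendrograms rarely state
either), with scipy's deterministic tie-breaking; the sharing report labels
rows shared-by-all / shared-subset / species-specific at a presence
threshold of 0.01 %, reusing the top-cluster cutoff.

## Determinism and problem sizes

One integer seed drives a run; each stochastic stage draws from a
stage-named substream (`SeedSequence([seed, stage_id])`), so stages never
perturb each other, and a rerun is byte-identical. The bundled evaluations
use desk-scale problem sizes chosen to keep the full suite interactive
while leaving every estimator in its asymptotic regime: dating cohorts of
300 elements with 2-kb LTRs, one 2-Mb genome with 60 planted elements for
detection, ≤500 reads for the clustering-equivalence check (brute-force
all-pairs alignment is quadratic), 100 random trees for NJ, 100 bootstrap
replicates. Genome-scale numbers from real multi-gigabase assemblies and
millions of reads are outside what these synthetic experiments measure;
the published-survey tables bundled with the package are used only for
arithmetic-consistency checks of the comparative statistics.
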