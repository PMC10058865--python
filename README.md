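# repeatome

Tools for characterizing the repetitive fraction ("repeatome") of plant
genomes, built around the analysis style used for multi-species surveys of
Asteraceae: graph-based repeat quantification from unassembled reads,
structural discovery of full-length LTR retrotransposons, insertion-age
dating from LTR divergence, RT-domain phylogenies, and cross-species
comparative statistics — all exercised end-to-end on synthetic genomes with
a known ground-truth registry.

## What it computes

**Repeat quantification without assembly.** Reads are compared all-to-all by
local alignment (default: ≥90 % identity over ≥55 % of the read length, on
either strand, with a lossless shared-9-mer prefilter); connected components
of the similarity graph are repeat *clusters* (subfamilies), clusters linked
by shared mate pairs form *superclusters* (families), and the fraction of
reads falling into clusters estimates the repetitive genome proportion.
Clusters are annotated against a labeled repeat library in nucleotide and
six-frame translated mode.

**Structural LTR-RE discovery.** A full-length LTR retrotransposon is a pair
of direct long terminal repeats (length 100–10 000 bp, element span
1 500–25 000 bp, inter-LTR identity ≥85 %) starting `TG`, ending `CA`, and
flanked by a 5-bp target-site duplication; boundaries are refined within
±10 bp. Internal protein domains (GAG, PR, INT, RT, RH, CHD) are found by
translated search; the INT position classifies the superfamily
(Copia: GAG–PR–INT–RT–RH; Gypsy: GAG–PR–RT–RH–INT[–CHD]) and the best RT hit
assigns the lineage. Nested elements and elements with an inappropriate
number or order of domains are filtered out.

**Insertion dating.** The two LTRs of an element are identical at insertion
and diverge at per-site rate *r* afterwards, so the insertion age is

    T = K / (2r),    K = −½ ln((1 − 2P − Q)·√(1 − 2Q)),

with K the Kimura two-parameter distance between the globally aligned LTRs
(P transitions, Q transversions over ungapped columns) and
*r* = 2×10⁻⁸ substitutions · site⁻¹ · yr⁻¹ by default.

**Phylogeny and comparison.** RT nucleotide sequences from retained
elements are multiply aligned (guide-tree progressive aligner), pairwise K2P
distances feed a Saitou–Nei neighbor-joining tree with bootstrap supports
from column resampling, and lineage/species monophyly is reported.
Cross-species abundance matrices drive Gypsy/Copia ratios, per-lineage
maximum differences, average-linkage dendrograms and repeat-sharing reports.

## Worked example

```python
import numpy as np
import repeatome as rp

rng = np.random.default_rng(7)
spec = rp.ElementSpec("Copia", "SIRE", ltr_len=2000, internal_len=2500,
                      age_T=2e6)          # inserted 2 million years ago
seq, realized = rp.make_element(spec, rng)

aln = rp.align_ltr_pair(seq[:2000], seq[-2000:])
dist = rp.k2p_distance(aln)
age = rp.insertion_age(dist.K)
print(f"K2P={dist.K:.4f}  estimated age={age.mya:.2f} MYA")
```

prints

```
K2P=0.0741  estimated age=1.85 MYA
```

The element was planted 2.0 MYA; with 2-kb LTRs a single estimate carries a
standard error of roughly 0.15 MY, and across replicates the estimator is
unbiased (the test suite checks the mean of 300-element cohorts against the
planted age at five ages up to 10 MYA).

Running the whole pipeline on synthetic species:

```bash
repeatome run --seed 5 --outdir run_out
```

writes per-species genomes, reads, cluster tables, detected and annotated
elements (GFF3), dating tables, an RT tree with bootstrap supports, and the
comparative summary tables; a rerun with the same seed is byte-identical.

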