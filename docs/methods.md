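# Methods

This note documents the models, conventions and numerical choices behind
strainkit, and what the synthetic benchmarks do and do not demonstrate.

## Sequence conventions

Coordinates are 0-based half-open on the forward strand throughout; GFF3
input (1-based inclusive) is converted at the boundary. Genomes are
uppercase over `{A,C,G,T,N}` with `U→T` on input. `N` is a legal base but
never counts as an identity and scores as a mismatch in every alignment —
a deliberately conservative identity convention. Translation uses the
bacterial code (table 11); initiator codons (ATG, GTG, TTG, …) are
rendered as `M`; an internal stop truncates the protein at the first stop
with a warning; codons containing `N` translate as `X`.

## Homology search

The search is k-mer seeded (word size 11 nt / 3 aa) followed by a full
affine-gap Smith–Waterman alignment of each seeded pair, computed with
Biopython's `PairwiseAligner`. Because the extension stage is exact DP
over the whole pair, a reported hit always carries the true optimal local
score for that pair; seeding can only *miss* pairs without the required
words. Nucleotide pairs are aligned after a single shared word; protein
pairs require two word hits on one alignment diagonal (the classic
two-hit heuristic) because 3-letter words are shared by essentially all
random protein pairs.

Scoring defaults: nucleotide +1/−2 with gap open −5, extend −2 (the open
score is the cost of the first gapped column); protein BLOSUM62 with gap
open −11, extend −1. E-values use the Karlin–Altschul form
`E = K·m·n·e^(−λS)` with the *ungapped* parameters (nt: λ=1.33, K=0.621;
aa: λ=0.3176, K=0.134) and search space `m·n` = query length × total
database length, evaluated in log space so large scores underflow cleanly
to 0. Applying ungapped statistics to gapped scores is an approximation;
it is used only to rank and threshold hits (cutoff 1e−5), never as a
calibrated probability. Ties anywhere resolve by bit score, then percent
identity, then lexicographic subject id, making all outputs reproducible.

Orthologs are reciprocal best hits — the minimal operational reading of
"gene with an ortholog". A gene participating in no significant hit in
either direction is **specific**. A gene with significant hits, none of
which falls in the focal taxonomic order, is an **HGT** gene with the
best hit's order as donor; a gene with *zero* hits is explicitly not HGT
(it is a specific-gene candidate), and subjects from the query's own
genome can be excluded from consideration.

## Fragment-based ANI

The Goris-style recipe: the query genome is cut per contig into
consecutive, non-overlapping fragments of 1020 bp (trailing remainder
discarded); each fragment is aligned to the other genome on both strands;
the best placement contributes iff identity > 30% of alignment columns
and the alignment spans ≥ 70% of the fragment length. ANI is the mean
identity over contributing fragments; a comparison with no contributing
fragment is reported as the 0 sentinel with `n_fragments_used = 0`.
Candidate placements come from counting shared 11-mers in diagonal bands
of width 64; bands with fewer than 3 seeds (or under 10% of the best
band) are not aligned. Reported ANI is the reciprocal mean of the two
one-way values — single published ANI figures rarely state a direction,
so both one-way values are always emitted alongside.

Per-category ANI uses the same cutoffs, but the aligned unit is a whole
gene versus the other genome's gene set *of the same category* (each gene
carries exactly one category letter from the input map). Restricting the
target set is what makes the 0 sentinel meaningful: a category ANI of 0
means no member of that category found any qualifying partner. Region
classification across all pairs: *upper* iff the category exceeds the
genome ANI in ≥ θ_up (default 0.9) of pairs with no sentinel; *divergent*
iff sentinel pairs occur where 16S identity < 94.5% (both thresholds are
parameters); *middle* otherwise.

## 16S identity and trees

16S genes are consumed as annotated features. Identity is computed from a
global alignment with free terminal gaps (+1/−1, gap open −2, extend
−0.5); terminal-gap columns are excluded from the denominator, so a
perfect prefix scores 100%. The input pair is ordered canonically before
aligning, which makes the value symmetric even when several alignments
tie; an alignment with no aligned columns scores 0. Distances for the
tree are p-distances `1 − identity/100`.

Neighbor joining is implemented directly because the exact tie-break and
clamping behaviour matter for reproducibility: Q-matrix ties resolve to
the lexicographically smallest pair of node labels (internal nodes carry
their smallest descendant leaf); negative branch lengths are clamped to
zero with the deficit moved to the sister branch, preserving the joined
path length; the last three nodes are resolved by the three-point
formulas into a trifurcating root. On additive matrices the recovery is
exact; scikit-bio's NJ serves as an independent topological cross-check
in the tests.

## Composition

Amino-acid composition excludes stops and ambiguous residues
(X, B, Z, J, U, O); codon usage covers all 64 codons including stops,
drops trailing partial codons with a warning and skips codons containing
`N`. Rows are relative frequencies summing to 1. The coefficient of
variation uses the **population** standard deviation (`ddof = 0`), fixed
as a documented convention, with truly constant features snapped to
exactly 0. Codon usage is raw relative frequency, not RSCU. Strain
clustering is scipy's average-linkage on Euclidean distances, emitted as
a merge table (node, children, height, leaf count) rather than a drawing
— rendering is out of scope.

## CRISPR detection

A simplified repeat-chain detector. Exact words of the minimum DR length
(23 bp) recurring at spacer-compatible intervals are chained; each chain
is extended outwards while **all** copies agree, bounded by the DR range
23–55 bp and the spacer bounds 0.6–2.5 DR lengths; additional copies
matching the consensus within the mismatch budget (default 1) are rescued
at the expected periods; finally the DR window is re-derived against the
full copy set (boundary columns on which copies disagree are trimmed,
then unanimous re-extension). Requiring unanimity for extension — rather
than spending the mismatch budget — is deliberate: with a budget, chance
agreement of flanking characters can extend the repeat past its true
boundary, destroying exact DR-length recovery. Candidates whose "spacers"
contain the repeat itself are rejected as tandem repeats. Overlaps
resolve by more spacers, then longer DR, then leftmost start. An array is
*confirmed* with ≥ 3 pairwise-distinct spacers, else *questionable*; this
is a re-interpretation of common detector practice, not a reproduction of
any specific tool, and truncated terminal repeats are not specially
detected (a planted-array suite does not need them; noted as a
limitation for real genomes).

## Synthetic strain sets

The generator emulates a set of congeneric strains: strain 1 *is* the
ancestor; each further strain is an independent site-wise mutated copy.
Substitutions only — no indels — so gene coordinates are identical across
strains and every fragment's homologous window is known exactly, giving
ANI a closed-form, coordinate-true oracle. Sites in genes of category *c*
flip with probability `rate[c]` to a uniformly chosen different base;
intergenic sites use the backbone rate; 16S genes their own rate. Under
this model two derived strains agree at a site with probability
`(1−p)² + p²/3`, and the truth object stores these pairwise expectations.

Defaults describe the standard desk-scale scenario and were chosen once:
4 strains × 120 kb at G+C 0.385 (the focal strain's measured value);
four categories of 12 × 900 bp genes at rates 0.02 / 0.05 / 0.10 / 0.25,
spanning the conserved-to-divergent range seen between real congeners,
with backbone 0.10 (≈ 90% ANI, the upper end of observed between-species
values); a 1500-bp 16S gene at rate 0.02 (≈ 96–98% pairwise identity,
the within-family range); ten planted foreign genes with donor G+C offset
+0.15; and two CRISPR arrays with DR 30 bp and 17 and 3 spacers,
mirroring the structure of the focal strain's confirmed arrays. Genome
sizes are desk-scale rather than the 4–8 Mb of real assemblies so the
full suite runs in minutes; every algorithm is size-agnostic.

Gene sequences start with ATG, end with TAA, and draw internal codons
from the genome-wide base distribution with stop codons replaced by
composition-preserving permutations (TAA→ATA, TAG→GTA, TGA→GTA), keeping
the ancestor's expected G+C at the target (observed within ±0.01 at
≥ 100 kb). Planted elements overwrite intergenic sequence
(length-preserving), so no coordinate shifts occur. The emitted hit
database plays the role of a general protein database: every native gene
gets a slightly mutated homolog labelled with the focal order (every
fifth gene also a non-focal homolog), while planted genes get only a
near-identical donor-order homolog — making both HGT recall and
precision measurable.

**What passing these benchmarks does not show:** the generator has no
indels, rearrangements, repeat landscapes, paralog families, codon-level
selection or annotation noise. Recovery on it validates the machinery
(cutoff logic, statistics, bookkeeping, determinism), not performance on
real assemblies, where alignment parameter choices and direction
conventions can shift ANI-type values by a few tenths of a point.

## Pipeline

`pipeline.run` executes stages sequentially (composition, ANI, trees,
homology, HGT, CRISPR, summary) from one config and seed, writing TSV /
Newick outputs and a YAML manifest of every effective parameter; a rerun
with the same config is byte-identical. Stage caching was considered and
rejected: runs are desk-scale and cache invalidation is a larger risk
than the seconds saved. Proteins shorter than one seed word cannot enter
the search and are reported as specific; genes whose translations
truncate at mutation-induced stops are handled the same way. In the
per-strain summary, "specific genes" means genes with no ortholog in
*any* compared genome (the intersection of the pairwise specific sets).

## Known limitations

- Ungapped E-value statistics applied to gapped alignments (ranking
  device, not a calibrated tail probability).
- Per-category ANI assigns each gene exactly one category; genes mapping
  to several subsystems must be disambiguated upstream.
- The CRISPR detector ignores cas genes, repeat orientation and leader
  sequences, and does not model degenerate terminal repeats.
- NJ trees are unrooted and carry no support values; bootstrap resampling
  is out of scope.
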