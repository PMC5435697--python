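# strainkit

Comparative genomics of closely related bacterial strain sets — the kind of
analysis used to ask how environmental pressure shapes genome divergence
within a family such as the Sphingobacteriaceae: which functional gene
categories evolve faster than the genome as a whole, which genes arrived by
horizontal transfer and from where, how codon and amino-acid usage vary
across strains, and what the 16S rRNA distance structure looks like.

It is a library for people who work from Python (with a thin `strainkit`
CLI for the common one-shot runs), built around five computations:

- **Fragment-based ANI.** One genome is cut into consecutive 1020-bp
  fragments; each fragment is locally aligned against the other genome on
  both strands, and contributes its best hit iff identity > 30% and at
  least 70% of the fragment aligns. ANI is the mean identity over
  contributing fragments, reported one-way and as the reciprocal mean.
- **Per-category ANI.** The same cutoffs applied gene-by-gene within one
  functional category (gene vs the other genome's same-category gene set).
  A category pair with no qualifying hit is recorded as ANI 0 (the
  0 sentinel), not missing — loss of a whole category is signal.
  Categories are then classified into three regions relative to the
  whole-genome ANI line: *upper* (conserved above the line in ≥ 90% of
  pairs), *middle*, and *divergent* (0-sentinel pairs among strains whose
  16S identity is below 94.5%).
- **Orthologs, specific genes, HGT.** Protein-space, k-mer-seeded
  Smith–Waterman search with Karlin–Altschul E-values
  (`E = K·m·n·e^(−λS)`, cutoff 1e−5). Orthologs are reciprocal best hits;
  a gene with no significant hit anywhere is *specific*; a gene whose
  significant hits all fall outside the focal taxonomic order is an *HGT*
  gene, its donor being the order of its best hit.
- **Composition.** Amino-acid and codon relative-frequency matrices per
  strain, per-feature coefficients of variation
  (`CV = 100·σ/μ`, population σ), G+C content, and average-linkage
  clustering for heat-map dendrograms.
- **CRISPR arrays and trees.** A repeat-chain CRISPR detector (direct
  repeats 23–55 bp separated by spacers of 0.6–2.5 DR lengths;
  "confirmed" = ≥ 3 pairwise-distinct spacers), plus global-alignment 16S
  identity and neighbor-joining trees with deterministic tie-breaking.

Every stage is verifiable without downloads through the built-in
synthetic-data generator: it emits an ancestor genome plus mutated copies
with known per-category substitution rates, planted composition-shifted
foreign genes backed by a taxonomy-labelled hit database, and planted
CRISPR arrays — all recorded in a truth object that the test suite scores
recovery against.

## Worked example

```python
from strainkit import SimulationConfig, compute_ani, compute_category_ani, simulate

scenario = simulate(SimulationConfig(seed=0))     # 4 strains, 120 kb each
a, b = scenario.genomes[:2]
result = compute_ani(a, b)
print(result.ani, result.n_fragments_used)        # 90.06 200

genes = {g.genome_id: [] for g in scenario.genomes}
for gene in scenario.genes:
    if gene.feature_type == "cds":
        genes[gene.genome_id].append(gene)
profile = compute_category_ani(genes["S01"], genes["S02"],
                               scenario.category_map, genome_ani=result.ani)
for cat, (ani, n) in sorted(profile.categories.items()):
    print(cat, round(ani, 2))
# D 75.77   M 95.02   Q 90.59   Y 97.82
```

The whole-genome ANI of 90.06% reflects the 0.10 backbone substitution
rate (two lineages at rate p agree at `(1−p)² + p²/3` of sites ⇒ 90.33%
expected, minus fragment-level selection effects). The four categories
were planted at rates 0.02/0.05/0.10/0.25 and come back in exactly that
conservation order — the per-category profile recovers heterogeneous
evolution from sequence alone.

The `examples/` directory holds one short script per capability
(simulation truth, ANI profiles, ortholog/HGT calls, CRISPR detection,
composition + trees); each prints the numbers it computes and what they
mean. The full pipeline over a strain set is one call:

```bash
strainkit run --config config.yaml    # or: strainkit.pipeline.run(PipelineConfig(...))
```

which writes the strain summary, CRISPR table, composition matrices + CV
vectors + dendrogram merge tables, ANI matrix + category long table +
region labels, 16S identity/distance matrices + Newick tree, HGT
summaries, and a manifest of every effective parameter.

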