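"""Whole-genome ANI and the per-category divergence profile of one pair.

Cuts one genome into 1020-bp fragments, aligns each against the other
genome, and averages the identities of qualifying best hits; then repeats
the computation per functional category (gene vs same-category gene set),
which is how heterogeneous evolution across categories becomes visible
relative to the whole-genome line.
"""

from strainkit import SimulationConfig, compute_ani, compute_category_ani, simulate

scenario = simulate(SimulationConfig(seed=0))
a, b = scenario.genomes[0], scenario.genomes[1]

result = compute_ani(a, b)
ab, ba = result.one_way
print(f"whole-genome ANI {a.genome_id} vs {b.genome_id}:")
print(f"  reciprocal mean: {result.ani:.2f}%  ({result.n_fragments_used} fragments)")
print(f"  one-way {ab.genome_a}->{ab.genome_b}: {ab.ani:.2f}%   "
      f"one-way {ba.genome_a}->{ba.genome_b}: {ba.ani:.2f}%")

genes = {g.genome_id: [] for g in scenario.genomes}
for gene in scenario.genes:
    if gene.feature_type == "cds":
        genes[gene.genome_id].append(gene)

profile = compute_category_ani(genes[a.genome_id], genes[b.genome_id],
                               scenario.category_map, genome_ani=result.ani)
print("\nper-category ANI (planted rate in parentheses):")
for cat, (ani, n_hits) in sorted(profile.categories.items()):
    rate = scenario.truth.per_category_divergence.get(cat)
    print(f"  {cat}: {ani:6.2f}%  ({n_hits} gene hits, planted rate {rate})")
print("\nCategories planted at lower divergence come back with higher ANI;"
      "\na category ANI of 0 would mean no qualifying hit at all (the 0 sentinel).")
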