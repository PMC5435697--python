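"""Generate a synthetic strain set and look at what was planted.

Builds the default four-strain scenario — one ancestor plus three mutated
copies, with per-category divergence rates, ten planted foreign genes and
two CRISPR arrays — and prints the planted truth a later analysis is
supposed to recover.
"""

from strainkit import SimulationConfig, gc_content, simulate

scenario = simulate(SimulationConfig(seed=0))

print("strains:", [g.genome_id for g in scenario.genomes])
print(f"genome length: {scenario.genomes[0].length:,} bp;",
      f"G+C of focal strain: {gc_content(scenario.genomes[0]):.2f}%")
print("genes per strain:",
      sum(g.genome_id == "S01" for g in scenario.genes))

print("\nplanted per-category divergence (substitutions/site):")
for cat, rate in sorted(scenario.truth.per_category_divergence.items()):
    print(f"  category {cat}: {rate:.2f}  ->  expected pairwise identity "
          f"S02-S03: {scenario.truth.expected_identity[('S02', 'S03')][cat]:.2f}%")

print("\nplanted foreign (HGT) genes and their donor orders:")
for gid, order in sorted(scenario.truth.hgt_genes.items()):
    print(f"  {gid}: {order}")

print("\nplanted CRISPR arrays:")
for c in scenario.truth.crisprs:
    print(f"  {c.contig_id}:{c.start}-{c.end}  DR {c.dr_length} bp, "
          f"{c.n_spacers} spacers")

# Expected identities follow from the mutation model: each derived strain
# mutates independently at rate p, so two derived strains agree at a site
# with probability (1-p)^2 + p^2/3.
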