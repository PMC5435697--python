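"""Detect CRISPR arrays and compare against the planted truth.

The detector chains exact repeat seeds at spacer-compatible intervals,
extends each chain to the full direct repeat, and reports arrays with
their DR length, spacer count and confidence (confirmed = at least three
pairwise-distinct spacers).
"""

from strainkit import SimulationConfig, detect_crispr_arrays, simulate

scenario = simulate(SimulationConfig(seed=0))
genome = scenario.genomes[0]

arrays = detect_crispr_arrays(genome)
print(f"{genome.genome_id}: {len(arrays)} arrays detected "
      f"({len(scenario.truth.crisprs)} planted)\n")
print(f"{'array':8} {'length':>7} {'DR':>4} {'spacers':>8} {'spacer len':>11} conf")
for i, a in enumerate(arrays, 1):
    rng = (f"{a.spacer_length_min}" if a.spacer_length_min == a.spacer_length_max
           else f"{a.spacer_length_min}-{a.spacer_length_max}")
    print(f"CRISPR {i:<2} {a.length:>7} {a.dr_length:>4} {a.n_spacers:>8} "
          f"{rng:>11} {a.confidence}")

print("\nplanted truth:")
for c in scenario.truth.crisprs:
    print(f"  DR {c.dr_length} bp, {c.n_spacers} spacers at "
          f"{c.contig_id}:{c.start}")
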