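"""Trade-off classification of the published Brazil nut response matrix.

Loads the transcribed arrow/letter matrix (28 environmental variables x
seed / AGB services), classifies every fitness-density-area triple, and
prints the headline neutralization and dominance ratios.
"""

import json

from habqual import classify_table, load_reference_matrix, tabulate

table = load_reference_matrix()
classified = classify_table(table)
counts = tabulate(classified)
print(classified[classified.relation == "divergent"]
      [["variable", "service", "fitness", "density", "area", "area_label"]]
      .to_string(index=False))
print(json.dumps(counts, indent=2))

seed = counts["services"]["seed"]
agb = counts["services"]["agb"]
print(f"\nseed: {seed['divergent_labels'].get('N', 0)} of {seed['n_divergent']} "
      "divergent cases neutralized (area response non-significant)")
print(f"agb:  {agb['divergent_labels'].get('D', 0)} of {agb['n_divergent']} "
      "divergent cases density-dominated")

# Where per-tree fitness and density respond in opposite directions, the
# area-based seed service mostly shows no signal (neutralization), while
# area-based biomass mostly follows density.
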