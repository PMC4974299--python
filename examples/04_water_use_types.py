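"""The four-way water-use typology on the packaged trait table.

Standardizes leaf area duration (LAD) and stomatal conductance (SC) by
their treatment means, classifies each genotype into a quadrant of the
resulting plane, and summarizes transpiration per type.
"""

from phenowater import records_to_frame, reference_trait_table, type_summary
from phenowater.typology import classify_table

traits = records_to_frame(reference_trait_table())
types = classify_table(traits)
print(types.sort_values(["type", "genotype_id"]).to_string(index=False,
                                                           float_format="%.2f"))
print("-> lad_rel/sc_rel = 1 marks the population average; the quadrant"
      " is the water-use strategy")

summary = type_summary(traits, {"control": 39.4, "stress": 18.6}, types)
print()
print(summary.to_string(index=False, float_format="%.2f"))
print("-> tr_rate: mean transpiration (ET minus soil evaporation), ml/d;"
      " spenders and area types move the most water")
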