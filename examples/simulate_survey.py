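"""Generate a synthetic paired-plot invasion survey and inspect it.

The generator reproduces the field design (22 locations x 3 sites,
51 five-pair + 15 three-pair sites = 300 invaded/uninvaded plot pairs)
and draws 16 environmental drivers plus 7 leaf traits from a known
linear effect structure, so the ground truth behind every downstream
analysis is available.
"""

from leafspectra import EffectModel, SurveyDesign, simulate_survey

bundle = simulate_survey(design=SurveyDesign(), model=EffectModel(), seed=42)

print(f"plot pairs: {len(bundle.trait_table)}")
print(f"populations (sites): {bundle.trait_table['site'].nunique()}")
print("\nfirst two trait rows:")
print(bundle.trait_table.head(2).round(2).to_string(index=False))
print("\nenvironment drivers (mean over pairs):")
print(bundle.environment_table.iloc[:, 4:].mean().round(3).to_string())
print("\nnonzero ground-truth effects on SLA (trait units per driver SD):")
print(bundle.ground_truth.effect_matrix["sla"].loc[lambda s: s != 0].to_string())
# The d_* columns are invader-community interaction metrics: the relative
# change (Vi - Vu)/(Vi + Vu) of each paired variable across the invasion
# boundary; negative d_richness means invasion reduced native richness.
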