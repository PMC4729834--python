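"""Generate a small synthetic imaging-flow-cytometry population.

Each cell gets a brightfield/darkfield image pair plus a stoichiometric
nuclear-stain channel; the truth table records phase and DNA content.
"""

from cytocycle import PopulationConfig, generate_population

config = PopulationConfig(n_cells=300, seed=7)
records, truth = generate_population(config)

print(f"generated {len(records)} cells")
print("phase counts:", truth["phase"].value_counts().to_dict())
print(truth.head())
# dna_content runs from 2 (G1, 2N) to 4 (G2/M, 4N); stain_integrated is
# the ground-truth DNA intensity the regressor will learn to predict.
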