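"""Generate a synthetic paternal-diet cohort and inspect its structure.

Builds a two-group litter-structured cohort (sires fed control chow, CD, or a
high-fat/high-simple-sugar diet, HFHSS), draws per-structure simulation
parameters, and simulates a relative-volume matrix plus weekly sire weights.
"""

import littervol as lv

design = lv.generate_cohort(n_litters_per_group=20, max_litter_size=6, seed=1)
print(f"cohort: {design.n_samples} pups in {len(design.litter_ids)} litters")
print(design.samples.groupby(["diet", "sex"]).size().unstack(), "\n")

params = lv.generate_structure_params(n_structures=185, seed=1)
rel = lv.simulate_relative_volumes(design, params, seed=1)
print("relative-volume matrix:", rel.shape, "(samples x structures, % TBV)")
print(rel.iloc[:3, :3].round(4), "\n")

weights = lv.simulate_weights(n_per_group=20, n_weeks=8, seed=1)
ct = lv.compare_weights(weights, at_week="gain")
print(f"sire 8-week weight gain, HFHSS - CD: {ct.estimate:.2f} g "
      f"(t={ct.t:.2f}, p={ct.p:.2g})")
print("A positive estimate with small p reproduces the expected diet-induced")
print("weight gain in sires; the cohort itself carries no brain-volume effect.")
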