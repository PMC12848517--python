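"""Extract per-structure simulation parameters from a reference dataset.

The MDVC procedure needs, per structure, the sex-specific mean relative
volume and the litter/residual SDs.  Here a reference cohort is simulated
from known parameters, written to TSV, read back through the I/O layer, and
the parameters are re-estimated with the mixed model - a full round trip of
the plumbing a real analysis would use.
"""

import tempfile
from pathlib import Path

import littervol as lv

truth = lv.StructureParams("hippocampus_like", 1.0, 1.05, 0.06, 0.10)
reference = lv.generate_cohort(n_litters_per_group=40, seed=4)
rel = lv.simulate_relative_volumes(reference, [truth], seed=4)

with tempfile.TemporaryDirectory() as tmp:
    vol_path = Path(tmp) / "relative_volumes.tsv"
    meta_path = Path(tmp) / "metadata.tsv"
    lv.write_volume_table(rel, vol_path)
    lv.write_metadata(reference, meta_path)

    rel_back = lv.read_volume_table(vol_path)
    design_back = lv.read_metadata(meta_path)
    [estimated] = lv.extract_structure_params(rel_back, design_back)

print(f"true:      mean_F={truth.mean_rel_f:.3f} mean_M={truth.mean_rel_m:.3f} "
      f"sd_litter={truth.sd_litter:.3f} sd_resid={truth.sd_resid:.3f}")
print(f"estimated: mean_F={estimated.mean_rel_f:.3f} mean_M={estimated.mean_rel_m:.3f} "
      f"sd_litter={estimated.sd_litter:.3f} sd_resid={estimated.sd_resid:.3f}")
print("\nWith 80 litters the REML estimates sit close to the generating values;")
print("these estimates are exactly what mdvc_map consumes as StructureParams.")
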