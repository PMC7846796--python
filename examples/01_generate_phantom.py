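"""Generate a CT-like head phantom with a known ground-truth skull mask.

The phantom is an ellipsoidal bone shell (about 1000 HU) around a
soft-tissue cavity (+40 HU) in air (-1000 HU), optionally with a CT-table
slab and intracranial calcification speckles — the structures a bone
threshold picks up besides the skull.
"""

import craniogen as cg

spec = cg.PhantomSpec(include_table=True, n_calcifications=8, seed=1)
ct, ground_truth = cg.generate_phantom(spec)

print(f"grid {ct.geometry.dims} at {ct.geometry.spacing} mm")
print(f"HU range [{ct.values.min():.0f}, {ct.values.max():.0f}]")
print(f"ground-truth shell: {ground_truth.voxel_count} voxels "
      f"({ground_truth.volume_mm3 / 1000:.0f} cm^3 of bone)")

above = (ct.values >= 150).sum()
print(f"voxels >= 150 HU: {above} "
      f"({above - ground_truth.voxel_count} from table + calcifications)")
# The surplus over the shell count is exactly the nuisance structure a
# segmentation pipeline must remove.
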