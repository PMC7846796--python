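"""Inject one randomized craniotomy defect and inspect the (defect, implant) pair.

The erasing mask (cube/cuboid/sphere with small drill-hole spheres on its
corners) is intersected with the skull: the removed bone is the implant,
the remainder the defective skull, and together they partition the
complete skull exactly.
"""

import numpy as np

import craniogen as cg

_, skull = cg.generate_phantom(cg.PhantomSpec(n_calcifications=0, seed=3))

spec = cg.DefectSpec(seed=42)  # shape/size/position drawn from the template
pair = cg.inject_defect(skull, spec)

r = pair.spec_used
print(f"shape {r.shape}, size {tuple(round(s, 1) for s in r.size_mm)} mm, "
      f"{len(r.hole_centers_mm)} drill holes at radius {r.hole_radius_mm} mm")
print(f"center voxel {pair.mask_center}")
print(f"removed bone (implant): {pair.implant.volume_mm3 / 1000:.1f} cm^3")

union = pair.defective.as_bool() | pair.implant.as_bool()
inter = pair.defective.as_bool() & pair.implant.as_bool()
print(f"defective OR implant == complete: {np.array_equal(union, skull.as_bool())}")
print(f"defective AND implant empty:      {not inter.any()}")

# Optional clinical implant offset: erode the implant by 2 mm to model the
# drilling gap a craniotome leaves at the defect border.
offset = cg.apply_implant_offset(pair, 2.0)
print(f"implant after 2 mm offset: {offset.implant.volume_mm3 / 1000:.1f} cm^3")
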