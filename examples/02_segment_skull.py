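"""Extract the skull from a noisy phantom CT and score it against truth.

Pipeline: threshold at 150 HU -> keep the largest connected component
(drops the CT table and free-floating calcifications) -> optional 2 mm
median smoothing (flattens speckles fused to the inner skull surface).
"""

import numpy as np

import craniogen as cg

ct, ground_truth = cg.generate_phantom(
    cg.PhantomSpec(include_table=True, n_calcifications=8, seed=2)
)


def dice(a, b):
    inter = (a.as_bool() & b.as_bool()).sum()
    return 2 * inter / (a.voxel_count + b.voxel_count)


mask = cg.segment_skull(ct, cg.SegmentationConfig())
print(f"default pipeline:   Dice {dice(mask, ground_truth):.4f}")

smoothed = cg.segment_skull(ct, cg.SegmentationConfig(smooth=True))
print(f"with 2 mm smoothing: Dice {dice(smoothed, ground_truth):.4f}")

clean_ct, clean_gt = cg.generate_phantom(
    cg.PhantomSpec(include_table=False, n_calcifications=0, seed=2)
)
exact = np.array_equal(cg.segment_skull(clean_ct).labels, clean_gt.labels)
print(f"artifact-free phantom recovered exactly: {exact}")
# Dice near 1 on the noisy volume shows the cleaning steps remove the
# table and speckles; the clean phantom must come back voxel-exact.
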