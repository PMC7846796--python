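"""Build and package a small training dataset end to end.

Cohort of phantoms -> skull extraction -> N defects per skull -> release
tree with per-case folders (NRRD + STL + PNG) and three zip archives per
case (healthy / defects / implants).
"""

import tempfile
from pathlib import Path

import craniogen as cg

N_CASES, N_DEFECTS = 4, 5

base = cg.PhantomSpec(include_table=True, n_calcifications=8)
cohort = cg.generate_cohort(N_CASES, base, seed=4)
skulls = [(cid, cg.segment_skull(ct)) for cid, ct, _ in cohort]
dataset = cg.enlarge_dataset(skulls, N_DEFECTS, cg.DefectSpec(), seed=4)

print(f"{len(dataset.cases)} cases, {dataset.n_pairs} (defective, implant) pairs, "
      f"{dataset.n_skull_volumes} skull volumes in total")

with tempfile.TemporaryDirectory() as tmp:
    layout = cg.package_release(dataset, Path(tmp) / "release")
    cg.validate_release(Path(tmp) / "release")
    for cid in layout.case_ids:
        names = [a.name for a in layout.archives_for(cid)]
        print(f"{cid}: {names}")
# Every case carries exactly three archives whose defect/implant members
# align index for index — the layout a downstream loader expects.
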