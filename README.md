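# craniogen

Synthetic training data for **automatic cranial implant design**.

Patient-specific implants for cranioplasty are, in essence, the complementary
piece of a defective skull: given a post-craniotomy skull, the implant is the
bone that is missing. Data-driven implant design therefore needs many
(defective skull, implant) ground-truth pairs — but real pre/post-operative CT
pairs are scarce. `craniogen` builds such pairs synthetically: it injects
randomized artificial craniotomy defects into complete binary skull volumes,
so that for every defective skull the removed bone — the ideal implant — is
known exactly, voxel for voxel.

The package covers the whole workflow:

- **`phantom`** — parametric CT-like head volumes (ellipsoidal bone shell,
  soft tissue, air) with known ground-truth skull masks, plus the two classic
  nuisance structures of clinical head CT: a CT-table slab and intracranial
  calcification speckles. Everything downstream is testable with no external
  data.
- **`segmentation`** — threshold-based skull extraction: crop, HU threshold
  (label 1 where HU ≥ 150 by default), largest-connected-component noise
  removal, median smoothing with a physical radius (2 mm default), and
  slice-wise hole filling with cranial-cavity protection.
- **`defects`** — the core method. A cube, cuboid or sphere mask (sizes drawn
  in mm), decorated with small "drill-hole" spheres on its corners to mimic
  the craniotome's roundish gap, erases bone from the cranial vault:

  ```
  defective = complete ∧ ¬mask        implant = complete ∧ mask
  ```

  so `defective ∨ implant = complete` and `defective ∧ implant = ∅` — an exact
  partition, asserted for every generated pair. An optional *clinical implant
  offset* erodes the implant by a physical radius. `enlarge_dataset` creates
  N defects per skull (10 by default) with fully seeded reproducibility.
- **`mesh_ops`** — marching-cubes surface extraction (binary volume → STL
  mesh in mm), watertight-mesh voxelization (parity inside test on voxel
  centers), and point-cloud extraction (all voxels or 6-connected surface).
- **`io_formats` / `packaging` / `cli`** — NRRD/STL/PNG I/O preserving
  spacing and origin, and a packager that reproduces the per-case release
  layout (folder `CaseNN/` with same-stem NRRD+STL+PNG, plus
  `CaseNN Healthy.zip`, `CaseNN Defects.zip`, `CaseNN Implants.zip`), all
  byte-deterministic for a fixed seed.

## Worked example

```python
import craniogen as cg

# a CT-like phantom with table + calcification artifacts
ct, truth = cg.generate_phantom(cg.PhantomSpec(include_table=True, seed=1))

# extract the skull and carve a randomized defect
skull = cg.segment_skull(ct)
pair = cg.inject_defect(skull, cg.DefectSpec(seed=42))
print(pair.spec_used.shape, pair.implant.volume_mm3)
```

Running `python examples/03_inject_defect.py` prints:

```
shape sphere, size (61.9,) mm, 2 drill holes at radius 5.0 mm
center voxel (30, 32, 48)
removed bone (implant): 17.7 cm^3
defective OR implant == complete: True
defective AND implant empty:      True
implant after 2 mm offset: 9.8 cm^3
```

i.e. a 61.9 mm spherical defect with two drill holes removed 17.7 cm³ of
vault bone; the pair partitions the skull exactly, and the optional 2 mm
offset shrinks the implant to 9.8 cm³. The other scripts under `examples/`
walk through phantom generation, segmentation scoring (Dice ≥ 0.999 against
ground truth on artifact-laden phantoms, exact recovery on clean ones),
dataset packaging, and mesh/point-cloud conversion (voxelization round-trip
Dice 1.000 on the default phantom).

A thin CLI wraps the same functions for shell pipelines:

```bash
craniogen phantom --cases 24 --seed 7 --out ws
craniogen segment --workspace ws
craniogen enlarge --workspace ws --n 10 --seed 7
craniogen package --workspace ws --out release
```

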