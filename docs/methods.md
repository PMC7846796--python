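# Methods

## The problem being modelled

A craniotomy removes a piece of the neurocranium; the patient-specific
implant that repairs it must match the removed bone in thickness, boundary
and shape. Supervised models for automatic implant design are trained on
(defective skull, implant) pairs in which the implant is the exact
complement of the defect. `craniogen` generates such pairs by construction:
starting from a complete binary skull volume, an erasing mask `M` is placed
on the cranial vault and

    defective = complete ∧ ¬M,    implant = complete ∧ M.

Because both members are derived from the same voxel set, the partition
property (`defective ∨ implant = complete`, `defective ∧ implant = ∅`) holds
exactly and is *asserted* on every constructed pair rather than assumed.

## Skull phantom

Real head CT cannot be redistributed with a package, so all testing runs on
a parametric phantom: the skull is the difference of two concentric
ellipsoids (outer semi-axes 65 × 80 × 55 mm, shell thickness 6 mm by
default — the scale of an adult neurocranium), air at −1000 HU outside,
soft tissue at +40 HU in the cavity, compact bone at +1000 HU in the shell.
Two optional nuisance structures emulate what a bone threshold picks up on
clinical scans besides the skull:

- **CT-table slab** (800 HU): a flat bar under the head (low y), 3 mm thick
  over the central half of x, explicitly kept one voxel clear of the head so
  thresholding yields it as a separate connected component. It is sized to
  stay smaller than the shell at every supported geometry, since the
  cleaning step keeps the *largest* component.
- **Calcification speckles** (400 HU): 3 mm-radius spheres in the cavity;
  a configurable fraction (default 0.3) is seated against the inner shell
  surface so that, after thresholding, they stay fused to the skull and can
  only be removed by smoothing — the rest float freely and fall to the
  largest-component filter.

The ground-truth mask is the shell alone. With both nuisances disabled,
thresholding at 150 HU reproduces the ground truth voxel-exactly, which
anchors the exact-recovery tests. Default grid: 128 × 128 × 96 voxels at
1.5 mm isotropic (fast); a paper-scale preset of 512 × 512 × 150 at
(0.98, 0.98, 1.25) mm mirrors clinical resolution. Cohorts jitter the radii
(±8%) and thickness (±15%) per case with independently derived seeds.

What the phantom does **not** model: facial skeleton, sutures,
trabecular/cortical differentiation, thin delicate bone (no genuine holes in
the shell), streak artifacts from dental metal, and a cranial cavity that
opens at the foramen magnum. Passing tests therefore demonstrate the
correctness of the *operations* (set algebra, component logic, geometry
handling), not segmentation quality on real anatomy.

## Segmentation pipeline

Fixed stage order: crop → threshold → largest connected component →
optional median smoothing → optional slice-wise hole filling.

- **Threshold** is inclusive (`HU ≥ t`), default 150, per-case overrides
  (e.g. 200) supported via a YAML config or a cohort CSV table.
- **Largest component** defaults to 26-connectivity (typical interactive
  tool behaviour); equal-size ties go to the component containing the
  lexicographically smallest (x, y, z) voxel, which makes the operation
  deterministic. Since arrays are (x, y, z) C-ordered, the first flat index
  realizes that order directly.
- **Median smoothing** is a strict-majority filter over an *ellipsoidal*
  neighbourhood of physical radius `r` mm (per-axis voxel radius
  `r / spacing`, rounded half up) — physical rather than voxel units because
  slice spacing on clinical data can reach ~3 mm, and a cubic voxel
  neighbourhood would smooth anisotropically. Ties go to background; edges
  replicate so constant masks are invariant. A radius below half the
  largest spacing degenerates to a single voxel: warning + identity.
  Smoothing is *off* by default (it is a per-case remedy, and it is not the
  identity on curved shells, which would break exact recovery on clean
  phantoms).
- **Hole filling** operates per 2D slice (4-connected background not
  reachable from the slice border is filled). The cranial cavity must never
  be filled in slices where the bone ring encloses it, and a 2D area cutoff
  cannot distinguish a small cavity cross-section near the vault apex from
  a real intra-bone hole. Protection is therefore 3D-aware: a slice region
  is skipped iff it belongs to a 3D background component (6-connected) that
  is enclosed (no path to the volume border) *and* larger than 5% of the
  volume — on a closed shell this is exactly the cavity, so filling is the
  identity on hole-free phantoms while one-voxel gaps, even gaps open along
  the slicing axis, still fill. Limitation: on a real skull the cavity
  drains to the exterior through the foramen magnum and would lose this
  protection; per-case review would be needed there, as it was in the
  original manual workflow.
- **Streak-artifact removal** beyond what components and smoothing achieve
  is out of scope.

## Defect injection

`DefectSpec` is a template: shape kind (cube / cuboid / sphere, or drawn
uniformly when unset), sizes drawn uniformly from [40, 90] mm (the scale of
craniotomy defects relative to an adult vault; configurable), 1–4 drill
holes of radius 5 mm placed on randomly chosen corners (cube/cuboid:
vertices; sphere: random surface points) to mimic the craniotome's entry
holes. Placement samples a bone voxel uniformly from the *vault region* —
the top `f` (default 0.5) of the skull bounding box along z — so defects
land on the cranium rather than the skull base. Rejection sampling retries
(up to 100 attempts per defect) until the removed volume reaches 5000 mm³,
preventing grazing masks that shave off slivers. Masks are rasterized only
inside their bounding box, so injection cost is independent of volume size.

`enlarge_dataset` derives one seed per (cohort seed, case index, defect
index) via `numpy` seed sequences: every slot is independent, the whole
dataset reproduces bit-identically from one integer, and a failed slot
retries with a fresh derived seed a bounded number of times before the
failure is reported with its case and index.

The *clinical implant offset* (the drilling gap between implant and defect
border) is modelled twice: the corner drill holes belong to the erasing
mask itself, and an optional post-step erodes the implant by a physical
radius (implemented as a Euclidean distance-transform threshold with
anisotropic sampling, i.e. erosion by a true physical sphere). The default
offset is 0 — implants ship as the exact complement — because the released
ground truth is described as the removed portion; the relaxed invariant
after an offset is `implant ⊆ complete ∧ ¬defective`.

## Mesh and point-cloud conversion

- **Volume → mesh**: marching cubes at iso-level 0.5 on the zero-padded
  binary field (padding closes meshes of masks touching the border);
  vertices in physical mm via spacing and origin; zero-area triangles
  dropped. No pre-smoothing by default — interactive exporters smooth the
  scalar field first and would produce different (smaller) surfaces; an
  optional Gaussian pre-smooth exposes that behaviour. Closed shells yield
  two nested watertight surface components (outer and inner table).
- **Mesh → volume**: a voxel is inside iff a ray from below crosses the
  surface an odd number of times below the voxel center. Implemented as a
  z-column sweep: each triangle's xy-projection is rasterized onto the
  voxel columns it covers, its plane-crossing height binned, and a cumulative
  parity along z labels the material — for nested shells this is exactly
  "inside outer XOR inside inner". Ray-through-edge ambiguities are
  dispelled by an irrational sub-voxel shift of the ray grid (~2×10⁻⁴
  voxel, far below any physical tolerance). Non-watertight input is
  rejected with a report of its open edges; vertical (degenerate-projection)
  triangles contribute no crossings, which the shared-edge parity of a
  closed mesh makes consistent.
- **Point clouds**: voxel centers in mm; "surface" mode keeps foreground
  voxels with at least one 6-connected background neighbour, counting the
  volume boundary as background (a 3³ block therefore has 27 "all" / 26
  "surface" points).

## Determinism and I/O

Every random draw flows from an explicit integer seed through
`numpy.random.Generator`; derived seeds stay below 2³¹. NRRD is written
gzip-compressed with masks as uint8 and HU volumes as int16/float32 (both
byte-deterministic with the ITK writer), STL as binary with a zeroed
header, PNG via a depth-shaded lateral projection, and zip archives with
fixed (epoch) timestamps and sorted members — so a repeated seeded run
produces a checksum-identical release tree, which the test suite verifies
end to end. The NRRD reader accepts raw or gzip encodings but rejects
non-axis-aligned orientation matrices rather than silently resampling.

## Problem sizes

The package's reference workflow — and the acceptance script — runs 24
cases at the default 128 × 128 × 96 geometry with 10 defects per skull
(240 pairs, 264 skull volumes), packaged and verified in well under a
minute on one CPU. The paper-scale preset exercises clinical resolution
where individual tests need it; the full cohort at that scale is
unnecessary for validating the operations and is left to users generating
production datasets.
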