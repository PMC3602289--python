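# Methods

`torsofuse` builds one 3D model of a scoliotic torso from three
modalities acquired in different postures: axial MRI slices (patient
prone), a biplanar-X-ray 3D spine reconstruction (standing), and an
optical surface topography (TP) of the trunk (standing).  The postural
change between acquisitions mixes a rigid part (the vertebrae move, but
do not deform) with a non-rigid part (soft tissue settles differently
when lying down), and the method treats the two separately.

## Registration model

**TP → X-ray.** External markers visible in both standing modalities
(adhesive markers on the optical scan, radio-opaque markers affixed on
top of them for the radiographs) drive a 3D thin-plate spline

    f(p) = a1 + a2 x + a3 y + a4 z + Σᵢ wᵢ U(|p − pᵢ|),   U(r) = |r|,

with one coefficient set per output coordinate, solved from the block
system `[[K + λI, P], [Pᵀ, 0]] · [w; a] = [V; 0]` with the side
condition `Pᵀw = 0`.  λ = 0 (interpolating) for the marker fit.  The
spline is applied to every TP mesh vertex.

**Articulated bone registration.** Each vertebra v (T1–T12, L1–L5) gets
a local coordinate frame — center plus orthonormal lateral/anterior/
superior axes — estimated from its landmarks: 6 per vertebra on the
X-ray reconstruction (endplate centers, four pedicle points), 8 per
vertebra from the sagittal MRI segmentation (left/right edges of the
anterior, posterior, superior, inferior body ends).  The two landmark
dialects share no correspondences, which is why registration goes
through frames rather than points.  The spine is a chain of rigid
intervertebral transforms; the global transform of vertebra v is the
fold

    T₀,ᵥ = Tᵥ₋₁,ᵥ ∘ … ∘ T₁,₂ ∘ T₀,₁,

and the per-vertebra bone transform from MRI into X-ray space is

    Tᵥ‑bone = T₀,ᵥ(X-ray) ∘ T₀,ᵥ(MRI)⁻¹.

Each axial slice is moved rigidly by the transform of the vertebra with
the nearest center z (ties resolve to the inferior vertebra; slice z is
taken at the vertebra-mask centroid mapped to world, so assignment
survives arbitrary poses).  Slices are treated as independent 2D
planes — the 12 mm inter-slice gap makes continuity constraints
meaningless.

**Soft-tissue refinement (per slice).** The registered slice plane cuts
the TP mesh; correspondence points are sampled on the MRI torso contour
and the TP cut at 30° intervals along rays from the vertebra center
(angle 0 anterior), giving 12 pairs that drive a planar edge spline
`T_edge` (same kernel, 2D in-plane coordinates, default λ = 1e-3 as an
approximating fit).  The final transform blends `T_edge` with the
identity through the distance ratio

    ρ(p) = D_vertebra(p) / (D_surface(p) + D_vertebra(p)),
    p ↦ p + ρ(p) · (T_edge(p) − p),

where `D_vertebra`/`D_surface` are Euclidean distances to the vertebra
and torso borders.  ρ = 0 on the vertebra border (bone stays rigid),
ρ = 1 on the skin (the contour lands on the TP cut), and the field is
continuous in between.  A literal "scalar × transform" weighting is
ill-typed for rigid motions; the identity-blended displacement above is
the formulation that reproduces all three limits.

## Validation metrics

* **2D Dice** `2|A∩B| / (|A|+|B|)` between the registered MRI torso
  mask and the TP cut interior, per slice.  (A Dice printed with a
  union denominator would give Dice(A,A) = 2; the standard
  sum-of-areas denominator is used.)
* **3D Dice** between voxelized volumes (1×1×3 mm, voxel centers
  inside a watertight surface): the registered slice contours are
  resampled (72 ring-aligned points), stitched, capped and refined by
  one 1-to-4 midpoint subdivision, then compared against the voxelized
  TP mesh.  This also probes the interpolation between the widely
  spaced slices, so it sits a few percent below the 2D mean.
* **Jacobian determinant** of the per-slice map x ↦ x + u(x), partial
  derivatives approximated by first-order Gaussian derivatives with
  σ = 1 px and kernel support truncated at 3σ.  With that truncation
  the determinant is *exactly* 1 wherever the displacement vanishes
  over the kernel support — in particular on the vertebra interior
  eroded by 3 px, which is the rigidity signature the method must
  show.  det > 1 is local expansion of the forward map.
* **Method comparison**: per-slice Dice of `rigid` (one least-squares
  Kabsch fit over all 17 frames), `articulated` (bone transform only)
  and `proposed` (bone + weighted spline), mean ± SD and a paired
  two-sided Wilcoxon signed-rank test (paired t-test available).

## Synthetic study conditions

No public dataset pairs the three modalities, so the phantom module
generates complete synthetic patients with known ground truth.  Chosen
conditions (fixed defaults):

* **Spine**: 17 vertebrae at 24 mm spacing (≈400 mm trunk), lateral
  half-sine curve solved to a requested Cobb-like severity (default
  50°, the range of pre-surgical scoliosis), apex T9, peak axial
  rotation 8°.  Landmark templates are stylized shapes with zero local
  centroid, so both landmark dialects recover identical frame centers.
* **Prone deformation**: every intervertebral joint perturbed by
  seeded uniform rotations within ±2° per axis and translations within
  ±1 mm — compounding to a realistic single-digit-degree postural
  change of the whole spine — under a fixed global scanner-frame
  offset.  The exact per-joint corrections are recorded, so closure
  (prone + corrections = standing) is testable to 1e-9 mm.
* **Torso**: elliptical cross-sections (semi-axes 150 × 110 mm) whose
  center line follows 60% of the spinal curve, modelled in a
  patient-canonical frame and posed rigidly with the spine.  The prone
  torso adds a smooth anterior compression — radial factor falling
  from 1 posteriorly to 0.82 at the anterior peak with a sin²
  profile.  A C¹ profile was chosen over a hard half-plane scale
  because tissue compression is smooth and because a C⁰ kink is
  unrepresentable by any 12-point spline, which would contaminate the
  method comparison with generator artifacts.
* **Slices**: 1×1 mm in-plane, 12 mm spacing, perpendicular to scanner
  z (axial acquisition through the posed patient), ~33 slices per
  trunk; vertebra masks are sections of posed elliptical cylinders
  (16 × 12 mm semi-axes, 14 mm half-height — no posterior elements,
  since only the vertebral body drives the landmarks).
* **TP device frame**: a seeded small rigid offset (±3°, ±15 mm).  It
  is exactly recoverable by the marker spline (affine exactness), so
  the TP registration has a closed-form truth; a non-rigid device
  error would have no independent readout.

What the phantom does *not* emulate: MRI intensities (only geometry and
masks), rib cage/scapulae/pelvis, breast tissue, tissue-specific
elasticity, gravity.  Passing tests therefore demonstrate the
geometric machinery — bone rigidity, contour confinement, metric
correctness — not anatomical fidelity on real patients.

## Numerical choices

* Composition order `compose(T2, T1)` = apply T1 first, unit-tested
  against sequential application (the main ambiguity surface of the
  chain notation).
* Frame estimation trusts the superior axis most (endplate centers are
  the most reliable landmarks) and orthogonalizes the remaining axes
  against it; rotations are stored as matrices to avoid gimbal issues.
* Planar spline fits use the |r| kernel (the stated 3D kernel) in the
  slice's 2D coordinates with a 2D affine part, keeping coplanar
  control points well-posed without switching to the classical
  r²·log r kernel.
* TPS systems are solved densely; condition numbers above 1e10 warn,
  duplicate/affinely degenerate control points raise with the
  condition number attached.
* Distance maps: border = mask pixel with a 4-neighbour outside;
  exact Euclidean distance transform to the border pixel set; ρ is
  sampled bilinearly (masks nearest-neighbour) at off-grid points.
* Mask resampling after the soft warp inverts the forward field by
  fixed-point iteration (20 iterations, adequate for these smooth
  moderate fields) and pulls masks back with nearest-neighbour
  interpolation.
* Voxelization slices the mesh plane-by-plane and tests pixel centers
  against the section polygons; volumes are compared after snapping
  the relative origin to the nearest voxel.
* Degenerate inputs fail loudly: empty masks, both-empty Dice, planes
  missing the mesh, rays without contour crossings, non-watertight
  meshes, mismatched marker names.

## Problem sizes

Default runs use the full phantom (17 vertebrae, ~33 slices of
~360×250 px, three methods) for the method comparison and the 3D Dice
at 1×1×3 mm; these complete in seconds to a couple of minutes on one
CPU, so no reduced test variants are needed.

## Known limitations

* Correspondence rays fan out opposite the (posterior) vertebra
  center: at 30° steps the anterior contour is sampled ~90 mm apart,
  leaving a few mm of between-ray deviation from the TP cut.  Exact
  containment holds only at the control points (λ = 0).  A smaller
  angular step tightens this at the cost of fidelity to the method's
  stated sampling.
* The edge spline extrapolates beyond the torso contour; the dense
  field is defined on the whole slice grid but only meaningful inside
  the torso.
* The fixed-point field inversion assumes a displacement below the
  grid scale of field variation; it is not a general diffeomorphic
  inverse.
* 2D Dice is orientation-dependent by construction (it assumes the
  articulated alignment put the slice in the right plane); the 3D
  measure reduces but does not remove that bias, and neither measures
  anatomical correctness of the interior deformation.
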