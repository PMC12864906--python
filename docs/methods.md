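# Methods

## Problem and pipeline

Two CT volumes of the same patient are acquired on the same table
position: quiet expiration ("rest") and forced Valsalva. The Valsalva
load makes mechanically weak regions of the abdominal wall bulge. The
pipeline estimates the dense displacement field of the body outline
between the two states and derives from it the quantities used in
biomechanical repair planning: the unstable-wall area, the
Green-Lagrange strain field, hernia volumetry, and a landmark-based
error estimate of the registration itself.

All rasters live on a single canonical frame: array axes are x
(left-right), y (posterior-anterior), z (inferior-superior); indices are
0-based and the world position of voxel (i, j, k) is
`origin + (i, j, k) · spacing` in mm. Inputs (NIfTI or DICOM series) are
reoriented into this frame once on load; DICOM slices are ordered by
spatial position, never file name, and a non-uniform slice increment is
a hard error (a missing slice silently corrupts the displacement field).

## Pair applicability (QC)

Registration of the outlines is meaningless unless both scans share the
acquisition geometry, so a fixed catalogue of checks runs before any
computation. Geometry: slice count, in-plane shape, slice thickness and
pixel spacing (equal to 1e-3 mm — tolerances only absorb float
round-off), origin (table reposition; tolerance half a voxel) and
orientation. Content, on thresholded body rasters:

- **truncation** — fraction of body *surface* voxels on the lateral or
  anterior image borders, fail above 0.5%. The surface-based measure is
  deliberate: a volume-voxel fraction scales with 1/spacing and fails to
  flag realistic truncations on coarse grids, whereas a truncation plane
  of area A always contributes ≈ A/(total surface) of surface voxels.
  The posterior border is exempt (the body rests near the table).
- **shift** — in-plane centroid offset between the two body rasters,
  fail above 10 mm. Genuine Valsalva expansion shifts the centroid
  anteriorly by a few mm; a reconstruction shift is typically tens of mm.
- **scale** — lateral (x) bounding-box extent ratio: warn outside
  [0.97, 1.03], fail outside [0.90, 1.10]. Only the x extent is used
  because genuine anterior expansion confounds y; a reconstruction zoom
  scales both axes, so the lateral extent is the clean signal.
- **foreign_object** — more than one detached component above 5000 mm³
  (arms in the field of view). This check runs on a raster that keeps
  detached components; the patient table is excluded as the component
  touching the posterior border (the table extends below the field of
  view). These thresholds are configurable defaults: the failure modes
  are documented qualitatively in the clinical literature, without
  published cutoffs.

Failures are report entries, not exceptions; the pipeline aborts on an
inapplicable pair unless explicitly overridden.

## Body masks and registration

The body outline is the largest 26-connected component above −300 HU
(separating soft tissue from air across 80–130 kVp; configurable), with
the patient table discarded as a detached component, then hole-filled in
3D and per axial slice so lungs and bowel gas cannot punch holes.
Volumes are resampled to 1 mm isotropic (protocol default) and the masks
block-reduced by a majority vote with factor 3, trading resolution for
runtime exactly as in the clinical protocol.

Binary masks carry no usable gradients, so the solver is driven on a
signed Euclidean distance transform of each mask, negative inside and
capped at ±20 mm — a smooth surface-matching similarity that honours the
mask-based formulation. The backend is symmetric-forces demons
(SimpleITK) over a 3-level pyramid (shrink 4/2/1, 100 iterations per
level, field smoothing 1.5 voxels, RMS convergence 1e-4). Any symmetric
diffeomorphic solver satisfying the recovery contract would conform; the
hyperparameters are engineering defaults validated by the phantom
recovery tests (Dice ≥ 0.95, positive Jacobian, normalised landmark
error ≤ 10% across bulge amplitudes 10–40 mm). The final-level iteration
count matters more than one might expect: the distance-map forces vanish
away from the surface, and it is the field smoothing that diffuses
displacement into the body interior, so stopping early leaves the
interior field — and with it the surface statistic on the *rest*
surface — underestimated.

The recovered field lives on the (downscaled) rest grid; vectors are mm
in world space pointing from a rest position to its Valsalva position.
Warping a mask forward is evaluated as a backward warp through the
inverted field; the inverse displacement satisfies the fixed-point
relation v(y) = −u(y + v(y)) and is iterated to 0.01 mm (the analytic
deformation is a contraction, and recovered fields are smooth enough in
practice). `det(I + ∇u) > 0` everywhere on the body is the
diffeomorphism diagnostic.

## Strain

The displacement gradient uses second-order central differences scaled
by the grid spacing, with second-order one-sided stencils on the
boundary planes; boundary voxels are flagged and the flag propagates, as
surface hotspots there can be artefacts of image-border effects. The
Green-Lagrange tensor E = ½(H + Hᵀ + HᵀH) is symmetrised against
round-off. Strain stays on the registration grid and is interpolated to
surfaces; tensors are never upsampled (that would invent resolution).

Maximum principal strain uses a vectorised closed-form (trigonometric)
symmetric 3×3 eigensolver; tests require agreement with LAPACK
(`eigvalsh`) to 1e-8, and rotation-invariance tests confirm E (unlike
the small-strain tensor) vanishes for finite rigid motions. Interior
strain error on the analytic bulge field converges as O(h²).

## Surfaces and the instability statistic

Surfaces come from marching cubes on the mask smoothed with a one-voxel
Gaussian: the raw 0/1 staircase overestimates smooth areas by ~8%,
while the smoothed 0.5-level surface recovers the analytic sphere area
to ≈ 0.1%. Only the largest surface component is kept; degenerate
triangles are dropped. Rest-phase vertices sample the forward field;
Valsalva-phase vertices sample the inverted field, so both surfaces
express the displacement relative to the rest state.

A triangle is unstable when the *mean* of its three vertex displacements
exceeds τ (unbiased at the boundary compared with any-/all-vertex
rules; configurable). The statistic is reported for both surfaces — the
clinical sources colour-code both without saying which one their cm²
figures use — with the rest surface as the headline value. The colour
map is two-regime by design, with a deliberate discontinuity at τ:
blue→cyan over [0, τ), red→yellow→white over [τ, max], linear within
each regime.

## Volumetry and landmarks

Class volumes are voxel counts × voxel volume. Loss of domain follows
the Sabbagh convention 100·V_hernia/(V_hernia+V_cavity); the convention
string is written into the output since a V_hernia/V_cavity variant also
circulates. Defect and mesh areas are manual/intraoperative inputs, not
derived from imaging. The report slice is the axial slice with the
largest hernia-sac cross-section, ties to the lowest index.

Landmark validation compares displacement *magnitudes* (the measured
quantities are mm scalars); vector errors are reported alongside. The
normalised error divides by the subject's maximum measured landmark
displacement, per landmark and as the mean.

## Phantom

The phantom is the package's study condition, not a tuning dial:
ellipsoidal torso (semi-axes 140 × 100 × 120 mm), 15 mm muscle shell
(rectus anterior, three lateral layers), cavity, optional hernia — a
30 mm half-width wall gap with a 40 mm sac — and a table slab extending
to the posterior border. HU per class (air −1000, cavity −10, muscle 55,
sac 30, table 300) with seeded Gaussian noise (sd 10 HU) give realistic
thresholding behaviour. The deformation is an anterior Gaussian bulge
u(p) = A·exp(−Σ(pᵢ−cᵢ)²/2σᵢ²)·ŷ centred on the anterior pole
(σ = 80, 80, 60 mm; default A = 25 mm, tests also use 10 and 40), which
keeps the map diffeomorphic whenever A·e^(−1/2)/σ_y < 1 — enforced at
construction. The Valsalva raster is built by evaluating the *analytic*
geometry at the fixed-point inverse of each voxel centre, so the two
rasters correspond point-to-point through u with no interpolation
smear; electrodes sit on a 5 cm grid on the anterior rest surface and
are transported by the exact field. The table is added after warping
(it is attached to the scanner, not the patient).

Ground-truth unstable area is evaluated on a finely subdivided analytic
ellipsoid with the same triangle rule the pipeline uses; it is defined
on the smooth torso (no sac), so end-to-end comparisons against it use
the hernia-free phantom. What the phantom does *not* emulate: realistic
muscle fibre anatomy, respiratory motion, beam hardening or metal
artefacts, and hernia shape variability — passing tests demonstrate the
mechanics of the pipeline, not segmentation robustness on clinical
images.

Controlled corruptions reproduce the acquisition failure modes with
known magnitude (in-plane shift or zoom of one scan, anterior crop,
detached arm-like slab, missing slices), and a zero magnitude is a
strict no-op.

## Problem sizes and numerical choices

Tests and the acceptance script run the phantom at a 3 mm grid
(~10⁶ voxels, registration ≈ 20 s), which the package treats as its
standard desk-scale configuration; a 1 mm phantom is available through
the same API and CLI. Degenerate inputs are errors, not guesses: empty
masks, all-air volumes, landmark sets without pairs, zero defect areas
and non-finite fields all raise with a named cause. Sampling outside a
field's extent is an error in `sample_field` but a counted clamp in
surface mapping, where marching-cubes vertices legitimately sit half a
voxel outside the lattice. All registration is deterministic given its
configuration (no random initialisation); the only randomness anywhere
is the phantom's HU noise, under a single seed.

## Known limitations

- The anterior-centroid confound bounds how aggressive the shift check
  can be: very large genuine bulges (≈ 40 mm amplitude over a wide
  area) approach the 10 mm centroid threshold.
- The unstable-wall statistic inherits a few percent of uncertainty
  from surface discretisation and from the interior diffusion of the
  demons field; rest- and Valsalva-surface values bracket the analytic
  truth in practice.
- Strain hotspot display is a visual aid; no stress or constitutive
  model is computed.
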