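# Methods

## Problem and model

The package converts an ordered stack of 2D cross-sectional images with
known pixel size Δx = Δy and inter-slice distance Δz (millimetres) into a
triangle mesh of the boundary of a segmented structure. The scalar field is
voxel-centered: sample (i, j, k) sits at `origin + (iΔx, jΔy, kΔz)`, and the
surface is the level set D = C₀ of the (implicitly trilinear) interpolant of
the samples.

Assumptions: slices are parallel, equally spaced, and ordered; in-plane
pixels are square; misalignment between slices is an invertible 2D affine
transform (what a camera/stage shift, small rotation, or scale change
produces); segmentation is given per slice (externally drawn masks or an
intensity window), not computed by this package.

## Registration

Each slice carries ≥ 3 labeled fiducial points (physical alignment rods
appear as disks in every slice). Detection thresholds an intensity window,
groups pixels by 8-connectivity, discards components under 4 px, takes the
expected number of largest components, and computes intensity-weighted
centroids over each component dilated by 2 px — the dilation captures the
interpolation tail of a previously resampled disk, which is what makes
sub-0.01 px centroids (and hence < 0.1 px transform recovery) possible.
Labels are assigned by ascending (y, x); correspondence across slices is by
label order, not nearest-neighbour matching, so fiducial layouts must keep
that order stable under the expected jitter (rods with well-separated y
coordinates; two rods with near-equal y can swap order under a ~2° rotation).

The affine with `target = T · source` in homogeneous coordinates is solved
per output coordinate by linear least squares; three non-collinear points
determine it exactly. Slices are resampled into the reference frame by
bilinear interpolation at T⁻¹(x, y), with out-of-bounds pixels set to a fill
value. Resampled values are clamped to the input range — bilinear output is
mathematically inside that range, and removing float round-off dust matters
because downstream threshold windows are inclusive (a pixel at 255 + 3e-14
must not fall out of a [128, 255] window).

Non-goals: intensity-based (mutual-information) registration, non-rigid
deformation, 3D volumetric registration.

## Volume assembly and inter-slice interpolation

Masked luminance becomes the field (`D = luminance` where mask = 1, else 0;
masks binarize nonzero → 1 from lossless files and ≥ 128 → 1 from JPEG,
whose compression rings around edges). Isotropization inserts z-samples at
spacing Δz′ = Δx with output depth `round((depth−1)·Δz/Δz′) + 1`; original
slice planes that land on the new grid are copied bit-exactly.

Two interpolation modes:

- **linear** — straight interpolation of intensities between the two
  bracketing slices; exact for fields linear in z and bound-preserving.
- **shape** — for segmentations: each slice's binary mask is converted to a
  signed Euclidean distance transform (positive inside), the distance fields
  are interpolated linearly in z, and the result is re-thresholded at 0, so
  an inserted cross-section between two nested disks is an intermediate
  disk rather than a fractional-valued ring.

The pipeline default is shape-based whenever masks are applied, linear
otherwise. This is not merely cosmetic: linear interpolation of a two-level
masked volume (0/255) creates interpolated samples *exactly at* the default
isovalue 127.5 wherever the new grid bisects an interval, i.e. a plateau on
the level set — the single worst input for any isosurfacer (ties, ambiguous
faces, pinched geometry). Shape interpolation keeps all samples at the two
levels. Degenerate inputs: a slice that is entirely empty/full has distance
±∞; interpolating an all-empty against an all-full slice is undefined and
not supported.

## Marching-cubes kernel

Conventions (the field's equations leave them open; these are fixed here):
corner i of a cube occupies offset `((i>>0)&1, (i>>1)&1, (i>>2)&1)` along
(x, y, z); edges 0–3 run along x, 4–7 along y, 8–11 along z (the table is in
`mc_core.py`). Corner state is Sᵢ = 1 ⇔ qᵢ ≥ C₀ — the boundary counts as
inside, exactly, with no epsilon perturbation. The configuration index is
ΣSᵢ·2ⁱ.

**Case table.** The 256 configurations fall into 15 equivalence classes
under the 24 proper rotations of the cube combined with complementation
(verified by brute-force orbit enumeration; 2⁸ − 1 = 255 configurations
produce geometry). One tessellation per class representative is frozen in
the source; it was derived once by a face-consistent cycle construction —
per face, marching-squares segments with ambiguous faces resolved by
separating the high corners; cut edges chained into cycles; cycles
fan-triangulated and oriented so normals point from the high side to the
low side — and the full table is expanded by applying the rotations, with
complementary indices reusing the intersected-edge set in reversed winding.
Construction is validated at build time (every index assigned; every
referenced edge joins opposite states).

**Known limitation.** Complement-expanded tables cannot resolve *ambiguous
faces* (diagonal corner states) consistently between a rotation-derived and
a complement-derived neighbour; an exhaustive check of all 4096
configuration pairs sharing a face confirms mismatches occur only there.
On smooth phantoms ambiguous faces do not arise (for a sphere one can show
a face can never see a diagonal in/out pattern), and the test suite asserts
hole-free meshes on sphere, torus, and tube phantoms; adversarial volumes
(random noise at the isovalue, plateaus) can produce open or pinched edges.
Topology-guaranteeing variants (asymptotic decider, exhaustive 33-case
tables) are out of scope.

**Iso-points.** An intersected edge between Pᵢ and Pⱼ gets its vertex at
Q = (C₀ − qᵢ)/(qⱼ − qᵢ), position Pᵢ + Q(Pⱼ − Pᵢ). (The obvious alternative
normalization by qⱼ − C₀ is not a valid interpolant — it divides by zero
when qⱼ = C₀ and misses the endpoint limit — so the standard form is used.)
Vertices are welded across cubes by exact (grid-edge) identity, no
coordinate tolerance. When Q lands exactly on 0 or 1 the iso-point *is* a
grid sample shared by several edges; bitwise-identical positions are merged
afterwards (still tolerance-free) and the collapsed zero-area triangles
dropped, which keeps tied-plateau surfaces closed.

**Normals.** Per-sample gradients are central differences
`(D[i+1] − D[i−1])/Δ` (one-sided at the grid boundary); the conventional
factor ½ is omitted deliberately since normals are normalized and the scale
cancels. Vertex normals interpolate the two corner gradients with the same
Q, are normalized, and negated so they point from high values to low —
outward for bright-inside data. Zero-gradient vertices (flat plateaus) fall
back to the average geometric normal of their incident triangles.

**Boundary handling.** If any boundary sample reaches the isovalue the
surface would be clipped; by default the volume is padded by one layer below
the isovalue (origin shifted accordingly), otherwise a warning is logged.

## Mesh metrics

Watertightness is an edge-incidence census over undirected vertex-index
pairs: closed ⇔ every edge borders exactly 2 triangles (boundary = 1,
non-manifold > 2 are reported separately). Euler characteristic is
V − E + F over referenced vertices (2 for sphere topology, 0 for a torus,
additive over components). Enclosed volume sums signed tetrahedra
v₀ · (v₁ × v₂)/6 against the origin and takes the absolute value (a flipped
winding is logged); it requires a watertight mesh. Translation invariance
is a tested property, not built into the formula.

## Mesh formats

Binary STL (80-byte fixed header, little-endian, per-facet normals from
winding; 80 + 4 + 50·n bytes), OBJ (1-based `v`/`vn`/`f`), ASCII PLY. All
writers are deterministic — no timestamps, fixed header text — so identical
meshes produce byte-identical files. STL holds unwelded triangle soup;
reading re-welds bitwise-identical positions so metrics survive a round
trip. ASCII STL and DICOM are out of scope.

## Phantoms: what they emulate and what they don't

`phantom` samples exact signed-distance fields (sphere, torus; the spline
tube uses 1000 dense centerline samples, an approximation adequate for a
phantom) and renders 8-bit slices at three hard intensity levels:
background 0, fiducial rods 100, solid interior 255, no antialiasing.
Rationale: the solid's level midpoint (127.5) equals the default
reconstruction isovalue, making linear edge crossings unbiased, and one
intensity window cleanly separates rods/solid/background even under σ = 5
noise. Jitter is applied by resampling the rendered slice (so disks
transform properly); Gaussian noise is added last and clipped to [0, 255];
geometry and the recorded truth (per-slice transforms, stamped rod centers)
stay exact. Identical spec + seed gives bit-identical output.

The phantoms emulate slice geometry, acquisition jitter, sensor noise, and
fiducial rods. They do **not** emulate tissue texture, color, partial-volume
blur, obscure boundaries, or segmentation error — so passing tests show the
*geometric* pipeline is correct, not that segmentation of real anatomical
photographs is easy (it is assumed given, as manual input).

## Default parameters

| parameter | default | why |
|---|---|---|
| pixel size | 0.33 mm | serial anatomical photograph geometry |
| slice spacing | 1.0 mm | typical cryosection interval |
| isovalue (8-bit) | 127.5 | midpoint of 0/255 render levels |
| isovalue (distance fields) | 0 | the surface by definition |
| fiducial window | (90, 110) | rod level 100 ± noise |
| mask window | [128, 255] | solid level, excludes rods and background |
| fiducial min component | 4 px | rejects noise specks |
| auto-pad | on | keeps boundary-touching surfaces closed |

Problem sizes used in the tests and examples — 32³ fields at 1 mm,
96×96×20–26 stacks at 0.33 mm/1 mm, convergence up to ~59³ at 0.5 mm — are
the package's chosen demonstration scales; the kernel is pure Python/NumPy
over active cubes and handles larger grids proportionally.

## Design choices that were genuinely open

- The registration equation is written with 3×3 matrices on 3-vectors;
  slices are 2D, so T is a 2D affine in homogeneous coordinates — the
  natural reading for cross-section alignment, and what three rods exactly
  determine.
- Whether inter-slice interpolation acts on intensities or shapes is not
  dictated by the workflow; both are provided, shape-based is the default
  for masks (see above).
- Bilinear rather than bicubic resampling: monotone, no overshoot at mask
  edges, and the range-clamp argument above only holds for monotone kernels.
- Masks are written as PNG even though segmentation tools often save JPEG;
  lossy masks are incorrect, but JPEG ingestion is supported with the ≥ 128
  rule for fidelity to existing datasets.
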