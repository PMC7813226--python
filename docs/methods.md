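# Methods

This note records the models and procedures `voxseg` implements, the
defaults and why they were chosen, what the synthetic phantom does and does
not emulate, and the numerical conventions that make results deterministic.

## Volumes and normalization

A volume is a `(nz, ny, nx)` grid of unsigned 8- or 16-bit samples with a
voxel size in µm; axis order is fixed to `(z, y, x)`, 0-based, slice-major
(`x` fastest in raw payloads), which matches slice-stack acquisition and
removes any axis ambiguity.  Raw volumes travel with a plain-text JSON
sidecar declaring dims, bit depth, endianness (default little), voxel size
and payload file; the declared byte count is checked on read.  Only
unsigned 8/16-bit samples are accepted — float or RGB slices are rejected
rather than silently converted.

All analysis operators work on the normalized volume
`v = raw / (2^bit_depth − 1) ∈ [0, 1]`.  Normalization is strictly
monotone, so thresholds expressed in the unit interval are
bit-depth-independent.

## Gradient thresholding

Three per-voxel gradient measures are defined on the normalized volume,
each clamped to [0, 1]:

| type | definition | neighbourhood |
|------|-----------|---------------|
| 1 | `‖(gx, gy, gz)‖₂`, `gx = (v[x+1] − v[x−1])/2`, … | 6 face neighbours |
| 2 | `|v_c − S/10|`, `S` = box sum minus centre (26 values) | 3×3×3 |
| 3 | `|v_c − S/70|`, `S` = box sum minus centre (124 values) | 5×5×5 |

The divisors 10 and 70 are fixed constants of the operators (they are not
the neighbour counts, so the measures do not vanish on constant input).
This makes types 2 and 3 deliberately *value-shifted*: on a constant volume
of value `v` they evaluate to `clamp(1.6·v)` and `clamp((124/70 − 1)·v)`,
so bright phases carry larger measure values than dark ones at equal local
contrast.  Type 1 is a pure edge detector (zero on constants) and suits
clean, few-phase data; types 2/3 are the practical choice for noisy
multi-phase material because the value shift separates phases *and*
boundaries in the joint (value, gradient) histogram.

Conventions:

* **Border handling** is replicate padding for all three types, so a
  constant volume yields an exactly constant field and the analytic
  constant-volume values above hold at every voxel including corners.
* **Selection** (multiple-thresholding) is the conjunction of a closed
  value interval and, optionally, a closed gradient interval for one
  operator type.  Closed intervals include ties, matching
  histogram-bracketing practice, and widening either interval can never
  deselect a voxel.
* Every vectorized field has a per-voxel loop twin
  (`gradient_volume_oracle`) with the identical contract; the test suite
  holds them equal to 1e−9 on random volumes.

## Morphology

Binary dilation and erosion use the radius-1 structuring element at
connectivity 6 (faces), 18 (+edges) or 26 (+corners); `n` iterations equal
`n` composed applications.  The default is 6 — the most conservative
boundary growth — and the connectivity is always an explicit parameter.
Voxels outside the volume count as unset for both operations (no
wrap-around, no mirror), which is deterministic and matches
"no object beyond the scan" semantics; the price is that
dilation/erosion duality, and the closing-⊇-identity property, hold exactly
only for masks at least one voxel away from the border.  Per-tag morphology
processes tags in ascending order; where dilated tags would collide, the
smaller tag id wins (a deterministic tie-break).

## Painting, components, extraction

The brush is a Euclidean sphere in voxel units (anisotropy is ignored at
paint time; a world-unit brush via the voxel size would be a
straightforward extension).  Stroke polylines are resampled at
`max(0.5·radius, 0.5)` voxel spacing between centres, which bounds
inter-stamp gaps at half a radius so the swept tube is simply connected;
the half-voxel floor keeps point brushes (radius 0) continuous along a
drawn line.  Painting writes the stroke's tag over any prior tag
(last-write-wins, so stroke order matters only where footprints overlap);
erasing clears only the stroke's *own* tag, protecting multi-structure
labelings.  An optional restriction mask confines all writes to a
threshold selection — the scripted analogue of painting only on
thresholded material.

Region growing returns the connected component of a mask containing a seed
(connectivity 6 by default, 26 optional).  Component labels are assigned
1..K in first-encounter raster `(z, y, x)` order, so labelings are
reproducible across runs.  Tag extraction crops to the tag's tight
bounding box, keeps original scan values on tagged voxels and fills the
rest with a pad value; bit depth and voxel size are inherited.

## Seeded segmentation

**Graph cut.**  The binary labeling minimizes

    E(L) = Σ_p D(p, L_p) + λ Σ_{(p,q)} exp(−(v_p − v_q)²/2σ²)·[L_p ≠ L_q]

with `D(p, fg) = −log P_fg(v_p)` and `D(p, bg) = −log P_bg(v_p)` estimated
from 32-bin histograms of the foreground/background seed intensities
(probability floor 1e−6), hard seeds (infinite capacity t-links), and
adjacency 6 or 26.  The optimum is exact: the energy is submodular and is
solved by max-flow/min-cut.  The foreground is taken as the set of nodes
reachable from the source in the residual graph — the *minimal* source
side among all minimum cuts — which resolves exact ties toward background;
the suite verifies optimality by exhaustive enumeration on instances up to
16 voxels.  Defaults λ = 1.0, σ = 0.1 (in normalized intensity units):
σ of about the inter-phase contrast divided by a few keeps the boundary
term selective, and λ ≈ 1 balances it against log-likelihoods of a few
nats.  The flow network holds every voxel, so the operator is intended for
cropped regions of interest rather than whole scans.

**Livewire.**  A minimal-cost 8-connected path between two pixels of one
slice, by Dijkstra search.  The cost of entering pixel `q` is
`(w_g·(1 − G(q)) + w_u) · step` with `step` 1 for axial and √2 for
diagonal moves; `G` is the slice's central-difference gradient magnitude
normalized by its maximum (identically zero on a constant slice).
Defaults `w_g = 1.0`, `w_u = 0.1`: the uniform term keeps costs strictly
positive (shortest paths well-defined) while the gradient term dominates,
so paths hug strong edges.  On cost ties the lexicographically smallest
predecessor is kept, making the returned path deterministic.  The
operator is strictly 2D per slice; stitching 3D curves from slice paths is
out of scope.

**Contour interpolation.**  Intermediate masks between two planar contours
come from blending signed Euclidean distance fields (negative inside):
`mask_t = {(1−t)·d_a + t·d_b ≤ 0}` at `t = k/(n+1)`.  Identical endpoints
reproduce themselves exactly, and swapping the endpoints while reversing
`t` yields the same sequence.  Because interpolation *infers* geometry
between measured slices it is not reproducible across operators, and every
call logs a warning to that effect; it is a convenience for sparse
tracing, not a measurement.

## Meshing and simplification

Isosurfaces are extracted by marching cubes at iso 0.5 on the binarized
0/1 field, after a one-voxel zero pad so masks touching the volume border
still produce closed surfaces; vertices are scaled to µm by the voxel
size.  The result is watertight (every edge shared by exactly two faces)
with Euler characteristic 2 for genus-0 objects.

The "smoothing factor" counts Taubin shrink/inflate passes (λ = 0.5,
µ = −0.53).  Unlike plain Laplacian averaging, the alternating signs keep
the enclosed volume nearly constant (< 2 % change at factor 2 on a
radius-10 ball), which matters for thin laminae.  "X % decimation" removes
X percent of the triangles by quadric edge collapse: per-vertex quadrics
accumulate face-plane outer products, collapses are ordered by a lazy
min-heap of quadric errors with the optimal collapse point from solving
the 3×3 quadric system (falling back to the best of the endpoints and
midpoint when singular), and an edge is skipped when its endpoints share
more than two neighbouring vertices (the link condition that would
otherwise pinch the surface).  The face target `ceil(F·(1 − p/100))` is
reached within 1 % or to the minimum collapsible count.  The recommended
setting — smoothing factor 2 with 50 % decimation — halves the triangle
count while keeping the enclosed volume of the test ball within 5 % of the
unsimplified mesh (measured: well under 1 %).

Exports: binary STL (80-byte header + 50-byte triangle records; a cube is
exactly 684 bytes), ascii PLY and ascii OBJ.  PLY/OBJ round-trip the
vertex/face lists; STL stores a triangle soup, re-merged on load.

## Synthetic phantom

`generate_phantom` paints ordered geometric phases (ellipsoid, spherical
shell with optional cap restriction, box) into a unit-scale field over a
constant background, records the last phase id per voxel as ground truth,
then applies Gaussian blur (the partial-volume stand-in), additive
Gaussian noise from a single seeded PRNG stream, clipping and
quantization.  Blur precedes noise, mirroring the physical order of
partial-volume averaging in reconstruction followed by detector noise.
Gaussian (not Poisson) noise keeps the model one-parameter; it is adequate
for exercising operators, though real CT noise is signal-dependent.

`preset_fossil_cheek` emulates a cropped specimen-in-matrix scan: 16-bit,
21 µm voxels, matrix at intensity 0.15, a curved shell plate at 0.85 (a
spherical-shell segment whose centre lies outside the volume), and two
0.55-intensity ellipsoids attached to the shell's inner surface; blur
σ = 0.7 voxels, noise σ = 0.02 of full scale.  The shell thickness is
0.34·min(dims) (~22 voxels at 64³), set by partial-volume arithmetic: with
blur σ = 0.7 the 0.15→0.85 edge profile crosses the 0.75 threshold about
0.75 voxels inside the shell on each face, and the plate must be thick
enough that this erosion, plus curvature and attachment interfaces, still
leaves a Dice overlap ≥ 0.95 between the thresholded mask and the shell
ground truth.  With blur and noise switched off the recovery is exact
(Dice = 1) because quantized phase codes fall on distinct sides of any
bracketing threshold.

What the phantom does *not* emulate: beam hardening, ring and streak
artifacts, reconstruction filters, intensity inhomogeneity across the
field of view, signal-dependent noise, and textured/porous phases.
Passing tests therefore demonstrate operator correctness and pipeline
determinism, not segmentation quality on artifact-laden scans.

## Problem sizes and determinism

The test suite and acceptance script run at desk scale, chosen to keep the
checks exhaustive rather than sampled: oracle equivalences on volumes up
to 8³ and masks up to 6³, graph-cut optimality by full enumeration on
instances of at most 16 voxels (2¹⁶ labelings), livewire against Dijkstra
on slices up to 10×10, phantom recovery at 64³, meshing on a radius-10
ball.  All randomness flows through seeded `numpy` generators; phantom
sidecars record the seed, and the CLI writes a manifest (input hashes,
parameters, version) next to every output.  Identical inputs and seed
reproduce every volume, mask and tag byte-exactly.

## Known limitations

* No DICOM/NIfTI/NetCDF containers, no out-of-core volumes; everything is
  in-memory.
* Import of the binary `.pvl.nc` processed-volume container is not
  attempted; the raw + JSON sidecar is the interchange format.
* Graph cut memory scales with the voxel count of the (cropped) input.
* The brush ignores voxel anisotropy; strokes are spheres in index space.
* Livewire is per-slice 2D; contour interpolation is a geometric inference
  and flagged as such.
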