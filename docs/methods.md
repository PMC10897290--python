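# Methods

This note documents the models, conventions and numerical choices behind
cristoscope, and what its phantom-based validation does and does not show
about real tomograms.

## Coordinate and contrast conventions

Volumes use 0-based voxel indices in (z, y, x) order with the beam along z
and the tilt axis along y; all metric quantities are in nanometres (volumes
in µm³).  Membranes are rendered *dark* (low intensity), matching cryo-ET
contrast; every template and profile downstream uses the same sign.  The
working pixel size of the width-measurement frame is 2.2 nm/px, the grid on
which the template bank's 2.2–88 nm separation range is defined, and the
default subvolume box is 48 voxels (105.6 nm edge).

## Phantom model

A phantom mitochondrion is four nested ellipsoids sharing a centre: the
outer membrane (OMM) between semi-axes *a* and *a − t*, the intermembrane
space of width *g* (default 10 nm), the inner boundary membrane (IBM)
between *a − t − g* and *a − 2t − g*, and the matrix inside.  Membrane
thickness *t* defaults to 5 nm (a bilayer).  Nesting by semi-axis
subtraction makes every shell volume an exact closed form
(4/3·π·product of semi-axes differences), which is what the voxel-count
volume oracle is checked against; the price is a slightly
direction-dependent membrane thickness on eccentric ellipsoids, which
nothing downstream measures.

Cristae are carved out of the matrix from signed-distance primitives whose
zero level is the **membrane mid-surface**: slab (lamellar,
straight-across), capsule (tubular), sphere (globular), torus (ring),
capped half-torus (loop) and a three-capsule Y (split).  A crista's
`width_nm` is therefore the membrane **centre-to-centre** distance — the
trough-to-trough distance of the density profile across the crista, which
is exactly what the template bank indexes — and the lumen clearance is
`width_nm − t`.  Cristae with declared junctions may reach the IBM and are
clipped there (the junction is where the crista membrane meets the IBM);
junction-free cristae that poke out of the matrix raise a geometry error.

Rendering order is: hard label assignment → Gaussian smoothing (σ = 1 voxel
by default, to avoid aliasing in cross-correlation) → additive Gaussian
noise → missing wedge.  The wedge is applied last, as corruption enters a
real reconstruction.  Noise level can be set from a target SNR defined as
signal variance over noise variance of the noiseless rendered volume.  One
integer seed drives a named generator; identical spec + seed is
bit-identical.

The missing wedge zeroes Fourier components within the half-angle of the
beam axis in the (k<sub>x</sub>, k<sub>z</sub>) plane, invariant along the
tilt axis — exactly the double cone a ±70° tilt series (20° half-angle)
never samples.  The operation is an orthogonal projection (idempotent), and
the k<sub>z</sub> = 0 plane, including the mean, is always kept.  A practical
consequence reproduced faithfully: membrane pairs whose normal lies along
the beam axis are erased by the wedge, so width-study phantoms plant cristae
with in-plane normals, as real averaging implicitly selects for.

## Width estimation

Template *k* holds two parallel membrane slabs (same thickness and
smoothing as the phantom membranes, rendered analytically with erf edges so
the density troughs sit exactly at the membrane centres) separated by *k*
pixels, centred in the box, normals along z, normalized to zero mean under
a soft spherical mask (raised-cosine edge, radius 0.45 × box).  Because a
template varies only along z, the masked normalized cross-correlation
against a particle over axial shifts collapses to a 1-D weighted Pearson
correlation after summing the masked particle over (x, y); shifted templates
are re-rendered from the analytic profile, so there is no wrap-around.  The
reported width is the separation of the argmax template with no
sub-template interpolation; ties break toward the smaller separation.  An
optional orientation refinement tilts the particle over a coarse 15° grid
on a hemisphere cap (two-membrane templates have 2-fold symmetry) with 3°
local refinement; the default pipeline instead orients particles by their
known membrane normals, and per-particle width is measured in that frame.

Separations below roughly the membrane thickness produce templates whose
two slabs merge into a single density blob; they remain distinct as
correlation targets (this is the collapsed-lumen regime that zipped and
pinched cristae occupy) but have no resolvable trough pair, so the
trough-distance oracle applies only from ~5 px up.

Alignment/averaging uses integer-grid translation search (FFT
cross-correlation under the soft mask, default bound 4 px) against a
reference initialized from a seeded random quarter of the particles, for at
most 12 iterations or until no shift changes by ≥ 0.5 px.  The shift set is
re-centred to zero mean each iteration: translations are a gauge freedom,
and fixing it keeps the reference centred and makes planted zero-mean
shifts exactly recoverable.  The mean per-iteration correlation is recorded
and non-decreasing in practice; rotational search is deliberately not part
of the averaging step (particles arrive pre-oriented), which keeps the
12-iteration budget cheap.

## 2-D morphometry

Outline areas use the shoelace formula on picked polygon vertices
(self-intersecting outlines are rejected), scaled by pixel size into µm²;
coverage divides by the field area.  Matrix gray density follows a
three-probe protocol: the projection image is first contrast-normalized by
a saturated linear stretch (0.35% total saturation, split between tails) —
interpreted as linear rather than rank equalization because the resulting
mean gray values are used as a comparable density scale, which
rank-equalization would destroy — then three line probes are sampled
bilinearly at half-pixel steps and their means averaged.  Junction width is
the Euclidean distance between the two picked membrane points; junction
angle is the interior angle between a ray along the local IBM and a ray
along the crista axis, so a perpendicular crista scores 90°.  Junctions
visible in several non-overlapping sections contribute one measurement per
section, averaged per junction.  Junction localisation is an input (ground
truth or interactive picks), not auto-detected: automating it would be a
new method, not a re-implementation of the measurement.

## 3-D morphometry and classification

Compartment volumes are voxel counts times voxel volume; the total is the
exact sum of matrix + IMS + cristae lumen by construction, and ratios refuse
a zero total.  Crista centrelines come from 3-D thinning of the solid
(membrane + lumen) component.  Two implementation details matter:

* skimage's Lee thinning deletes objects that are mirror-symmetric about an
  inter-voxel plane (even-parity cross-sections thin to nothing); the
  skeletonizer therefore also thins a parity-flipped copy (2×2×2 dilation)
  and keeps the richer skeleton;
* thinning erodes component ends by about their half-thickness, so the
  centreline (after moving-average smoothing to remove lattice zig-zag) is
  extended along its end tangents to the component boundary before length
  is measured.  On rod-like phantoms this recovers planted lengths within
  a few percent.  For genuinely sheet-like (lamellar) cristae the thinned
  "centreline" is not a meaningful length axis; the pipeline reports the
  longest principal extent for such components instead.

Ring topology is read from the solid itself via the Euler characteristic
(a closed tube is genus-1, χ = 0) rather than from cycles in the lattice
skeleton graph, which are full of incidental triangles.

The shape classifier is an explicit decision cascade standing in for what
was originally a visual taxonomy; all thresholds live in `ShapeConfig` and
were chosen once so that canonical geometric exemplars classify
unambiguously:

1. **ring** — ring topology and no junctions;
2. **loop** — two junctions and curved centreline
   (end-to-end / arc length < 0.8);
3. **straight_across** — two junctions and near-straight centreline
   (ratio ≥ 0.95);
4. **split** — a curve-like skeleton (skeleton voxels ≤ 2.5 × main-path
   voxels — branch counting on the medial surface of a sheet is
   meaningless) with a branch arm ≥ 15 nm off the main path;
5. **zipped** — a contiguous stretch ≥ 20 nm of the lumen-width profile at
   or below the resolvable floor (2.2 nm, one template step); the profile
   is evaluated on the pre-extension centreline so end caps do not read as
   collapse;
6. **pinched** — shorter, isolated collapsed stretches;
7. **vesicular** — ≥ 5% of interior lumen voxels darker than halfway from
   solvent to membrane density (enclosed membranous material);
8. canonical geometry by principal extents: **lamellar** if the two largest
   extents are each ≥ 3× the smallest, **tubular** if the largest is ≥ 3×
   the second and the cross-section is round (second/third < 1.5),
   **globular** if max/min < 2; otherwise **unusual/amorphous**.

Directionality is straight when all junction angles are within 90° ± 20°,
tilted otherwise, and "no attachment observed" when no junction was
captured.  Multijunction cristae (≥ 2 junctions) are straight or loop by
the same straightness ratio.  Stacking is three or more lamellar cristae
with pairwise sheet-normal angles ≤ 15° whose convex-hull footprints,
projected along the common normal, mutually overlap by ≥ 50% of the smaller
footprint.  Mitochondrial outlines are partial if they touch the field
boundary, else round/ellipsoidal/polygon by fitted-ellipse aspect (cut
1.3) and solidity (cut 0.95).

## Statistics policy

Each group is compared to a designated reference with a two-sided
Mann–Whitney U test unless *both* samples pass Shapiro–Wilk at α = 0.05, in
which case Welch's unequal-variance t is used.  The exact Mann–Whitney
branch enumerates all C(n₁+n₂, n₁) relabelings of the pooled midranks —
valid under ties, and reproducing textbook cases such as p = 0.1 for
{1,2,3} vs {4,5,6} — whenever both samples have ≤ 8 observations; larger
samples use the tie- and continuity-corrected normal approximation (the
branch used is recorded on every result).  Pairwise tests are uncorrected
by default, matching the reporting convention they mirror; a Holm
adjustment is available behind a flag.  No outlier removal is performed by
default.

## Validation scale and scope

Tests and drivers run phantoms of 80³–160³ voxels with 15–100 particles per
condition and seven planted width levels (3–30 px) at SNR 0.5 under a 20°
wedge — sizes chosen so the whole suite validates every stage in minutes on
one core.  What passing shows: the estimator is unbiased to within one
template step under noise and wedge at these SNRs, alignment recovers exact
planted shifts, volumes and lengths agree with closed forms, the classifier
separates canonical geometric exemplars perfectly, and the statistics
policy has correct size.  What it does not show: performance on real
membranes with protein decoration, segmentation errors, lamella compression
or denoising artefacts; the phantom suite has no model of any of these, and
classifier thresholds tuned for clean exemplars will not reproduce
visual-inspection frequencies on experimental data.  The phantom SNR is a
free parameter, not calibrated to any instrument.
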