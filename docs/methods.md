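# Methods

This note documents the models, conventions and numerical choices behind
`retinaquant`: what the synthetic phantoms emulate, how each measurement
is defined, which parameters matter, and what the passing tests do and
do not demonstrate about real microscope data.

## Coordinate and data conventions

All computation happens in physical micrometres with a fixed
`(t?, c?, z, y, x)` axis order; voxel indices are 0-based and a voxel's
physical coordinate is `index × spacing`. The vitreous side is +z.
TIFF/OME-TIFF carry the spacing in metadata; plain TIFFs fall back to a
configured spacing (1 µm with a logged warning otherwise). Track CSVs
use `track_id,frame,x_um,y_um,z_um`; the ImageJ Manual Tracking dialect
(pixel coordinates, `Track n°`/`Slice n°` headers) is converted with a
supplied pixel size.

## Synthetic phantoms (synthgen)

The generator produces the geometric and statistical structure the
measurements assume, with exhaustive ground truth; it makes no attempt
at optical realism (no anisotropic PSF, scattering or photobleaching).
Rendering is mask-first: objects are rasterized into boolean voxel
masks, blurred with a Gaussian (default σ 0.7 µm per axis; 0.5 µm for
the nuclei channel), and additive Gaussian noise (σ 0.02) plus a
constant background (0.05) are applied. This is the simplest model that
makes thresholding non-trivial while keeping the 0.5-level of the
blurred mask at the true object surface, which is what makes subvoxel
chord localization meaningful. All randomness flows from one
`numpy.random.default_rng(seed)`; identical (spec, seed) pairs are
byte-identical.

**Surface.** The retinal cup is a spherical cap of radius 1700 µm
(mouse-eye order of magnitude), so a ~100 µm field tilts by only a few
degrees across its extent; a flat plane is available for already-flat
phantoms. Signed height above the cap is the exact signed distance to
the sphere.

**Vessels** are tubes of circular cross-section around polyline
centrelines (distance-to-polyline rasterization). Radii below twice the
coarsest voxel pitch are rejected as unresolvable. The plexus preset is
a rectilinear capillary grid (pitch 22 µm, radius 2.5 µm) draped on the
surface — enough centreline material for local plane fits, which is the
property the real plexus provides.

**Flat-mount distortion** maps the curved surface to a flat plane
(optional "unbend") and scales the along-normal axis by a compression
factor in (0, 1], by inverse-mapping voxel coordinates with linear
interpolation. Ground truth transforms consistently: expected depth
scales by the factor, expected width is untouched, control points and
masks are warped, and repeated application composes multiplicatively.
The study default of 0.4 produces the qualitative effect seen when
comparing flat-mounted confocal stacks with suspended-tissue imaging:
markedly elliptical cross-sections.

**Tufts** are bodies protruding above the plexus, assembled from three
parts. The body encodes the requested topology: an ellipsoid (no
tunnel), a solid torus (one tunnel), or two overlapping tori (two
tunnels), each with the requested vertical extent (the body occupies
heights 12 µm → `protrusion_height` above the surface) and scaled —
tori by stretching along the ring axis — toward the target volume while
the tunnel radius stays ≥ 3.5 µm so blurring cannot close it.
`n_connections` vertical stalk tubes (radius 2 µm) connect the body to
the plexus at well-separated footprint positions (greedy
farthest-point, ≥ 7 µm apart so their centrelines remain distinct
skeleton edges). Nuclei are rendered into a separate channel: flat
nuclei as straight capsules (9 µm × 3.2 µm), curved nuclei as C-shaped
tubes following a circular arc (14 µm of centreline turning 170° in
total) — the dramatically bent morphology that motivates the curvature
metric. Placement is rejection sampling inside the eroded body with a
≥ 2.5 µm surface gap between nuclei so rendered blobs stay separable;
orientations are biased along the local body axis (PCA of the nearby
interior), as real endothelial nuclei align with their vessel. Ground
truth records the realized body volume (voxel count), every nucleus
centreline and curved flag, and the stalk/tunnel counts.

**Tuft population.** Class structure follows the observed cohort
statistics: many small (2–3 nuclei) and medium (4–20) tufts, few large
(>20); volume rises roughly linearly with nuclei up to ~10, plateaus
within the medium class, and jumps ~3-fold past the 20-nuclei boundary
while connections jump ~2.5-fold; curved nuclei are about half the
nuclei in small/medium tufts and a roughly constant count (~8) in large
ones. Absolute volumes are not published for these cohorts, so the
scale (small ≈ 6×10³, medium plateau ≈ 3.3×10⁴, large ≈ 1×10⁵ µm³) is
this package's choice, with 12% lognormal scatter and a feasibility
floor (≥ 1700–2000 µm³ per nucleus) so every sampled tuft can host its
nuclei. The cohort R² values the pipeline reports are therefore
emergent, not calibrated.

**Time lapses** are fully scripted: each filopodium is a base point,
direction and per-frame length series; each actin bundle a per-frame
position series. The generator emits the rendered 4D stack (optional),
the exact track CSV, and ground-truth kinematics computed from the
scripts in closed form. Cohort presets encode the live-imaging
conditions: P5 n=67 filopodia with max lengths around 14.84 µm, OIR
n=23 around 4.3 µm (20% relative SD, triangular grow–dwell–retract
profiles at ~2 µm/min), and 18 bundles doing constant-speed random
walks with speeds around 2.56 µm/min over 7–40 min. Frame interval is
constant by contract (default 1 min).

**Layered volumes** place `round(density × area)` spherical nuclei
(radius 2.5 µm) uniformly over the footprint at uniform depth within a
curved slab of the requested thickness, so the ground-truth areal
density is exact; a flag is raised when placements touch.

## Measurements

**Segmentation** is Otsu or a fixed threshold with
minimum-component-size cleanup. On the synthetic volumes the studies
use the fixed 0.5 threshold, which sits at the true surface of a
blurred binary object; Otsu is the default for data whose intensity
scale is unknown.

**Skeleton graph.** `skimage.morphology.skeletonize` (3D thinning)
followed by conversion to a junction/edge multigraph: voxels with ≠ 2
skeleton neighbours (26-connectivity) become nodes, degree-2 chains
become edge polylines with spacing-aware lengths; free-tip spurs
shorter than 4 µm (thinning artefacts at junctions) are pruned. Pure
cycles get an arbitrary anchor node and a self-loop edge.

**Plexus plane.** The local tangent plane at a site is fitted to all
skeleton points within `fit_radius` (default 30 µm): anchor at their
centroid, normal along the least-variance principal direction, oriented
toward the vitreous-side reference (+z by default), with the RMS
out-of-plane residual reported. At least 10 points are required;
off-plexus structures (tufts) can be excluded by mask. On the 1700 µm
cap the fitted normal lands within 3° of the analytic sphere normal.

**Diameters.** Depth is the chord of the vessel through the site along
the plane normal; width is the chord along `normal × axis` — the unique
in-plane direction perpendicular to the local vessel axis (taken from
the nearest skeleton edge over an 8 µm window). Chords are found by
bidirectional ray casting with linear interpolation and subvoxel
localization of the 0.5-level crossing; passing the pre-threshold
intensity as the chord image keeps genuinely subvoxel edges. A maximal
in-plane chord variant (`width_mode="max_inplane"`) covers the
alternative reading of an XY measurement; the perpendicular chord is
the default. Sites whose vessel axis lies within 15° of the normal are
rejected (width direction ill-defined), as are measurement sites at
junctions in the study drivers — chords there run into the crossing
vessel, which is why the distortion study measures mid-segment, in a
corridor free of parallel plexus vessels.

**Group comparison** reports per-group mean width, depth and W/D, and
unpaired two-sample t-tests (Student by default — the common Prism
default when a test is reported only as "unpaired t-test" — with Welch
available) on depth and on the aspect ratio. Two constant equal groups
return p = 1 flagged degenerate rather than NaN.

**Tuft detection** labels 26-connected vessel voxels whose signed
height above the plexus model exceeds `min_height` (default 10 µm — the
generated plexus tubes reach ~5 µm above the surface, stalks cross the
threshold, bodies start at 12 µm), filtered by a minimum volume.
Volume is voxel integration of the label (interior cavities are not
filled). Depth is the maximum signed height of label voxels — the
tuft's extent perpendicular to the plexus, since tufts are anchored at
the surface. Size classes on nuclei count: < 4 small, 4–20 medium,
> 20 large ("over 20" ⇒ 21 is the first large count).

**Nuclei.** Blob detection is threshold + 26-connected components with
a volume filter, optionally restricted to a 3 µm dilation of one tuft
label. An optional watershed split (seeded at h-maxima of the distance
transform, h = 0.8 µm) divides round nuclei merged through a neck; it
is off by default because on strongly elongated or bent nuclei the EDT
ridge is shallow and the watershed over-splits. Each nucleus's
principal curve is its skeleton's longest geodesic, lightly smoothed
(3-point moving average) and extended along the end tangents to the
mask boundary (the medial skeleton stops ~1 radius short of the tips);
from it come arc length, end-to-end chord, and the maximum turning
angle between 3 µm secants. A nucleus is *curved* iff arc/chord > 1.2
or the turning angle exceeds 60° — this operationalizes a judgement the
original workflow made visually, and the thresholds are the package's
own: the straight-capsule phantom measures arc/chord ≈ 1.01, the
C-shaped phantom ≈ 1.4, so the 1.2 boundary separates them with ≥ 95%
per-nucleus agreement in the end-to-end study. Sub-voxel (degenerate)
nuclei are flat by definition, flagged.

**Connections** are distinct skeleton edges crossing the
`min_height` iso-surface with their above-side inside the tuft label —
stalks are near-vertical there, so the count is stable to ±2 µm changes
of the threshold. A detached tuft yields 0 with a warning.

**Topology.** Tunnels through a tuft are the first Betti number,
b1 = b0 + b2 − χ, under the fixed 26-connectivity-foreground /
6-connectivity-background convention (stated explicitly because Betti
numbers depend on it): b0 from 26-connected foreground components, b2
from enclosed 6-connected background cavities after padding, χ from the
voxel complex (`skimage.measure.euler_number`, connectivity 3). Masks
touching the volume border are rejected ("pad required") since cavity
counting needs a closed exterior. The test suite checks this against an
independent brute-force oracle that counts vertices/edges/faces/cubes
of the union of closed unit cubes; the two conventions coincide on the
fat, smooth phantoms used (balls, tori, smoothed random blobs) — on
single-voxel-thin or pinched structures they can differ, which is why
the phantoms are kept fat.

**Regressions and fold changes.** Ordinary least squares with
intercept (`scipy.stats.linregress`), R² = 1 − SS_res/SS_tot (defined
as 0 for a constant response). The class fold change is
mean(large)/mean(medium) across the 20-nuclei boundary.

**Polarity.** Each nucleus centroid pairs with its nearest Golgi
centroid (Euclidean, unconstrained — one Golgi may serve several
nuclei, matching a per-cell nearest-body rule); the vector's angle to a
reference direction is reported in [0°, 180°].

**Filopodium kinematics.** Length(t) is the Euclidean tip→base
distance (base = supplied anchor or the first tracked tip position —
manual tracks record the tip only). A filopodium is alive while length
> ε (default 0.5 µm); lifetime spans the half-open interval from first
alive frame to first subsequent dead frame, right-censored at the end
of the recording (the disappearance frame is excluded — the verbal
"appeared and then disappeared" rule fixes endpoints but not this
convention, so it is fixed here). Max length is over the alive
interval. Extension/retraction speeds are means of the
positive/negative per-frame length rates (maximum-rate variants are
also exposed); monotone growth reports retraction 0 with a flag.
Bundle statistics: path length = Σ‖Δposition‖ ≥ net displacement,
duration = (n−1)Δt, average speed = path/duration, plus the cumulative
distance curve. Halving Δt exactly doubles all speeds.

**ONL metrics.** Density: threshold the nuclear channel inside a
polygonal ROI (Otsu per ROI by default), count particles ≥ 4 µm²,
divide by polygon area. Two modes: per-slice 2D (the manual procedure)
and a column mode that carries the ROI footprint through the stack and
counts 3D-connected nuclei — used for the slab phantom, where the
ground truth is a column (areal) density and projection merging would
bias a 2D count low; merged round nuclei are watershed-split.
Thickness: mean of three line measurements per sampled slice (stride
50 by default, mirroring a 50-slice z-increment; ~8 areas per
condition), either from supplied line lengths or from the z-extent of a
layer mask at three in-slice positions; a stride beyond the stack falls
back to a single mid-slice estimate with a warning.

## Study drivers and problem sizes

`studies.py` holds the end-to-end drivers shared by the `analysis/`
scripts, the CLI and the acceptance machinery. Problem sizes mirror the
measured datasets: 50 vessels (radii uniform 3–15 µm, one per ~80 µm
scene) for the distortion study, 30 tufts (one 120 µm scene each)
spanning all classes for the morphometrics study, the printed cohort
sizes (67/23 filopodia, 18 bundles) for kinematics, and one 128 µm
layered slab for the ONL study. Scenes are generated per object so a
failure is attributable and memory stays at desk scale.

## Known limitations

- Optical realism is out of scope; recovery rates on these phantoms
  bound what the pipeline can do when its assumptions hold, not its
  performance on real light-sheet data with scattering, anisotropic
  PSFs and staining variability.
- The curvature thresholds (1.2, 60°) were chosen against phantom
  geometry; on real nuclei the visual judgement they replace has no
  published quantitative anchor.
- The watershed nucleus splitter handles round blobs merged through a
  neck; heavily interpenetrating or bent-and-touching nuclei are not
  reliably separable and are avoided by construction in the generator.
- Betti-number equality between the implementation's 26/6 convention
  and the closed-cube oracle holds for fat, unpinched solids only.
- `read_source_table` locates spreadsheet columns heuristically (the
  deposited files' headers are not standardized); the per-figure
  mapping is configurable and must be confirmed against the actual
  files before benchmarking real source data.
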