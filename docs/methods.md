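# Methods

`magfiber` re-implements, as a reusable and tested pipeline, the
computational analyses used to characterize 3D hydrogel composites whose
embedded electrospun fiber segments are aligned by the field of two
permanent magnets: prediction of the magnetic flux density in the gelation
chamber, quantification of fiber-architecture anisotropy and geometry,
per-cell orientation and viability statistics, and the spheroid-outgrowth
migration analysis. Because no imaging data are deposited for these
experiments, every analysis is exercised end-to-end on synthetic scenes
with exact ground truth; this note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## Magnetostatics of the gelation chamber

The chamber holds two coaxial cylindrical N52 neodymium magnets (radius
R = 1.905 cm, length L = 3.81 cm) facing each other with opposite poles so
their fields aid in the gap; the hydrogel sits at the midpoint. Each magnet
is modeled as a uniformly magnetized cylinder — equivalently a solenoidal
surface current sheet K = Br/μ0 — in free space (μr = 1, open boundary).
On the axis, a distance z outside a face,

    B(z) = (Br/2) · [ (z+L)/√((z+L)² + R²) − z/√(z² + R²) ].

Datasheets print the *surface field* Bs = B(0); the remanence is recovered
by inverting that relation, Br = 2·Bs·√(L²+R²)/L. With the printed
Bs = 661.9 mT this gives Br ≈ 1.480 T, consistent with N52 material
(≈1.43–1.48 T). (Two slightly different surface-field figures circulate
for these magnets, 661.9 and 669.1 mT; the package standardizes on
661.9 mT, the value used for the calibration.) The pair field is the
superposition of the two single-magnet fields; off-axis values for the
flux-density slice are obtained by stacking circular current loops
(complete elliptic integrals, Gauss–Legendre quadrature along the length,
96 nodes). The closed form and the quadrature agree to better than 1e-6
relative on the axis — the quadrature is kept as an independent oracle,
not the production path.

An open-boundary model cannot reproduce midpoint values computed inside a
finite "air sphere" with truncating boundary conditions; our model gives
176 / 42 / 16 mT at 6 / 12 / 18 cm spacing where the finite-domain
reference gives 126.9 / 24.8 / 7.5 mT. The package therefore asserts the
physically meaningful properties instead: strict decrease of midpoint flux
with spacing, agreement within a factor of 2.5 of the reference values,
superposition and mirror symmetry to numerical precision, the dipole
far-field limit z³B → Br·R²·L/2 (z from the magnet center) to <1 %, and a
divergence-free slice field. Demagnetization, nonlinear B–H behavior and
forces on fibers are out of scope.

## Axial orientation statistics

Fiber axes, cell long axes and outgrowth directions are *axial* data
(θ ≡ θ+180°). All sampling and summaries use the angle-doubling
construction: φ = 2θ is treated as circular, concentration is the von
Mises κ of the doubled angles (κ = 0 isotropic), and the axial density is
∝ exp(κ·cos 2θ). Closed forms used as oracles throughout the tests:

* band mass P(|θ| ≤ w) by quadrature of the density;
* FWHM = arccos(1 − ln2/κ) in doubled-angle degrees, saturating at 180°
  when the density never falls to half its peak (κ ≤ ln2/2).

## Synthetic scenes

The generator is first-class, tested code; its defaults are the study
conditions the analyses are validated under.

**Coordinates.** 0-based pixels, origin top-left, x = column,
y = row (downward); angles in degrees from +x toward +y; exported
distances/areas in μm/μm². Default pixel size 0.5 μm/px (a 2 μm fiber is
4 px wide — resolvable); spheroid scenes use 1 μm/px.

**Rendering.** Objects are capsules (rods, spindle cells), ellipses
(spheroid bodies, single cells) and disks (nuclei), drawn with 4×4
supersampled coverage fractions and max-composited, then blurred with a
Gaussian PSF (σ 0.8–1 px) and overlaid with additive Gaussian background
noise (σ = 0.04–0.05 of object intensity). Poisson noise and optical
sectioning are deliberately omitted; the noise level is chosen to make
segmentation non-trivial, not to mimic any specific detector, since no
intensity statistics are available for the original images. The noise-free
support of a scene is exactly the union of the per-object supports, so the
truth tables fully determine the rasterized geometry (tested pixelwise).

**Fiber fields.** ~2 μm diameter rods (5 % lognormal diameter jitter) with
lengths from either a *photomasked* model — truncated normal,
means 60–120 μm, sd = 15 % of the mean — or the *unmasked* model — a
lognormal truncated to [100, 550] μm whose log-location is solved
numerically so the truncated mean equals 225 μm (log-sd 0.45, a broad
spread chosen to reflect the much larger variance of unmasked segments).
Axial orientations follow the von Mises law about a mean axis. Placement
is either independent (overlaps allowed, as in a dense gel) or
non-overlapping by rejection sampling on exact capsule–capsule distances
("spread", used for per-fiber length/width calibration scenes where each
fiber must remain an individual connected component).

**Tenocyte scenes.** Non-overlapping spindle (capsule) cells, default
width 12 μm, tip-to-tip length = aspect ratio × width; aspect ratio 1
renders round cells whose orientation is undefined (flagged isotropic in
truth). Packing failure raises an error naming the attempted density.

**Viability scenes.** Hoechst/PI channel pairs; exactly
round(n·dead_fraction) nuclei (banker's rounding) carry PI signal; nucleus
centers keep ≥2.1 radii spacing so the truth count is recoverable.

**Spheroid scenes.** An elliptical body (semi-axes ~55–90 px) densely
populated with nuclei (overlap allowed, as in a projection of a 3D body),
plus outgrowths of three classes: contiguous strands (14 μm wide capsules
starting inside the body boundary), disconnected multicellular clusters
(wider capsules at a positive clearance from the body), and disconnected
single cells (small ellipses). Outgrowth nuclei are placed along the path
with ≥1 diameter spacing so counts are recoverable; per-nucleus
distance-to-boundary, per-outgrowth area and maximum depth are recorded
exactly. Scene randomization draws outgrowth directions from the axial von
Mises law about the alignment axis with random polarity; a minimum angular
separation (default 15°) keeps distinct outgrowths resolvable. At high
concentration this repulsion measurably flattens the realized direction
law, so directional-bias studies draw with the separation disabled —
occasional merged outgrowths leave the rose-plot fraction essentially
unbiased because near-axis losses hit numerator and denominator alike.

## Fiber-architecture metrics

**Anisotropy score.** The local fiber axis at a pixel is perpendicular to
the intensity gradient (central differences after σ = 1 px pre-smoothing).
Axes are averaged as nematic tensors weighted by gradient energy |∇I|²
(the structure-tensor mean) over pixels whose gradient magnitude exceeds
2 % of the image maximum; the score A = λ₁ − λ₂ of the unit-trace average
lies in [0, 1] and the mean orientation is the principal axis. The energy
weighting matters: with unweighted unit tensors the vast, individually
weak, isotropic background-noise gradients of a sparse fluorescence image
dominate by count and cap the score of a perfectly parallel scene near
0.4. The score is invariant to intensity scaling and equivariant under
90° rotation (both tested). Like the original plugin's score, A depends on
object length: the rounded end caps of a rod contribute isotropic edge
energy in proportion ~d/ℓ, so short rods cannot reach A = 1 even when
perfectly parallel. No correction is applied; the alignment sweep in the
acceptance suite uses the 100 μm photomask model, for which the cap
fraction is small enough that the parallel endpoint exceeds 0.95.

**Orientation maps.** Per-pixel structure tensor with a Gaussian window
(default σ = 2 px); orientation from the minor eigenvector, coherency
(λ₁−λ₂)/(λ₁+λ₂) with a rounding-noise floor so flat regions report zero,
HSV rendering (hue = orientation, saturation = coherency, value =
intensity).

**Fiber geometry.** Intensity images are binarized at the half-maximum
level (midpoint between the background median and the foreground 99th
percentile) — for a blurred rod this contour coincides with the pre-blur
boundary, the right place to cut when widths are measured; Otsu, which
lands below half-max on sparse scenes, widens rods by ~25 %. Each
connected component is skeletonized (Lee's method; Zhang thinning can drop
whole runs of an anti-aliased diagonal band), the longest geodesic path is
found by double-sweep Dijkstra on the 8-connected skeleton graph, and its
length is measured on the path polyline subsampled every 4 px, which
removes the staircase over-count of oblique digital lines (≤1.6 % length
error across orientations for straight rods, vs ~8 % for raw chain-code
length). Diameter is 2× the mean Euclidean distance transform over
skeleton pixels (≤12 % discretization error at 4 px width). Components are
flagged *entangled* when their area exceeds 3× the expected single-fiber
area or their solidity falls below 0.2; the entanglement fraction is
entangled area over total fiber area.

## Cell morphometry

Cells are Otsu-segmented, size-filtered (default ≥100 μm²), and fit with
second-moment equivalent ellipses; orientation is reported only above an
aspect-ratio cutoff of 1.2 (rounder cells have no meaningful axis).
Orientation histograms use 10° axial bins centered on the alignment axis
(the field axis, x by convention, configurable). FWHM interpolates
linearly between bin centers around the modal peak with wrap-around at
±90°, returning 180° when no bin falls below half max. FWHM of a binned
finite sample is noisy — the peak is an extreme statistic and early noise
dips truncate the walk — so it is biased low for weakly concentrated
samples at small n; the acceptance sweep uses 400 cells per scene, where
the bias leaves the κ-ordering intact (verified by simulation). Angular
stratification reports the exact fractions within 0–30°, 30–60° and
60–90° of the axis. Viability segments nuclei on the Hoechst channel
(Otsu, ≥20 μm², watershed split via h-maxima of the distance transform,
h = 0.3× nucleus radius) and calls a nucleus PI⁺ when its mean PI
intensity exceeds the PI background mean by 3 background standard
deviations; the estimator is exact on the synthetic scenes across dead
fractions 0–1 (bias < 2 percentage points asserted at n = 400).

## Spheroid migration pipeline

Channels are maximum-projected over Z, Otsu-thresholded and size-filtered
(nuclei ≥20 μm², actin ≥50 μm²). The body ROI is either a user-supplied
ellipse (used verbatim, the scriptable stand-in for a hand-drawn ROI) or
an automatic fit: the actin mask is opened with an 8 μm disk to strip
strand-scale protrusions, the largest remaining component is fit with its
second-moment equivalent ellipse (for a filled ellipse this fit is exact).
The interior of the ellipse *inflated by 5 %* (a covering ROI) is
subtracted; 8-connected components of the remainder are outgrowths, and an
outgrowth is *contiguous* when its mask dilated by 2 px reaches back into
the inflated ellipse — bridging 1 px segmentation gaps without merging
genuinely disconnected objects. Nuclei are watershed-split and assigned:
inside the inflated ellipse → body; otherwise → the outgrowth with the
nearest mask pixel (the nearer mask wins ambiguities). Body nuclei are
detected but excluded from migratory totals. Phenotypes follow the
partition contiguous → strand; disconnected with one nucleus → single,
with two or more → cluster; nucleus conservation (body + outgrowth = all
detected) is exact by construction and asserted per scene.

Migration distances reference the *uninflated* fitted ellipse — the
spheroid periphery — not the covering ROI and not the centroid:
per-nucleus distance is the Euclidean nearest-point distance to the
ellipse, an outgrowth's maximum invasion depth is the largest such
distance over its mask pixels, and totals are stratified by contiguity.
Whether the original workflow measured along the outgrowth skeleton or by
Euclidean depth is not documented; Euclidean depth from the periphery is
fixed here and used consistently for truth and measurement. Nearest-point
distance to an ellipse has no closed form; it is computed by projecting
onto a 4096-point boundary polyline with a KD-tree (error < 1e-3 px,
tested against direct minimization). Populations are aggregated by
translation-only registration of body centers (conditions share the
alignment axis, so no rotation is applied): summed binarized actin masks
give the occupancy heatmap, and the polar angles of all migratory nuclei
about their body centers fill a 10°-bin rose histogram. The per-outgrowth
spreadsheet carries index, phenotype, contiguity, migratory-cell count,
area, summed migration distance and maximum depth, plus one totals row per
spheroid, as CSV with a config-hash/seed comment header.

## Problem sizes and tolerances in the shipped checks

The test suite validates recovery at the following scales, chosen to keep
the full suite under a few minutes on one CPU while leaving the statistics
decisive: anisotropy sweep — 500 fibers/scene, 5 seeds × 6 concentrations;
length recovery — 500 fibers per length model (non-overlapping placement);
FWHM sweep — 400 cells/scene, 5 seeds × 5 concentrations; spheroid
recovery and directional bias — 25 scenes per condition (the population
size the migration analysis is designed around). Measured tolerances all
hold with margin: single-rod length ≤3 %, scene mean length ≤10 %,
diameter ≤15 %, cell orientation ≤5° (aspect ≥3), migratory counts ≤10 %,
summed migration distance ≤15 %, per-scene max depth ≤5 %, phenotype
accuracy ≥90 %.

## What passing tests do and do not show

The synthetic scenes establish that the *implementations* recover known
geometry, counts, orientations and distances under realistic blur, noise
and overlap. They do not establish robustness to properties of real
confocal data that the generator does not emulate: intensity
inhomogeneity and vignetting, out-of-focus haze and optical sectioning,
touching outgrowths from neighboring spheroids, debris, curved or
branching strands, photobleaching, or 3D effects beyond maximum
projection. Thresholds (Otsu/half-max, PI background + 3 sd, 2 px
contiguity tolerance, 5 % ROI inflation, 1.2 aspect cutoff) are the
documented tunables a user should revisit for real images.
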