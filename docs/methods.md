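# Methods

This note documents the models, algorithms and numerical choices behind
`angioquant`, in the spirit of a methods section: what each stage computes,
which parameters matter, what the synthetic phantoms do and do not emulate,
and the known limitations.

## Input model and calibration

The input is an en-face maximum-intensity (or equivalent) projection of an
OCTA volume slab: a single-channel raster in which flow appears bright.
Instruments export these at native pixel counts from roughly 304×304 to
1000×1000 for a 3×3 mm macular field.  The user supplies the physical field
of view in millimetres, already corrected for transverse magnification (the
axial-length correction itself is upstream of this tool).  Intensities are
rescaled to [0, 1] by the file's bit-depth maximum; RGB-stored grayscale
collapses to its first channel when the channels are identical, and to
Rec.601 luma otherwise.

All images are bicubically resampled to one square analysis grid (default
1000 px).  This is not cosmetic: every kernel-based stage (median, Frangi,
twig threshold) is parameterised in pixels, so comparable physical behaviour
across instruments requires one common pixel pitch.  Coordinates are 0-based
(row, col) with row increasing downward; physical positions sit at pixel
centres.

## Vesselness enhancement

The enhancement stage is the classical multiscale Frangi filter.  At each
scale σ ∈ {1, …, max_kernel} the image is convolved with Gaussian
second-derivative kernels and the 2×2 Hessian is γ-normalised (multiplied by
σ², γ = 2) so responses are comparable across scales.  With eigenvalues
ordered |λ1| ≤ |λ2|, the bright-ridge response is

    V_σ = exp(−R_b²/2β²) · (1 − exp(−S²/2c²)),  λ2 < 0,
    R_b = |λ1|/|λ2|,  S = ‖H‖_F,

with β = 0.5.  The output is the pixel-wise maximum over scales, min–max
rescaled to [0, 1].

Numerical choices worth knowing:

* **The structureness constant c is shared across scales** (auto: half the
  maximum scale-normalised Hessian norm over the whole scale set).  A
  per-scale automatic c normalises every scale's peak response to the same
  height and destroys scale selection — with it, a Gaussian ridge produces
  identical responses at every σ and the multiscale maximum is meaningless.
* Under γ = 2 normalisation the matched scale of a Gaussian ridge of width
  parameter σ_r is √2·σ_r (the argmax of σ²/(σ²+σ_r²)^{3/2}), not σ_r — the
  test suite pins this closed form.
* The image mean is subtracted before filtering: truncated derivative
  kernels do not sum exactly to zero, and without this an additive intensity
  offset leaks into the response at the 1e-4 level.
* The recommended maximum kernel (4 px at the 1000-px grid) fully recovers
  vessels up to about kernel + 2 px in diameter after thresholding; wider
  vessels are partially trimmed because the global threshold cuts the
  response near half height.  This mirrors the familiar behaviour that small
  kernels under-segment large vessels, and is why the kernel is exposed as a
  setting.

## Segmentation

Default segmentation is two-cluster fuzzy c-means (fuzziness m = 2) run on
the 256-bin intensity histogram — mathematically identical to per-pixel FCM
for a scalar feature, at O(bins) per iteration.  Centres start at the
intensity extremes and iterate to a 1e-6 shift tolerance (cap 200
iterations); the threshold is the midpoint of the converged centres, which
for m = 2 is the exact equal-membership point.  The mask is "strictly
above".  A local-mean adaptive threshold (window image/8 rounded to odd,
offset 0.02, vessel iff intensity > mean + offset) is included for
comparison with studies that use it.  No morphological cleanup happens here;
noise specks are removed later, once, by twig pruning — cleaning twice would
bias the density metrics.

## Skeleton graph

The mask is thinned with Lee's homotopic algorithm to 8-connected unit-width
centrelines.  Vessel diameter at each centreline pixel is read off the
Euclidean distance transform as D = (2·d_EDT − 1)·pitch; the −1 calibrates
the discrete transform so a w-px-wide bar reports exactly w·pitch.

Graph construction: skeleton pixels with ≥ 3 neighbours form junction
clusters (thinning emits 2–3-px clumps; adjacent junction pixels merge into
one node, twins split by up to a knight's move merge through a 1-px halo,
and — when diameters are known — clusters lying within each other's vessel
radius (+2 px) merge as well, since they sit inside one anatomical
junction's footprint).  Pixels with one neighbour are endpoints.  Maximal
paths between nodes become edges carrying their ordered pixel polyline,
geodesic length and chord.  Two length-measurement details:

* **Staircase correction.**  Raw 8-connected step sums overestimate smooth
  curves by several percent, so edge lengths are measured on a 5-point
  moving-average smoothing of the polyline (endpoints pinned; collinear
  paths are untouched, so a straight 100-px edge still measures 99 steps and
  a semicircular arc measures its true π·r).
* **End-erosion compensation.**  Thinning erodes each free vessel end by
  about the local radius.  When the diameter map is available, each free end
  adds max(0, d_EDT − 1) pixels to both the path and the chord (the virtual
  extension runs along the end direction, leaving tortuosity unaffected).

Edges are classified segment (junction–junction), branch (junction–free
end) or isolated (free at both ends).  Twig pruning removes isolated and
branch edges shorter than the twig size (default 8 px at the 1000-px grid);
segments are never length-filtered.  The skeleton is rebuilt from the
surviving polylines plus the junction clusters that still join ≥ 2 edges
(a cluster left with one edge keeps only the attach pixel already inside
that edge, so no orphan stubs survive), and the graph is rebuilt and
re-classified exactly once.  There is no iterative re-pruning: an element
whose class changes during the rebuild is not re-tested, which keeps the
operation a single well-defined exclusion step rather than a cascade that
can eat whole trees.

## Metrics

All metrics take an arbitrary boolean region mask.  VAD and VLD are pixel
ratios.  Length statistics clip each edge to the region step-wise (a step
counts when both its pixels are inside) and scale the edge's stored geodesic
length by the in-region fraction; per-edge statistics include every edge
with ≥ 1 in-region pixel.  Branch-point density divides in-region junction
nodes by in-region vessel length — nodes/mm, consistent with histology
reports.  Tortuosity is the mean per-edge arc-to-chord ratio with closed
loops (zero chord) excluded.  The fractal dimension is box counting on the
in-region skeleton with box sizes 2, 4, …, image/4 and FD = −slope of the
log–log least-squares fit; it needs ≥ 10 skeleton pixels.

## FAZ segmentation and metrics

The rapid candidate comes from the binary map: vessels dilated by r = 5 px
(at the 1000-px grid, scaled with the grid) to close inter-capillary gaps;
the complement blurred (σ = 10 px scaled) and thresholded at 0.5; candidate
components must not touch the image border (the FAZ never does; sprawling
background framing often has a deceptively central centroid), must exceed
0.02 mm² (an order of magnitude above ordinary inter-capillary gaps, well
below any clinical FAZ), and must have a centroid within 25% of the image
width of the centre.  The largest survivor is dilated back by r — the
gap-closing dilation otherwise shrinks the recovered boundary by exactly
that radius — and must be roughly convex (circularity ≥ 0.25; clinical FAZ
circularity runs ~0.5–0.8).  Failing any of this raises a segmentation
error, and the pipeline falls back to FAZ-less analysis with the ETDRS grid
on the image centre.  A stringency factor s ∈ [0, 1] then dilates (s < 0.5)
or erodes (s > 0.5) the mask with a disc of radius round(20·|s − 0.5|) px;
0.5 is neutral.

Optional refinement runs Chan-Vese two-phase active contouring (smoothing
weight 0.2, default 100 iterations) on the median-filtered grayscale image,
initialised at the candidate; the phase and component overlapping the seed
most is kept.  Manual contours are rasterised with an even-odd rule counting
pixel centres on or inside the boundary (a square with corners (100,100) to
(200,200) fills 101×101 pixels).

FAZ area is pixel count × pixel area.  The perimeter is the 0.5-level
marching-squares contour after a 7-point moving-average smoothing: the raw
staircase contour overestimates a rasterised disc's perimeter by ~6%, which
would bias circularity to ~0.89 for a perfect circle; with smoothing a
100-px-radius disc measures within 0.2% of 2πr.  The residual ~0.3%
discretisation floor can push 4πA/P² marginally above 1 for near-perfect
discs, so circularity is clamped at 1 and acircularity computed as
1/√circularity (making the identity exact by construction).  The axis ratio
comes from the second-central-moment equivalent ellipse (pixel units — for
the usual square-pixel exports this equals the physical ratio).  FD-300 is
the vessel area density inside the ring obtained by dilating the FAZ by
300 µm (via the distance transform) minus the FAZ, clipped to the image.

## Regions

The ETDRS sectors that fit a 3×3 mm field are built: the 1-mm-diameter
fovea disc and the 1–3-mm parafoveal annulus split into four quadrants by
the ±45° diagonals, centred on the FAZ centroid (or the image centre when
no FAZ is available).  Quadrants are named superior/inferior and, when the
eye is known, nasal/temporal (nasal = image right for OD, left for OS);
without laterality the geometric names left/right are used.  The
nine-square grid tiles the image with floor(i·N/3) boundaries and is always
centred on the image.  Custom rectangles are half-open and clipped.

## Synthetic phantoms

`generate_phantom` renders, deterministically from a seed, a 3×3 mm field
(default 512 px, 5.86 µm/px) containing:

* branching vessel trees — trunks at arteriole calibre (3–6 px default;
  sweep tests use a wider 4–14 px tail), daughters tapering toward 2-px
  capillaries, centrelines sinusoidally perturbed;
* a greedy capillary-bed fill that repeatedly seeds short vessels in the
  largest remaining gap until no gap radius exceeds 5 px, emulating the
  dense perifoveal mesh (and making the avascular centre an actual enclosed
  hole rather than one corner of a percolating background);
* a terminal capillary arcade: a closed ring whose inner edge sits at the
  avascular disc boundary, as in the real perifoveal plexus;
* optional sub-threshold "spur" artefacts for pruning tests: attached spurs
  whose branch length from the host junction (host radius + 1.5–4.5 px)
  stays below the 8-px twig threshold, attached mid-path with freely
  dangling tips, plus short isolated dashes;
* noise: multiplicative Gaussian speckle (variance 0.05) then additive
  Gaussian noise (σ 0.03) on a background of 0.12 with vessels at 0.85.
  These levels put the vessel contrast-to-noise ratio near 3.5 — the
  "good-quality" regime that OCTA studies screen for before quantitative
  analysis; heavier speckle models images such screening rejects, in which
  thin vessels fragment and no length-based cleanup is meaningful.

Vessels never touch each other or the avascular disc (paths are truncated
at a clearance distance and retried; junctions keep ≥ 12 px separation and
≥ 12 px margins from their parent's ends so every junction is a resolvable
Y), so the rendered mask and all per-path bookkeeping — lengths, calibres,
arc-chord tortuosities, branch-point count, FAZ geometry — are exact truth,
not estimates.

What the phantoms do **not** emulate: real OCTA speckle statistics and
motion/projection artefacts; capillary loops and anastomoses (phantom trees
are acyclic and disjoint, so phantom VAD ~25% sits below the ~35% of a real
superficial plexus, and phantom branch-point density is far below retinal
values because the fill is junction-free); depth projection of multiple
plexuses; signal fall-off.  Passing the phantom suite therefore establishes
that the measurement chain is correct on known geometry at realistic noise,
not that segmentation of any particular instrument's images is optimal.

## Validation design

The test suite validates each stage against values computed by independent
means: closed forms (bar diameters, arc tortuosity, ETDRS areas, the
Bland–Altman and repeatability worked examples), brute-force enumerations
(graph node/edge counts by pure-python flood fill, box counts by nested
loops, per-sample fuzzy c-means), and Monte-Carlo checks (95% coverage of
the limits of agreement; E[CR] = 2.77σ under duplicate noise).  End-to-end,
twenty seeded noise-free phantoms must be recovered with exact VAD, total
length within 5% (the residual is thinning bias at junctions), the exact
branch-point count, and FAZ area within 10% (measured ≲ 2%).  Noise-free
recovery runs without vesselness filtering and without pruning — on clean
two-level images there is nothing to enhance or prune, and both stages
would only perturb the geometry being checked.  Pruning and the
parameter-sweep directions (VAD rising with the Frangi kernel on phantoms
with a wide vessel-calibre tail; total length falling and tortuosity rising
with twig size) are exercised on noisy phantoms at the default noise.
Problem sizes (512-px phantoms, 3–20 per test, 10⁴ Monte-Carlo draws) keep
the full suite around two minutes on one core.

## Known limitations

* Tortuosity and fractal-dimension definitions vary across the literature;
  this package uses the arc-chord ratio and skeleton box counting, the most
  common retinal choices, and reports them dimensionless.
* The diameter estimate is a centreline EDT; it reports the inscribed-disc
  diameter and widens at junctions.
* Metrics from images below ~400-px native resolution are resolution-
  limited even after upsampling; rescaling cannot recover lost detail, and
  short-vessel and branch-point statistics are affected first.
* The FAZ rapid segmentation presumes a dense perifoveal capillary bed; on
  sparse or very noisy images it deliberately fails toward manual
  contouring rather than returning an implausible region.
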