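# Methods

This note documents the models, algorithms and numerical choices behind
`leaftooth`, in the order the pipeline runs.

## Scope and assumptions

The pipeline assumes a photograph of a **single, simple (non-compound) leaf**
on a roughly uniform background, with the leaf either darker or lighter than
the background.  It measures only margin serrations; blade shape, venation
and texture are deliberately out of scope.  Species whose leaves are entire
(toothless) produce an *unclassifiable* feature vector rather than a forced
label.

## Margin extraction

Grayscale conversion uses the standard luminance weights (0.299, 0.587,
0.114).  Thresholding defaults to Otsu's global method (deterministic,
parameter-free, well suited to a leaf on a uniform background); a local mean
threshold (window 35 px, offset 0) is available for uneven illumination.
Foreground polarity is chosen automatically as the side whose largest
non-border-touching connected component is bigger — a photographed leaf is
centered while the background touches the frame.

Venation and other interior structure are removed by *filling interior
holes* of the binary mask before edge detection, which deterministically
guarantees that only the silhouette boundary survives; a dilation-based
pathway (radius-2 disk) is retained as an option.  A light binary opening
(3×3 cross) then removes single-pixel nubs which would otherwise thin into
tiny loops at sharp tooth tips.  Roberts-cross gradients mark the boundary
band, morphological thinning reduces it to unit width, and the contour is
traced into an ordered closed sequence by depth-first chain following with
backtracking (thinning occasionally leaves degree-3 staircase clusters;
redundant pixels are deleted first, and the walk accepts the first cycle
covering ≥ 90 % of the component).  Margin length is the number of traced
pixels, not Euclidean arc length — consistent with teeth-per-pixel rates in
the 0.005–0.02 range for typical leaves.

Margin length is invariant to axis-aligned rotations and flips to within
2 % (thinning sub-iterations are directional, so exact pixel counts can
shift by a few pixels).

## Corner detection on a one-pixel curve

The SUSAN detector compares each pixel's circular-mask neighborhood with
the nucleus brightness; the similar set is the USAN.  On *area* images the
USAN area drops at corners, but on a one-pixel margin curve the area is
nearly constant — both curve arms lie inside the mask wherever the nucleus
sits on the curve.  The discriminating signal is instead the **offset of
the USAN centroid from the nucleus**: it vanishes on straight runs, grows
with bend sharpness, and grows with the mask radius (the arms act as levers)
while rasterization staircase noise stays at ~0.7 px regardless of radius.
The pipeline therefore:

* computes USAN area (kept as the classical gate `USAN < g·n_max`,
  `g = 0.5`) and the centroid offset per on-curve pixel, via FFT
  convolutions for binary curves;
* uses a **13 px mask radius** by default at the 768 px image scale — large
  enough that a shallow 150° bend (the base of a 120° tooth) scores ~1.7
  against the ~0.7 px staircase floor; the classical 3.4 px default remains
  on `susan_corners` itself.  The mask must stay below the tooth flank
  length, so scale it down for low-resolution images;
* suppresses non-maxima in two tiers: only the strongest candidate within
  12 px survives, and within 18 px a candidate weaker than 0.75× an accepted
  one is also dropped (a sharp bend casts a response plateau out to roughly
  the mask diameter, while two genuine bends of comparable strength may
  coexist 13 px apart);
* gates candidates on **local bend evidence**: the deviation of the snapped
  contour point from the chords joining its ±{4, 6, 8} px contour neighbors,
  averaged — single-pixel staircase peaks do not persist across window
  sizes.  Candidates bending *away* from the leaf interior face stricter
  thresholds (score ≥ 1.5, deviation ≥ 1.3 px): every true convex vertex is
  a sharp tooth apex with strong evidence, whereas weak convex detections
  are blade-arc artifacts; weak reflex corners are recoverable later (see
  refinement), so the asymmetry loses nothing;
* ignores candidates within one mask radius of the image border.

Corner-level outlier rejection follows the classical 3σ (PauTa) rule: with
μ/σ the mean and population standard deviation of the corner x and y
coordinates, a corner deviating by more than 3σ in either coordinate is
removed, in a single pass.  Equality with the 3σ boundary preserves the
corner.  A useful consequence, pinned by tests: among n corners with n−1
coincident and one displaced arbitrarily, the displaced one is removed iff
√(n−1) > 3, i.e. iff n ≥ 11.

## Tooth polygon and refinement

Corners are ordered by arc position along the traced margin and oriented
counterclockwise (positive shoelace area).  Interior angles come from the
edge-vector turn direction: convex (< 180°) vertices are tooth apexes,
reflex vertices tooth bases; exactly 180° counts as base.  Each apex and
its two polygon neighbors form the tooth triangle — neighbors are used even
when not base-labeled (real detections do not always alternate), with a
per-tooth flag.

`refine_polygon` then cleans the vertex set geometrically:

1. vertices within 5 arc px merge, keeping the one with larger local bend
   deviation (detector responses do not always peak at the bend point);
2. **reflex insertion**: wherever the margin dips > 2.5 px toward the leaf
   interior from a polygon edge, the deepest contour point is inserted —
   tooth notches are reflex, so a base suppressed at detection is recovered;
   the blade between teeth bulges outward and never triggers this;
3. **flank-line intersection**: each vertex moves to the intersection of
   total-least-squares lines fitted to the contour on either side (arc
   offsets 3–12 px, clipped at neighboring vertices).  Rasterization erodes
   sharp convex tips by 1–3 px, so the true corner lies *beyond* the traced
   pixels; line intersection recovers it to sub-pixel accuracy, which is
   what brings apex-angle errors from ~3–7° down to under ~1°.

## Features and normalization

`leaf_sharpness` averages the apex angles `Ta_i` (degrees) after a 3σ pass
over all teeth of the leaf (population σ, strict >, single pass, mean
recomputed over survivors); `leaf_obliqueness` does the same for
`Te_i = |d₁|²/(2S)`, which equals base/height since `S = |d₁||d₂|/2`.
Degenerate (collinear) teeth count toward `leaf_num` but are excluded from
the angle/ratio pools — the count is a detection-level feature, the
measures require valid geometry.

Min-max scaling to [0, 1] is learned from training features only; test
features use the training minima/maxima and are clipped.  A constant
training dimension maps to 0.5.  After scaling, vectors are normalized to
unit Euclidean length when entering the dictionary or as queries.  A
consequence worth knowing: feature vectors differing only by a common
scalar factor become indistinguishable after unit normalization — species
must differ in feature *direction*, which the four-feature mix (count,
rate, angle, ratio) provides in practice.

## Sparse-representation classifier

The dictionary stacks all normalized training vectors as unit-norm columns
grouped by species.  The query is coded by the squared-loss lasso
(½‖y − Dx‖² + α‖x‖₁, default α = 0.01, exposed everywhere), and the class
residuals `r_m = ‖y − D_m x_m‖` decide the label; exact ties break to the
lowest class index.  With 4-dimensional features and dozens-to-hundreds of
atoms the dictionary is massively overcomplete and the lasso *solution* is
far from unique, but the class-residual rule remains well defined.

The solver is cyclic coordinate descent with exact soft-threshold updates
(numba-JIT inner loop).  Convergence is declared when the largest
coefficient change in a sweep falls below 1e-8 or the duality gap falls
below 1e-12.  Real leaf dictionaries contain near-duplicate atoms
(pairwise correlations up to 1 − 1e-6), on which plain coordinate descent
zigzags along a nearly flat valley for millions of sweeps; two exact
finishers handle such stalls:

1. an active-set polish of the stationarity system
   `D_Sᵀ(y − D_S x_S) = α·s` with Bland's-rule add/drop steps and
   minimum-norm solves for singular blocks;
2. the **dual least-distance QP** — projecting y onto
   `{ν : ‖Dᵀν‖∞ ≤ α}` — which is strictly convex in the 4-dimensional
   feature space and therefore immune to primal degeneracy, followed by
   non-negative least squares on the sign-adjusted active atoms to recover
   a primal solution.

On random well-conditioned problems all routes agree with an independent
accelerated proximal-gradient solver to ~1e-14 in objective; a genuine
failure of all three raises a solver error reporting the final KKT gap.

Evaluation replicates a repeated stratified train/test protocol: per run,
half of each species' leaves (random, stratified) train the scaler and
dictionary, the held-out half is classified, and per-species and overall
accuracies are reported as mean ± population std over five runs.

## Synthetic leaves

The generator renders an elliptic or ovate blade outline carrying
`n_teeth` isoceles triangular serrations.  Tooth base vertices sit on the
blade curve; the apex is displaced along the chord normal by exactly
`(|base|/2)/tan(θ/2)`, so the polygon's apex angle equals the requested θ
and the base/height ratio equals `2·tan(θ/2)` by construction.  Parameter
defaults — 12 teeth, 60° apex angle, tooth height 10 % of the local blade
radius, 768 px raster, aspect 1.35 — describe a typical serrate leaf and
keep the whole 40–120° apex-angle range geometrically feasible (teeth
whose bases would overlap raise an error; at 12 teeth and aspect 1.35 the
feasibility bound is roughly height fraction < 0.10 at θ = 120°).
Boundary noise jitters the tooth vertices (not the arc samples — real
blade margins are smooth at pixel scale) in vector space before
rasterization, so ground truth for the jittered polygon stays exact.
Rasterization is hard binary via PIL's polygon scanline; ground truth
records both the Euclidean perimeter and the rasterized outline pixel
count (the latter is the right reference for a traced 8-connected margin,
which counts a diagonal step as one pixel).

`generate_dataset` adds within-species parameter jitter (tooth count ±8 %,
apex angle ±6 %, tooth height ±10 % relative sd), redrawing the rare
infeasible combination, and writes PNGs plus a manifest and per-image
ground-truth JSON when given an output directory.

**What passing these tests does and does not show.**  The generator
exercises geometry — detection, localization, angular measurement,
classification — under controlled, known-truth conditions including
boundary jitter, shape variation and parameter spread.  It does not emulate
photometric reality: shadows, specular highlights, blur, venation texture,
petioles, overlapping or damaged leaves, or compound leaves.  Accuracy
numbers on synthetic species therefore validate the machinery, not
field-level performance.

## Standard experiments

`leaftooth.experiments` fixes the package's validation conditions (all
seeded):

* **tooth-count recovery** — counts {8, 12, 16, 24, 30}, ten noise-free
  leaves each with jittered nuisance shape parameters, 768 px;
* **angle recovery** — apex angles {40°, 60°, 90°, 120°} at 12 teeth,
  three leaves each, tooth height drawn in [0.075, 0.092] (the
  density-feasible band at the widest angle);
* **species benchmark** — three species (10 teeth/55°, 18 teeth/85° ovate,
  26 teeth/70°), forty images each with within-species jitter and 0.5 px
  boundary noise; five stratified 50/50 runs at α = 0.01, plus a
  permuted-label control (ten runs) that must sit at chance.

These sizes keep the full validation under a few minutes on one CPU while
spanning the regimes the measurements are designed for.

## Known limitations

* Tooth base width must exceed the non-maximum-suppression radius (12 px by
  default): finer serrations need either higher-resolution input or a
  rescaled detector (mask radius, NMS radii, refinement window all scale
  with image size).
* Doubly-serrate margins (teeth on teeth) are measured as their dominant
  scale only.
* Lobes are not distinguished from very large teeth.
* The 3σ corner filter assumes a roughly convex leaf outline; on extremely
  elongated leaves the coordinate statistics it relies on become
  uninformative (it then simply removes nothing).
* Margin pixel counts, and hence `leaf_rate`, depend on the thinning
  algorithm's diagonal conventions; rates are comparable within a pipeline
  but not across different margin tracers.
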