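# Methods

This note records the models, numerical choices and their rationale, what the
synthetic phantom does and does not emulate, and the known limits of what the
test suite demonstrates.

## Coordinate conventions

World coordinates are physical millimetres throughout; voxel indices are
0-based with `world = origin + direction @ (spacing * index)` (the NIfTI
convention); intervals are half-open. The cardiac-phase axis is measured in
phase-index units and is cyclic modulo `n_phases`; all wrap-around arithmetic
lives in `core.wrap_phase` and `CineSeries`. Sampling a cine series at a
fractional phase interpolates linearly between the two neighbouring phases,
cyclically — the spatiotemporal optimiser needs a smooth temporal axis.

## The spatiotemporal transform T_P

Seven parameters {θ, Cx, Cy, Tx, Ty, Tz, Tφ}: a rotation θ about the in-plane
centre (Cx, Cy), in-plane translation (Tx, Ty), through-plane translation Tz,
and a continuous temporal translation Tφ. Out-of-plane rotations are
structurally impossible: slice-to-volume registration with free 3D rotation is
badly conditioned, and excluding it confines rotational error to the imaging
plane. The closed-form inverse is a rotation by −θ about the shifted centre
(C + T) with negated translations; round-trip error is at machine precision
(verified to 1e−9 over random draws).

Embedding when composing with 3D transforms: the x–y part acts in-plane, Tz
selects the slice position, and Tφ is bookkeeping that selects the cine phase
— the spatial action on 3D points uses only the rigid part. The returned
transform stores Tφ as the *absolute* converged temporal position, so a
perfusion-plane point with nominal phase 0 lands on the correct cine phase.

ECG trigger-delay normalisation maps a delay to a continuous phase index,
`(delay mod RR) / RR × n_phases`; delays beyond one R–R interval wrap. The
normalised value initialises Tφ; the optimiser then searches within a hard
window of ±3 phases (configurable) — the cyclic shape of the cardiac cycle
admits up to two plausible temporal matches, and the window plus
initialisation disambiguates them. The final integer phase is
`round(Tφ) mod n_phases`: the optimum is continuous, and an argmax over
integer-phase metric values is fragile when two neighbours straddle the
optimum (the per-phase metric trace is still recorded for inspection).

## Similarity metric and optimisers

The deformable stage uses SimpleITK (Mattes mutual information, B-spline
transform, L-BFGS-B, two image-pyramid levels, seeded random metric sampling
at 25% so runs are reproducible). The stages SimpleITK has no transform model
for — the 4D cyclic spatiotemporal transform, the joint stack-alignment
vector, the 2D average-image motion-correction loop — share a package-authored
mutual-information metric with *linear binning* (each sample splits its mass
bilinearly over four neighbouring histogram bins, making the metric smooth in
the transform parameters) and a regular-step gradient-descent optimiser:
central-difference gradients in a scaled parameter space (so radians,
millimetres and phase indices share one step length), step halved on gradient
reversal, best-so-far returned with a convergence flag. Defaults: 32 bins,
2 pyramid levels (Gaussian smoothing σ = 1.5 px at the coarse level), initial
step 2.0, minimum step 0.02, ≤120 iterations per level.

Stack misalignment correction optimises one in-plane translation per cine
slice *jointly*: a single parameter vector (2 × n_slices entries) scored by
one pooled MI metric against reformatted reference slices, which preserves
stack integrity (no per-slice drift, no overlaps or gaps). This stage uses
Powell's method rather than gradient descent: per-slice gradients of the
pooled joint histogram are numerically flat, and the derivative-free search
is robust on the 24-dimensional joint vector. Translations are bounded at
±12 mm.

## The deformable phase chain T_C

Direct long-span registration between distant cardiac phases fails once the
span exceeds a few phases. The chain therefore walks from the
angiography-selected phase φ_A toward each perfusion-selected phase φ_P along
the *shorter cyclic arc* (wrap-around is legitimate because the cycle is
periodic; the shorter arc minimises accumulated error). At each step the
angiography-selected frame — the moving image throughout — is re-registered
to the next fixed frame, initialised with the accumulated transform of the
preceding step. The accumulated T_C is thus a single B-spline refined
incrementally, not a composition of separately estimated steps: during
development the pairwise-composition alternative was measured to accumulate
warm-start bias (mean error ≈ 1 voxel over a half-cycle span versus ≈ 0.5
voxel for incremental refinement) on the phantom. Parameter snapshots are
recorded whenever the walk passes a target phase, so the longest arc per
direction is registered exactly once and nearer targets reuse its recorded
intermediate states. Inverse transforms are estimated simultaneously by
swapping fixed and moving images — the deformable component is never inverted
numerically.

B-spline defaults: mesh of 5×5×2 cells (≈ 8×8×5 control points) on the cine
grid, 30 L-BFGS-B iterations, metric restricted to the extruded elliptic ROI
mask. The mesh is deliberately coarse: the phantom's deformation field is
smooth and large-scale, and a finer mesh measurably overfits flat image
regions.

## Motion correction

Each dynamic frame registers to the evolving *average image* of its series —
the average contains features of every contrast phase, so pre-contrast,
ventricular-contrast and wash-out frames all find structure to match. Two
outer iterations per stage (build average under current transforms, register
all frames, re-reference); translation first, then rigid 2D initialised from
the translation result. Every frame is registered, including the
maximal-contrast key frame, and all transforms are then composed with the
inverse of the key frame's estimate so the key frame is exactly identity:
the average is only a registration target, the key frame is the spatial
reference. (Pinning the key frame *during* optimisation instead leaves a
systematic offset equal to the key position minus the series mean position.)

Transform conventions: the stored *direct* transform of frame f maps frame-f
anatomy coordinates to key-frame coordinates; its closed-form inverse places
key-frame contours and masks onto frame f, and is what the exported vector
deformation fields sample (`field(x) = inverse(x) − x`). Basal-only
correction propagates the basal per-frame transforms to the medial and apical
slices — the three slices of a frame are acquired within ~150 ms of one
cardiac cycle, over which respiratory displacement is negligible; on phantoms
with shared respiratory motion this performs within 0.02 Dice of correcting
every slice. An optional deformable stage exists (2D B-spline against the
average) and is off by default.

## Territories

Per-segment contour distance maps follow the body-text reading: distances run
along the LV *epicardial* contour (the vessels lie on the epicardial
surface); a configuration switch (`contour_choice`) exposes the endocardial
alternative rather than resolving the ambiguity silently. The anchor pair
(p_S, c_S) is the closest segment-point/contour-point pair by 3D Euclidean
distance (coronary points are genuinely 3D after warping; the contour is
planar); the arc term δ(c_i, c_S) is the shorter of the two accumulated
polyline lengths; the map value is the hypotenuse `sqrt(δ² + gap²)` — exact
geodesics of the developable extruded-cylinder approximation of the
ventricular surface near the slice plane (verified against Dijkstra on a
finely meshed unrolled cylinder to < 2%). Territory maps are pointwise minima
over each group's segments (RCA {1,2}, LAD {3–6}, LCX {7–9}); contour labels
are distance argmins; ties break by the fixed order RCA < LAD < LCX for
determinism. The slice partition assigns every pixel the label of its nearest
labelled contour point — exact nearest-point Voronoi, verified against a
brute-force per-pixel scan — then masks to the annulus between the endo- and
epicardial contours. Note the min/argmin structure is monotone under
anchor-gap reduction at a fixed anchor position; a perturbation that moves a
segment closer but relocates its anchor along the contour can legitimately
grow distances beyond the anchor.

Territories are computed independently per slice location: each location is
gated to its own cardiac phase and so has its own warped tree. The AHA
17-segment baseline (6 basal + 6 mid + 4 apical + apex) takes its angular
origin from the RV insertion point; the segment-to-artery map is the standard
one (LAD: 1, 2, 7, 8, 13, 14, 17). Bull's-eye plots use the polar
parameterisation (φ, h) about the LV long axis through the apex — no surface
projection; h is plotted as the polar radius directly, with the basal band
radius taken from the registered basal-slice height and band widths from
slice thickness and inter-slice offset. The long axis and apex come from
configuration or phantom truth; automatic LV-axis detection is out of scope.

## The phantom

A bullet-shaped left ventricle (base radius 30 mm epicardial / 18 mm
endocardial, tapering as √height toward the apex, length 100 mm) deforms by
radial contraction `r' = r·(1 − a·g(p))` and a long-axis twist linear in
distance from the base, both driven by a shared activation
`g(p) = sin²(π·h(u))` where the cycle fraction u is warped so peak
contraction falls at 40% of the cycle — systole is shorter than diastole, and
the asymmetry breaks the pre/post-systolic mirror degeneracy that would
otherwise make temporal matching ill-posed at window edges. The default
amplitude a = 0.2 gives ≈ 7 mm peak epicardial displacement, the magnitude
reported for coronary points between end-systole and end-diastole. The
deformation is closed-form and invertible; every image is rendered by
evaluating a material-coordinate intensity model at the inverse-mapped
position, so the analytic truth field is exact image-wide.

Intensity: blood pools 0.85/0.75, myocardium 0.45 with an advected angular
texture, background 0.05, all with smoothstep interfaces (2 mm), plus two
deterministic band-limited cosine-sum fields — an everywhere "thoracic
clutter" field and a finer myocardial texture — that advect with the same
deformation. Real cine images carry such structure, and deformable
registration needs it: without texture the B-spline field drifts unobservably
in flat regions (measured as spurious through-plane displacement). The
coronary tree is painted as Gaussian tubes (radius 1.5 mm) along nine
centreline segments on the end-diastolic epicardial surface, three trunks at
120° spacing with branches within ±0.3 rad of their trunk, so the
construction-truth territory of a myocardial point is its nearest trunk by
circular angle. Perfusion intensities follow gamma-variate bolus curves
through RV pool → LV pool → myocardium (peak myocardial contrast at frame
21 of 40 by default); the respiratory trace is a breath-hold rest followed by
drift plus a shallow sinusoid; an optional hypo-enhancement factor scales the
myocardial uptake inside one true territory for diagnosis experiments.
Optional Rician noise is off by default: oracle tests need exactness, and
robustness experiments switch it on explicitly.

Default sizes are the desk-scale study conditions: cine 64×64×12 voxels at
2.5×2.5×10 mm, 12 phases; angiography 96×96×80 at 1.5 mm; perfusion 64² at
2.5 mm, 3 slices × 40 frames. What the phantom does *not* emulate: MR physics
(no k-space, coils or saturation effects), papillary muscles and trabecular
detail, through-plane respiratory motion (the 2D correction could not recover
it anyway), heart-rate variability between beats, and perfusion-defect
morphology beyond a sector-wise enhancement factor. Passing tests therefore
demonstrate correctness of the geometry and algebra and adequate behaviour of
the registration machinery on idealised contrast — not clinical-grade
robustness.

## Numerical and degenerate-input choices

* Resampling outside the source extent fills a configurable background
  (default 0); reformat planes that miss the volume entirely warn and return
  background.
* Points on the LV long axis have undefined polar angle: φ = 0 is returned
  with a degenerate flag.
* Empty arterial segments contribute no distance map; a territory with no
  segments is absent from the combination, and at least one territory must
  survive.
* Exact distance ties in labelling and Voronoi assignment resolve by the
  fixed territory order; equality at machine precision behaves like any other
  tie.
* The optimisers return best-so-far parameters with a convergence flag rather
  than raising on non-convergence; a failed SimpleITK registration yields an
  identity-initialised transform flagged `flagged=True`.
* All stochastic components (phantom noise, metric sampling, trial draws) are
  seeded; fixed seed implies byte-identical outputs.

## Problem sizes used in tests

Unit and property tests run on a compact phantom (48×48×8 cine, 8 phases);
the acceptance suite and `scripts/acceptance.py` use the full default phantom
(64×64×12, 12 phases) with 20 recovery trials, chain spans up to 7 of 12
phases, 24-frame motion series and the complete end-to-end pipeline. These
sizes were chosen so the whole suite documents the method at the scale the
phantom defaults describe while remaining convenient to run on a laptop.

## Known limitations

* The spatiotemporal stage's through-plane translation Tz is weakly
  constrained by a single slice (the taper toward the apex is the only
  signal); in-plane parameters and the temporal position are the reliable
  outputs, matching how the transform is consumed downstream.
* Accumulated chain accuracy degrades gracefully with span length; spans
  beyond ~60% of the cycle are better reached along the other arc, which the
  shorter-arc rule does automatically.
* Hausdorff distances are computed on polyline vertices after dense
  resampling (default 1 mm); this approximates the continuous metric to the
  resampling scale.
* The "true" supply territory of tissue is a physiological, not geometric,
  quantity (collateral flow exists); proximity-based territories are an
  approximation by construction, on the phantom as in reality.
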