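# Methods

`vascatlas` builds a voxel-wise statistical atlas of the cerebroarterial
system from a cohort of time-of-flight MR angiography (TOF-MRA) volumes
and compares new subjects against it. This note documents the model at
each stage, the parameters that matter, the numerical choices, what the
synthetic phantom cohorts emulate (and what they do not), and known
limitations.

## Coordinate and data conventions

Volumes are 3D scalar grids with a voxel-to-world affine in mm (RAS).
Voxel centers sit at integer indices (0-based); every physical distance
is computed in mm using the per-axis voxel spacing derived from the
affine, because clinical TOF grids are anisotropic (typically
0.47 × 0.47 × 0.8 mm). Each subject may carry a boolean *coverage* mask
marking the acquired field of view; a voxel outside a subject's coverage
never contributes to any population statistic. Coverage is an explicit
input (all-true when absent; a loader can optionally derive it as
`data > 0`), because acquisition extent cannot be reconstructed reliably
from image content alone.

## Intensity normalization

Multi-center TOF intensities differ by large multiplicative factors
(scanner, coil, sequence). Volumes are standardized by linear histogram
matching to one reference subject: 25 equally spaced interior quantiles
(levels k/26) of the foreground intensity distribution are read off a
100-bin histogram, and each volume is transformed by the monotone
piecewise-linear map sending its landmarks onto the reference's, with
linear extrapolation beyond the outermost landmarks using the end
segments' slopes.

The foreground entering the histogram is, by default, voxels strictly
brighter than the image mean — appropriate for bright-vessel /
dark-background MRA, where the mean sits just above the dominant
background mode. Caveat: the mean-threshold foreground *set* is itself
intensity-dependent, so strict idempotence of the normalization holds
exactly only for the set-stable `all` rule; with the default rule,
landmarks in low-density intensity regions can move by more than a bin
width on re-normalization. Order of intensities is always preserved
(the map is monotone non-decreasing).

## Vessel segmentation

Segmentation is a pluggable backend behind a stable contract
(`(volume, config) -> binary mask`); the default chain is:

1. **Vesselness.** Multiscale Hessian (Frangi-type) tubularity for
   bright curvilinear structures, per-voxel maximum over scales
   {0.5, 1.0, 1.5, 2.0} mm (spanning artery radii of roughly
   0.4–2 mm), rescaled to [0, 1]. Scales are specified in mm and
   realized as per-axis Gaussian sigmas in voxels, so anisotropic grids
   are handled without resampling. The Hessian is γ = 2 scale-normalized;
   α = β = 0.5 and the structureness constant defaults to half the
   maximum Frobenius norm per scale. A constant volume returns zero
   everywhere by construction.
2. **Fuzzy combination.** `s = w·μ_vesselness + (1 − w)·μ_intensity`
   with w = 0.5 and a sigmoidal intensity membership. The sigmoid
   midpoint defaults to halfway between the median intensity
   (background) and the 99.9th percentile (vessel), with width one
   tenth of that span; vessels occupy well under 1% of a TOF volume, so
   global two-class thresholds such as Otsu drift into the background
   mode, while the percentile rule does not.
3. **Hysteresis binarization.** Voxels ≥ 0.55 seed regions grown
   through voxels ≥ 0.30 under 26-connectivity; surviving components
   smaller than 20 voxels are removed. Lowering the high threshold can
   only add voxels (monotonicity).

Any external segmentation tool can replace this default; the rest of
the pipeline only consumes the binary mask.

## Radius quantification

1. **Centerline.** Topology-preserving 3D medial-axis thinning (Lee-style).
   Loops — Circle-of-Willis-like cycles — are preserved, nothing is
   pruned, and a representative voxel is retained for any component the
   thinning would erase entirely, so the skeleton keeps the mask's
   26-connected component count.
2. **Centerline radius.** Exact Euclidean distance transform of the
   mask (per-axis mm sampling): each skeleton voxel's radius is its
   distance to the nearest non-vessel voxel. The raw distance is used,
   with no half-voxel boundary correction; on grid-aligned digital
   cylinders this reads high by up to ~half an in-plane voxel, while on
   oblique tubes the thinned skeleton zigzags off-axis by up to ~0.3
   voxel, biasing reads low by a comparable amount. Net systematic bias
   at 0.5 mm spacing is about −0.05 to −0.1 mm for oblique mm-scale
   vessels; averaging over a few core voxels cancels the random part of
   the quantization but not this bias.
3. **Expansion.** A second distance transform assigns to every voxel
   within 5 mm (Euclidean, mm) of the centerline *exactly* the radius
   of its nearest centerline voxel; everything else is 0. No averaging
   or blending occurs anywhere, so the value multiset of the expanded
   map is a subset of the centerline radii: radius information is never
   smeared across nearby arteries nor along a tapering artery, unlike
   morphological dilation. The expansion exists to give rarely-visited
   atlas voxels enough radius evidence for stable population means.
   Equidistant ties are broken toward the lowest flattened (C-order)
   voxel index — deterministic and matched exactly by the brute-force
   oracle used in validation (ties are detected at 1e-9 relative
   tolerance, which is how mathematical ties surface in floating
   point). The 5 mm cutoff is interpreted in mm (not voxels) on
   anisotropic grids and is configurable.

## Spatial normalization

Transforms map world points to world points and are stored
target-to-source, so pull-resampling onto the atlas grid is direct.
Rigid 4×4 matrices (subject TOF → subject T1 in the clinical setting)
and dense displacement fields (T1 → atlas) compose into a single
mapping; the image is interpolated exactly once per chain, avoiding
double-interpolation blur. Displacement vectors between field nodes are
looked up trilinearly with edge extension.

Interpolation discipline: intensity volumes are resampled linearly;
segmentations and radius maps strictly nearest-neighbour (enforced at
the API level), so resampling can never fabricate radius values or
soften label edges. Voxels whose pre-image falls outside the source
extent get value 0 and coverage false; coverage itself is transported
with nearest-neighbour lookup (a target voxel is covered iff its
pre-image lies inside the source coverage).

Registration *estimation* is a backend interface: the shipped
`ground_truth` backend returns known transforms (phantom cohorts), and a
thin SimpleITK adapter (rigid/affine, mean-squares metric, axis-aligned
affines) covers real image pairs. Optimizer re-implementation is out of
scope by design; any tool that produces a rigid matrix or displacement
field in the conventions above plugs in.

## Atlas construction

Per-voxel sufficient statistics are accumulated over subjects in one
streaming pass: covering-subject count, intensity sum, segmentation
count, and count/sum/sum-of-squares of positive radii. Finalization
produces:

- `tofAverage` — mean intensity over covering subjects;
- `vesselProbabilities` [%] — 100 × segmentation count / covering count;
- `vesselRadius` [mm] — mean of positive radii (zeros excluded);
- `vesselRadiusStd` [mm] — **population** (divide-by-n) standard
  deviation over the same subject set as the mean, computed from the
  sufficient statistics (algebraically identical to a literal second
  pass over squared differences; the equivalence is a tested
  invariant, and variance is clamped at 0 against float cancellation).
  Voxels with n ≤ 1 report 0.

All four volumes are zeroed outside a brain mask (border artefacts), and
an optional exclusion mask removes non-arterial structures (venous
sinus) from the probability atlas. Accumulation order is irrelevant;
streaming equals batch stacking exactly for counts and to ≤ 1e-6
relative for floats.

## Z-scores and ROI statistics

A new subject's expanded radius map x is compared voxel-wise:
`Z = (x − μ) / max(σ, σ_floor)` on the support `x > 0, μ > 0,
probability ≥ p_min`. Defaults σ_floor = 0.05 mm and p_min = 1% guard
against division by near-zero standard deviations at rarely-visited
voxels — the atlas itself does not define Z where σ = 0, so the floor is
an explicit design decision of this package. Dilated vessels give
positive Z, stenosed negative.

Calibration caveat at small cohort sizes: σ is *estimated* (population
divisor) from the n atlas subjects, so Z has heavier-than-normal tails,
exactly as a t statistic does. For n = 20, Monte-Carlo gives an
expected fraction of |Z| > 2 voxels of ≈ 6.5% for a perfectly typical
subject, versus the 4.6% of normal theory with known σ; voxels along
one vessel are additionally correlated through shared caliber draws,
so the per-subject flagged fraction fluctuates segment-wise. A z-map
against a small-cohort atlas therefore runs slightly "hot" and its
threshold should be calibrated against the cohort size if used for
screening. The formula is pointwise, so either
warping direction (subject → atlas or atlas → subject) is supported.
ROI statistics report, per subject × named artery ROI, the mean of
positive radii inside the ROI (a subject without vessel voxels there is
*missing*, never 0), plus cohort mean/std/quartiles per ROI.

## Synthetic phantom cohorts

The generator emulates the statistical structure the pipeline assumes,
with every quantity known analytically:

- **Geometry:** a Circle-of-Willis-inspired toy tree of straight
  tapered segments (radii ~0.8–1.8 mm; ICA segments at 1.5 mm) in a
  48 mm cube, 96³ at 0.5 mm isotropic by default. Each ICA is split at
  an interior mid-ICA landmark node.
- **Population:** radius draws per tree *node* (landmark), Normal
  truncated positive, interpolated linearly along segments; segments
  meeting at a shared node with the same population parameters share
  its draw, so radius profiles are continuous across such nodes and the
  radius at any landmark node is exactly Normal(μ, σ) across subjects,
  while caliber decorrelates along a vessel over one edge length.
  Default σ: 0.2 mm on ICA/basilar, 0.12–0.15 mm elsewhere.
- **Scanner effects:** vessel 100 / background 20 intensity, per-center
  multiplicative shifts ×0.6/×1.0/×1.8 assigned cyclically, additive
  Gaussian noise (σ = 6, scaled with the center multiplier).
- **Spatial variability:** a smooth random displacement field
  (correlation-length-filtered Gaussian vector noise, RMS amplitude
  1 mm, correlation 16 mm — amplitude must stay below the correlation
  length for invertibility-in-practice) plus a small rigid misalignment
  (±2°, ±1 mm); the exact atlas-to-subject chain is stored so the
  oracle registration backend can replay it.
- **Coverage:** a per-subject axial sub-box spanning 80–100% of the
  grid (the tree sits inside the always-covered region, so coverage
  variation exercises the bookkeeping without confounding the truth).

Everything is deterministic given (seed, subject index). What the
phantoms do **not** emulate: MR flow physics (flow-related enhancement,
signal dropouts), partial-volume intensity gradients at vessel walls,
venous structures, curved vessels, bias fields, or registration
estimation errors (the oracle backend replays the truth). Passing the
closed-loop tests therefore demonstrates correctness of the pipeline's
computations and bookkeeping under the model's assumptions — not
segmentation or registration robustness on clinical data.

## Validation experiments and problem sizes

`vascatlas.experiments` packages the validation study; the test suite
and `scripts/acceptance.py` run it end-to-end. Sizes were chosen so the
whole study completes in minutes on one CPU: digital cylinders of radii
1–4 voxels; expansion exactness on 20³ grids against an O(V·C)
exhaustive oracle; streaming-vs-batch atlas statistics on 20 random
subjects at 48³; interpolation discipline over 5 random rigid+field
chains at 24³; end-to-end recovery on a 20-subject 96³ cohort (ICA
landmark population Normal(1.5, 0.2) mm, zero smooth deformation so the
recovered mean is attributable to the radius chain rather than geometry
blur); z-score detection with a held-out subject, one ICA dilated by 4σ;
normalization convergence on 9 subjects across three centers. The
end-to-end landmark readout averages atlas mean-radius over a small
tube-core ROI at both ICA landmarks — the same ROI-style readout used
for artery radii generally — rather than trusting a single voxel's
quantized value.

## Known limitations

- Radius estimates carry the raw-distance convention's systematic
  discretization bias (above); sub-voxel centerline refinement is out
  of scope.
- The default segmentation backend is a vesselness + fuzzy + hysteresis
  chain, not a level-set; it is intended as a reasonable, replaceable
  default behind the backend contract.
- The SimpleITK registration adapter assumes axis-aligned affines and
  mono-modal (mean-squares) matching.
- No vein suppression, no age/sex stratification, no statistical
  calibration of Z thresholds against disease cohorts, and no
  multiple-comparison control across voxels (the z-map is exploratory).
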