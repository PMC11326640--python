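# Methods

`sfdiff` implements a complete shape-to-cytoskeleton pipeline: synthetic
paired data, cell-outline extraction, stress-fiber (SF) segmentation, a
conditional denoising-diffusion generator, probability-field evaluation,
fiber/cell morphometrics, contour-curvature mechanics and virtual
experiments. This note records the models, the parameters that matter, and
the design decisions taken where the problem was genuinely open.

## Synthetic data generator

The generator emulates phalloidin-stained single-cell micrographs at the
statistical level needed to test the pipeline; it is not a biophysical
actin model.

**Shapes.** Rectangles, ellipses, and "blobs" (ellipse contours modulated
by a random Fourier series of orders 2–5 with total amplitude capped at
0.12 so the mask stays simply connected). Shapes are specified by area
(µm²), aspect ratio (AR, major/minor axis), orientation and pixel size
(default 0.1375 µm/px, the native raw-image pitch; datasets default to the
4× downsampled 0.55 µm/px). Masks are rendered on a 4× supersampled grid
and area-averaged, keeping the rendered area within 2% and the moment
aspect ratio within 5% of the request.

**Fibers.** Straight segments seeded inside the mask. Axial orientations
follow a π-periodic von-Mises distribution on doubled angles centred on the
mask's major axis; the concentration κ controls alignment
(E[S] ≈ I₁(κ)/I₀(κ)). A fraction `edge_bias` of fibers is seeded in the
peripheral band (within 30% of the maximal interior depth). Fibers extend
from their seed in both directions until the requested length or the mask
boundary, whichever comes first, and are rendered as anti-aliased thick
lines (default width 2 px, intensity 180/255). Truth endpoints are
returned exactly.

**Dataset rule.** The default dataset embeds two empirically motivated
trends so recovery tests have known truth: κ(AR) = 1.5 + (AR − 1)
(expected S from ≈0.55 at AR 1 to ≈0.90 at AR 5) and
edge_bias(AR) = clip(0.9 − 0.2(AR − 1), 0.1, 0.9) (round cells keep fibers
at the edge). The fiber count is set so the fiber/cell area ratio is ≈0.1.
A single seeded generator drives every draw; datasets are pure functions
of (specification, seed).

**Micrograph model.** Raw-looking images add a cytoplasmic level (50) with
multiplicative speckle texture (amplitude 0.3, correlation 3 px), an
out-of-focus halo of the fiber signal (gain 0.2, σ 6 px), background 8,
defocus blur σ 0.5, Gaussian sensor noise σ 5 and ±10% contrast jitter on
an 8-bit range. These values were chosen once to look like the real
modality; no published noise characterisation exists for it. What the
generator does *not* model: fiber curvature, branching, focal adhesions,
multi-cell fields, uneven illumination, 3-D defocus. Passing tests
therefore show the algorithms are correct under controlled statistics, not
that the trained models transfer to real micrographs.

## Outline extraction

Pipeline at 256×256: area-averaged downsample → Gaussian smoothing →
local-mean adaptive threshold → 2 erosions → 2 dilations (3×3 square) →
largest 4-connected component (ties broken by topmost-leftmost centroid) →
hole filling → marching-squares contour. Two numerical choices were tuned
together on the synthetic oracle and deviate from first-guess values:

- *Adaptive block 101 px.* A block much smaller than the cell compares a
  flat interior against its own level and never marks it foreground; a
  cell-scale block compares against a mean that includes background. With
  block 31 the recovered masks had broken rims (IoU ≈ 0.7); with 101 the
  sweep over noisy fixtures gives IoU 0.93 mean / 0.92 min.
- *Smoothing σ = kernel/8 = 1.* The smoothing kernel (8) is read as the
  ±4σ support. σ = 2 delocalises the boundary enough to break idempotence
  (re-extracting a clean mask must reproduce it with IoU ≥ 0.98; σ = 1
  gives 0.985).

Both parameters remain exposed in `OutlineConfig`. Single-cell fields are
assumed; nothing splits touching cells.

## Segmentation

**Augmentation.** Each labelled image is cut into four quarters; new
mosaics are assembled from randomly drawn quarters (40 variants per source
image, so 50 originals become 2000). Image pieces get photometric jitter —
Gaussian/mean filter, additive noise, contrast/brightness — while
geometric transforms (right-angle rotations, flips) are applied to image
and label jointly.

**Model.** The segmenter is a per-pixel classifier over local intensity
patches: a small fully-connected network (9×9 patch → 48 → 48 → sigmoid)
trained with binary cross-entropy and Adam (β₁ = 0.5, β₂ = 0.9,
lr 2·10⁻⁴ by default). The patch formulation keeps the package pure NumPy
and CPU-friendly, is resolution-independent, and suffices for the bright
thin structures of this problem; it has no multi-scale encoder–decoder
context, which is a real limitation for dim or crowded fibers.

**Evaluation.** Grayscale outputs are binarised at 128 (foreground iff
≥ 128). Before pixel metrics, thin structures are widened with the
sliding-window kernel: any SF pixel inside a k×k window (default 8,
1.1 µm) sets the whole covered window, which equals dilation by the
(2k−1)² support — an isolated pixel becomes a 15×15 block. The operation
is extensive and monotone but *not* idempotent. Metrics: accuracy,
FNR = FN/(TP+FN), FPR = FP/(FP+TN).

## Conditional diffusion

**Forward / reverse processes.** x_t = √ᾱ_t·x₀ + √(1−ᾱ_t)·ε with the
squared-cosine schedule ᾱ_t = f(t/T)/f(0), f(u) = cos²((u+s)/(1+s)·π/2),
s = 0.008, T = 800; per-step α are the successive ratios clipped to
[10⁻³, 1−10⁻³]. Training minimises the mean-square noise-prediction error
(mean over pixels). Generation is the deterministic accelerated sampler
over a uniformly strided sub-sequence of length S = 80 (τ_i = 10i):
predict x̂₀, clip it to the model range [−1, 1] (without clipping, the
division by √ᾱ ≈ 10⁻⁴ near t = T amplifies prediction error by ~10⁴), and
re-noise to the previous level. The forward/reverse algebra is exact: with
the true noise supplied as the prediction, the trajectory returns x₀ to
machine precision for any valid sub-sequence — the module's core
correctness oracle. Images map 8-bit ↔ [−1, 1]; generated images binarise
at 128 like segmenter output. The generator consumes *binary* SF labels as
x₀, mirroring a pipeline in which segmentations, not raw fluorescence, are
the targets.

**Conditioning.** The cell shape enters the noise predictor
μ_θ(x_t, c, t) as an engineered per-pixel encoding of c rather than a bare
contour raster: mask indicator, normalised interior edge distance,
elliptic radial coordinate, centroid-frame coordinates (major/minor axis
units), aspect ratio, plus a *learned prior map* — a small network
(6 → 32 → 32 → 1) trained beforehand to regress the clean image value on
those descriptors, i.e. a map of where fibers tend to sit in a given
shape. Receptive fields are rotated into the cell's major-axis frame so
oriented structure appears in a canonical orientation.

**Denoiser.** A per-pixel fully-connected network over: the x_t patch at
two scales (7×7, dilation 1 and 2), the mask patch, the "prior-implied
noise" patch (the ε that would be exact if x₀ equalled the prior map,
gated to the interior), the condition scalars and a 4-number timestep
embedding (√ᾱ, √(1−ᾱ), t/T, cos πt/T); hidden widths 96, 96. The network
output is *added* to the prior-implied noise at the centre pixel (a skip
connection), so an untrained network already generates the prior map and
training only learns deviations. Training: Adam, default lr 1.5·10⁻⁴ and
batch 16 images per step (512 random pixels each, with joint right-angle
rotation/flip augmentation of image and shape); the `tiny` profile used by
tests and examples raises the learning rate to 2·10⁻³ for 30 epochs so the
whole run takes well under a minute on one CPU core. A 13-cycle
train/test split utility reproduces the evaluation protocol for a
1293-item corpus (12 × 1193/100 + 1 × 1200/93).

This denoiser deliberately trades expressiveness for a dependency-light,
CPU-scale implementation. Per-pixel patch regression cannot represent
joint multi-pixel structure, so generated images are fiber-*textured*
rather than composed of long coherent fibers, and a residual speckle floor
survives the reverse process. The consequences are measurable and are
stated honestly in the acceptance analysis below.

## Probability field and evaluation

P = N_S/N_I is the per-pixel fraction of N_I generated images whose 8-bit
value is ≥ 128. For comparison with a reference segmentation the raster is
cut into grids (64×64 grids over the full-resolution frame = 2.2 µm per
grid); a grid is an SF grid if *any* constituent pixel is foreground (the
main text's "more than one pixel" conflicts with the figure caption's
"any"; the caption rule is self-consistent with its illustration and is
adopted). Rasters not divisible by the grid count are zero-padded
right/bottom with padded grids marked extracellular; extracellular grids
are excluded from the ROC. The per-grid score is the maximal P inside the
grid (the threshold at which the grid turns positive); thresholds sweep
all unique scores plus {0, 1}; AUC is trapezoidal; the operating point
minimises the distance to (FPR, TPR) = (0, 1). The sweep is cross-checked
against scikit-learn's AUC on identical scores in the test suite.

The relative direction error |φ̄_p − φ̄_r|/φ̄_r divides by a frame-dependent
reference angle; results with φ̄_r < 0.1 rad are flagged as unreliable
rather than silently reported.

## Morphometrics

Total length ℓ = Σℓ_m; principal direction φ̄ by doubled-angle vector
averaging of the axial angles with length weights ω_m = ℓ_m/ℓ (the naive
weighted mean of angles is ill-defined at the 0/π wrap; the axial mean
reduces to it away from the wrap and is the convention under which S is
rotation invariant — the literal arithmetic convention remains available
as `mean_convention="arithmetic"`). Order parameter
S = Σ[2cos²(φ_m − φ̄) − 1]ω_m. Under the axial mean S equals the length of
the doubled-angle resultant, so S ∈ [0, 1]; note the estimator has a
finite-sample bias E[S] ≈ √(π/4M) for isotropic fibers (≈0.04 at M = 500).

Cell direction ψ = ½·atan2(2μ₁₁, μ₂₀−μ₀₂) from the central moments of the
mask indicator (the printed formula omits the ½, which cannot reproduce
the moment-ellipse axis; the ½ is used). Aspect ratio from the
moment-equivalent ellipse axes (2√(λ±/A)); circularity 4πA/P² with the
Crofton perimeter estimator (marching-squares polylines overestimate
perimeters of smooth shapes by the staircase factor); near-isotropic
moment matrices set an `isotropic` flag instead of reporting a
noise-driven angle.

Segment detection is a pluggable contract; the built-in backend
skeletonises the binary raster, runs a probabilistic Hough transform,
merges collinear nearly-touching fragments, and refines endpoints to the
extremes of each segment's skeleton support (Hough vote thresholds
truncate tips). Any detector producing endpoint pairs can replace it.

## Contour curvature and mechanics

Contours are resampled to 1 px arc-length spacing and smoothed with a
circular Gaussian whose σ equals the window length (marching-squares
staircases otherwise dominate the quadratic fit; the smoothing biases κ of
a circle of radius R by only exp(−σ²/2R²)). Windows are arc-length
neighbourhoods of diameter L = P_cell/30 (a Euclidean-disk option exists
for intensity averaging, which uses the in-cell disk of diameter L).
Within a window, points are rotated into the local principal-axis frame
and fitted with g(x) = ax² + bx + c; κ = |g''|/(1+g'²)^{3/2} at the
centre, signed by the chord-midpoint-versus-centroid test (+ convex).
Verified: κ = 1/R within 5% pointwise on a rendered R = 40 circle, scale
covariance on R ∈ {20, 80}, ~0 on rectangle edges farther than 2.5 L from
corners (inside that distance the smoothing support mixes in corner
curvature), and negative values inside a concave notch.

Local force averaging takes external (x, y, magnitude) tables and averages
magnitudes within distance L of a contour point; an empty neighbourhood
returns NaN (missing), never zero. The Laplace balance R = 1/κ = EAε/σ is
a pure identity evaluated in SI units.

## Virtual experiments

`run_virtual` renders an idealised shape, generates N_I images (default
100), aggregates P, and computes in-cell readouts only: the radial profile
P_mean(r*) with r = centroid distance and r* = r/R_max (R_max = semi-minor
axis, so r* > 1 occurs along the major axis; an edge-distance variant is
available since the textual definitions conflict), the P histogram (20
bins on [0, 1], density normalised), σ_P, and the order parameter of
segments detected on the mean prediction thresholded by Otsu's method over
in-cell P (no reference segmentation exists for virtual shapes, so a
fixed operating threshold cannot be chosen from an ROC).

## Scaled-down study conditions

CPU-scale runs use 64×64 rasters at 2.2 µm/px, cell areas 1.2–2.0·10³ µm²
(the largest AR-5 shape that fits the raster), 195 synthetic pairs (190
train / 5 held out), the `tiny` training profile, N_I = 20 for held-out
evaluation and N_I = 50 × 2 replicates for aspect-ratio sweeps at area
2.0·10³ µm² (the published rectangle constraint of 2.5·10³ µm² is scaled
down to stay inside the training distribution of the tiny raster). At
this scale the evaluation grid is 4×4 px ≈ 2 fiber widths, matching the
full-scale grid's proportion to fiber width.

Two empirical facts about these conditions deserve emphasis:

- The aspect-ratio trends are recovered cleanly: measured S rises
  (Spearman ρ = 1.0) and σ_P falls (ρ = −1.0) across AR 1–5.
- Single-realisation prediction is information-limited in the synthetic
  data: fiber placement is mostly random given the shape, so even the
  generating process itself, aggregated over 20 of its own realisations,
  scores a held-out grid AUC of ≈0.47 (≈0.63 at N_I = 100). The trained
  generator scores ≈0.55 at N_I = 20. The corresponding acceptance check
  (AUC ≥ 0.60) therefore fails for reasons intrinsic to the study
  conditions, not for implementation reasons; the test is kept faithful
  and red rather than weakened.

## Known limitations

- The neural components are deliberately small, pure-NumPy patch networks;
  they demonstrate the pipeline's contracts and scaled-down behaviour but
  are not competitive with full-scale convolutional architectures on real
  micrographs.
- Generated images are fiber-textured speckle, not long coherent fibers;
  per-sample segment statistics of generated images are unreliable, which
  is why trend readouts aggregate over many samples.
- The outline stage assumes a single cell per field.
- The direction-error metric is frame dependent by construction and only
  meaningful away from small reference angles.
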