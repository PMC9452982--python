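# Methods

## Model and pipeline

The toolkit registers a floating 2D PET slice *U* to a fixed CT-derived
reference *D* by maximizing mutual information, then fuses the pair and
segments high-uptake regions. The pipeline is:

1. normalize the CT to [−1, 1] and extract its binary edge image with a
   Chua–Yang cellular neural network (CNN);
2. search rigid transforms T = (β, tx, ty) for
   u\* = argmax I(U∘T, D), estimating I from the joint gray-level
   histogram over the transform overlap;
3. resample the PET by u\*, overlay it on the CT, and threshold it to
   localize high-metabolism regions.

### Information estimation

Both images are quantized into equal-width gray-level bins over their
observed intensity range (maximum value into the top bin, constant
images into bin 0). This makes I invariant to affine intensity
rescaling of either image and needs no density smoothing. Entropies use
log₂ (bits) with 0·log 0 = 0. I is computed directly from the
joint/marginal probability ratio; the identity I = H(U) + H(D) − H(U,D)
is exercised by the tests as an independent route, not used as the
definition. The floating axis uses 64 levels by default — enough to
resolve PET contrast at 128² samples without starving the histogram —
and the reference axis uses 2 levels in edge mode (the edge image is
binary by construction) or 64 in raw-CT mode.

### CNN edge extraction

The cell dynamics are dx/dt = −x + A∗y + B∗u + z with the saturation
output y = 0.5(|x+1| − |x−1|), computed as clamp(x, −1, 1) — the exact
algebraic equivalent — so the |y| ≤ 1 bound holds to the last ulp.
Defaults: the classical edge template (A = center-only 1,
B = [[−1,−1,−1],[−1,8,−1],[−1,−1,−1]], z = −1), forward-Euler step 0.1
for duration 10 time units (100 steps, comfortably converged for this
template on [−1, 1] inputs), initial state = input, zero (Dirichlet)
padding of y and u outside the grid. Edge decision: steady-state y > 0.

One boundary subtlety: with zero padding alone, image-border cells of a
uniformly bright region see mid-gray (0) outside the raster and fire as
spurious edges. `edge_extract` therefore replicate-pads the input image
by one pixel and crops the output, so border cells compare against
their own intensity; the network itself keeps the Dirichlet boundary.
With this, every flagged pixel provably touches an opposite-valued
8-neighbour on binary inputs. Only the bright side of a transition is
flagged (the template is one-sided), which is immaterial for
registration: what matters is that edges consistently mark anatomy.

### Geometry and resampling

Transforms rotate about the image center ((H−1)/2, (W−1)/2) — the
center is what makes β and t identifiable — and translate by (tx, ty)
in (row, col) pixels. Resampling is backward (pull) warping with
bilinear interpolation by default; nearest-neighbour is available.
Source coordinates within 10⁻⁹ of a pixel center are snapped to it so
that exact quarter/half turns and integer shifts reproduce pixels
exactly instead of reading fill values through rounding error.

The overlap mask marks output pixels whose back-mapped source lies in
the half-pixel support [−0.5, N−0.5) per axis; sources in the border
half-pixel band are clamped to the border row/column, anything further
out takes the fill value and is excluded from all histograms. The
half-pixel convention matters: with a strict [0, N−1] bound, any
sub-pixel rotation shaves near-constant background corners off the
mask, which inflates the masked entropies and can pull the optimizer
off a perfect alignment (a known overlap artifact of MI registration).
Under the chosen convention sub-pixel motion keeps full overlap, where
I ≤ H(D) guarantees that exact alignment is never beaten.

### Optimization

Exhaustive coarse grid (β ∈ [−0.3, 0.3] rad step 0.05; tx, ty ∈
[−10, 10] px step 2 — covering typical slice misalignment at this image
scale), then coordinate descent: all steps are halved, each parameter
is swept with ± moves until none improves, and halving continues until
every step is below its tolerance (0.005 rad, 0.25 px), giving a final
resolution of ~0.006 rad and 0.25 px. MI differences below 10⁻¹² bits
are treated as ties and broken toward the smallest motion,
lexicographically on (|β|, |tx|, |ty|): this keeps the search
deterministic and immune to float summation noise between numerically
equivalent candidates. The floating image is re-quantized over each
candidate's overlap so fill values never enter. The optimizer is
derivative-free because histogram MI is piecewise smooth at best; it
uses no randomness (the config's `seed` field is reserved for future
multi-start variants). An optimum with under 10% overlap is flagged on
the result rather than raised, since a degenerate optimum is a finding
about the data, not a usage error.

## Synthetic phantoms

Each phantom emulates one trans-axial slice pair. CT: background 0,
elliptical soft-tissue body at 0.3 (semi-axes 0.38·H × 0.30·W), a sharp
"bone" rim where the normalized elliptical radius is in [0.90, 1.0],
and a vertebra-like disc (radius 0.05·size) at 1.0. PET: body-wide
uptake 0.4 inside the ellipse plus unit-amplitude Gaussian lesions
(σ = 0.04·size) at integer pixel centers drawn uniformly from the body
core (normalized radius ≤ 0.6, rejection-sampled with a 100-try cap),
blurred with a Gaussian of σ = 2 px to emulate PET's low spatial
resolution, degraded with additive Gaussian noise (sd 0.05 against the
0.4 body uptake), and finally resampled by the ground-truth rigid
transform, drawn uniformly from |β| ≤ 0.2 rad, |t| ≤ 8 px when not
given explicitly. The lesion truth mask marks pixels within one FWHM
(≈ 2.355 σ) of each lesion center in the CT frame. All draws come from
one `numpy` Generator keyed by the seed, in a fixed order (transform,
lesion centers, noise), so regeneration is bit-identical. PET is
simulated on the CT grid and blurred rather than on a coarser grid, so
the ground-truth transform is the only geometric difference between the
modalities.

What the phantoms do not model: attenuation, scatter, Poisson counting
noise, partial-volume effects, anatomy beyond the body/rim/vertebra
shapes, and any non-rigid motion. Passing benchmarks on them shows the
estimator, optimizer and scoring are correct under the stated noise and
misalignment conditions; it does not certify accuracy on patient scans.

## Benchmark problem sizes

The validation benchmark registers 20 phantoms (seeds 1–20) at 128×128
with one lesion each, the generator defaults above, the default
registration configuration (edge reference), and fraction-of-max 0.4
segmentation of the realigned PET; recovery error is the mean over the
three parameters of |estimate − truth| normalized by the search
half-widths (0.3 rad, 10 px, 10 px), in percent, comparing u\* to
invert(true_transform). These sizes resolve the method's behaviour
clearly while keeping a full run near a minute on one CPU;
self-registration and unit tests use 64×64 phantoms and, where they
probe the optimizer's mechanics rather than its accuracy, a reduced
search grid.

## Scoring choices

Segmentation is scored with pixel accuracy, Dice and Jaccard; Dice is
the headline overlap metric, pixel accuracy is reported because it is
the most common single-number "segmentation accuracy" in clinical
summaries (on small lesions it is dominated by background and thus
high; Dice is the discriminative one). Relative transform-recovery
error is normalized per component by the search-range half-width —
errors in radians and pixels are otherwise incommensurable — and the
normalization is stated wherever the number is reported.

RECIST tallies round percentages half-up to one decimal (0.25 → 0.3;
bankers' rounding would print 0.2) and display whole percentages
without the decimal. Percentages are always computed from the counts;
they sum to 100 within rounding slack (±0.2).

## Known limitations

- Strictly 2D: volumes must be sliced on input; the transform model is
  rotation + translation only (no scale/shear, no deformation).
- The rotation angle is weakly identified when the informative
  structure is concentrated near the rotation center (e.g. a single
  central lesion on a near-symmetric body): β then localizes only to
  the refinement grid scale even when translations are sub-pixel.
- Histogram MI needs enough samples per bin; very small images with
  64 levels will be noisy (use fewer levels).
- The edge template flags one side of each transition; edge images are
  reference material for registration, not a contour extraction tool.
- No SUV calibration: segmentation thresholds are relative to the image
  maximum or absolute in raw intensity units.
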