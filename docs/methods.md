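# Methods

`visnorm` implements four image-computable encoding models of the fMRI BOLD
response of human visual areas V1–V3 to band-pass textures, together with
the stimulus synthesizer, the fitting/cross-validation engine, and the
diagnostic experiments that distinguish the models. This note documents the
model equations as implemented, the numerical choices, the synthetic study
conditions, and the known limitations.

## The models

Every model is a three-stage cascade. Stages 1 and 3 are shared; the models
differ only in stage 2.

**Stage 1 — oriented contrast energy.** The preprocessed image *I(x, y)*
(zero mean, range −0.5…0.5, gray outside a circular aperture) is projected
onto a bank of 128 Gabor filters: 8 orientations spaced 22.5°, 8 peak
spatial frequencies log-spaced 0.75–6 cpd, and 2 phases in quadrature. Each
filter is a 4-cycle sine or cosine carrier under a Gaussian window with SD
of one cycle, realized on a square support of 4 carrier wavelengths; the
even (cosine) kernel's mean is removed so uniform gray yields exactly zero
energy. Quadrature outputs are squared and summed (phase-invariant energy),
energies are summed over frequency bands with uniform weights, and the
resulting map

E(x, y, θ) = Σ_{φ,f} ( Σ_{x′,y′} I(x−x′, y−y′) F(x′, y′, θ, f, φ) )²

is downsampled to 12 px/deg. This stage has no free parameters.

**Stage 2 — pooling functional Φ.**

- *Contrast energy (ce)*: s = mean over (x, y, θ) of E. Blind to how energy
  is distributed across orientations.
- *Untuned divisive normalization (dn)*: each element of E is divided by
  σ + Z, where Z is a spatial Gaussian convolution of E summed over all 8
  orientation planes; s is the mean of the normalized map E/(σ+Z).
- *Orientation-tuned normalization (otn)*: as dn, except the Gaussian
  surround pools only the same-orientation plane; the other 7 orientations
  contribute through their energy at the center pixel alone
  (cross-orientation suppression). A grating concentrates its energy in one
  channel and therefore recruits the large same-orientation surround pool;
  a curved texture spreads energy across channels, each of which sees a much
  smaller pool.
- *Normalization by orientation anisotropy (noa)*: the spatial sum is taken
  first, e(θ) = mean over (x, y) of E(·, ·, θ), and the normalizer is the
  spread across the 8 channel outputs:
  s = mean(e²) / (σ² + V), with V = Σ_θ (e(θ) − ē)². Numerator and σ are
  squared so the parameter stays on the same footing as the squared
  deviations inside V. A configuration switch (`sqrt_variant`) provides the
  first-power form s = mean(e)/(σ + √V). The two forms differ in their
  weak-normalization limit: as σ → ∞ the first-power form reduces exactly
  to the contrast-energy model (its numerator is the mean energy), whereas
  the squared form tends to mean(e²)/σ², which weights orientation-
  concentrated stimuli more heavily than contrast energy does.

**Stage 3 — power law.** r = g·s^α, with gain g > 0 and exponent
α ∈ (0, 1), predicting BOLD amplitude in percent signal change. Because
each stimulus is a set of exemplar images, the stimulus prediction is the
average of the per-exemplar predictions (power law first, then average).

## Normalization-pool weights

The spatial pool is a 2-D Gaussian with SD equal to 4% of the
(padded, downsampled) energy-map width, truncated at 3 SD. The planes are
normalized to unit **peak** amplitude (center weight 1), not unit sum. This
choice is load-bearing for the tuned model: with sum-normalized planes, the
Gaussian surround of the same-orientation plane and the single-pixel cross
terms would all carry total weight 1, so for spatially homogeneous textures
the tuned pool would collapse onto the untuned one
(G∗E(θ) ≈ E(θ) ⇒ Z_tuned ≈ Σ_θ E = Z_untuned) and the snakes/gratings
dissociation would vanish. With unit-peak planes the surround carries total
weight ≈ 2π·sd², against weight 1 per cross term, and the dissociation
appears (measured class ratios on energy-matched fixtures: ce 1.00, dn
1.06, otn 2.2, noa 4.3). The absolute weight scale is absorbed by the
fitted σ; fixing the convention makes σ comparable across runs. For a
uniform field E = c the untuned pool gives Z = 8·c·W with W the weight sum
of one plane.

The denominator is floored at 1e−12 to guard σ = 0 on zero-energy pixels.

## Padding and geometry

Images are padded with 0 (= mean gray) by the largest kernel half-width on
all sides before convolution, which is the minimal padding that makes
zero-fill FFT convolution exact; the padded region is retained in the
pooled output. The padded sizes therefore differ from other realizations of
the same cascade that pad by the full filter width — the difference only
rescales the pooled mean and is absorbed by the fitted gain.

Display geometries of the four fMRI sessions (12.5 deg/400 px,
18.75 deg/600 px, 12.5 deg/256 px) are available as named dialects. All
simulations and tests run on a scaled-down canvas of 6 deg at 24 px/deg,
the package's default study size: it preserves every pipeline stage
(band-pass spectra, filter supports in degrees, 12 px/deg energy
resolution) at roughly a tenth of the full-canvas cost.

## Stimulus synthesis

All families are band-pass textures with power near 3 cpd, enforced by a
zero-mean isotropic Difference-of-Gaussians filter whose amplitude spectrum
peaks at 3 cpd and crosses half-maximum at 1.4 and 4.7 cpd. The two
Gaussian scales are solved by least squares against those three spectral
features (two degrees of freedom against three constraints; the realized
kernel is verified by FFT, achieving the peak within ~4% and the crossings
within ~1%).

- *Snakes* (curved contours): white noise → low-pass at the density cutoff
  (2.8, 1.6, 0.9, 0.5, or 0.3 cpd; raised-cosine spectral edge) → threshold
  at the median → first-difference edge detection in x and y combined by
  maximum → polarity inversion (edges dark) → band-pass filter. The
  threshold level and edge operator are implementation choices; the
  upstream description fixes only the step names.
- *Gratings*: 1-px parallel lines every 3, 2.5, 1.75, 1, or 1/3 deg
  convolved with the band-pass kernel ("lines" mode), or 3 cpd sinusoids
  with the 9 exemplars spanning phases equally spaced over [0, 2π)
  ("sinusoid" mode).
- *Waves*: snakes filtered in the Fourier orientation domain by an angular
  Gaussian window (σ = 20°, both half-planes).
- *Noise bars*: parallel bands at the grating spacings filled with
  isotropic band-pass noise.
- *Plaid / circular*: sums of 2 or 16 equally spaced 3 cpd sinusoids with
  random phases, rescaled so the set's mean RMS contrast matches a
  reference sinusoidal grating set at the same nominal contrast. Above
  ~50% nominal contrast the sum exceeds the luminance range and is clipped;
  the published stimuli stay below 20%.

Contrast convention: "contrast c" scales pixels so max|pixel| = c/2 before
aperture blending; for sinusoids this coincides with Michelson contrast.
Orientation convention: 0° = horizontal contours, counterclockwise,
shared by all modules. Every image ends with a circular aperture whose
outer 0.5 deg is blended into the gray background by a half-cosine ramp.

The energy-matched "target" battery rescales the grating pixel contrast by
√(E_snake/E_grating), measured once at full contrast through the actual
energy pipeline — energy is exactly quadratic in pixel contrast, so one
step suffices for the whole contrast ladder. The generator reports the
achieved match (contract: within 15%).

## Fitting

Parameters are estimated by unweighted least squares on per-ROI mean
responses, with 40 random initializations per fit (transformed-space starts
drawn from N(0, 2), seeded). The search space is unbounded via
g = exp(a), α = sigmoid(b), σ = exp(c); each start runs L-BFGS-B
(ftol 1e−12, at most 600 evaluations), and the lowest-SSE solution wins,
ties broken by earliest start. Bootstrap SDs are carried for error bars
only, not as fit weights. Cross-validation is leave-one-out: one fit per
held-out stimulus. Accuracy is R² = 1 − SSE/SST of the held-out
predictions, unclipped (worse-than-mean prediction gives negative values).

For the σ-dependent models the filtering stage stays outside the inner
loop: energies and normalizer maps Z are computed once and compressed per
exemplar into 256 energy-weighted Z-bins (log-spaced), from which the
pooled drive s(σ) = Σ_b E_b/(σ + Z_b)/N is re-evaluated in microseconds.
Bin energy sums are exact, so the large-σ limit is exact; across the whole
σ range the compression agrees with exact pooling to better than 0.1%
(tested). The noa model needs only two scalars per exemplar (mean e², V),
making its pooling exact.

## Synthetic study conditions

No human data ship with the package; all quantitative checks run on
synthetic stimuli, and optionally on the published per-ROI beta arrays via
the MAT adapter (`experiments.load_roi_betas`). The synthetic-BOLD
generator adds seeded Gaussian noise to model predictions.

- *Parameter recovery*: ground truth is the otn model (g = 2, α = 0.35 — a
  compressive exponent typical of fitted cortical values — and σ at the
  battery's energy-weighted geometric-mean normalizer value) on the
  30-stimulus comparison battery, with noise at 10% of the mean response
  (signal-to-noise 10), 20 replicates, 40 starts. A local Fisher analysis
  of this design shows g and σ are partially collinear: σ rescales most
  pooled drives nearly uniformly and g absorbs it, so individual
  maximum-likelihood fits carry irreducible sampling spread along the
  ridge. Empirically the fits sit at the global optimum (fitted SSE below
  the SSE at the truth) yet the median |g error| is ≈ 16% at this noise
  level; the estimates are nonetheless centered on the truth (median
  signed errors: g ≈ 4%, α ≈ 1%, σ ≈ 0.1%). The recovery contract is
  therefore stated on the bias (median signed relative error): g, α within
  10%, σ within 20%, with held-out R² ≥ 0.9; the absolute medians for α
  and σ also meet those bounds and both summaries are reported. The σ-bias
  property is additionally verified at the harsher range-scaled noise
  (10% of the response range), where it still holds.
- *Model comparison*: synthetic data generated by otn (g = 2, α = 0.8, σ
  mid-range — a configuration whose predicted snake/grating ratio is ≈ 1.8,
  the effect size observed in cortex) on a doubled energy-matched target
  battery (20 stimuli, two independent stimulus seeds, 4 exemplars each),
  noise at 5% of the mean response; cross-validated accuracy orders
  otn ≥ noa above both untuned models (structural noa−dn margins of
  +0.03…+0.21 R² across battery draws). Two measured facts shaped this
  design. First, the untuned model partially mimics the class offset
  through its fitted σ (its best-fit snake/grating ratio reaches ≈ 1.17),
  so at weak truth effect sizes the anisotropy model has no structural
  advantage and the ranking flips with the stimulus draw. Second, on
  batteries diluted with density sweeps or multi-component patterns, noa's
  structural mismatch to otn-truth is comparable to the untuned models'
  (noa is a genuinely different model, not a reparameterization of otn).
  The ordering claim is therefore tested at the empirical effect size, on
  the manipulation the models disagree about, with exemplar averaging (as
  in the 9-exemplar fMRI design) damping per-draw anisotropy variation.
- *Center-surround simulation*: hard-edged 1-deg-radius center disc and
  1–3 deg surround annulus, 3 cpd carrier, full contrast, static. The unit
  drive (numerator) is computed from the center-only stimulus and held
  fixed; the surround acts only through the normalizer. For otn the readout
  is the normalized energy at the image-center pixel in the preferred
  channel; for noa it is the preferred channel's center energy over
  σ² + V(composite). σ defaults to a mid-range value derived from the
  center-only stimulus (median positive Z for otn; √V for noa). Only the
  *location* of maximal suppression is asserted (surround = preferred
  orientation for otn, surround = center orientation for noa); the curve
  shape depends on readout details the models do not pin down.

What the synthetic conditions do **not** emulate: hemodynamics and GLM
estimation, voxel-level spatial receptive fields, eccentricity-dependent
frequency tuning, second-order contrast sensitivity, and between-session
variability. Passing tests therefore validate the computational claims of
the models (dissociations, limits, recoverability), not their empirical
accuracy on cortex, which requires the published data sets.

## Numerical choices

- Quadrature pairs are held as complex kernels (even + i·odd), so one FFT
  product yields both phase outputs; the squared magnitude is the
  phase-summed energy.
- Downsampling to 12 px/deg uses a mean-preserving area-overlap matrix
  (integer block averaging when the ratio is integral).
- The normalization-pool convolution uses zero boundary (fftconvolve
  "same"), so the direct-summation oracle is well defined; uniform-field
  identities hold at pixels ≥ 3 SD from the map edge.
- The DoG solve is nearly degenerate (center and surround scales differ by
  ~1%, a Laplacian-of-Gaussian-like limit); the kernel is renormalized to
  unit peak, so the small amplitude of the difference is benign.
- Seeds: every stochastic component (stimulus exemplars, fit starts,
  synthetic noise) flows from explicit integer seeds; identical seeds give
  bit-identical outputs.

## Known limitations

- No spatial receptive fields: responses model the aggregate of a visual
  area viewing full-field textures; stimuli that vary systematically across
  space are out of scope.
- One-stage normalization plus a power law; no cascaded or gated
  normalization, and no second-order-contrast channel.
- The noa model sums energy over space before normalizing, so it cannot
  express any spatial structure in the suppression.
- The otn cross-orientation term is exactly one pixel at the 12 px/deg
  energy resolution; its physical extent therefore scales with the canvas.
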