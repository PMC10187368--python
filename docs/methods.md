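# Methods

This note documents the physical models, numerical choices and evaluation
protocol implemented in `xstrack`, including the places where the design was
genuinely open and what the package chose.

## Wave-optics image formation

The imaging chain is a monochromatic 30 keV point source (10 μm focal spot),
a diffuser 1 m downstream, an optional sample, and a detector at 3 m with
12 μm pixels.  The wavefield is a complex scalar on a regular grid
(micrometre units throughout); free-space propagation uses the exact
angular-spectrum transfer function exp(i2πz√(1/λ² − f²)), with evanescent
components decayed.  Before each propagation the field is edge-padded by 25%
per side to suppress FFT wrap-around, and the propagation distance is checked
against the sampling bound z ≤ NΔ²/λ of the padded grid (an `AliasingError`
names the violated bound).  Unpadded propagation is exactly unitary — total
intensity is conserved to machine precision — which the test suite asserts at
1e-10 relative, along with reciprocity (z then −z) at 1e-8 and agreement with
a direct Fresnel-integral quadrature oracle for a 100 μm slit at 1e-3
relative.

**Divergent beam.**  The cone-beam geometry is mapped to an equivalent
parallel-beam system by the Fresnel scaling theorem: the simulation runs at
the diffuser plane with effective distance z_eff = z₁z₂/(z₁+z₂) (= 2/3 m for
1 m / 3 m) and the output grid is read as magnified by M = (z₁+z₂)/z₁ = 3.
The simulation grid is 4× finer than the detector pitch at the detector
plane (3 μm, i.e. 1 μm at the object plane); the oversampling factor is
configurable.

**Objects.**  Thin objects enter in projection approximation: the amplitude
is multiplied by exp(−μt/2) and the phase advanced by −2πδt/λ, with
projected thickness t(x, y) in μm.  δ and μ at 30 keV are taken from a small
embedded table (Al₂O₃, the C₆H₁₀O₅ backing, PMMA), computed from
r_e λ² n_e / 2π with bulk densities and NIST mass-attenuation values; the
tests cross-check δ against an independent electron-density computation.

**Diffuser.**  Each of the 10 sandpaper layers is a random rough surface of
Al₂O₃ — white noise low-pass filtered by a Gaussian of the grain FWHM and
scaled to an RMS roughness — on a uniform 200 μm backing.  Layers are
separated by 200 μm and propagated between.  The source literature does not
give the surface statistics, so both grain FWHM and roughness are exposed in
`DiffuserSpec`.  The default roughness follows 0.22·g^1.35 for grain FWHM g:
coarser grit has taller grains, and the slightly superlinear exponent keeps
the near-field speckle visibility approximately flat (0.25–0.40) across the
grain sweep — with constant roughness the deep-near-field contrast
(∝ z·δ·σ_h/g²) fades for coarse grains and the stated minimum 20% visibility
cannot hold across the full 2–10 px speckle-size range.  The grain sweep
8–50 μm spans detector-level speckle autocorrelation FWHMs of ≈2.3–9 px
(28–108 μm), and both visibility-vs-grain and FWHM-vs-grain behaviour are
asserted as trends in the tests.

**Detection.**  The detector takes |amplitude|², blurs with a Gaussian PSF of
σ = 1/2.355 detector pixels (FWHM ≈ 1 px, reading the stated "PSF of 1/2.355
pixels" as σ), combines in quadrature the magnified focal-spot blur
(10 μm × z₂/z₁ = 20 μm FWHM at the detector), and averages over pixel bins.
No noise is added at detection; noise lives in the augmentation stage.
Coordinates are row-major, x = column rightward, y = row downward, 0-based
pixel centres.

## Deformation, attenuation, noise

Random piecewise-smooth displacement fields tile the image with independent
patches (4–128 px).  Within a patch each component is bilinear between four
random corner magnitudes sharing a single per-patch sign ("smooth in only one
direction"); patches do not share corners, so fields may jump at patch
boundaries while being linear inside.  Pooled over draws the values are
symmetric about zero and bounded by ±1 px.  Special kinds (identity, constant
x / y / both, within ±0.15 px) make up ~2% of generated datasets, split
evenly, mirroring the published dataset composition (the published train
count 21841 is treated as an off-by-one of 364×60; the builder records actual
counts in its manifest).

Warping applies sample(x) = reference(x − u(x)) by inverse mapping with cubic
spline interpolation and edge extension at borders; a numerically zero field
short-circuits to an exact copy.  Transmission maps reuse the patchwise
bilinear construction (fresh seed, no sign constraint) with values in
[0.5, 1.0].  Poisson noise scales an image so its mean equals the configured
photon fluence, samples, and rescales; reference and sample always receive
independent draws.  The fluence is never stated in the source literature; the
package default is 10⁴ photons/pixel (≈1% shot noise on the mean), recorded
in every report.

## Classical trackers

Both trackers compare, densely at every pixel, a (2M+1)² window of the
sample against the reference displaced by integer shifts within ±3 px
(search radius), then refine to sub-pixel.  Default M = 15 (31×31), the
mid-range of the published 10–50 px window sweep; the headline-figure window
is not stated in the source, so every report records the window used.
Windowed sums are separable box filters (a Hamming taper is available;
uniform is the default since the ZNCC formulation subtracts plain window
means), making the cost volume O(shifts × pixels).

- **ZNCC** maximizes the zero-normalized correlation of mean-subtracted
  windows and refines per axis with a 3-point log-Gaussian fit
  δ = (ln c₋₁ − ln c₊₁)/(2(ln c₋₁ − 2 ln c₀ + ln c₊₁)), clamped to ±0.5.
  Correlation triples are lifted by 1 + 1e-6 only when not already positive,
  so the closed-form identity on sampled Gaussians holds exactly.
- **UMPA** minimizes Σw(I_s − T·I_r(x+u))² with the scalar transmission
  solved in closed form per shift (T = ⟨I_sI_r⟩/⟨I_r²⟩) and refines with a
  least-squares paraboloid fit on the 3×3 cost neighbourhood (stationary
  point of the fitted quadratic, positive-definite Hessian required,
  clamped to ±0.5).  Sub-pixel refinement operates on the integer-shift
  cost surface; the cost is never re-evaluated at fractional shifts.

Ties in the integer search go to the smallest |shift|, then lexicographic.
Border pixels within M + search_radius are invalid; flat windows (zero
variance) and singular T-solves are invalid, not exceptions.  A numerically
perfect integer match (correlation ≈ 1, or zero UMPA residual) is not
refined: the 3-point interpolators are only unbiased for symmetric peaks,
and refining a perfect match injects a spurious ±0.03 px offset from the
asymmetry of the local speckle autocorrelation.  This micro-bias of the
estimators is also why tracking at exactly zero displacement reports nonzero
RMSE on noisy images.

## CNN tracker (CADE)

The network is an encoder-decoder optical-flow architecture: ten feature
convolutions (kernels 7, 5, 5 and seven 3s; strides 2,2,2,1,2,1,1,1,1,1 —
four down-samplings) followed by a decoder with four up-samplings built from
eight 4×4 stride-2 transposed convolutions (four feature deconvs, four flow
up-samplers) and five 3×3 prediction convolutions emitting displacement
estimates at 1/16, 1/8, 1/4, 1/2 and full resolution, with encoder skip
connections at matching scales.  Leaky ReLU (slope 0.1) follows feature and
deconv layers; prediction layers are linear.  Channel widths follow the
published StrainNet-f widths scaled by `base_width`/64.  Inputs are the
reference and sample stacked as two channels, each standardized to zero mean
and unit variance (the source does not state its normalization; the choice is
recorded in checkpoints and makes predictions exactly invariant to affine
intensity changes).  The output is scaled by a constant div_flow = 2 (the
FlowNet convention for sub-pixel targets; the source's remark about dividing
the flow every 40 epochs conflicts with that convention and is implemented as
the constant scaling).

Training minimizes the multiscale endpoint-error loss — the weighted sum of
mean EPE at the five scales, weights [0.005, 0.01, 0.02, 0.08, 0.32]
coarsest first, truth average-pooled per scale — with Adam (lr 1e-3,
β = 0.9/0.999, weight decay 4e-4 on weights, none on biases) and learning
rate halved at each milestone.  The full-fidelity configuration
(`FULL_NETWORK`, `FULL_TRAIN`: base width 64, 350 epochs, batch 16,
milestones 40…240, 364×60 training pairs) is expressible and recorded but
is a multi-day run; the desk-scale mode (`SCALED_NETWORK`, `SCALED_TRAIN`:
base width 8, 300 epochs, batch 2, milestones 220/270) trains on the 8-pair
64×64 fixture set in ≈2 minutes and reaches train EPE < 0.10.  Small batches
matter at this scale: full-batch training performs one Adam update per epoch
and converges far more slowly per unit compute.  The fixture training fields
use the smoothest patch size (one bilinear patch per image) so the sanity
check probes optimization rather than memorization capacity.  Everything —
initialization, shuffling, training — is seeded; the network, its
convolutions (im2col matrix products) and the reverse-mode gradient tape are
implemented directly on numpy, and the gradients are verified against finite
differences in the tests.

## Evaluation protocol

**Accuracy.**  Ten independently simulated 256×256 references are warped by
constant maps 0→1 px (step 0.1, along x), then 90% uniform transmission and
Poisson noise are applied to each pair.  Per pair the relative bias
(u_GT − mean u)/u_GT and per-component RMSE are computed over the tracker's
valid mask.  Bias is undefined at the 0 px point (excluded; RMSE still
reported).  Headline numbers are the grand means over shifts and references;
the headline bias is reported in pixels (|u_GT − mean u|, i.e. the relative
bias times the shift), the scale on which the reference values are printed.

**Spatial resolution.**  The star displacement map is a unidirectional
sinusoid of constant 0.5 px amplitude whose local wavelength shrinks
linearly from 200 px at the right edge to 4 px at the left (endpoints are a
package choice; the source prints none).  After tracking, the row-averaged
profile is fitted column-by-column against the known quadrature carrier in a
sliding one-period window, giving a recovered amplitude and hence a bias
profile vs wavelength; the profile is moving-averaged over one tenth of the
wavelength span and scanned from long to short wavelengths for the first 10%
crossing.  A windowed tracker cannot resolve below the box-average bound
sin(πW/λ)/(W sin(π/λ)) = 0.9 → λ ≈ 124 px for W = 31, and the measured ZNCC
crossing sits essentially at that bound; at a 15 px window the ZNCC crossing
is ≈66 px.  The window-resolution relationship is mapped explicitly by
`window_sweep`.

**Noise sweep.**  "Loss of x% SNR" maps to fluence·(1 − x/100)² via
SNR ∝ √fluence (the mapping is a package choice).  Levels are coupled by
sequential binomial thinning of a single photon-count realization, so moving
along the sweep only removes photons and the monotone error trend is
testable above Monte-Carlo variance.

**Timing** is wall-clock per tracker per image size with a linear fit in
pixel count — environment-relative, logged rather than asserted.

## Phantom validation

The phantom is a 1500 μm wide PMMA band with projected thickness
t = b + A sin(wx), b = 1000 μm, A = 800 μm, w = 1.33×10⁻³ μm⁻¹; the sine's
phase origin sits at the band's left edge (unstated in the source; this
choice lets the thickness attain its b + A = 1800 μm crest inside the band
and gives the refraction profile peaks of both signs).  The sample sits at
the diffuser plane, so the sample-to-detector distance is d = 2 m and
phantom coordinates magnify by 3 onto the detector.  The analytic refraction
is α_x = −δAw·cos(wx) (0.315 μrad peak for PMMA at 30 keV) and the chain
thickness → projection phase → gradient → α is verified to 1e-6 relative.
Note the printed reference profiles reach ±2 μrad, ≈6× the value the stated
parameters and a standard PMMA δ give; the package reports both the analytic
and the tracked values and does not adjust δ.  Tracked displacement maps are
compared with the analytic ground truth over the band interior, excluding a
24-px margin at the band edges where the thickness discontinuity produces
ground-truth spikes of many pixels that no ±3 px search can follow (with the
edges included the RMSE is dominated entirely by those columns).  The
modulation period is estimated from the all-row-averaged profile by a
quadrature frequency scan without an offset term — the band spans only a
third of a period, where a free offset would make the frequency
unidentifiable — and lands within 2% of 2π/w.

## What the synthetic data does and does not show

The simulator reproduces the statistical structure that matters for
tracking: near-field speckle of controllable size and ≥20% visibility,
partially developed from a multi-layer phase diffuser in a magnifying
geometry, plus sub-pixel deformations, patchwise attenuation and shot noise.
It does not model polychromatic spectra, partial coherence beyond the
source-size blur, detector electronic noise or crosstalk, scatter/dark-field
signal, or sample-dependent speckle decorrelation.  Passing results
therefore demonstrate the correctness and relative behaviour of the
trackers under controlled conditions, not their absolute performance on
experimental data.

## Problem sizes

Desk-scale defaults keep every run on one CPU core: 10 reference images at
256², star and noise sweeps on the same references, the phantom at 512² with
4× oversampling, and the scaled CNN mode above.  The full-fidelity dataset
(364 references, 60+10 deformations each) and training configuration are
expressible through the same interfaces.
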