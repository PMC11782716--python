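# Methods

This note records the models implemented in `smscine`, the assumptions they
make, the defaults and why, and what the synthetic experiments do and do not
establish.

## Acquisition model

**Spiral trajectory.** Readouts are uniform-density Archimedean spirals,
`r(θ) ∝ θ`, reaching `kmax = 1/(2·resolution)` with constant angular sample
density. Only the sample coordinates enter the reconstruction; gradient
waveform design, slew limits, moment nulling and trajectory-error correction
are out of scope — the package accepts already-corrected coordinates.
Successive arms rotate by the 2D golden angle 360·(1 − 1/φ) ≈ 137.508°
(configurable), the standard choice for real-time imaging because any
contiguous window of arms covers azimuth near-uniformly. The
fully-sampling arm count `n_arms_full` sets the radial turn spacing to
`n_arms_full/fov`, so that many uniformly rotated arms meet the 1/fov
Nyquist spacing; the default fixture uses `ceil(matrix/4)` arms (about two
turns per arm), a typical few-turn design — the scanner's actual count is
not modelled.

**Frame binning.** Real-time frames are fixed-duration windows of
consecutive arms: `arms_per_frame = floor(frame_duration/TR)`, default
45 ms, giving 6 arms/frame at the 6.6 ms SMS TR and 8 at the 5.3 ms
single-band TR. A trailing group that does not fill a frame is dropped so
every frame has identical temporal resolution.

**SMS encoding.** Simultaneous slices are phase-tagged per excitation with
the cyclic blipped-CAIPI schedule `Φ[s, a] = exp(2πi·s·a/N)`; over one cycle
the table is a scaled DFT matrix (unitary), which is what makes the
simultaneous slices separable. The exact scanner schedule is not published;
the table is configurable.

## Phantom and simulator

The phantom is analytic per slice: a chest ellipse, an epicardial ellipse, a
contracting endocardial ellipse (blood), and papillary-muscle discs that
ride at a fixed fraction of the endocardial radius. Rasterization uses 4×
supersampled box averaging, so tissue edges carry realistic partial volume.
Contraction scales the endocardial semi-axes by
`1 − contraction_fraction · w(phase)` with `w(phase) = sin²(π·phase)`
(smooth, zero at end-diastole, maximal at end-systole; configurable). The
cardiac clock is a cyclic list of beat durations; an irregular (PVC-like)
beat is simply a longer entry.

There is no Bloch/steady-state simulation: tissue intensities are
prescribed directly because the evaluation pipeline operates on signal
intensities, not spin physics. Defaults (stated once): blood 1.0,
myocardium and papillary 0.10, chest 0.05 — a strongly blood-weighted
balanced-SSFP-like contrast in which the endocardial edge dynamic range is
dominated by blood. The inflow-saturation penalty of multi-band excitation
is emulated by a single factor, `sms_blood_attenuation = 0.5`, applied to
blood in SMS simulations; this value is the stated construction that
reproduces the ~2-fold single-band-to-SMS contrast gap.

k-space is simulated arm-wise: arm `a` samples the phantom frozen at
`t = a·TR` (the 2.7 ms readout is far below the cardiac motion scale).
Complex Gaussian noise of known σ is added i.i.d. per sample and coil; the
RNG is fully determined by the seed. Coil maps are smooth complex Gaussian
lobes on a circle around the FOV (12 coils by default, six anterior + six
posterior), normalized to unit root-sum-of-squares so that coil combination
preserves the intensity scale. Ground truth (coil maps, σ, seed, geometry)
is stored in a `/truth` group of the HDF5 container.

The default experiment noise level targets a blood-to-noise ratio of 50 on
the Nyquist-rate gridded reference, the level implied by published
normalized-contrast magnitudes of order 30 (≈ 0.6 × SNR); it is computed
analytically from the density-compensation weights, not tuned.

**What the phantom does not model:** respiration, flow jets, fat/chemical
shift, off-resonance blurring, metal artifacts, through-plane motion, and
bSSFP banding. A green test on this phantom establishes correctness of the
pipeline's numerics and statistics, not robustness to those effects.

## NUFFT and density compensation

The non-uniform Fourier transform is a Kaiser-Bessel gridding transform:
2× oversampled FFT, width-8 kernel (Beatty shape parameter), numerically
exact deapodization, and a precomputed sparse interpolation matrix so the
forward and adjoint are exact matrix transposes of each other. Accuracy
against a direct non-uniform DFT is ~1e-7 relative — comfortably below the
1e-6 the tests require. Convention: the forward transform is the plain
complex-exponential sum over pixels (no FFT normalization); the
density-compensated adjoint therefore multiplies by the pixel area and by
DCF weights in (cycles/mm)², which lands gridding reconstructions on the
image's own intensity scale (so the STCR scaling factor C is directly
comparable to tissue intensity).

Three DCF methods are provided, all normalized to tile the kmax disc:
`radial` (|k|-proportional with an interior floor; the analytic choice for
uniform-density spirals), `voronoi` (cell areas clipped at the kmax disc via
a dense guard ring), and `pipe` (Pipe-Menon iterative equalization of the
kernel-convolved sampling density). **Pipe is the default for the weighted
data term and gridding**: for 6-arm frame subsets the radial floor
under-weights the densely-crossed k-space center, which makes the weighted
normal operator nearly singular at DC and the blood-pool scale converge
erratically; the Pipe weights keep the weighted normal operator close to
the identity at all scales.

## STCR

The reconstruction minimizes data consistency plus smoothed spatial and
temporal total variation. Numerical choices:

- **Operator scaling.** The data term is evaluated through a
  DCF-weighted operator (samples scaled by `pixel_spacing·sqrt(dcf)`, the
  same weighting applied to the data). The weighted normal operator is then
  approximately the identity, the initialization `A†Wd` *is* the gridding
  reconstruction, and the relative weights balance directly against image
  intensities. On noiseless consistent data the weighting does not move the
  data-consistent solution.
- **Regularization.** `λt = 0.05·C`, `λs = 0.005·C` with `C = max |A⁻¹d|`,
  where `A⁻¹` is interpreted as the density-compensated adjoint (A has no
  literal inverse; this is the standard reading in the constrained-
  reconstruction literature). C is computed per dataset (per SMS slice set)
  before iterating. The smoothing constant is `ε = 1e-8·C²` (scale-adjusted
  so the TV limit is approached identically at any intensity scale).
- **Optimizer.** Fletcher-Reeves NCG, restart every 30 iterations, Armijo
  backtracking (sufficient decrease 1e-4, shrink 0.5) with the initial step
  from a quadratic fit of the data term along the search direction — the
  data term is exactly quadratic, so backtracking re-evaluates only the
  (cheap) regularizer. Default 60 iterations or relative gradient norm
  below 1e-6; the cost is non-increasing across accepted steps by
  construction and the per-iteration log (cost, gradient norm, step) is
  stored in the output provenance. Iteration count, NCG flavor and
  line-search constants are not published; all are configurable.
- **Finite differences.** Forward differences with replicate (Neumann)
  boundaries in x, y and frame; no temporal wrap-around.
- **Degenerate inputs.** Zero data returns a zero series; NaN/Inf in the
  iterate raises; a failed line search returns the last accepted iterate
  with a warning status in the provenance rather than raising.

Coil maps come from the simulator's ground truth when the container carries
it, otherwise from Walsh estimation (per-pixel dominant eigenvector of the
7×7-block-averaged coil covariance of the time-averaged gridding images,
unit-norm, phase-referenced to the strongest coil). Whether the original
study calibrated on single-band or SMS data is unstated; both routes are
available.

## Evaluation

Segments: the reference line bisects the septum (the S8/S9 boundary); its
60° and 120° rotations complete three diameters that cut six 60° sectors,
labelled in the AHA mid-cavity order around the ring, so that rotating
image and reference together never permutes labels. Per segment, 50 radial
lines at uniform angular spacing cross the endocardial ellipse, extending
6 mm inside and outside the border (line length is not published;
configurable). Profiles are sampled bilinearly at native resolution and
cubic-interpolated to a 100× finer grid.

The sigmoid is the 4-parameter logistic; its functional form is not
published, and a logistic slope is the standard edge-response model. Fits
are bounded least squares (amplitude within 3× the profile range, slope
bounded at the native-sample scale) with multi-start: unbounded logistic
fits on noisy near-linear profiles diverge (amplitude → ∞ as slope → 0).
A fit is invalid when the amplitude is below 20% of the profile range or no
start converges; invalid lines are excluded and counted, and a segment with
more than half its lines invalid is flagged. ES is |s| in 1/mm — reversing
a profile flips the sign of s but not the score.

**I20/I80 convention.** The published definition reads "the 20%- and 80%-
of the maximum signal intensities", i.e. fractions of the fitted *maximum*:
`I80 − I20 = 0.6·max(fitted)`, which is the default here and which makes
the 2-fold contrast gap follow directly from halving the blood signal. The
alternative range-based reading (`0.6·|b|`, a blood-myocardium difference)
is available via `contrast_convention="range"`.

σ is the standard deviation of the gridded-reference magnitude over a
background region, rescaled by the ratio of mean LV-blood intensity between
the iterative and gridded series. Two implementation points: the noise
reference for SMS data is the slice-resolved (CAIPI-conjugate) 144-arm
adjoint, so the blood rescaling refers to the same slice as the evaluated
series; and the background region is everything outside the chest ellipse
rather than small corner boxes — gridded noise is spatially correlated, and
a small region makes the σ estimate itself noisy at the ±20% level (the
original study's manual "avoiding tissue signal and residual artifact" ROI
plays the same role).

Phase selection on synthetic data: end-systole is the frame maximizing the
contraction waveform, mid-diastole the frame nearest phase 0.8 of the beat;
on external data frame indices are supplied in the geometry sidecar.

The pipeline's SMS-vs-SB comparison uses a two-sided Mann-Whitney U test
per segment and phase across line-level values, FDR-controlled with the
in-package Benjamini-Hochberg step-up at q = 0.05. (The original analysis
used a hierarchical Poisson GEE model, an off-the-shelf fit that is out of
scope here; only the BH procedure is part of the package.)

The AVG row averages the six segment means (not the pooled lines) — with
equal per-segment line counts the two differ only through invalid-fit
exclusions.

## Known limitations

- The NUFFT is CPU/numpy; at the published matrix size (112×112, ~330
  frames) reconstruction takes tens of minutes rather than the seconds of a
  GPU implementation. Tests and the acceptance script run at 64×64.
- Walsh calibration from heavily undersampled SMS data inherits aliasing;
  ground-truth maps are preferred for fidelity studies.
- The contrast ratio of the paired experiment inherits a few-percent bias
  from residual SMS aliasing entering the blood-pool rescaling of σ; at the
  desk scale it lands within ~10% of the constructed value of 2.
- Converters for scanner raw-data exports are not included; the HDF5
  container is package-native.
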