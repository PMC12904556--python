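# Methods

`octstitch` computationally combines the spectra of two (or more)
sequentially sweeping swept-source lasers into one broadband spectrum for
full-field Fourier-domain OCT (FF-FD-OCT). This note records the signal
model, the estimation procedures, the numerical conventions, the choices
made where the design was genuinely open, and the limits of what the
synthetic tests demonstrate.

## Signal model and conventions

A swept source tunes its wavenumber nonlinearly in time ("chirp",
`k(t)`), while an area camera records one interferogram frame per time
point. After DC removal, the detected signal at one lateral position is

    I(t) = S(k(t)) * alpha(k(t)) * ∫ eta(z) cos[2 k(t) z + phi(k(t))] dz
           + b(k(t)) + noise,

with `S` the source envelope, `alpha` the interference contrast,
`b` the incoherent ASE background, `eta` the scattering potential and
`phi` a spectral phase collecting dispersion mismatch and axial bulk
motion.

Units and depth axis, used consistently everywhere:

* wavenumbers in rad/nm (`k = 2*pi / lambda_nm`), depths in micrometres of
  air path;
* under the `cos(2 k z)` fringe convention, a uniform spectrum of `N`
  pixels with spacing `dk` has depth pixels `pi / (N dk)` and a Nyquist
  depth `pi / (2 dk)`;
* the depth reconstruction is the *forward* orthonormal FFT along k, so a
  fringe `exp(i 2 k z)` appears at `+z`; Parseval holds exactly for
  unapodized spectra;
* decibels are intensity ratios, `20 log10` of magnitude; the "-6 dB
  FWHM" is the magnitude half-maximum width. For a rectangular spectrum
  of span `dk0` it equals `1.21 pi / dk0`, with a first sidelobe at
  -13.26 dB.

## Forward simulator

The simulator generates raw frame stacks with complete ground truth, so
every estimator can be verified by closure. Default study conditions
mirror a dual-laser retinal instrument: one source sweeping 805–882 nm
over 515 camera frames and one sweeping 879–950 nm over 478 frames
(~3 nm of shared range), sweeping in the same direction with an
(informational) 74-frame switching gap.

* **Chirp**: parametric monotone shape functions — linear, polynomial
  (default: a 10–12% quadratic bow with a small cubic term, opposite
  signs for the two lasers), or sinusoidally perturbed. The sweep-rate
  variation is kept below ~18% so mirrors up to 80% of the uniform-grid
  Nyquist depth never alias locally.
* **Envelope/ASE**: contrast `alpha(k) = 1 - (1 - floor) * edge_ramp(k)`
  with a raised-cosine ramp over a configurable edge fraction (default
  8% of the sweep, floor 0.7), plus an additive background
  `b(k) = b0 * edge_ramp(k)` (default 0.3 of the fringe amplitude). This
  makes `alpha` the literal ground truth for the contrast estimator.
* **Phantoms**: single mirror, fixed layers, or a tissue-like volume with
  independently random scatterer depths/amplitudes at every lateral
  position (lateral decorrelation is what makes the scattering-mode
  envelope estimator and frame-mean background removal work).
* **Disturbances**: polynomial spectral phase in the normalized detuning
  `u = (k - k0)/(span/2)` (orders >= 2), a per-volume axial displacement
  applied to all lasers of that volume (phase `2 k dz`), a constant phase
  offset per sweep (fixed or uniformly random), and additive white
  Gaussian detector noise. No shot noise or speckle statistics are
  modelled.
* **Margins**: `margin` frames at each sweep end lie outside the nominal
  wavelength range (modelling trigger jitter) and are marked for
  discarding; the retained frames span the nominal endpoints exactly.

Determinism: all randomness flows from one integer seed.

## One-time calibration

1. **Trimming.** A configurable number of frames (default 8 per end) is
   discarded at the sweep start/stop.
2. **Chirp determination.** All A-lines of a single-mirror sweep are
   averaged; the analytic signal is formed by a Hilbert transform along
   the frame axis, band-filtered around the fringe carrier's support
   (0.4x the lower to 1.8x the upper support edge; removes residual ASE
   background), and its unwrapped phase — `2 k(t) z0` up to a constant —
   is rescaled affinely to the laser's nominal endpoint wavenumbers. The
   discarded margins are cosine-tapered to zero *before* the Hilbert
   transform; this suppresses the finite-fringe spectral leakage that
   otherwise ripples the phase by several milliradians and dominates the
   error budget. Only the relative nonlinearity is physically determined;
   the nominal-endpoint anchoring is a convention shared with the overlap
   value. With it, chirp recovery errors stay below 0.01% of the span in
   noiseless closure tests (tolerance 0.1%).
3. **k-linearization.** The common pixel size is
   `dk = span_ref / (N_ref - 1)` of the first (reference) laser, leaving
   it essentially unresampled. Each A-line, known at the nonuniform nodes
   `k(t)`, is expanded by least squares in a basis of below-Nyquist depth
   fringes `exp(i 2 z_j k)` and evaluated on the uniform grid — the
   inverse-NUFFT/gridding view of resampling, exact for noiseless
   depth-limited signals (for an already-linear sweep the basis contains
   the DFT vectors and the fit is the identity). A cubic-spline resampler
   is provided as a documented fallback; both meet the 1%
   instantaneous-frequency flatness contract. Requested upsampling beyond
   4x is refused.
4. **Envelope/contrast.** Scattering samples: `Gamma(k)` is the sum over
   lateral positions of the analytic-signal magnitude (a raw `|I|`
   variant is available behind a flag); reflecting samples: the analytic
   signal is filtered in the depth domain to isolate one surface (a
   window containing two resolved surfaces is rejected — their
   interference would modulate the estimate). `alpha = Gamma /
   max(smoothed Gamma)`; the lightly smoothed maximum keeps narrow edge
   artifacts from skewing the normalization, and `alpha` is floored at
   0.05 and capped at 1. Data are corrected by pointwise division.
   Accuracy caveat: with a hard depth window and a surface at a
   fractional depth bin, truncation leakage ripples the estimate by a few
   percent near the sweep ends; on exact depth bins the estimator is
   exact to 1e-6.
5. **Overlap determination.** The two k-linearized, laterally averaged
   spectra from one mirror depth are zero-padded to the common length
   `N_m + N_{m+1}` (spectrum m in the lower block, m+1 in the upper; the
   padding prevents circular correlation), cross-correlated via FFT with
   the spectral product zero-padded 99x (0.01-px lag resolution), and
   normalized by the regularized magnitude
   `max(|R|, 1e-3 max|R|)`. A single depth gives the periodic curve
   `cos(2 dk z (lag + kappa))`; summing the curves from several
   pairwise-distinct, non-harmonic depths (near-integer depth ratios
   trigger a warning) makes them add constructively only at the true
   overlap. The estimate is the argmax restricted to
   `[0.25, 4] x kappa_nominal` (from the nominal wavelength ranges), with
   ties broken toward the nominal value and boundary hits flagged.
   Residual shallow-depth content (ASE leftovers) is removed by a 5%
   depth high-pass before correlating. Noiseless recovery is exact to
   0.01 px in the controlled setting and to ~0.02 px through the full
   chirped pipeline; six depths suffice.

The overlap convention: `kappa` is the inclusive pixel count of the
shared wavenumber interval, `(k_stop_low - k_start_high)/dk + 1`; grids
need not be commensurate — fractional values are carried exactly.

## Reconstruction

Per volume and laser: background subtraction (per-pixel temporal mean, a
supplied reference sweep, and/or the per-frame lateral mean for laterally
diverse samples), contrast correction, k-linearization with the stored
calibration, then:

* **Motion/dispersion phase (orders >= 2).** Polynomial spectral phase in
  `u` is estimated by minimizing the sharpness metric
  `S = sum |U|^gamma`, `gamma = 1.4`, of the 4x zero-padded
  reconstruction (Powell, started at zero). An injected quadratic is
  recovered to 2%, and a blurred PSF is restored to within 5% of its
  clean width. Known limitation: on deterministic few-layer scenes the
  metric weakly prefers a small odd-order phase (~0.1 rad), with
  negligible PSF impact; it behaves best on structured (speckle-like)
  volumes, its intended regime.
* **Registration.** Volumes of each laser are registered to that laser's
  first volume via a magnitude-weighted fit of the cross-spectrum phase
  slope (subpixel-exact on a shared grid) and deramped by
  `exp(-i 2 k dz)` on the absolute wavenumber grid, which also removes
  the displacement's constant-phase contribution. A cross-laser
  estimator (depth-magnitude correlation on a common zero-padded axis) is
  provided, but the pipeline does not chain lasers through it by default:
  its subpixel noise injects phase tilts larger than the residual it
  would remove, and the remaining inter-laser constant is exactly what
  the phase search handles.
* **Phase-offset search.** For each lateral bin (default 25 x 25 pixels,
  edge bins truncated) the stitched local volume is reconstructed with 4x
  zero padding (at least 2x enforced, so sidelobes are visible) for 64
  trial phases in [0, 2 pi), followed by parabolic refinement on the
  periodic grid. The metric is made scale-invariant,
  `sum |U|^gamma / (sum |U|^2)^(gamma/2)`: a wrong phase destructively
  cancels energy in the blend region, and without the normalization that
  energy loss biases the raw metric's argmin. Bins without signal energy
  are filled from their neighbours and flagged; no smoothing across bins
  is applied by default. Noiseless recovery on layered scenes is within
  pi/32 over 100 random truths; with 5% noise the 95th percentile stays
  below pi/16. Calibration-target sessions from the stable interferometer
  are stitched directly at zero offset (`phase_search=False`).
* **Stitching.** The lower-k spectrum keeps its grid; the upper spectrum
  is moved onto it by an exact Fourier shift of the fractional part of
  `kappa` and placed at offset `N_m - ceil(kappa)`. Across the
  `ceil(kappa)`-pixel blend a linear ramp `w = (p - (N_m - kappa)) /
  kappa` (clipped to [0, 1], evaluated at pixel centres) weights
  `(1 - w) I_m + w I_{m+1} e^{i phi}`; `kappa = 0` degenerates to plain
  concatenation. Chains of three or more lasers stitch pairwise in
  ascending-k order.
* **Apodization and depth transform.** Optional Tukey window (ratio 0.5
  by default when enabled); the reconstruction is the forward orthonormal
  FFT along k with optional zero padding.

## PSF diagnostics

`psf_report` zero-pads the laterally averaged spectrum (>= 16x, default
64x), measures the -6 dB FWHM by linear interpolation of the magnitude
half-maximum crossings, and reports the highest local maximum on each
side of the main lobe beyond its first nulls, within +-15 FWHM, with
parabolic refinement. `theoretical_resolution` returns
`1.21 pi / dk0` in micrometres; an `n`-pixel sampled flat spectrum is
assigned the bandwidth `n * dk` when comparing (the measured discrete
constant is 1.2067, i.e. 1.21 at two decimals).

`error_sensitivity_sweep` re-stitches an ideal dual-laser mirror scenario
with injected errors: a constant phase on the second laser, an offset on
the overlap used for stitching, or — for amplitude — a residual contrast
notch at the seam (Gaussian, FWHM of four overlap widths) emulating
uncorrected ASE where the sweeps end. A uniform gain on one laser was
deliberately *not* used as the amplitude error: through the blend it acts
like a soft taper and lowers the first sidelobe while broadening the PSF,
which is not the degradation of interest. Reference behaviours: a pi/4
phase error raises the one-sided sidelobe by ~3 dB, growing monotonically
until the main lobe splits at pi; a 0.5-px overlap error is negligible at
shallow depth but raises the one-sided sidelobe by ~5 dB at 850 um (on a
~975-pixel combined grid), because an overlap error mislabels the second
laser's wavenumbers and the resulting seam phase jump `2 z dkappa dk`
grows with depth.

## Problem sizes and scope of validation

Tests and the acceptance script run desk-scale versions of the study
conditions: lateral fields of 1x1 to 48x48 pixels (the paper-scale
512x512 changes only averaging statistics), six calibration depths
log-spaced over 10–80% of the Nyquist depth with seeded jitter against
harmonic ratios, and full-length sweeps (515/478 frames). What passing
tests show: every estimator closes on the simulator's ground truth under
chirp, ASE, motion, phase offsets and Gaussian noise. What they do not
show: behaviour under real speckle statistics, camera nonidealities,
wavelength-dependent absorption, spatial-coherence effects, or trigger
jitter beyond the discard margins; lateral eye motion and computational
aberration correction are out of scope.
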