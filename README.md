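# octstitch

Phase-correct stitching of multi-laser swept-source OCT spectra.

Axial resolution in Fourier-domain OCT scales inversely with the
wavenumber span of the source: `Δz_FWHM = 1.21 π / Δk₀` for a rectangular
spectrum. Single swept lasers in the near infrared are limited to roughly
70–80 nm of tuning range (~5–7 µm resolution). `octstitch` implements a
computational framework that combines two (or more) sequentially sweeping
lasers with a small shared wavelength range into one broadband spectrum —
e.g. 805–882 nm plus 879–950 nm into an effective 145 nm sweep centred at
878 nm, with ~3.1 µm axial resolution in air — for full-field
Fourier-domain OCT, where an area camera records interferogram frames
while each laser sweeps.

The framework has three parts:

1. **A one-time calibration** from single-mirror sweeps at several depths:
   the nonlinear sweep `k(t)` of each laser is extracted from the
   unwrapped analytic-signal phase; all sweeps are resampled onto one
   uniform wavenumber grid with shared pixel size `δk` (a computational
   k-clock); the interference-contrast curve `α(k)` (lowered near the
   sweep ends by incoherent ASE) is estimated as the normalized envelope
   `Γ(k) = Σ_{x,y} |Ĩ(x,y,k)|`; and the fractional pixel overlap `κ`
   between adjacent lasers is found by summing the normalized
   cross-correlations `ρ_zₙ(k) = Re(R)/|R| = cos(2(k−κ)zₙ)` of padded
   mirror spectra over the depths `zₙ` — the sum peaks constructively only
   at the true overlap, to 0.01-pixel resolution.
2. **A per-measurement reconstruction**: background subtraction, contrast
   correction, k-linearization, removal of the motion/dispersion phase
   `φ(k) = φ(k₀) + φ′(k₀)Δk + O(Δk²)` (registration handles the linear
   term, a sharpness-metric optimization the higher orders), a per-bin
   grid search for the remaining constant phase offset minimizing
   `S = Σ|U|^γ` (γ = 1.4) of the locally stitched volume, and the
   phase-correct stitch itself with a linear amplitude blend across the
   overlap.
3. **PSF diagnostics**: −6 dB FWHM and sidelobe measurement, the
   resolution formula, and error-sensitivity sweeps (phase-offset,
   overlap, amplitude errors at the seam).

Because raw dual-laser data are not generally available, the package
includes a first-class forward simulator that generates chirped,
ASE-shaded, noisy frame stacks with full ground truth (chirp curves,
contrast, overlap, motion, phase offsets), so every stage is testable by
closure.

## Worked example

```python
import numpy as np
import octstitch as ox

# simulate a noiseless dual-laser mirror calibration (6 depths) and
# run the one-time calibration on it
session = ox.simulate_calibration_set(seed=1, n_depths=6, lateral_size=(2, 2))
calib = ox.calibrate_session(session.raw, session.lasers,
                             depths_um=list(session.truth["depths_um"]))
print(f"common dk      : {calib.dk:.4e} rad/nm")
print(f"overlap kappa  : {calib.kappa[0]:.2f} px "
      f"(ground truth {session.truth['kappa'][0]:.2f})")

# stitch every mirror acquisition and inspect the deepest one
result = ox.run_pipeline(
    session, calib,
    ox.PipelineConfig(bins=(2, 2), phase_search=False, registration=False),
)
stitched = result.stitched[-1]
span = 2 * np.pi / stitched.k_start - 2 * np.pi / stitched.k_stop
rep = ox.psf_report(stitched)
print(f"stitched span  : {span:.1f} nm over {stitched.n_k} px")
print(f"mirror depth   : {rep.depth_um:.1f} um")
print(f"-6 dB FWHM     : {rep.fwhm_minus6db_um:.2f} um "
      f"(theory {ox.theoretical_resolution(stitched.k_start, stitched.k_stop):.2f})")
print(f"sidelobes      : {rep.sidelobe_left_db:.1f} / {rep.sidelobe_right_db:.1f} dB")
```

prints

```
common dk      : 1.3683e-06 rad/nm
overlap kappa  : 18.32 px (ground truth 18.33)
stitched span  : 144.9 nm over 871 px
mirror depth   : 914.2 um
-6 dB FWHM     : 3.18 um (theory 3.19)
sidelobes      : -13.3 / -13.2 dB
```

i.e. the calibration recovers the inter-laser overlap to ~0.01 px, the
stitched spectrum spans the full 145 nm combined range, and a mirror at
914 µm reconstructs at the theoretical 3.2 µm resolution with sidelobes
at the −13.26 dB rectangular-spectrum limit.

## Command line

A thin CLI wraps the library:

```bash
octstitch simulate-calibration --seed 1 --n-depths 6 --out cal_session.h5
octstitch calibrate --session cal_session.h5 --out calib.h5
octstitch simulate-sample --seed 2 --n-volumes 3 --out sample.h5
octstitch reconstruct --session sample.h5 --calib calib.h5 \
    --bins 25 25 --pad 4 --gamma 1.4 --apodize tukey:0.5 --out recon.h5
octstitch psf-report --in recon.h5 --pad 16
octstitch error-sweep --kind phase_offset --steps 8 --depth-um 850
```

Sessions live in a single HDF5 file (one float32 dataset per laser and
volume plus a JSON manifest; simulator output carries a `/truth` group);
multi-page TIFF with a JSON sidecar is supported as an equivalent frame
format. Exit codes distinguish usage (2), schema (3) and numerical (4)
errors.

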