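"""Axial PSF diagnostics: resolution, sidelobe levels, error sensitivity.

The axial point-spread function of a Fourier-domain OCT system is the
depth-domain transform of its spectral envelope.  For a rectangular
spectrum of wavenumber span ``dk0`` the field PSF is a sinc whose full
width at half maximum of the *magnitude* (equivalently -6 dB of intensity)
is ``1.21 * pi / dk0`` and whose first sidelobe sits at -13.26 dB of
intensity.

Decibel convention used everywhere in this package: intensity ratios,
``10 log10(I / I_peak) = 20 log10(|U| / |U_peak|)``; the "-6 dB FWHM" is
therefore the magnitude half-maximum width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .calibration import AnalyticSpectrum, CalibrationError, depth_pixel_um
from .reconstruction import ReconVolume, stitch_spectra

__all__ = [
    "PSFReport",
    "theoretical_resolution",
    "psf_report",
    "psf_from_response",
    "error_sensitivity_sweep",
    "mirror_stitch_scenario",
    "StitchScenario",
]

RESOLUTION_CONSTANT = 1.21  # FWHM * dk0 / pi for a rectangular spectrum
DEFAULT_PSF_PAD = 64
MIN_PSF_PAD = 16
SIDELOBE_WINDOW_FWHM = 15.0  # search +- this many FWHMs around the main lobe


@dataclass
class PSFReport:
    """Width and sidelobe levels of one axial point response."""

    depth_um: float
    fwhm_minus6db_um: float
    sidelobe_left_db: float
    sidelobe_right_db: float
    pad_factor: int

    def __post_init__(self) -> None:
        if self.fwhm_minus6db_um <= 0:
            raise CalibrationError("FWHM must be positive")

    @property
    def worst_sidelobe_db(self) -> float:
        return max(self.sidelobe_left_db, self.sidelobe_right_db)


def theoretical_resolution(k_min: float, k_max: float) -> float:
    """Rectangular-spectrum axial resolution (um in air).

    ``k_min``/``k_max`` in rad/nm; returns ``1.21 pi / (k_max - k_min)``
    converted to micrometres.
    """
    if not k_max > k_min:
        raise CalibrationError("k_max must exceed k_min")
    return RESOLUTION_CONSTANT * np.pi / (k_max - k_min) / 1000.0


# ----------------------------------------------------------------------
# PSF measurement
# ----------------------------------------------------------------------

def psf_report(
    spectrum: AnalyticSpectrum | ReconVolume,
    *,
    pad_factor: int = DEFAULT_PSF_PAD,
    depth_window_um: tuple[float, float] | None = None,
) -> PSFReport:
    """Measure the -6 dB FWHM and sidelobe levels of a point response.

    The laterally averaged spectrum is zero-padded by ``pad_factor`` (>= 16
    for subpixel width interpolation) and transformed to depth; the FWHM is
    found by linear interpolation of the magnitude half-maximum crossings
    and the sidelobes are the highest local maxima on each side of the main
    lobe, beyond its first nulls, within +-15 FWHM.
    """
    if isinstance(spectrum, ReconVolume):
        # back to the spectral domain so the response can be re-padded
        aline = np.fft.ifft(spectrum.data.mean(axis=(0, 1)))
        dk = np.pi / (spectrum.data.shape[2] * spectrum.z_pixel_um * 1000.0)
        spectrum = AnalyticSpectrum(aline, k_start=0.0, dk=dk)
    if pad_factor < MIN_PSF_PAD:
        raise CalibrationError(
            f"pad_factor must be >= {MIN_PSF_PAD} for subpixel interpolation"
        )
    aline = spectrum.mean_aline()
    n_fine = pad_factor * spectrum.n_k
    mag = np.abs(np.fft.fft(aline, n=n_fine))
    z_fine_um = depth_pixel_um(n_fine, spectrum.dk)

    if depth_window_um is not None:
        lo = int(np.floor(depth_window_um[0] / z_fine_um))
        hi = int(np.ceil(depth_window_um[1] / z_fine_um))
        lo, hi = max(lo, 0), min(hi, n_fine)
        if hi <= lo or mag[lo:hi].max() < 0.1 * mag.max():
            raise CalibrationError("no peak inside the requested depth window")
        peak = lo + int(np.argmax(mag[lo:hi]))
    else:
        peak = int(np.argmax(mag))
    peak_val = mag[peak]
    if peak_val <= 0:
        raise CalibrationError("response is identically zero")

    fwhm_px = _fwhm_interp(mag, peak)
    fwhm_um = fwhm_px * z_fine_um
    window_px = int(np.ceil(SIDELOBE_WINDOW_FWHM * fwhm_px))
    left_db = _sidelobe_db(mag, peak, -1, window_px)
    right_db = _sidelobe_db(mag, peak, +1, window_px)
    return PSFReport(
        depth_um=peak * z_fine_um,
        fwhm_minus6db_um=fwhm_um,
        sidelobe_left_db=left_db,
        sidelobe_right_db=right_db,
        pad_factor=pad_factor,
    )


def psf_from_response(
    response: np.ndarray, z_pixel_um: float
) -> PSFReport:
    """PSF metrics from an already finely sampled depth response."""
    spec = AnalyticSpectrum(
        np.fft.ifft(np.asarray(response, complex)),
        k_start=0.0,
        dk=np.pi / (np.asarray(response).size * z_pixel_um * 1000.0),
    )
    return psf_report(spec, pad_factor=MIN_PSF_PAD)


def _fwhm_interp(mag: np.ndarray, peak: int) -> float:
    """Half-maximum width in (fine) pixels, linear crossing interpolation."""
    n = mag.size
    half = mag[peak] / 2.0
    i = peak
    while mag[(i + 1) % n] > half:
        i += 1
        if i - peak > n:
            raise CalibrationError("no half-maximum crossing found")
    hi = i + (mag[i % n] - half) / (mag[i % n] - mag[(i + 1) % n])
    i = peak
    while mag[(i - 1) % n] > half:
        i -= 1
        if peak - i > n:
            raise CalibrationError("no half-maximum crossing found")
    lo = i - (mag[i % n] - half) / (mag[i % n] - mag[(i - 1) % n])
    return float(hi - lo)


def _sidelobe_db(
    mag: np.ndarray, peak: int, direction: int, window_px: int
) -> float:
    """Highest local maximum beyond the first null, in dB re the peak."""
    n = mag.size
    i = peak
    # descend to the first null (local minimum)
    steps = 0
    while mag[(i + direction) % n] < mag[i % n]:
        i += direction
        steps += 1
        if steps > n:
            raise CalibrationError("no null found next to the main lobe")
    start = i
    stop = peak + direction * window_px
    idx = (np.arange(start, stop, direction) if direction > 0
           else np.arange(start, stop, direction))
    if idx.size == 0:
        return -np.inf
    seg = mag[idx % n]
    j = int(np.argmax(seg))
    # parabolic refinement of the sidelobe peak
    if 0 < j < seg.size - 1:
        y0, y1, y2 = seg[j - 1], seg[j], seg[j + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            d = 0.5 * (y0 - y2) / denom
            y1 = y1 - 0.25 * (y0 - y2) * d
        peak_val = y1
    else:
        peak_val = seg[j]
    return float(20.0 * np.log10(peak_val / mag[peak]))


# ----------------------------------------------------------------------
# Error-sensitivity sweeps
# ----------------------------------------------------------------------

@dataclass
class StitchScenario:
    """A calibrated two-laser mirror measurement ready for stitching."""

    spec_low: AnalyticSpectrum
    spec_high: AnalyticSpectrum
    kappa: float
    depth_um: float
    phase_truth: float = 0.0


def mirror_stitch_scenario(
    depth_um: float,
    *,
    kappa: float = 18.4,
    n_low: int = 403,
    n_high: int = 515,
    dk: float = 1.3258e-6,
) -> StitchScenario:
    """Ideal k-linear dual-laser mirror spectra with a known overlap.

    This isolates the *stitching* stage: flat envelopes, no chirp, no
    noise, so any PSF degradation comes solely from the error injected.
    """
    from .forward_model import simulate_klinear_pair

    (pair,) = simulate_klinear_pair(
        kappa, [depth_um], n_a=n_low, n_b=n_high, dk=dk
    )
    return StitchScenario(
        spec_low=pair[0], spec_high=pair[1], kappa=kappa, depth_um=depth_um
    )


def error_sensitivity_sweep(
    kind: Literal["phase_offset", "overlap", "amplitude"],
    magnitudes: Sequence[float],
    scenario: StitchScenario | None = None,
    *,
    depth_um: float = 850.0,
    pad_factor: int = DEFAULT_PSF_PAD,
) -> dict:
    """Re-stitch a mirror scenario with injected errors and report the PSF.

    ``kind`` selects the injected error: an extra constant phase (rad) on
    the second laser; an offset (pixels) added to the overlap used for
    stitching; or, for ``"amplitude"``, an uncorrected contrast dip at the
    seam — the stitched spectrum is multiplied by a Gaussian notch centred
    on the seam (FWHM of four overlap widths) whose floor is the magnitude,
    emulating residual ASE contrast loss where the two sweeps end.
    Magnitude 0 (or contrast 1) reproduces the baseline.  Returns
    ``{"baseline": PSFReport, "magnitudes": [...], "reports": [...]}``.
    """
    if scenario is None:
        scenario = mirror_stitch_scenario(depth_um)

    def run(mag: float) -> PSFReport:
        a, b = scenario.spec_low, scenario.spec_high
        kappa = scenario.kappa
        phi = scenario.phase_truth
        if kind == "phase_offset":
            phi = phi + mag
        elif kind == "overlap":
            kappa = kappa + mag
        elif kind != "amplitude":
            raise CalibrationError(f"unknown error kind {kind!r}")
        stitched = stitch_spectra(a, b, phi, kappa=kappa)
        if kind == "amplitude":
            n = stitched.n_k
            seam = a.n_k - int(np.ceil(kappa)) // 2
            width = 4.0 * max(kappa, 1.0)
            j = np.arange(n)
            notch = 1.0 - (1.0 - mag) * np.exp(
                -0.5 * ((j - seam) / (width / 2.355)) ** 2
            )
            stitched = AnalyticSpectrum(
                stitched.data * notch, k_start=stitched.k_start,
                dk=stitched.dk, laser_id=stitched.laser_id,
            )
        return psf_report(stitched, pad_factor=pad_factor)

    baseline = run(1.0 if kind == "amplitude" else 0.0)
    reports = [run(m) for m in magnitudes]
    return {
        "kind": kind,
        "baseline": baseline,
        "magnitudes": list(magnitudes),
        "reports": reports,
    }
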