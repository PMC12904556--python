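"""Per-measurement reconstruction: from raw sweeps to stitched volumes.

Order of operations for one acquisition session (per volume, per laser):

1.  background subtraction and contrast (ASE) correction,
2.  k-linearization onto the calibrated common grid,
3.  removal of quadratic-and-higher spectral phase (in-volume motion and
    dispersion mismatch) by sharpness-metric optimization,
4.  mutual registration of all volumes (removes the phase ramp linear in k,
    i.e. bulk axial displacement),
5.  per-lateral-bin grid search for the remaining constant phase offset
    between adjacent lasers,
6.  phase-correct stitching with a linear amplitude blend across the
    overlap, optional Tukey apodization, and the inverse transform to depth.

Sample motion enters the spectral phase as a Taylor series around the
central wavenumber: the constant term is the per-sweep phase offset matched
by the grid search, the linear term is bulk displacement removed by
registration, and everything quadratic and above is handled by the
per-volume motion/dispersion correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.signal.windows import tukey as tukey_window

from .calibration import (
    AnalyticSpectrum,
    CalibrationError,
    RawSweep,
    SystemCalibration,
    depth_pixel_um,
)

__all__ = [
    "MotionPhase",
    "PhaseOffsetField",
    "StitchPlan",
    "ReconVolume",
    "subtract_background",
    "correct_motion_phase",
    "estimate_axial_shift",
    "register_volumes",
    "shift_spectrum",
    "search_phase_offsets",
    "stitch_spectra",
    "stitch_chain",
    "apodize",
    "reconstruct_volume",
    "sharpness_metric",
]

DEFAULT_GAMMA = 1.4
DEFAULT_BIN_SIZE = (25, 25)
DEFAULT_PAD_FACTOR = 4
MIN_PAD_FACTOR = 2
N_PHASE_GRID = 64


# ----------------------------------------------------------------------
# Types
# ----------------------------------------------------------------------

@dataclass
class MotionPhase:
    """Polynomial spectral-phase model removed from one volume/laser.

    ``coefficients[p]`` multiplies ``u**p`` with ``u = (k - k0) /
    (half span)``; orders 0 and 1 are always zero here — the constant
    offset belongs to the phase search and the linear ramp to registration.
    """

    volume_index: int
    laser_id: str
    coefficients: np.ndarray
    converged: bool = True


@dataclass
class PhaseOffsetField:
    """Per-lateral-bin constant phase offset between two lasers."""

    offsets: np.ndarray  # (n_bins_x, n_bins_y), wrapped to [0, 2 pi)
    bin_size: tuple[int, int]
    metric_gamma: float = DEFAULT_GAMMA
    pad_factor: int = DEFAULT_PAD_FACTOR
    flagged: np.ndarray | None = None  # bins with no signal energy

    def __post_init__(self) -> None:
        self.offsets = np.mod(np.asarray(self.offsets, float), 2 * np.pi)

    @classmethod
    def constant(cls, phi: float) -> "PhaseOffsetField":
        return cls(offsets=np.array([[phi]]), bin_size=(0, 0))

    def expand(self, nx: int, ny: int) -> np.ndarray:
        """Per-pixel phase map from the per-bin offsets."""
        bx, by = self.bin_size
        if bx <= 0 or by <= 0 or self.offsets.size == 1:
            return np.full((nx, ny), float(self.offsets.flat[0]))
        ix = np.minimum(np.arange(nx) // bx, self.offsets.shape[0] - 1)
        iy = np.minimum(np.arange(ny) // by, self.offsets.shape[1] - 1)
        return self.offsets[np.ix_(ix, iy)]


@dataclass
class StitchPlan:
    """How adjacent laser spectra are composed into one broadband spectrum."""

    laser_order: list[str]
    kappa: list[float]  # fractional pixels, one per adjacent pair
    weight_kind: Literal["linear"] = "linear"
    apodization: str | tuple = "none"  # "none" or ("tukey", ratio)

    @classmethod
    def from_calibration(
        cls, calib: SystemCalibration, apodization="none"
    ) -> "StitchPlan":
        return cls(
            laser_order=[s.laser_id for s in calib.lasers],
            kappa=list(calib.kappa),
            apodization=apodization,
        )


@dataclass
class ReconVolume:
    """Reconstructed complex volume with its depth-axis scaling."""

    data: np.ndarray  # (nx, ny, nz), complex
    z_pixel_um: float
    provenance: dict = field(default_factory=dict)

    @property
    def depth_axis_um(self) -> np.ndarray:
        return np.arange(self.data.shape[2]) * self.z_pixel_um


# ----------------------------------------------------------------------
# Background subtraction
# ----------------------------------------------------------------------

def subtract_background(
    raw: RawSweep,
    reference: np.ndarray | None = None,
    *,
    remove_lateral_mean: bool = False,
) -> RawSweep:
    """Remove the non-interferometric background from a sweep.

    By default the per-pixel temporal mean is subtracted (constant DC per
    camera pixel); a measured ``reference`` sweep (sample arm blocked) can
    be supplied instead.  ``remove_lateral_mean`` additionally subtracts the
    lateral frame mean per time point, which removes a k-dependent
    background that is common to all pixels — appropriate for laterally
    diverse samples whose fringes average out across the field, but not for
    a mirror, whose fringe *is* the lateral mean.
    """
    frames = raw.frames.astype(float)
    if reference is not None:
        frames = frames - reference
    frames = frames - frames.mean(axis=2, keepdims=True)
    if remove_lateral_mean:
        lateral = frames.mean(axis=(0, 1), keepdims=True)
        frames = frames - (lateral - lateral.mean())
    return RawSweep(
        frames=frames,
        laser=raw.laser,
        discard_head=raw.discard_head,
        discard_tail=raw.discard_tail,
        volume_index=raw.volume_index,
    )


# ----------------------------------------------------------------------
# Sharpness metric
# ----------------------------------------------------------------------

def sharpness_metric(volume: np.ndarray, gamma: float = DEFAULT_GAMMA) -> float:
    """Sum of |U|^gamma over all voxels.

    For gamma < 2 this is minimal when the energy (which a pure phase
    correction conserves) is maximally concentrated — i.e. when sidelobes
    and motion blur are smallest.
    """
    return float(np.sum(np.abs(volume) ** gamma))


def _normalized_sharpness(volume: np.ndarray, gamma: float) -> float:
    """Sharpness metric made scale-invariant by energy normalization."""
    energy = np.sum(np.abs(volume) ** 2)
    if energy <= 0:
        return np.inf
    return float(np.sum(np.abs(volume) ** gamma) / energy ** (gamma / 2.0))


def _phase_basis(spectrum: AnalyticSpectrum) -> np.ndarray:
    """Normalized detuning u in [-1, 1] over the spectrum's k grid."""
    n = spectrum.n_k
    return (np.arange(n) - (n - 1) / 2) / ((n - 1) / 2)


# ----------------------------------------------------------------------
# Motion / dispersion phase correction (orders >= 2)
# ----------------------------------------------------------------------

def correct_motion_phase(
    spectrum: AnalyticSpectrum,
    order_max: int = 3,
    *,
    gamma: float = DEFAULT_GAMMA,
    pad_factor: int = DEFAULT_PAD_FACTOR,
) -> tuple[AnalyticSpectrum, MotionPhase]:
    """Estimate and remove polynomial spectral phase of orders 2..order_max.

    In-volume sample motion and dispersion mismatch add a smooth spectral
    phase that blurs the axial PSF uniformly over depth.  The coefficients
    are found by minimizing the sharpness metric of the reconstructed
    (zero-padded) volume; orders 0 and 1 are left untouched.
    """
    if order_max < 2:
        raise CalibrationError("order_max must be >= 2")
    u = _phase_basis(spectrum)
    data = spectrum.data
    n_pad = pad_factor * spectrum.n_k

    powers = np.stack([u**p for p in range(2, order_max + 1)])

    def objective(c: np.ndarray) -> float:
        phase = np.tensordot(c, powers, axes=1)
        vol = np.fft.fft(data * np.exp(-1j * phase), n=n_pad, axis=2)
        return sharpness_metric(vol, gamma)

    x0 = np.zeros(order_max - 1)
    res = minimize(objective, x0, method="Powell",
                   options={"xtol": 1e-4, "ftol": 1e-10, "maxiter": 2000})
    if not res.success:
        warnings.warn(
            f"motion-phase optimization did not converge for volume "
            f"{spectrum.volume_index} / laser {spectrum.laser_id!r}; "
            "returning the best coefficients found",
            stacklevel=2,
        )
    coeffs = np.zeros(order_max + 1)
    coeffs[2:] = res.x
    phase = np.tensordot(res.x, powers, axes=1)
    corrected = AnalyticSpectrum(
        data=data * np.exp(-1j * phase),
        k_start=spectrum.k_start,
        dk=spectrum.dk,
        laser_id=spectrum.laser_id,
        volume_index=spectrum.volume_index,
    )
    return corrected, MotionPhase(
        volume_index=spectrum.volume_index,
        laser_id=spectrum.laser_id,
        coefficients=coeffs,
        converged=bool(res.success),
    )


# ----------------------------------------------------------------------
# Registration (linear phase ramp / axial displacement)
# ----------------------------------------------------------------------

def estimate_axial_shift(
    ref: AnalyticSpectrum, other: AnalyticSpectrum
) -> float:
    """Axial displacement (um) of ``other`` relative to ``ref``.

    Same-grid volumes: weighted fit of the cross-spectrum phase slope
    (equivalent to subpixel cross-correlation of A-scans).  Different
    grids (other laser): cross-correlation of the zero-padded depth
    magnitude profiles, with parabolic subpixel refinement.
    """
    if not np.isclose(ref.dk, other.dk, rtol=1e-9):
        raise CalibrationError("spectra must share dk for registration")
    same_grid = ref.n_k == other.n_k and np.isclose(
        ref.k_start, other.k_start, rtol=1e-12, atol=1e-9 * ref.dk
    )
    if same_grid:
        cross = np.sum(ref.data * np.conj(other.data), axis=(0, 1))
        w = np.abs(cross)
        if w.max() <= 0:
            raise CalibrationError("decorrelated volumes: empty cross-spectrum")
        phase = np.unwrap(np.angle(cross))
        j = np.arange(ref.n_k)
        wsum = w.sum()
        jm = (w * j).sum() / wsum
        pm = (w * phase).sum() / wsum
        slope = ((w * (j - jm) * (phase - pm)).sum()
                 / (w * (j - jm) ** 2).sum())
        dz_nm = -slope / (2.0 * ref.dk)
        return dz_nm / 1000.0
    # different grid: correlate depth magnitudes on a common padded axis
    n_common = 8 * max(ref.n_k, other.n_k)
    prof_r = np.abs(np.fft.fft(ref.mean_aline(), n=n_common))
    prof_o = np.abs(np.fft.fft(other.mean_aline(), n=n_common))
    xc = np.fft.ifft(np.fft.fft(prof_r) * np.conj(np.fft.fft(prof_o)))
    mag = np.real(xc)
    peak = int(np.argmax(mag))
    y0 = mag[(peak - 1) % n_common]
    y1 = mag[peak]
    y2 = mag[(peak + 1) % n_common]
    denom = y0 - 2 * y1 + y2
    frac = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    lag = peak + frac
    if lag > n_common / 2:
        lag -= n_common
    # ref = other shifted by +lag pixels in depth => other sits shallower
    dz_um = -lag * np.pi / (n_common * ref.dk) / 1000.0
    return float(dz_um)


def register_volumes(
    spectra: Sequence[AnalyticSpectrum],
    *,
    ref_index: int = 0,
    correlation_threshold: float = 0.05,
) -> tuple[list[float], list[AnalyticSpectrum]]:
    """Mutually register volumes and remove their linear phase ramps.

    All volumes (every laser, every repetition) are registered directly to
    ``spectra[ref_index]``; the estimated displacement ``dz`` is removed by
    multiplying with ``exp(-i 2 k dz)`` on each volume's absolute
    wavenumber grid, which also removes the displacement's contribution to
    the constant phase.  Returns (shifts in um, deramped spectra).
    """
    if not spectra:
        raise CalibrationError("no volumes to register")
    ref = spectra[ref_index]
    ref_energy = float(np.sum(np.abs(ref.data) ** 2))
    shifts: list[float] = []
    out: list[AnalyticSpectrum] = []
    for i, s in enumerate(spectra):
        if i == ref_index:
            dz = 0.0
        else:
            energy = float(np.sum(np.abs(s.data) ** 2))
            if energy < correlation_threshold**2 * ref_energy:
                warnings.warn(
                    f"volume {s.volume_index} / laser {s.laser_id!r} has "
                    "too little energy to register; excluded (shift NaN)",
                    stacklevel=2,
                )
                shifts.append(float("nan"))
                out.append(s)
                continue
            dz = estimate_axial_shift(ref, s)
        shifts.append(dz)
        ramp = np.exp(-2j * s.k_grid * (dz * 1000.0))
        out.append(
            AnalyticSpectrum(
                data=s.data * ramp,
                k_start=s.k_start,
                dk=s.dk,
                laser_id=s.laser_id,
                volume_index=s.volume_index,
            )
        )
    return shifts, out


# ----------------------------------------------------------------------
# Spectral shifting (Fourier shift theorem)
# ----------------------------------------------------------------------

def shift_spectrum(data: np.ndarray, shift_px: float, axis: int = -1) -> np.ndarray:
    """Shift samples by a (fractional) number of pixels along ``axis``.

    ``out[j] = in[j - shift_px]`` evaluated by the Fourier shift theorem:
    exact for band-limited content, equal to ``np.roll`` for integer
    shifts, and an exact inverse pair with ``-shift_px``.
    """
    data = np.asarray(data)
    n = data.shape[axis]
    f = np.fft.fftfreq(n)
    phase = np.exp(-2j * np.pi * f * shift_px)
    shape = [1] * data.ndim
    shape[axis] = n
    spec = np.fft.fft(data, axis=axis) * phase.reshape(shape)
    out = np.fft.ifft(spec, axis=axis)
    if np.isrealobj(data):
        return np.real(out)
    return out


# ----------------------------------------------------------------------
# Stitching
# ----------------------------------------------------------------------

def _stitch_components(
    a: np.ndarray, b: np.ndarray, kappa: float
) -> tuple[np.ndarray, np.ndarray]:
    """Decompose the stitched spectrum as P + exp(i phi) * Q.

    ``a`` (lower wavenumbers, length Na along the last axis) keeps its
    integer grid; ``b``'s grid starts at the fractional pixel position
    ``Na - kappa``, so ``b`` is moved onto integer pixels by an exact
    Fourier shift of the fractional residue and placed at offset
    ``Na - ceil(kappa)``.  A linear ramp ``w`` rises 0 -> 1 across the
    overlap; ``P`` carries ``(1 - w) a`` and ``Q`` carries ``w b`` so the
    phase offset can be applied afterwards as ``P + Q e^{i phi}``.
    """
    na = a.shape[-1]
    nb = b.shape[-1]
    if kappa < 0:
        raise CalibrationError("kappa must be non-negative")
    if kappa > min(na, nb):
        raise CalibrationError(
            f"kappa = {kappa:.2f} exceeds a spectrum length ({na}, {nb})"
        )
    kc = int(np.ceil(kappa))
    delta = kc - kappa  # in [0, 1)
    b_grid = shift_spectrum(b, delta) if delta != 0.0 else b

    n_out = na + nb - kc
    p_idx = np.arange(n_out, dtype=float)
    if kappa > 0:
        w = np.clip((p_idx - (na - kappa)) / kappa, 0.0, 1.0)
    else:
        w = (p_idx >= na).astype(float)

    shape = a.shape[:-1] + (n_out,)
    p_part = np.zeros(shape, complex)
    q_part = np.zeros(shape, complex)
    p_part[..., :na] = (1.0 - w[:na]) * a
    q_part[..., na - kc:na - kc + nb] += w[na - kc:na - kc + nb] * b_grid
    return p_part, q_part


def stitch_spectra(
    spec_m: AnalyticSpectrum,
    spec_m1: AnalyticSpectrum,
    phase_field: PhaseOffsetField | float = 0.0,
    plan: StitchPlan | None = None,
    *,
    kappa: float | None = None,
) -> AnalyticSpectrum:
    """Phase-correct composition of two adjacent laser spectra.

    The combined spectrum keeps ``spec_m`` verbatim below the overlap,
    blends ``(1 - w) spec_m + w spec_m1 e^{i phi}`` across the overlap
    (``w`` linear from 0 to 1), and continues with the phase-shifted
    ``spec_m1`` above it.  ``phi`` may vary per lateral bin.
    """
    if kappa is None:
        if plan is None:
            raise CalibrationError("provide kappa or a StitchPlan")
        kappa = plan.kappa[0]
    if not np.isclose(spec_m.dk, spec_m1.dk, rtol=1e-9):
        raise CalibrationError("dk mismatch between spectra to stitch")

    nx, ny = spec_m.data.shape[:2]
    if spec_m1.data.shape[:2] != (nx, ny):
        raise CalibrationError("lateral shapes differ between lasers")
    if isinstance(phase_field, PhaseOffsetField):
        phi_map = phase_field.expand(nx, ny)
    else:
        phi_map = np.full((nx, ny), float(phase_field))

    p_part, q_part = _stitch_components(spec_m.data, spec_m1.data, kappa)
    out = p_part + np.exp(1j * phi_map)[:, :, None] * q_part
    return AnalyticSpectrum(
        data=out,
        k_start=spec_m.k_start,
        dk=spec_m.dk,
        laser_id=f"{spec_m.laser_id}+{spec_m1.laser_id}",
        volume_index=spec_m.volume_index,
    )


def stitch_chain(
    spectra: Sequence[AnalyticSpectrum],
    phase_fields: Sequence[PhaseOffsetField | float],
    kappas: Sequence[float],
) -> AnalyticSpectrum:
    """Stitch an ascending-k chain of spectra pairwise: ((s0+s1)+s2)+..."""
    if len(spectra) != len(kappas) + 1 or len(phase_fields) != len(kappas):
        raise CalibrationError("need n spectra, n-1 kappas, n-1 phase fields")
    acc = spectra[0]
    for nxt, phi, kap in zip(spectra[1:], phase_fields, kappas):
        acc = stitch_spectra(acc, nxt, phi, kappa=kap)
    return acc


# ----------------------------------------------------------------------
# Phase-offset grid search
# ----------------------------------------------------------------------

def search_phase_offsets(
    spec_m: AnalyticSpectrum,
    spec_m1: AnalyticSpectrum,
    plan: StitchPlan | None = None,
    bins: tuple[int, int] = DEFAULT_BIN_SIZE,
    *,
    kappa: float | None = None,
    gamma: float = DEFAULT_GAMMA,
    pad_factor: int = DEFAULT_PAD_FACTOR,
    n_phases: int = N_PHASE_GRID,
) -> PhaseOffsetField:
    """Find the constant phase offset of ``spec_m1`` per lateral bin.

    For every bin of ``bins`` pixels the stitched local volume is
    reconstructed (zero-padded in depth by ``pad_factor``) for trial phases
    on a uniform grid over [0, 2 pi); the sharpness metric ``sum |U|^gamma``
    is minimal at the correct offset, and a quadratic refinement around the
    grid minimum gives subgrid resolution.  Bins without signal energy are
    filled from their neighbors and flagged.
    """
    if kappa is None:
        if plan is None:
            raise CalibrationError("provide kappa or a StitchPlan")
        kappa = plan.kappa[0]
    if pad_factor < MIN_PAD_FACTOR:
        raise CalibrationError(
            f"pad_factor must be >= {MIN_PAD_FACTOR}; the sharpness metric "
            "needs visible sidelobes"
        )
    p_part, q_part = _stitch_components(spec_m.data, spec_m1.data, kappa)
    nx, ny, n_k = p_part.shape
    n_pad = pad_factor * n_k
    bx = min(bins[0], nx) or nx
    by = min(bins[1], ny) or ny
    nbx = int(np.ceil(nx / bx))
    nby = int(np.ceil(ny / by))

    phis = np.linspace(0.0, 2 * np.pi, n_phases, endpoint=False)
    offsets = np.zeros((nbx, nby))
    flagged = np.zeros((nbx, nby), bool)
    mean_energy = (np.sum(np.abs(p_part) ** 2 + np.abs(q_part) ** 2)
                   / (nbx * nby))
    for ix in range(nbx):
        for iy in range(nby):
            sl = (slice(ix * bx, min((ix + 1) * bx, nx)),
                  slice(iy * by, min((iy + 1) * by, ny)))
            p_loc = p_part[sl]
            q_loc = q_part[sl]
            energy = float(np.sum(np.abs(p_loc) ** 2 + np.abs(q_loc) ** 2))
            if energy < 1e-9 * mean_energy:
                flagged[ix, iy] = True
                continue
            u_p = np.fft.fft(p_loc, n=n_pad, axis=2)
            u_q = np.fft.fft(q_loc, n=n_pad, axis=2)
            # scale-invariant sharpness: normalize by the stitched volume's
            # own energy.  A wrong phase cancels energy in the blend region,
            # which would otherwise lower the raw metric and bias the argmin
            # away from the true offset.
            costs = np.array([
                _normalized_sharpness(u_p + np.exp(1j * phi) * u_q, gamma)
                for phi in phis
            ])
            offsets[ix, iy] = _refine_periodic_min(phis, costs)
    if flagged.any():
        valid = ~flagged
        if valid.any():
            # circular mean of valid neighbors (global fallback)
            fill = np.angle(np.exp(1j * offsets[valid]).mean())
            offsets[flagged] = fill % (2 * np.pi)
        warnings.warn(
            f"{int(flagged.sum())} lateral bin(s) had no signal energy; "
            "phase offsets interpolated from neighbors",
            stacklevel=2,
        )
    return PhaseOffsetField(
        offsets=offsets,
        bin_size=(bx, by),
        metric_gamma=gamma,
        pad_factor=pad_factor,
        flagged=flagged,
    )


def _refine_periodic_min(phis: np.ndarray, costs: np.ndarray) -> float:
    """Parabolic refinement of the minimum on a periodic uniform grid."""
    n = phis.size
    i = int(np.argmin(costs))
    y0, y1, y2 = costs[(i - 1) % n], costs[i], costs[(i + 1) % n]
    denom = y0 - 2 * y1 + y2
    frac = 0.0 if denom <= 0 else 0.5 * (y0 - y2) / denom
    step = phis[1] - phis[0]
    return float((phis[i] + frac * step) % (2 * np.pi))


# ----------------------------------------------------------------------
# Apodization and reconstruction
# ----------------------------------------------------------------------

def apodize(
    spectrum: AnalyticSpectrum, window: str | tuple = ("tukey", 0.5)
) -> AnalyticSpectrum:
    """Multiply the spectrum by a window along k to trade resolution for
    sidelobe suppression.  ``"none"`` is the identity; ``("tukey", r)`` (or
    the string ``"tukey:r"``) applies a Tukey window with taper ratio r.
    """
    if window in ("none", None):
        return spectrum
    if isinstance(window, str):
        name, _, arg = window.partition(":")
        window = (name, float(arg) if arg else 0.5)
    name, ratio = window
    if name != "tukey":
        raise CalibrationError(f"unknown apodization window {name!r}")
    w = tukey_window(spectrum.n_k, alpha=float(ratio))
    return AnalyticSpectrum(
        data=spectrum.data * w,
        k_start=spectrum.k_start,
        dk=spectrum.dk,
        laser_id=spectrum.laser_id,
        volume_index=spectrum.volume_index,
    )


def reconstruct_volume(
    spectrum: AnalyticSpectrum, *, pad_factor: int = 1
) -> ReconVolume:
    """Inverse transform along k to the depth domain.

    Uses the orthonormal transform, so the unapodized volume conserves
    spectral energy (Parseval).  With zero padding the depth pixel shrinks
    accordingly: ``z_pixel = pi / (pad * N * dk)``.
    """
    # forward transform: a fringe exp(i 2 k z) lands at +z
    n_pad = pad_factor * spectrum.n_k
    data = np.fft.fft(spectrum.data, n=n_pad, axis=2, norm="ortho")
    return ReconVolume(
        data=data,
        z_pixel_um=depth_pixel_um(n_pad, spectrum.dk),
        provenance={
            "laser_id": spectrum.laser_id,
            "volume_index": spectrum.volume_index,
            "k_start": spectrum.k_start,
            "dk": spectrum.dk,
            "pad_factor": pad_factor,
        },
    )
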