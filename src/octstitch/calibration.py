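"""One-time system calibration for multi-laser swept-source FF-FD-OCT.

A swept-source full-field OCT system records interferogram frames while the
laser tunes its wavenumber ``k`` nonlinearly in time ("chirp").  Before
spectra from two sequentially sweeping lasers can be stitched into one
broadband spectrum, the system needs a one-time calibration:

1.  *Chirp determination* — from a single-mirror sweep, the analytic-signal
    phase is unwrapped to obtain ``k(t)`` for each laser.
2.  *k-linearization* — every sweep is resampled onto a uniform wavenumber
    grid with a spacing ``dk`` shared by all lasers (a computational
    k-clock).
3.  *Envelope / ASE correction* — incoherent amplified-spontaneous-emission
    background near the sweep ends lowers interference contrast; the
    contrast curve ``alpha(k)`` is estimated and divided out.
4.  *Overlap determination* — the fractional number of spectral pixels
    ``kappa`` shared by two adjacent lasers is found by summing normalized
    cross-correlations of mirror spectra recorded at several depths.

Units used throughout the package: wavenumbers in rad/nm (``k = 2*pi /
lambda_nm``), optical depths in micrometres of air path.  Spectral fringes
follow the ``cos(2 k z)`` convention, so a uniform grid of ``N`` pixels with
spacing ``dk`` has depth pixels of ``pi / (N * dk)`` (in nm) and a Nyquist
depth of ``pi / (2 * dk)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import h5py
import numpy as np
from scipy.signal import hilbert

__all__ = [
    "CalibrationError",
    "LaserSpec",
    "RawSweep",
    "ChirpCurve",
    "EnvelopeCorrection",
    "AnalyticSpectrum",
    "OverlapEstimate",
    "SystemCalibration",
    "trim_sweep",
    "average_alines",
    "estimate_envelope",
    "correct_amplitude",
    "estimate_chirp",
    "regrid_klinear",
    "pad_spectra",
    "depth_cross_correlation",
    "determine_overlap",
    "build_system_calibration",
    "calibrate_session",
    "nyquist_depth_um",
    "depth_pixel_um",
    "nominal_overlap_px",
]

# Interference contrast is never allowed below this floor; dividing by a
# smaller alpha would amplify noise without bound at the sweep ends.
ALPHA_FLOOR = 0.05

# |R| regularization for the normalized cross-correlation: the envelope
# cross-correlation vanishes outside its support, where dividing Re(R) by
# |R| would blow up.
RHO_REGULARIZATION = 1e-3

# Fine-grid factor of the cross-correlation: the spectral product is
# zero-padded 99x, i.e. evaluated on a 100x grid -> 0.01 px resolution.
CROSS_CORR_UPSAMPLING = 100

# Frames discarded at each sweep end when no count is configured.  The sweep
# start jitters by a fraction of a camera frame, so the first/last frames of
# a sweep are unreliable.
DEFAULT_TRIM = 8

MIN_RETAINED_FRAMES = 16


class CalibrationError(ValueError):
    """Raised when a calibration input violates its contract."""


# ----------------------------------------------------------------------
# Domain types
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class LaserSpec:
    """Nominal description of one swept laser.

    ``lambda_min_nm``/``lambda_max_nm`` are the wavelengths reached by the
    *retained* frames of the sweep (after edge trimming); ``n_frames`` is
    the number of camera frames recorded while the laser sweeps.
    """

    laser_id: str
    lambda_min_nm: float
    lambda_max_nm: float
    n_frames: int
    sweep_direction: Literal["increasing_k", "decreasing_k"] = "increasing_k"

    def __post_init__(self) -> None:
        if not self.lambda_min_nm < self.lambda_max_nm:
            raise CalibrationError(
                f"laser {self.laser_id!r}: lambda_min must be < lambda_max "
                f"(got {self.lambda_min_nm}, {self.lambda_max_nm})"
            )
        if self.n_frames < MIN_RETAINED_FRAMES:
            raise CalibrationError(
                f"laser {self.laser_id!r}: n_frames must be >= "
                f"{MIN_RETAINED_FRAMES}, got {self.n_frames}"
            )
        if self.sweep_direction not in ("increasing_k", "decreasing_k"):
            raise CalibrationError(
                f"unknown sweep_direction {self.sweep_direction!r}"
            )

    @property
    def k_min(self) -> float:
        """Smallest wavenumber of the sweep, rad/nm."""
        return 2.0 * np.pi / self.lambda_max_nm

    @property
    def k_max(self) -> float:
        """Largest wavenumber of the sweep, rad/nm."""
        return 2.0 * np.pi / self.lambda_min_nm

    @property
    def k_span(self) -> float:
        return self.k_max - self.k_min


@dataclass
class RawSweep:
    """Real-valued frame stack ``I(x, y, t)`` for one sweep of one laser."""

    frames: np.ndarray  # (nx, ny, n_frames), real
    laser: LaserSpec
    discard_head: int = 0
    discard_tail: int = 0
    volume_index: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise CalibrationError(
                f"frames must be (nx, ny, n_frames); got shape "
                f"{self.frames.shape}"
            )
        if self.discard_head < 0 or self.discard_tail < 0:
            raise CalibrationError("discard counts must be non-negative")
        if self.n_retained < MIN_RETAINED_FRAMES:
            raise CalibrationError(
                f"only {self.n_retained} frames would remain after "
                f"discarding {self.discard_head}+{self.discard_tail}; "
                f"need at least {MIN_RETAINED_FRAMES}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]

    @property
    def n_retained(self) -> int:
        return self.n_frames - self.discard_head - self.discard_tail

    @property
    def lateral_shape(self) -> tuple[int, int]:
        return self.frames.shape[:2]


@dataclass
class ChirpCurve:
    """Sampled wavenumber-versus-frame function of one laser.

    ``k_of_t[i]`` is the wavenumber (rad/nm) of retained frame ``i``.  The
    curve is anchored so that its endpoints equal the laser's nominal sweep
    endpoints; only the *relative* nonlinearity is physically determined by
    the unwrapped fringe phase, the absolute scale is a convention shared
    with the overlap value.
    """

    laser_id: str
    k_of_t: np.ndarray
    anchoring: str = "nominal-endpoints"

    def __post_init__(self) -> None:
        self.k_of_t = np.asarray(self.k_of_t, dtype=float)
        d = np.diff(self.k_of_t)
        if not (np.all(d > 0) or np.all(d < 0)):
            bad = int(np.argmin(d * np.sign(d[np.argmax(np.abs(d))])))
            raise CalibrationError(
                f"chirp curve for laser {self.laser_id!r} is not strictly "
                f"monotonic (first violation near frame {bad})"
            )

    @property
    def ascending(self) -> bool:
        return bool(self.k_of_t[-1] > self.k_of_t[0])

    @property
    def k_span(self) -> float:
        return float(abs(self.k_of_t[-1] - self.k_of_t[0]))


@dataclass
class EnvelopeCorrection:
    """Spectral-envelope estimate and interference-contrast curve.

    ``gamma`` is the envelope estimate Gamma(k) (sum of analytic-signal
    magnitudes over all lateral positions); ``alpha = gamma / gamma_max`` is
    the contrast used to flatten the fringe amplitude.
    """

    laser_id: str
    gamma: np.ndarray
    alpha: np.ndarray
    gamma_max: float
    mode: Literal["scattering", "reflecting"]

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if not np.isclose(self.alpha.max(), 1.0):
            raise CalibrationError("alpha must be normalized to max 1")
        if np.any(self.alpha < ALPHA_FLOOR - 1e-12):
            raise CalibrationError(f"alpha fell below floor {ALPHA_FLOOR}")


@dataclass
class AnalyticSpectrum:
    """Complex spectrum on a uniform wavenumber grid.

    ``data`` has shape (nx, ny, N); pixel ``j`` sits at wavenumber
    ``k_start + j * dk`` (rad/nm).  After calibration all lasers share the
    same ``dk``.
    """

    data: np.ndarray
    k_start: float
    dk: float
    laser_id: str = ""
    volume_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 1:
            self.data = self.data[None, None, :]
        if self.data.ndim != 3:
            raise CalibrationError("spectrum data must be 1-D or (nx, ny, N)")

    @property
    def n_k(self) -> int:
        return self.data.shape[2]

    @property
    def k_grid(self) -> np.ndarray:
        return self.k_start + self.dk * np.arange(self.n_k)

    @property
    def k_stop(self) -> float:
        """Wavenumber of the last pixel."""
        return self.k_start + self.dk * (self.n_k - 1)

    def mean_aline(self) -> np.ndarray:
        """Laterally averaged complex A-line spectrum."""
        return self.data.mean(axis=(0, 1))

    @property
    def depth_pixel_um(self) -> float:
        return depth_pixel_um(self.n_k, self.dk)


@dataclass
class OverlapEstimate:
    """Subpixel overlap between two adjacent lasers.

    ``kappa`` is the (fractional) number of uniform-grid pixels shared by
    the two spectra; ``rho0`` is the summed normalized cross-correlation on
    the 0.01-px lag grid restricted to the search window, with ``lags_px``
    giving the corresponding candidate overlaps.
    """

    kappa: float
    rho0: np.ndarray
    lags_px: np.ndarray
    depths_used_um: list[float]
    n_depths: int
    search_window: tuple[float, float]
    on_boundary: bool = False


@dataclass
class SystemCalibration:
    """Everything the reconstruction needs: chirps, envelopes, dk, overlaps.

    ``lasers`` is ordered by ascending wavenumber (the stitching order);
    ``kappa[i]`` is the overlap between lasers ``i`` and ``i + 1``.
    """

    lasers: list[LaserSpec]
    chirps: dict[str, ChirpCurve]
    envelopes: dict[str, EnvelopeCorrection]
    kappa: list[float]
    dk: float
    trim: tuple[int, int] = (DEFAULT_TRIM, DEFAULT_TRIM)
    provenance: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            header = {
                "lasers": [dataclasses.asdict(s) for s in self.lasers],
                "kappa": list(self.kappa),
                "dk": self.dk,
                "trim": list(self.trim),
                "provenance": self.provenance,
                "format": "octstitch-calibration-1",
            }
            f.attrs["header"] = json.dumps(header)
            for lid, chirp in self.chirps.items():
                f.create_dataset(f"chirp/{lid}", data=chirp.k_of_t)
            for lid, env in self.envelopes.items():
                g = f.create_group(f"envelope/{lid}")
                g.create_dataset("gamma", data=env.gamma)
                g.create_dataset("alpha", data=env.alpha)
                g.attrs["gamma_max"] = env.gamma_max
                g.attrs["mode"] = env.mode

    @classmethod
    def load(cls, path) -> "SystemCalibration":
        with h5py.File(path, "r") as f:
            header = json.loads(f.attrs["header"])
            lasers = [LaserSpec(**d) for d in header["lasers"]]
            chirps = {
                lid: ChirpCurve(laser_id=lid, k_of_t=f[f"chirp/{lid}"][()])
                for lid in f["chirp"]
            }
            envelopes = {}
            if "envelope" in f:
                for lid in f["envelope"]:
                    g = f[f"envelope/{lid}"]
                    envelopes[lid] = EnvelopeCorrection(
                        laser_id=lid,
                        gamma=g["gamma"][()],
                        alpha=g["alpha"][()],
                        gamma_max=float(g.attrs["gamma_max"]),
                        mode=str(g.attrs["mode"]),
                    )
        return cls(
            lasers=lasers,
            chirps=chirps,
            envelopes=envelopes,
            kappa=[float(k) for k in header["kappa"]],
            dk=float(header["dk"]),
            trim=tuple(header["trim"]),
            provenance=header.get("provenance", {}),
        )


# ----------------------------------------------------------------------
# Depth-axis conventions
# ----------------------------------------------------------------------

def depth_pixel_um(n: int, dk: float) -> float:
    """Depth pixel size (um of air path) of an n-pixel spectrum with spacing dk.

    Under the ``cos(2 k z)`` fringe convention one full fringe cycle across
    the sweep corresponds to ``2 * n * dk * z = 2 * pi``.
    """
    return np.pi / (n * dk) / 1000.0


def nyquist_depth_um(dk: float) -> float:
    """Maximum unaliased optical depth (um in air) for pixel spacing dk."""
    return np.pi / (2.0 * dk) / 1000.0


def nominal_overlap_px(low: LaserSpec, high: LaserSpec, dk: float) -> float:
    """Overlap in pixels predicted from the nominal wavelength ranges.

    ``low`` is the laser occupying the lower wavenumbers.  Counting grid
    pixels inclusively, a shared wavenumber interval of width ``w`` spans
    ``w / dk + 1`` pixels.
    """
    w = low.k_max - high.k_min
    if w < 0:
        raise CalibrationError(
            f"lasers {low.laser_id!r} and {high.laser_id!r} have no "
            "overlapping wavenumber range"
        )
    return w / dk + 1.0


# ----------------------------------------------------------------------
# Sweep trimming and averaging
# ----------------------------------------------------------------------

def trim_sweep(raw: RawSweep) -> RawSweep:
    """Drop the configured number of frames at the sweep start and stop.

    The camera runs freely and the laser sweep start jitters by a fraction
    of a frame, so a margin of frames near the start/stop points carries an
    uncertain wavenumber and is discarded before any estimation.
    """
    h, t = raw.discard_head, raw.discard_tail
    if raw.n_retained < MIN_RETAINED_FRAMES:  # pragma: no cover - guarded
        raise CalibrationError("over-trimming: fewer than 16 frames left")
    stop = raw.n_frames - t
    return RawSweep(
        frames=raw.frames[:, :, h:stop],
        laser=raw.laser,
        discard_head=0,
        discard_tail=0,
        volume_index=raw.volume_index,
    )


def average_alines(raw: RawSweep) -> np.ndarray:
    """Average all A-lines (lateral positions) of a sweep into one trace."""
    return raw.frames.mean(axis=(0, 1))


def _margin_taper(n: int, head: int, tail: int) -> np.ndarray:
    """Window equal to 1 on the retained frames, cosine-tapered to zero
    across the discard margins.

    Tapering the (discarded) margins suppresses the spectral leakage of the
    finite fringe, which otherwise ripples the analytic-signal phase by
    several milliradians, without touching the retained samples.
    """
    w = np.ones(n)
    if head > 0:
        w[:head] = 0.5 * (1 - np.cos(np.pi * np.arange(head) / head))
    if tail > 0:
        w[n - tail:] = 0.5 * (1 - np.cos(np.pi * np.arange(tail, 0, -1) / tail))
    return w


def _analytic_retained(raw: RawSweep) -> np.ndarray:
    """Analytic signal of each A-line, computed on the full sweep and then
    cropped to the retained frames.

    Computing the Hilbert transform *before* cropping pushes its edge
    ringing into the discarded margin.
    """
    frames = raw.frames - raw.frames.mean(axis=2, keepdims=True)
    frames = frames * _margin_taper(
        raw.n_frames, raw.discard_head, raw.discard_tail
    )
    a = hilbert(frames, axis=2)
    stop = raw.n_frames - raw.discard_tail
    return a[:, :, raw.discard_head:stop]


# ----------------------------------------------------------------------
# Envelope / ASE correction
# ----------------------------------------------------------------------

def estimate_envelope(
    sweeps: RawSweep | Sequence[RawSweep],
    mode: Literal["scattering", "reflecting"] = "scattering",
    *,
    depth_window: tuple[int, int] | None = None,
    use_raw_magnitude: bool = False,
) -> EnvelopeCorrection:
    """Estimate the spectral envelope Gamma(k) and contrast alpha(k).

    Parameters
    ----------
    sweeps
        One or several DC-subtracted raw sweeps of the same laser.  Multiple
        sweeps are averaged after the per-sweep magnitude is formed.
    mode
        ``"scattering"``: for samples with depth-distributed scattering the
        magnitude of the analytic signal of every A-line is summed over all
        lateral positions.  With ``use_raw_magnitude=True`` the absolute
        value of the real frames is summed instead.
        ``"reflecting"``: for mirrors/coverslips the analytic signal is
        filtered in depth to isolate a single surface before taking the
        magnitude; interference between two surfaces would otherwise
        modulate the envelope.
    depth_window
        Depth-pixel interval ``(lo, hi)`` isolating one surface (reflecting
        mode).  Auto-detected around the strongest peak when omitted.
    """
    if isinstance(sweeps, RawSweep):
        sweeps = [sweeps]
    if not sweeps:
        raise CalibrationError("estimate_envelope needs at least one sweep")
    laser = sweeps[0].laser

    gammas = []
    for raw in sweeps:
        analytic = _analytic_retained(raw)
        if mode == "scattering":
            if use_raw_magnitude:
                stop = raw.n_frames - raw.discard_tail
                frames = raw.frames[:, :, raw.discard_head:stop]
                frames = frames - frames.mean(axis=2, keepdims=True)
                gammas.append(np.abs(frames).sum(axis=(0, 1)))
            else:
                gammas.append(np.abs(analytic).sum(axis=(0, 1)))
        elif mode == "reflecting":
            gammas.append(_reflecting_gamma(analytic, depth_window))
        else:
            raise CalibrationError(f"unknown envelope mode {mode!r}")
    gamma = np.mean(gammas, axis=0)

    # normalize against a lightly smoothed maximum so that narrow edge
    # artifacts of the analytic signal cannot skew the whole contrast curve
    from scipy.ndimage import uniform_filter1d

    gamma_max = float(uniform_filter1d(gamma, 7).max())
    if gamma_max <= 0:
        raise CalibrationError("envelope estimate is identically zero")
    alpha = np.clip(gamma / gamma_max, ALPHA_FLOOR, 1.0)
    return EnvelopeCorrection(
        laser_id=laser.laser_id,
        gamma=gamma,
        alpha=alpha,
        gamma_max=gamma_max,
        mode=mode,
    )


def _reflecting_gamma(
    analytic: np.ndarray, depth_window: tuple[int, int] | None
) -> np.ndarray:
    """Envelope from a localized reflector: depth-filter the analytic signal."""
    n = analytic.shape[2]
    spec = np.fft.fft(analytic, axis=2)  # to depth
    mean_mag = np.abs(spec).mean(axis=(0, 1))
    if depth_window is None:
        # auto-detect: a generous window around the strongest non-DC peak;
        # the lower bound also keeps out the residual background near z=0,
        # and a wide window keeps the envelope resolution high
        lo_guard = max(2, n // 64)
        peak = lo_guard + int(np.argmax(mean_mag[lo_guard:]))
        half = max(2, n // 4)
        lo = max(lo_guard, peak - half, int(0.4 * peak))
        depth_window = (lo, min(n, peak + half + 1))
    lo, hi = depth_window
    inside = mean_mag[lo:hi]
    if _count_resolved_peaks(inside) > 1:
        raise CalibrationError(
            "reflecting-mode depth window contains more than one surface; "
            "their interference would modulate the envelope estimate"
        )
    mask = np.zeros(n)
    mask[lo:hi] = 1.0
    filtered = np.fft.ifft(spec * mask, axis=2)
    return np.abs(filtered).mean(axis=(0, 1))


def _count_resolved_peaks(mag: np.ndarray) -> int:
    """Count distinct reflecting surfaces in a depth-magnitude profile.

    A chirped mirror produces one broadened, rippled lobe; ripples must not
    be mistaken for extra surfaces, so the profile is smoothed and only
    prominent maxima count.
    """
    from scipy.ndimage import uniform_filter1d
    from scipy.signal import find_peaks

    if mag.size < 3:
        return 1
    width = max(3, mag.size // 50)
    smooth = uniform_filter1d(mag.astype(float), width)
    top = smooth.max()
    peaks, _ = find_peaks(smooth, height=0.5 * top, prominence=0.35 * top)
    return max(1, peaks.size)


def correct_amplitude(
    data: RawSweep | AnalyticSpectrum, env: EnvelopeCorrection
) -> RawSweep | AnalyticSpectrum:
    """Divide the (DC-subtracted) data by alpha(k) to flatten the contrast."""
    if isinstance(data, RawSweep):
        if data.n_retained != env.alpha.size:
            raise CalibrationError(
                f"alpha has {env.alpha.size} samples but the sweep retains "
                f"{data.n_retained} frames"
            )
        frames = data.frames.copy().astype(float)
        stop = data.n_frames - data.discard_tail
        frames[:, :, data.discard_head:stop] /= env.alpha
        return RawSweep(
            frames=frames,
            laser=data.laser,
            discard_head=data.discard_head,
            discard_tail=data.discard_tail,
            volume_index=data.volume_index,
        )
    if isinstance(data, AnalyticSpectrum):
        if data.n_k != env.alpha.size:
            raise CalibrationError("alpha length does not match spectrum")
        return AnalyticSpectrum(
            data=data.data / env.alpha,
            k_start=data.k_start,
            dk=data.dk,
            laser_id=data.laser_id,
            volume_index=data.volume_index,
        )
    raise TypeError("correct_amplitude expects a RawSweep or AnalyticSpectrum")


# ----------------------------------------------------------------------
# Chirp determination
# ----------------------------------------------------------------------

def _bandpass_analytic_trace(
    trace: np.ndarray,
    band: tuple[float, float] = (0.4, 1.8),
    taper: tuple[int, int] = (0, 0),
) -> np.ndarray:
    """Analytic signal of a mirror fringe, band-filtered around its carrier.

    Residual ASE background and DC drift occupy low temporal frequencies;
    a band of ``band[0]..band[1]`` times the dominant fringe frequency
    passes the (chirp-broadened) fringe while rejecting them.
    """
    trace = trace - trace.mean()
    trace = trace * _margin_taper(trace.size, *taper)
    analytic = hilbert(trace)
    spec = np.fft.fft(analytic)
    n = trace.size
    guard = max(2, n // 64)
    mag = np.abs(spec[: n // 2 + 1])
    # the chirp spreads the carrier over a band; take the band's support
    # (bins above 30% of the maximum) rather than a single peak bin
    strong = np.flatnonzero(mag[guard:] > 0.3 * mag[guard:].max()) + guard
    lo_sup, hi_sup = int(strong.min()), int(strong.max())
    lo = max(guard, int(band[0] * lo_sup))
    hi = min(n - 1, int(np.ceil(band[1] * hi_sup)))
    mask = np.zeros(n)
    mask[lo:hi + 1] = 1.0
    return np.fft.ifft(spec * mask)


def estimate_chirp(mirror_sweep: RawSweep, anchor: LaserSpec) -> ChirpCurve:
    """Extract k(t) from a motion- and dispersion-free single-mirror sweep.

    All A-lines of the volume are averaged, the analytic signal is formed by
    a Hilbert transform along the frame axis and its unwrapped phase —
    ``2 k(t) z0`` up to a constant — is rescaled affinely so that the
    retained endpoints hit the laser's nominal sweep wavenumbers.  The
    unknown mirror depth ``z0`` and phase offset drop out in the anchoring.
    """
    trace = average_alines(mirror_sweep)
    analytic = _bandpass_analytic_trace(
        trace, taper=(mirror_sweep.discard_head, mirror_sweep.discard_tail)
    )
    stop = mirror_sweep.n_frames - mirror_sweep.discard_tail
    analytic = analytic[mirror_sweep.discard_head:stop]

    phase = np.unwrap(np.angle(analytic))
    d = np.diff(phase)
    sign = np.sign(np.median(d))
    if np.any(d * sign <= 0):
        bad = int(np.argmax(d * sign <= 0))
        raise CalibrationError(
            f"unwrapped phase is not strictly monotonic (first violation at "
            f"retained frame {bad}); the mirror may be too shallow or the "
            "SNR too low — raise z0 and repeat the calibration sweep"
        )

    if anchor.sweep_direction == "increasing_k":
        k0, k1 = anchor.k_min, anchor.k_max
    else:
        k0, k1 = anchor.k_max, anchor.k_min
    k_of_t = k0 + (phase - phase[0]) / (phase[-1] - phase[0]) * (k1 - k0)
    return ChirpCurve(laser_id=anchor.laser_id, k_of_t=k_of_t)


# ----------------------------------------------------------------------
# k-linearization (regridding)
# ----------------------------------------------------------------------

def regrid_klinear(
    sweep: RawSweep,
    chirp: ChirpCurve,
    dk: float,
    *,
    method: Literal["lsq", "spline"] = "lsq",
    k_start: float | None = None,
    n_out: int | None = None,
    rcond: float = 1e-8,
) -> AnalyticSpectrum:
    """Resample a chirped sweep onto a uniform wavenumber grid.

    The analytic signal (Hilbert transform along the frame axis, computed
    before edge cropping) is known at the nonuniform wavenumbers ``k(t)``
    given by the chirp curve and is resampled to pixels
    ``k_start + j * dk``.

    Two resamplers are provided.  ``"lsq"`` (default) expands every A-line
    in a basis of below-Nyquist depth fringes ``exp(i 2 z_j k)`` by least
    squares on the nonuniform nodes and evaluates the expansion on the
    uniform grid — the gridding-style inverse-NUFFT view of resampling,
    exact for noiseless depth-limited signals.  ``"spline"`` interpolates
    real and imaginary parts with cubic splines; adequate for smooth chirps.
    """
    if chirp.k_of_t.size != sweep.n_retained:
        raise CalibrationError(
            f"chirp curve has {chirp.k_of_t.size} samples but the sweep "
            f"retains {sweep.n_retained} frames"
        )
    analytic = _analytic_retained(sweep)
    kt = chirp.k_of_t
    if not chirp.ascending:  # adopt a single global ascending-k convention
        kt = kt[::-1]
        analytic = analytic[:, :, ::-1].conj()

    k_lo, k_hi = float(kt[0]), float(kt[-1])
    if k_start is None:
        k_start = k_lo
    if n_out is None:
        n_out = int(np.floor((k_hi - k_start) / dk + 1e-9)) + 1
    if n_out > 4 * kt.size:
        raise CalibrationError(
            f"requested dk implies {n_out / kt.size:.1f}x upsampling "
            "(limit 4x): refusing to extrapolate"
        )
    k_uniform = k_start + dk * np.arange(n_out)

    nx, ny, nt = analytic.shape
    flat = analytic.reshape(nx * ny, nt).T  # (nt, n_alines)
    if method == "lsq":
        # depth basis up to (just past) the Nyquist depth of the output grid
        n_depth = n_out // 2 + 2
        z_grid = np.arange(n_depth) * (np.pi / (n_out * dk))  # nm
        basis = np.exp(2j * np.outer(kt, z_grid))
        coeff, *_ = np.linalg.lstsq(basis, flat, rcond=rcond)
        out = np.exp(2j * np.outer(k_uniform, z_grid)) @ coeff
    elif method == "spline":
        from scipy.interpolate import CubicSpline

        cs = CubicSpline(kt, flat, axis=0)
        out = cs(np.clip(k_uniform, k_lo, k_hi))
    else:
        raise CalibrationError(f"unknown regridding method {method!r}")

    return AnalyticSpectrum(
        data=np.ascontiguousarray(out.T.reshape(nx, ny, n_out)),
        k_start=float(k_start),
        dk=float(dk),
        laser_id=sweep.laser.laser_id,
        volume_index=sweep.volume_index,
    )


# ----------------------------------------------------------------------
# Overlap determination
# ----------------------------------------------------------------------

def pad_spectra(
    a: AnalyticSpectrum, b: AnalyticSpectrum
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-pad two laterally averaged spectra to the common length Na + Nb.

    Spectrum ``a`` (lower wavenumbers) occupies pixels ``[0, Na)``;
    spectrum ``b`` occupies ``[Na, Na + Nb)``.  The padding prevents the
    FFT-based cross-correlation from being circular.
    """
    if not np.isclose(a.dk, b.dk, rtol=1e-9):
        raise CalibrationError(
            f"dk mismatch: {a.dk} vs {b.dk}; regrid to a common dk first"
        )
    na, nb = a.n_k, b.n_k
    if na == 0 or nb == 0:
        raise CalibrationError("cannot pad an empty spectrum")
    pa = np.concatenate([a.mean_aline(), np.zeros(nb, complex)])
    pb = np.concatenate([np.zeros(na, complex), b.mean_aline()])
    return pa, pb


def depth_cross_correlation(
    padded_a: np.ndarray,
    padded_b: np.ndarray,
    *,
    upsampling: int = CROSS_CORR_UPSAMPLING,
    regularization: float = RHO_REGULARIZATION,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cross-correlation of two padded mirror spectra.

    Returns ``(lags_px, rho)`` where ``rho(lag)`` is the real part of the
    FFT-based cross-correlation divided by its regularized magnitude.  The
    spectral product is zero-padded ``upsampling - 1`` times before the
    inverse transform, so the lag grid has a resolution of
    ``1 / upsampling`` pixels (0.01 px by default).  For a single mirror at
    depth ``z`` the curve follows ``cos(2 dk z (lag + kappa))`` and peaks
    (ambiguously — it is periodic) wherever the cosine hits 1.
    """
    if padded_a.shape != padded_b.shape:
        raise CalibrationError("padded spectra must have equal length")
    n = padded_a.size
    product = np.fft.fft(padded_a) * np.conj(np.fft.fft(padded_b))
    r = np.fft.ifft(product, n=upsampling * n) * upsampling
    mag = np.abs(r)
    peak = mag.max()
    if peak <= 0 or not np.isfinite(peak):
        raise CalibrationError("cross-correlation has no common fringe content")
    rho = np.real(r) / np.maximum(mag, regularization * peak)
    idx = np.arange(upsampling * n)
    lags = np.where(idx < upsampling * n // 2, idx, idx - upsampling * n)
    return lags / upsampling, rho


def determine_overlap(
    pairs: Sequence[tuple[AnalyticSpectrum, AnalyticSpectrum]],
    *,
    kappa_nominal: float | None = None,
    search_window: tuple[float, float] | None = None,
    depths_um: Sequence[float] | None = None,
) -> OverlapEstimate:
    """Estimate the fractional pixel overlap from several mirror depths.

    The normalized cross-correlation from one depth is periodic and cannot
    identify the overlap by itself; summing the curves from several
    pairwise-distinct, non-harmonic depths makes them add constructively
    only at the true overlap.  The argmax of the summed curve, restricted
    to a physically plausible window around the nominal overlap, is the
    estimate.
    """
    if len(pairs) < 2:
        raise CalibrationError(
            "overlap determination needs >= 2 mirror depths; a single "
            "depth gives a periodic, ambiguous correlation"
        )
    if search_window is None:
        if kappa_nominal is None:
            raise CalibrationError(
                "provide kappa_nominal (from the nominal laser ranges) or "
                "an explicit search_window"
            )
        search_window = (0.25 * kappa_nominal, 4.0 * kappa_nominal)
    lo, hi = search_window

    if depths_um is not None and len(depths_um) >= 2:
        z = np.sort(np.asarray(depths_um, float))
        ratio = z[1:] / z[:-1]
        if np.any(np.abs(ratio - np.round(ratio)) < 1e-3):
            import warnings

            warnings.warn(
                "some calibration depths are near-integer multiples of each "
                "other; their correlation aliases may add up coherently",
                stacklevel=2,
            )

    rho_sum = None
    lags = None
    for a, b in pairs:
        pa, pb = pad_spectra(a, b)
        lags, rho = depth_cross_correlation(pa, pb)
        rho_sum = rho if rho_sum is None else rho_sum + rho

    # a true overlap kappa produces a correlation peak at lag = -kappa
    candidates = -lags
    in_window = (candidates >= lo) & (candidates <= hi)
    if not np.any(in_window):
        raise CalibrationError("search window contains no correlation lags")
    rho_win = rho_sum[in_window]
    kap_win = candidates[in_window]
    best = np.flatnonzero(rho_win == rho_win.max())
    if best.size > 1 and kappa_nominal is not None:
        best = best[np.argmin(np.abs(kap_win[best] - kappa_nominal))]
    else:
        best = best[0]
    kappa = float(kap_win[best])
    span = hi - lo
    on_boundary = (kappa - lo) < 0.01 * span or (hi - kappa) < 0.01 * span

    order = np.argsort(kap_win)
    return OverlapEstimate(
        kappa=kappa,
        rho0=rho_win[order],
        lags_px=kap_win[order],
        depths_used_um=list(depths_um) if depths_um is not None else [],
        n_depths=len(pairs),
        search_window=(float(lo), float(hi)),
        on_boundary=on_boundary,
    )


# ----------------------------------------------------------------------
# Assembling a system calibration
# ----------------------------------------------------------------------

def build_system_calibration(
    lasers: Sequence[LaserSpec],
    chirps: dict[str, ChirpCurve],
    envelopes: dict[str, EnvelopeCorrection],
    overlaps: dict[tuple[str, str], OverlapEstimate],
    dk: float,
    *,
    trim: tuple[int, int] = (DEFAULT_TRIM, DEFAULT_TRIM),
    provenance: dict | None = None,
) -> SystemCalibration:
    """Combine per-laser calibrations into one serializable object.

    ``lasers`` may be given in any order; they are sorted by ascending
    wavenumber, and an overlap estimate must exist for every adjacent pair
    in that order (keys ``(low_id, high_id)``).
    """
    ordered = sorted(lasers, key=lambda s: s.k_min)
    kappa = []
    for lo, hi in zip(ordered[:-1], ordered[1:]):
        key = (lo.laser_id, hi.laser_id)
        if key not in overlaps:
            raise CalibrationError(f"missing overlap estimate for pair {key}")
        kappa.append(overlaps[key].kappa)
    for lid in (s.laser_id for s in ordered):
        if lid not in chirps:
            raise CalibrationError(f"missing chirp curve for laser {lid!r}")
    return SystemCalibration(
        lasers=ordered,
        chirps=chirps,
        envelopes=envelopes,
        kappa=kappa,
        dk=dk,
        trim=trim,
        provenance=provenance or {},
    )


def calibrate_session(
    sweeps: dict[str, list[RawSweep]],
    lasers: Sequence[LaserSpec],
    *,
    envelope_mode: Literal["scattering", "reflecting"] = "reflecting",
    correct_envelope: bool = True,
    method: Literal["lsq", "spline"] = "lsq",
    provenance: dict | None = None,
    depths_um: Sequence[float] | None = None,
) -> SystemCalibration:
    """Run the full one-time calibration on a set of mirror sweeps.

    ``sweeps[laser_id]`` holds one single-mirror sweep per calibration
    depth (the same depths for every laser).  The common pixel size ``dk``
    is taken from the first laser in ``lasers`` (its trimmed span divided
    by its retained pixel count minus one), which leaves the reference
    laser essentially unresampled.
    """
    by_id = {s.laser_id: s for s in lasers}
    if set(sweeps) != set(by_id):
        raise CalibrationError("sweeps and lasers name different laser ids")
    n_depths = {len(v) for v in sweeps.values()}
    if len(n_depths) != 1:
        raise CalibrationError("every laser needs a sweep at every depth")

    ref = lasers[0]
    n_ref = sweeps[ref.laser_id][0].n_retained
    dk = ref.k_span / (n_ref - 1)

    chirps: dict[str, ChirpCurve] = {}
    envelopes: dict[str, EnvelopeCorrection] = {}
    spectra: dict[str, list[AnalyticSpectrum]] = {}
    trim = (sweeps[ref.laser_id][0].discard_head,
            sweeps[ref.laser_id][0].discard_tail)
    for lid, laser in by_id.items():
        # the deepest mirror gives the most fringe cycles -> best chirp SNR
        chirp_sweep = max(
            sweeps[lid], key=lambda s: _fringe_cycles(s)
        )
        chirps[lid] = estimate_chirp(chirp_sweep, laser)
        envelopes[lid] = estimate_envelope(sweeps[lid], mode=envelope_mode)
        spectra[lid] = []
        for raw in sweeps[lid]:
            use = correct_amplitude(raw, envelopes[lid]) if correct_envelope else raw
            spectra[lid].append(regrid_klinear(use, chirps[lid], dk, method=method))

    ordered = sorted(lasers, key=lambda s: s.k_min)
    overlaps: dict[tuple[str, str], OverlapEstimate] = {}
    for lo, hi in zip(ordered[:-1], ordered[1:]):
        kappa_nom = nominal_overlap_px(lo, hi, dk)
        # residual ASE background lives at shallow depths; drop it so it
        # cannot bias the fringe cross-correlation
        pairs = [
            (_depth_highpass(a), _depth_highpass(b))
            for a, b in zip(spectra[lo.laser_id], spectra[hi.laser_id])
        ]
        overlaps[(lo.laser_id, hi.laser_id)] = determine_overlap(
            pairs, kappa_nominal=kappa_nom, depths_um=depths_um
        )
    return build_system_calibration(
        lasers, chirps, envelopes, overlaps, dk,
        trim=trim, provenance=provenance,
    )


def _depth_highpass(
    spec: AnalyticSpectrum, frac_of_nyquist: float = 0.05
) -> AnalyticSpectrum:
    """Suppress depth content below a fraction of the Nyquist depth."""
    n = spec.n_k
    depth = np.fft.fft(spec.data, axis=2)
    cut = max(1, int(frac_of_nyquist * n / 2))
    depth[..., :cut] = 0.0
    depth[..., n - cut:] = 0.0  # mirror-image / conjugate leakage
    return AnalyticSpectrum(
        data=np.fft.ifft(depth, axis=2),
        k_start=spec.k_start,
        dk=spec.dk,
        laser_id=spec.laser_id,
        volume_index=spec.volume_index,
    )


def _fringe_cycles(raw: RawSweep) -> float:
    """Rough number of fringe cycles in a mirror sweep (zero crossings / 2)."""
    trace = average_alines(raw)
    trace = trace - trace.mean()
    return float(np.sum(np.abs(np.diff(np.signbit(trace)))) / 2.0)
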