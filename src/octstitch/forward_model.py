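"""Seeded forward simulator of multi-laser swept-source FF-FD-OCT raw data.

Generates the camera frame stacks a dual-laser (or n-laser) full-field
swept-source OCT system would record, together with the ground truth for
every quantity the calibration and reconstruction stages estimate: the
nonlinear sweep ``k(t)``, the interference-contrast curve ``alpha(k)``, the
inter-laser pixel overlap ``kappa``, per-volume bulk motion and phase
offsets, and the scattering phantom itself.

The detected interferogram of one laser, after removing DC and
autocorrelation terms, is modelled as

    I(x, y, t) = S(k(t)) * alpha(k(t))
                 * sum_layers A(x, y) * cos(2 k(t) z + phi(k(t)))
                 + b(k(t)) + noise,

where ``S`` is the source envelope, ``alpha`` the interference contrast
lowered near the sweep ends by incoherent ASE background ``b``, and ``phi``
collects dispersion, bulk axial motion (a phase linear in ``k``) and a
per-sweep constant phase offset.  With every disturbance switched off and a
mirror phantom this reduces to a pure sampled cosine.

Default laser parameters follow a dual-laser retinal system: one source
sweeping 805–882 nm over 515 camera frames and one sweeping 879–950 nm over
478 frames, overlapping by roughly three nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .calibration import (
    CalibrationError,
    ChirpCurve,
    LaserSpec,
    RawSweep,
    nominal_overlap_px,
    nyquist_depth_um,
)
from .calibration import AnalyticSpectrum

__all__ = [
    "ChirpModel",
    "EnvelopeModel",
    "ScatteringPhantom",
    "DisturbanceModel",
    "SimulatedSession",
    "LASER_840",
    "LASER_950",
    "default_lasers",
    "default_chirps",
    "build_chirp_curve",
    "simulate_sweep",
    "simulate_calibration_set",
    "simulate_sample_session",
    "simulate_klinear_pair",
    "default_calibration_depths",
]

# The two sources of the reference dual-laser system.  The wavelength
# endpoints refer to the retained frames after edge trimming.
LASER_840 = LaserSpec("laser840", 805.0, 882.0, 515)
LASER_950 = LaserSpec("laser950", 879.0, 950.0, 478)

# Frames between the two sweeps while the optical switch toggles.
# Informational only; no frames are synthesized for the gap.
INTER_SWEEP_GAP_FRAMES = 74


def default_lasers() -> list[LaserSpec]:
    return [LASER_840, LASER_950]


# ----------------------------------------------------------------------
# Chirp models
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ChirpModel:
    """Parametric model of the nonlinear sweep k(t).

    The sweep is written ``k(t) = k_start + span * g(tau)`` with
    ``tau in [0, 1]`` the normalized frame index and ``g`` a monotone shape
    function with ``g(0) = 0`` and ``g(1) = 1``:

    - ``linear``: ``g = tau``.
    - ``polynomial``: ``g = tau + sum_j c_j (tau**(j+2) - tau)`` with
      ``coefficients = (c_0, c_1, ...)`` for quadratic, cubic, ... terms.
      A single coefficient ``c`` peaks at ``|c| * span / 4`` deviation.
    - ``sinusoidal-perturbed``: ``g = tau + a * sin(m * pi * tau)`` with
      ``coefficients = (a,)`` or ``(a, m)``; the perturbation vanishes at
      both endpoints for integer ``m`` and its extremum is ``a * span``.
    """

    kind: Literal["linear", "polynomial", "sinusoidal-perturbed"] = "linear"
    coefficients: tuple[float, ...] = ()

    def shape(self, tau: np.ndarray) -> np.ndarray:
        tau = np.asarray(tau, dtype=float)
        if self.kind == "linear":
            return tau
        if self.kind == "polynomial":
            g = tau.copy()
            for j, c in enumerate(self.coefficients):
                g = g + c * (tau ** (j + 2) - tau)
            return g
        if self.kind == "sinusoidal-perturbed":
            if not self.coefficients:
                return tau
            a = self.coefficients[0]
            m = self.coefficients[1] if len(self.coefficients) > 1 else 1.0
            return tau + a * np.sin(m * np.pi * tau)
        raise CalibrationError(f"unknown chirp kind {self.kind!r}")


def build_chirp_curve(
    spec: LaserSpec,
    model: ChirpModel,
    *,
    margin: tuple[int, int] = (0, 0),
) -> ChirpCurve:
    """Sample the chirp model at every recorded frame of the sweep.

    ``margin = (head, tail)`` adds frames before and after the nominal
    sweep (the shape function is evaluated outside [0, 1]); those frames
    model the uncertain sweep start/stop region that the pipeline later
    discards.  The retained frames run exactly from one nominal endpoint
    wavenumber to the other, in the order given by ``sweep_direction``.
    """
    head, tail = margin
    n_total = spec.n_frames
    n_retained = n_total - head - tail
    if n_retained < 2:
        raise CalibrationError("margin leaves fewer than 2 nominal frames")
    tau = (np.arange(n_total) - head) / (n_retained - 1)
    g = model.shape(tau)
    if spec.sweep_direction == "increasing_k":
        k = spec.k_min + spec.k_span * g
    else:
        k = spec.k_max - spec.k_span * g
    d = np.diff(k)
    sgn = 1.0 if spec.sweep_direction == "increasing_k" else -1.0
    if np.any(d * sgn <= 0):
        bad = int(np.argmax(d * sgn <= 0))
        raise CalibrationError(
            f"chirp model is not monotonic for laser {spec.laser_id!r}: "
            f"first violation between frames {bad} and {bad + 1}"
        )
    return ChirpCurve(laser_id=spec.laser_id, k_of_t=k)


def default_chirps(
    lasers: Sequence[LaserSpec] | None = None,
) -> dict[str, ChirpModel]:
    """Study-condition chirps: a 5% quadratic bow plus a 1% sine wiggle.

    Tunable SOA-based swept sources tune smoothly but not linearly; a
    few-percent
    smooth deviation from linearity is representative.
    """
    lasers = lasers or default_lasers()
    out = {}
    for i, s in enumerate(lasers):
        # alternate the bow sign so the two lasers are not trivially alike;
        # the sweep-rate variation stays below ~18% so that mirrors up to
        # ~80% of the uniform-grid Nyquist depth never alias locally
        c = 0.12 if i % 2 == 0 else -0.10
        out[s.laser_id] = ChirpModel("polynomial", (c, -0.03 * (-1) ** i))
    return out


# ----------------------------------------------------------------------
# Envelope / ASE model
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class EnvelopeModel:
    """Source envelope S(k) and ASE contrast model.

    Swept SOA sources emit an almost rectangular spectrum, but towards the
    sweep ends a growing share of the output is incoherent ASE: the total
    intensity stays high while the interference contrast drops.  This is
    modelled as a contrast curve

        alpha(k) = 1 - (1 - ase_contrast_floor) * edge_ramp(k)

    (``edge_ramp`` is a raised-cosine going from 0 in the interior to 1 at
    the sweep endpoints over ``ase_edge_fraction`` of the sweep) plus an
    incoherent background ``b(k) = ase_background * edge_ramp(k)`` added to
    the DC level.  ``alpha`` is the literal ground truth for the contrast
    the calibration estimates.
    """

    shape: Literal["rectangular", "rounded-rectangular"] = "rectangular"
    ase_edge_fraction: float = 0.0
    ase_contrast_floor: float = 1.0
    ase_background: float = 0.0
    rounding_fraction: float = 0.06

    def __post_init__(self) -> None:
        if not 0.0 <= self.ase_edge_fraction <= 0.3:
            raise CalibrationError("ase_edge_fraction must be in [0, 0.3]")
        if not 0.0 < self.ase_contrast_floor <= 1.0:
            raise CalibrationError("ase_contrast_floor must be in (0, 1]")

    def _edge_ramp(self, tau: np.ndarray) -> np.ndarray:
        f = self.ase_edge_fraction
        if f <= 0:
            return np.zeros_like(tau)
        ramp = np.zeros_like(tau)
        lo = tau < f
        hi = tau > 1 - f
        ramp[lo] = 0.5 * (1 + np.cos(np.pi * tau[lo] / f))
        ramp[hi] = 0.5 * (1 + np.cos(np.pi * (1 - tau[hi]) / f))
        return ramp

    def source_envelope(self, tau: np.ndarray) -> np.ndarray:
        if self.shape == "rectangular":
            return np.ones_like(tau)
        r = self.rounding_fraction
        env = np.ones_like(tau)
        lo = tau < r
        hi = tau > 1 - r
        env[lo] = 0.5 * (1 - np.cos(np.pi * tau[lo] / r))
        env[hi] = 0.5 * (1 - np.cos(np.pi * (1 - tau[hi]) / r))
        return env

    def contrast(self, tau: np.ndarray) -> np.ndarray:
        return 1.0 - (1.0 - self.ase_contrast_floor) * self._edge_ramp(tau)

    def background(self, tau: np.ndarray) -> np.ndarray:
        return self.ase_background * self._edge_ramp(tau)


FLAT_ENVELOPE = EnvelopeModel()

# mild, realistic ASE: contrast dips to ~0.7 over the outer 8% of the sweep
DEFAULT_ENVELOPE = EnvelopeModel(
    shape="rectangular",
    ase_edge_fraction=0.08,
    ase_contrast_floor=0.7,
    ase_background=0.3,
)


# ----------------------------------------------------------------------
# Phantoms
# ----------------------------------------------------------------------

@dataclass
class ScatteringPhantom:
    """Discrete-layer scattering phantom.

    ``depths_um`` lists the optical depths (air path, micrometres) of the
    layers — either a 1-D array shared by all lateral positions or a
    (nx, ny, n_layers) array for laterally decorrelated scatterers;
    ``amplitudes`` likewise is 1-D or (nx, ny, n_layers).
    """

    kind: Literal["mirror", "layered", "volumetric"]
    depths_um: np.ndarray
    amplitudes: np.ndarray
    lateral_size: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        self.depths_um = np.atleast_1d(np.asarray(self.depths_um, float))
        self.amplitudes = np.asarray(self.amplitudes, float)
        if np.any(self.amplitudes < 0):
            raise CalibrationError("phantom amplitudes must be non-negative")
        if np.any(self.depths_um <= 0):
            raise CalibrationError("phantom depths must be positive")

    @classmethod
    def mirror(
        cls, z_um: float, amplitude: float = 1.0,
        lateral_size: tuple[int, int] = (1, 1),
    ) -> "ScatteringPhantom":
        return cls("mirror", np.array([z_um]), np.array([amplitude]),
                   lateral_size)

    @classmethod
    def layered(
        cls, layers: Sequence[tuple[float, float]],
        lateral_size: tuple[int, int] = (1, 1),
    ) -> "ScatteringPhantom":
        z = np.array([l[0] for l in layers])
        a = np.array([l[1] for l in layers])
        return cls("layered", z, a, lateral_size)

    @classmethod
    def random_volume(
        cls,
        rng: np.random.Generator,
        n_layers: int,
        z_range_um: tuple[float, float],
        lateral_size: tuple[int, int],
        amplitude: float = 1.0,
    ) -> "ScatteringPhantom":
        """Tissue-like stand-in: independent random scatterer depths and
        amplitudes at every lateral position (lateral speckle decorrelates).
        """
        nx, ny = lateral_size
        z = rng.uniform(*z_range_um, size=(nx, ny, n_layers))
        a = amplitude * rng.uniform(0.3, 1.0, size=(nx, ny, n_layers))
        return cls("volumetric", z, a, lateral_size)

    def amplitude_array(self) -> np.ndarray:
        """Amplitudes broadcast to (nx, ny, n_layers)."""
        nx, ny = self.lateral_size
        if self.amplitudes.ndim == 1:
            return np.broadcast_to(
                self.amplitudes, (nx, ny, self.amplitudes.size)
            )
        return self.amplitudes

    def check_nyquist(self, dk: float) -> None:
        zmax = nyquist_depth_um(dk)
        if np.any(self.depths_um >= zmax):
            raise CalibrationError(
                f"phantom depth {self.depths_um.max():.1f} um is at or above "
                f"the Nyquist depth {zmax:.1f} um; the fringe would alias "
                "and invalidate the calibration"
            )


# ----------------------------------------------------------------------
# Disturbances
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class DisturbanceModel:
    """Phase and noise disturbances applied to simulated sweeps.

    ``dispersion_coeffs`` are polynomial spectral-phase coefficients in the
    normalized detuning ``u = (k - k0) / (span / 2) in [-1, 1]``, starting
    at the quadratic order: ``phi_disp(u) = c2 u^2 + c3 u^3 + ...`` (rad at
    the sweep edge).  ``bulk_motion_um`` is a per-volume axial displacement
    trace adding ``2 k dz`` to the phase; ``phase_offset`` a constant phase
    per sweep; ``noise_sigma`` the detector-noise standard deviation
    relative to the summed fringe amplitude.  With all fields zero the
    generated frames are exactly the noiseless interferogram model.
    """

    dispersion_coeffs: tuple[float, ...] = ()
    bulk_motion_um: tuple[float, ...] = ()
    phase_offset: float = 0.0
    random_phase_offsets: bool = False
    noise_sigma: float = 0.0
    seed: int = 0


NO_DISTURBANCE = DisturbanceModel()


# ----------------------------------------------------------------------
# Session container
# ----------------------------------------------------------------------

@dataclass
class SimulatedSession:
    """Raw sweeps plus the ground truth needed to verify every estimator."""

    lasers: list[LaserSpec]
    raw: dict[str, list[RawSweep]]
    truth: dict = field(default_factory=dict)

    @property
    def n_volumes(self) -> int:
        return len(next(iter(self.raw.values())))


# ----------------------------------------------------------------------
# Sweep synthesis
# ----------------------------------------------------------------------

def simulate_sweep(
    spec: LaserSpec,
    chirp: ChirpCurve,
    envelope: EnvelopeModel,
    phantom: ScatteringPhantom,
    disturb: DisturbanceModel = NO_DISTURBANCE,
    *,
    rng: np.random.Generator | None = None,
    volume_index: int = 0,
    discard: tuple[int, int] = (0, 0),
    dc_level: float = 0.0,
    extra_phase_offset: float = 0.0,
    bulk_shift_um: float = 0.0,
) -> RawSweep:
    """Synthesize the camera frames of one sweep of one laser.

    ``chirp.k_of_t`` must cover every recorded frame (``spec.n_frames``
    samples, including any head/tail margin declared via ``discard``).
    """
    kt = np.asarray(chirp.k_of_t, float)
    if kt.size != spec.n_frames:
        raise CalibrationError(
            f"chirp has {kt.size} samples, laser records {spec.n_frames} "
            "frames"
        )
    # guard against aliasing with the *largest* local node spacing: the
    # instantaneous fringe frequency must stay below the frame-rate Nyquist
    # everywhere along the (chirped) sweep
    dk_native = np.abs(np.diff(kt)).max()
    phantom.check_nyquist(dk_native)

    tau = _tau_of(kt, spec)
    s_env = envelope.source_envelope(tau)
    alpha = envelope.contrast(tau)
    bg = envelope.background(tau)

    k0 = 0.5 * (spec.k_min + spec.k_max)
    half_span = 0.5 * spec.k_span
    u = (kt - k0) / half_span
    phi = np.full(kt.shape, disturb.phase_offset + extra_phase_offset)
    for p, c in enumerate(disturb.dispersion_coeffs, start=2):
        phi = phi + c * u**p
    if bulk_shift_um != 0.0:
        phi = phi + 2.0 * kt * (bulk_shift_um * 1000.0)

    z_nm = phantom.depths_um * 1000.0
    amps = phantom.amplitude_array()  # (nx, ny, nl)
    if z_nm.ndim == 1:
        # shared layer depths: one carrier per layer
        carrier = np.cos(
            2.0 * np.multiply.outer(z_nm, kt) + phi[None, :]
        )  # (nl, nt)
        frames = np.einsum("xyl,lt->xyt", amps, carrier)
    else:
        # per-position depths: accumulate layer by layer to bound memory
        nx, ny = z_nm.shape[:2]
        frames = np.zeros((nx, ny, kt.size))
        for l in range(z_nm.shape[2]):
            frames += amps[:, :, l, None] * np.cos(
                2.0 * z_nm[:, :, l, None] * kt + phi
            )
    frames *= (s_env * alpha)[None, None, :]
    frames += (bg + dc_level)[None, None, :]

    if disturb.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(disturb.seed)
        scale = disturb.noise_sigma * float(np.abs(amps).sum(axis=2).mean())
        frames = frames + rng.normal(0.0, scale, size=frames.shape)

    return RawSweep(
        frames=frames.astype(np.float64),
        laser=spec,
        discard_head=discard[0],
        discard_tail=discard[1],
        volume_index=volume_index,
    )


def _tau_of(kt: np.ndarray, spec: LaserSpec) -> np.ndarray:
    """Normalized sweep position in [0, 1] of each frame (0 = k_min end)."""
    return (kt - spec.k_min) / spec.k_span


# ----------------------------------------------------------------------
# Calibration sessions
# ----------------------------------------------------------------------

def default_calibration_depths(
    n: int,
    dk: float,
    seed: int = 0,
    *,
    span: tuple[float, float] = (0.10, 0.80),
) -> np.ndarray:
    """Log-spaced mirror depths over a fraction of the Nyquist depth.

    The depths are jittered (deterministically from ``seed``) to avoid
    integer depth ratios, which would let correlation aliases from
    different depths add up coherently.
    """
    zmax = nyquist_depth_um(dk)
    rng = np.random.default_rng(seed)
    base = np.geomspace(span[0] * zmax, span[1] * zmax, n)
    jitter = rng.uniform(0.97, 1.03, size=n)
    return base * jitter


def truth_overlap_px(lasers: Sequence[LaserSpec], dk: float) -> list[float]:
    """Ground-truth overlap for each adjacent pair on the calibrated grid.

    The calibration anchors each laser's grid at its nominal ``k_min`` with
    ``N = floor(span / dk) + 1`` pixels; the overlap between adjacent
    lasers (ascending k order) is the inclusive pixel count of the shared
    interval ``(k_stop_low - k_start_high) / dk + 1``.
    """
    ordered = sorted(lasers, key=lambda s: s.k_min)
    out = []
    for lo, hi in zip(ordered[:-1], ordered[1:]):
        n_lo = int(np.floor(lo.k_span / dk + 1e-9)) + 1
        k_stop_lo = lo.k_min + (n_lo - 1) * dk
        out.append((k_stop_lo - hi.k_min) / dk + 1.0)
    return out


def simulate_calibration_set(
    lasers: Sequence[LaserSpec] | None = None,
    chirps: dict[str, ChirpModel] | None = None,
    envelopes: dict[str, EnvelopeModel] | EnvelopeModel | None = None,
    depths_um: Sequence[float] | None = None,
    seed: int = 0,
    *,
    n_depths: int = 6,
    margin: tuple[int, int] = (8, 8),
    lateral_size: tuple[int, int] = (2, 2),
    noise_sigma: float = 0.0,
    dc_level: float = 1.0,
) -> SimulatedSession:
    """Simulate the one-time calibration acquisition.

    A mirror in a stable, dispersion-free interferometer is locked at a
    fixed depth and both lasers record one sweep; this repeats for several
    depths.  ``margin`` frames at each sweep end lie outside the nominal
    wavelength range (uncertain sweep start/stop) and are marked for
    discarding.  The recorded ground truth includes the chirp curves on the
    retained frames, the contrast curves, the depths, and the overlap in
    pixels on the calibrated common grid.
    """
    lasers = list(lasers) if lasers is not None else default_lasers()
    if chirps is None:
        chirps = default_chirps(lasers)
    if envelopes is None:
        envelopes = {s.laser_id: DEFAULT_ENVELOPE for s in lasers}
    elif isinstance(envelopes, EnvelopeModel):
        envelopes = {s.laser_id: envelopes for s in lasers}

    ref = lasers[0]
    dk = ref.k_span / (ref.n_frames - sum(margin) - 1)
    if depths_um is None:
        depths_um = default_calibration_depths(n_depths, dk, seed)
    depths_um = np.asarray(depths_um, float)
    if depths_um.size < 2:
        raise CalibrationError(
            "calibration needs >= 2 mirror depths for overlap determination"
        )
    if depths_um.size != np.unique(depths_um).size:
        raise CalibrationError("calibration depths must be pairwise distinct")

    rng = np.random.default_rng(seed)
    raw: dict[str, list[RawSweep]] = {s.laser_id: [] for s in lasers}
    truth_chirps: dict[str, ChirpCurve] = {}
    truth_alpha: dict[str, np.ndarray] = {}
    head, tail = margin
    for spec in lasers:
        n_total = spec.n_frames
        curve = build_chirp_curve(spec, chirps[spec.laser_id],
                                  margin=margin)
        retained = curve.k_of_t[head:n_total - tail]
        truth_chirps[spec.laser_id] = ChirpCurve(spec.laser_id, retained)
        tau = _tau_of(retained, spec)
        truth_alpha[spec.laser_id] = envelopes[spec.laser_id].contrast(tau)
        for z in depths_um:
            sweep = simulate_sweep(
                spec,
                curve,
                envelopes[spec.laser_id],
                ScatteringPhantom.mirror(float(z), 1.0, lateral_size),
                DisturbanceModel(noise_sigma=noise_sigma,
                                 seed=int(rng.integers(2**31 - 1))),
                rng=rng,
                discard=margin,
                dc_level=dc_level,
            )
            raw[spec.laser_id].append(sweep)

    truth = {
        "chirp": truth_chirps,
        "alpha": truth_alpha,
        "depths_um": depths_um,
        "dk": dk,
        "kappa": truth_overlap_px(lasers, dk),
        "seed": seed,
    }
    return SimulatedSession(lasers=lasers, raw=raw, truth=truth)


# ----------------------------------------------------------------------
# Sample sessions
# ----------------------------------------------------------------------

def simulate_sample_session(
    lasers: Sequence[LaserSpec] | None = None,
    chirps: dict[str, ChirpModel] | None = None,
    envelopes: dict[str, EnvelopeModel] | EnvelopeModel | None = None,
    phantom: ScatteringPhantom | None = None,
    n_volumes: int = 1,
    disturb: DisturbanceModel = NO_DISTURBANCE,
    seed: int = 0,
    *,
    margin: tuple[int, int] = (8, 8),
    dc_level: float = 1.0,
) -> SimulatedSession:
    """Simulate a sample acquisition of one or more volumes.

    One sweep per laser per volume is generated.  Bulk motion is drawn (or
    taken from ``disturb.bulk_motion_um``) per volume and applied to both
    lasers of that volume; an additional constant phase offset per sweep
    models the inter-sweep motion the phase search must recover.
    """
    if n_volumes < 1:
        raise CalibrationError("n_volumes must be >= 1")
    lasers = list(lasers) if lasers is not None else default_lasers()
    if chirps is None:
        chirps = default_chirps(lasers)
    if envelopes is None:
        envelopes = {s.laser_id: DEFAULT_ENVELOPE for s in lasers}
    elif isinstance(envelopes, EnvelopeModel):
        envelopes = {s.laser_id: envelopes for s in lasers}
    if phantom is None:
        rng0 = np.random.default_rng(seed)
        phantom = ScatteringPhantom.random_volume(
            rng0, 12, (80.0, 700.0), (4, 4)
        )

    rng = np.random.default_rng(seed + 1)
    motion = np.asarray(disturb.bulk_motion_um, float)
    if motion.size == 0:
        motion = np.zeros(n_volumes)
    if motion.size != n_volumes:
        raise CalibrationError(
            f"bulk_motion_um has {motion.size} entries for {n_volumes} "
            "volumes"
        )

    offsets = np.zeros((n_volumes, len(lasers)))
    if disturb.random_phase_offsets:
        offsets = rng.uniform(0.0, 2.0 * np.pi, size=offsets.shape)
    elif disturb.phase_offset != 0.0:
        # a constant offset on every laser except the one that leads the
        # stitching chain (lowest wavenumber)
        lead = int(np.argmin([s.k_min for s in lasers]))
        offsets[:, :] = disturb.phase_offset
        offsets[:, lead] = 0.0

    raw: dict[str, list[RawSweep]] = {s.laser_id: [] for s in lasers}
    truth_chirps = {}
    for j, spec in enumerate(lasers):
        curve = build_chirp_curve(spec, chirps[spec.laser_id], margin=margin)
        head, tail = margin
        truth_chirps[spec.laser_id] = ChirpCurve(
            spec.laser_id, curve.k_of_t[head:spec.n_frames - tail]
        )
        for v in range(n_volumes):
            sweep = simulate_sweep(
                spec,
                curve,
                envelopes[spec.laser_id],
                phantom,
                DisturbanceModel(
                    dispersion_coeffs=disturb.dispersion_coeffs,
                    noise_sigma=disturb.noise_sigma,
                    seed=int(rng.integers(2**31 - 1)),
                ),
                rng=rng,
                volume_index=v,
                discard=margin,
                dc_level=dc_level,
                extra_phase_offset=float(offsets[v, j]),
                bulk_shift_um=float(motion[v]),
            )
            raw[spec.laser_id].append(sweep)

    truth = {
        "chirp": truth_chirps,
        "phantom": phantom,
        "bulk_motion_um": motion,
        "phase_offsets": offsets,
        "dispersion_coeffs": tuple(disturb.dispersion_coeffs),
        "seed": seed,
    }
    return SimulatedSession(lasers=lasers, raw=raw, truth=truth)


# ----------------------------------------------------------------------
# Directly k-linear spectrum pairs (overlap-estimator test bench)
# ----------------------------------------------------------------------

def simulate_klinear_pair(
    kappa_px: float,
    depths_um: Sequence[float],
    *,
    n_a: int = 403,
    n_b: int = 515,
    dk: float = 1.3258e-6,
    k_start: float | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> list[tuple[AnalyticSpectrum, AnalyticSpectrum]]:
    """Pairs of ideal k-linear mirror spectra with a known pixel overlap.

    Bypasses chirp simulation and calibration entirely: two flat-envelope
    complex fringes on uniform grids whose wavenumber ranges share exactly
    ``kappa_px`` pixels, one pair per mirror depth.  This is the controlled
    input for validating the overlap estimator in isolation.
    """
    if k_start is None:
        k_start = 2.0 * np.pi / 950.0
    rng = np.random.default_rng(seed)
    k_b0 = k_start + (n_a - kappa_px) * dk
    ka = k_start + dk * np.arange(n_a)
    kb = k_b0 + dk * np.arange(n_b)
    out = []
    for z_um in depths_um:
        z_nm = z_um * 1000.0
        a = np.exp(1j * 2.0 * ka * z_nm)
        b = np.exp(1j * 2.0 * kb * z_nm)
        if noise_sigma > 0:
            a = a + noise_sigma * (
                rng.normal(size=n_a) + 1j * rng.normal(size=n_a)
            ) / np.sqrt(2.0)
            b = b + noise_sigma * (
                rng.normal(size=n_b) + 1j * rng.normal(size=n_b)
            ) / np.sqrt(2.0)
        out.append(
            (
                AnalyticSpectrum(a, k_start=k_start, dk=dk, laser_id="low"),
                AnalyticSpectrum(b, k_start=k_b0, dk=dk, laser_id="high"),
            )
        )
    return out
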