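"""File formats, session manifests, and the end-to-end pipeline driver.

Canonical on-disk layout is a single HDF5 file per acquisition session::

    /                attrs: format, seed
    /manifest        JSON string (lasers, trim counts, acquisition metadata)
    /raw/<laser>/vol<i>   float32 dataset (nx, ny, n_frames)
    /truth/...       optional ground-truth group written by the simulator

Frame stacks can alternatively be stored as one multi-page TIFF per sweep
(pages along the frame axis) with a JSON sidecar carrying the same
metadata; both formats load to identical arrays.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional, Sequence

import h5py
import numpy as np
import tifffile
from pydantic import BaseModel, Field, ValidationError

from . import forward_model as fm
from .calibration import (
    AnalyticSpectrum,
    CalibrationError,
    ChirpCurve,
    LaserSpec,
    RawSweep,
    SystemCalibration,
    correct_amplitude,
    regrid_klinear,
)
from .reconstruction import (
    PhaseOffsetField,
    ReconVolume,
    StitchPlan,
    apodize,
    correct_motion_phase,
    reconstruct_volume,
    register_volumes,
    search_phase_offsets,
    stitch_chain,
    subtract_background,
)

__all__ = [
    "SchemaError",
    "SessionManifest",
    "LaserEntry",
    "PipelineConfig",
    "PipelineResult",
    "write_session",
    "read_session",
    "write_sweep_tiff",
    "read_sweep_tiff",
    "write_session_tiff",
    "read_session_tiff",
    "run_pipeline",
    "calibration_checksum",
]

SESSION_FORMAT = "octstitch-session-1"

log = logging.getLogger("octstitch.pipeline")


class SchemaError(ValueError):
    """A file does not follow the documented session schema."""


class LaserEntry(BaseModel):
    laser_id: str
    lambda_min_nm: float
    lambda_max_nm: float
    n_frames: int = Field(ge=16)
    sweep_direction: Literal["increasing_k", "decreasing_k"] = "increasing_k"

    def to_spec(self) -> LaserSpec:
        return LaserSpec(**self.model_dump())


class SessionManifest(BaseModel):
    """Declarative description of one acquisition session."""

    lasers: list[LaserEntry]
    n_volumes: int = Field(ge=1)
    discard_head: int = 0
    discard_tail: int = 0
    frame_rate_hz: Optional[float] = None
    gap_frames: int = fm.INTER_SWEEP_GAP_FRAMES
    seed: Optional[int] = None


# ----------------------------------------------------------------------
# HDF5 sessions
# ----------------------------------------------------------------------

def write_session(session: fm.SimulatedSession, path) -> None:
    """Write a session (and its ground truth, if any) to one HDF5 file."""
    first = next(iter(session.raw.values()))[0]
    manifest = SessionManifest(
        lasers=[LaserEntry(**dataclasses.asdict(s)) for s in session.lasers],
        n_volumes=session.n_volumes,
        discard_head=first.discard_head,
        discard_tail=first.discard_tail,
        seed=session.truth.get("seed"),
    )
    with h5py.File(path, "w") as f:
        f.attrs["format"] = SESSION_FORMAT
        f.attrs["manifest"] = manifest.model_dump_json()
        for lid, sweeps in session.raw.items():
            g = f.create_group(f"raw/{lid}")
            for i, sw in enumerate(sweeps):
                d = g.create_dataset(
                    f"vol{i:03d}", data=sw.frames.astype(np.float32)
                )
                d.attrs["discard_head"] = sw.discard_head
                d.attrs["discard_tail"] = sw.discard_tail
                d.attrs["volume_index"] = sw.volume_index
        _write_truth(f, session.truth)


def _write_truth(f: h5py.File, truth: dict) -> None:
    if not truth:
        return
    g = f.create_group("truth")
    for key, val in truth.items():
        if key in ("chirp",):
            for lid, curve in val.items():
                g.create_dataset(f"chirp/{lid}", data=curve.k_of_t)
        elif key == "alpha":
            for lid, arr in val.items():
                g.create_dataset(f"alpha/{lid}", data=arr)
        elif key == "phantom":
            ph = g.create_group("phantom")
            ph.attrs["kind"] = val.kind
            ph.create_dataset("depths_um", data=val.depths_um)
            ph.create_dataset("amplitudes", data=val.amplitudes)
            ph.attrs["lateral_size"] = val.lateral_size
        elif np.isscalar(val):
            g.attrs[key] = val
        else:
            g.create_dataset(key, data=np.asarray(val))


def read_session(
    path,
) -> tuple[SessionManifest, fm.SimulatedSession]:
    """Load a session HDF5 file, validating it against the schema."""
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != SESSION_FORMAT:
            raise SchemaError(
                f"{path}: not an octstitch session (format attribute "
                f"{f.attrs.get('format')!r})"
            )
        try:
            manifest = SessionManifest.model_validate_json(f.attrs["manifest"])
        except (KeyError, ValidationError) as exc:
            raise SchemaError(f"{path}: invalid manifest: {exc}") from exc
        lasers = [e.to_spec() for e in manifest.lasers]
        raw: dict[str, list[RawSweep]] = {}
        for spec in lasers:
            lid = spec.laser_id
            if f"raw/{lid}" not in f:
                raise SchemaError(f"{path}: missing dataset group raw/{lid}")
            g = f[f"raw/{lid}"]
            sweeps = []
            for i in range(manifest.n_volumes):
                name = f"vol{i:03d}"
                if name not in g:
                    raise SchemaError(
                        f"{path}: missing dataset raw/{lid}/{name}"
                    )
                d = g[name]
                if d.ndim != 3 or d.shape[2] != spec.n_frames:
                    raise SchemaError(
                        f"{path}: raw/{lid}/{name} has shape {d.shape}, "
                        f"expected (nx, ny, {spec.n_frames})"
                    )
                sweeps.append(
                    RawSweep(
                        frames=d[()],
                        laser=spec,
                        discard_head=int(d.attrs.get("discard_head", 0)),
                        discard_tail=int(d.attrs.get("discard_tail", 0)),
                        volume_index=int(d.attrs.get("volume_index", i)),
                    )
                )
            raw[lid] = sweeps
        truth = _read_truth(f) if "truth" in f else {}
    return manifest, fm.SimulatedSession(lasers=lasers, raw=raw, truth=truth)


def _read_truth(f: h5py.File) -> dict:
    g = f["truth"]
    truth: dict = dict(g.attrs)
    if "chirp" in g:
        truth["chirp"] = {
            lid: ChirpCurve(laser_id=lid, k_of_t=g[f"chirp/{lid}"][()])
            for lid in g["chirp"]
        }
    if "alpha" in g:
        truth["alpha"] = {lid: g[f"alpha/{lid}"][()] for lid in g["alpha"]}
    if "phantom" in g:
        ph = g["phantom"]
        truth["phantom"] = fm.ScatteringPhantom(
            kind=str(ph.attrs["kind"]),
            depths_um=ph["depths_um"][()],
            amplitudes=ph["amplitudes"][()],
            lateral_size=tuple(int(v) for v in ph.attrs["lateral_size"]),
        )
    for key in ("depths_um", "kappa", "bulk_motion_um", "phase_offsets"):
        if key in g:
            truth[key] = g[key][()]
    return truth


# ----------------------------------------------------------------------
# TIFF + JSON sidecar
# ----------------------------------------------------------------------

def write_sweep_tiff(sweep: RawSweep, path) -> None:
    """One multi-page TIFF per sweep (pages = frames) + JSON sidecar."""
    path = Path(path)
    # pages along the frame axis
    tifffile.imwrite(path, np.moveaxis(
        sweep.frames.astype(np.float32), 2, 0))
    sidecar = {
        "laser": dataclasses.asdict(sweep.laser),
        "discard_head": sweep.discard_head,
        "discard_tail": sweep.discard_tail,
        "volume_index": sweep.volume_index,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_sweep_tiff(path) -> RawSweep:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise SchemaError(f"missing JSON sidecar for {path}")
    sidecar = json.loads(sidecar_path.read_text())
    frames = np.moveaxis(tifffile.imread(path), 0, 2)
    spec = LaserSpec(**sidecar["laser"])
    if frames.shape[2] != spec.n_frames:
        raise SchemaError(
            f"{path}: {frames.shape[2]} pages, laser declares "
            f"{spec.n_frames} frames"
        )
    return RawSweep(
        frames=frames,
        laser=spec,
        discard_head=int(sidecar["discard_head"]),
        discard_tail=int(sidecar["discard_tail"]),
        volume_index=int(sidecar["volume_index"]),
    )


def write_session_tiff(session: fm.SimulatedSession, directory) -> None:
    """Session as one TIFF+sidecar pair per sweep (no ground truth)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for lid, sweeps in session.raw.items():
        for i, sw in enumerate(sweeps):
            write_sweep_tiff(sw, directory / f"{lid}_vol{i:03d}.tiff")


def read_session_tiff(directory) -> fm.SimulatedSession:
    directory = Path(directory)
    sweeps = [read_sweep_tiff(p) for p in sorted(directory.glob("*.tiff"))]
    if not sweeps:
        raise SchemaError(f"no TIFF sweeps found in {directory}")
    raw: dict[str, list[RawSweep]] = {}
    lasers: dict[str, LaserSpec] = {}
    for sw in sweeps:
        raw.setdefault(sw.laser.laser_id, []).append(sw)
        lasers[sw.laser.laser_id] = sw.laser
    for lid in raw:
        raw[lid].sort(key=lambda s: s.volume_index)
    return fm.SimulatedSession(lasers=list(lasers.values()), raw=raw)


# ----------------------------------------------------------------------
# Pipeline driver
# ----------------------------------------------------------------------

class PipelineConfig(BaseModel):
    """Resolved configuration of one reconstruction run."""

    bins: tuple[int, int] = (25, 25)
    pad_factor: int = Field(default=4, ge=2)
    gamma: float = 1.4
    apodization: str = "none"  # "none" or "tukey:<ratio>"
    motion_order: int = 0  # 0 disables the order >= 2 phase correction
    registration: bool = True
    # calibration-target sessions from the stable interferometer carry no
    # inter-sweep phase jumps and are stitched directly at zero offset
    phase_search: bool = True
    regrid_method: Literal["lsq", "spline"] = "lsq"
    remove_lateral_mean: bool = False
    seed: int = 0


@dataclasses.dataclass
class PipelineResult:
    """Everything a reconstruction run produced, with its provenance."""

    stitched: list[AnalyticSpectrum]
    volumes: list[ReconVolume]
    shifts_um: list[float]
    phase_fields: list[list[PhaseOffsetField]]
    motion: list
    config: PipelineConfig
    calibration_checksum: str


def calibration_checksum(calib: SystemCalibration) -> str:
    """Stable digest of a calibration (identifies outputs' provenance)."""
    h = hashlib.sha256()
    h.update(json.dumps(
        {
            "lasers": [dataclasses.asdict(s) for s in calib.lasers],
            "kappa": list(calib.kappa),
            "dk": calib.dk,
        },
        sort_keys=True,
    ).encode())
    for lid in sorted(calib.chirps):
        h.update(np.ascontiguousarray(calib.chirps[lid].k_of_t).tobytes())
    return h.hexdigest()[:16]


def run_pipeline(
    session: fm.SimulatedSession,
    calib: SystemCalibration,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Execute the full reconstruction on every volume of a session.

    Stages: split by laser -> background subtraction -> contrast
    correction -> k-linearization on the calibrated grid -> motion-phase
    correction -> mutual registration -> per-bin phase-offset search ->
    stitching -> optional apodization -> depth reconstruction.
    Deterministic for a given session, calibration and config.
    """
    config = config or PipelineConfig()
    order = [s.laser_id for s in calib.lasers]  # ascending k
    log.info("pipeline start: lasers=%s volumes=%d config=%s",
             order, session.n_volumes, config.model_dump())
    t_start = time.perf_counter()

    spectra: dict[str, list[AnalyticSpectrum]] = {lid: [] for lid in order}
    motion = []
    for lid in order:
        if lid not in session.raw:
            raise SchemaError(f"session has no sweeps for laser {lid!r}")
        env = calib.envelopes.get(lid)
        for sweep in session.raw[lid]:
            try:
                s = subtract_background(
                    sweep, remove_lateral_mean=config.remove_lateral_mean
                )
                if env is not None and env.alpha.size == s.n_retained:
                    s = correct_amplitude(s, env)
                spec = regrid_klinear(
                    s, calib.chirps[lid], calib.dk,
                    method=config.regrid_method,
                )
                if config.motion_order >= 2:
                    spec, mp = correct_motion_phase(
                        spec, config.motion_order, gamma=config.gamma
                    )
                    motion.append(mp)
            except CalibrationError as exc:
                raise CalibrationError(
                    f"stage failure (laser {lid!r}, volume "
                    f"{sweep.volume_index}): {exc}"
                ) from exc
            spectra[lid].append(spec)
    log.info("preprocessing (background, contrast, regrid%s) done in %.2fs",
             ", motion" if config.motion_order >= 2 else "",
             time.perf_counter() - t_start)

    # volumes of each laser are registered to that laser's first volume
    # (same-grid phase-slope estimates are subpixel-exact); the remaining
    # inter-laser mismatch is a constant phase handled by the bin search
    n_vol = session.n_volumes
    shifts: list[float] = []
    for lid in order:
        if config.registration and n_vol > 1:
            s, deramped = register_volumes(spectra[lid])
            spectra[lid] = deramped
            shifts.extend(s)
        else:
            shifts.extend([0.0] * n_vol)

    plan = StitchPlan.from_calibration(calib, apodization=config.apodization)
    stitched: list[AnalyticSpectrum] = []
    volumes: list[ReconVolume] = []
    all_fields: list[list[PhaseOffsetField]] = []
    checksum = calibration_checksum(calib)
    for v in range(n_vol):
        chain = [spectra[lid][v] for lid in order]
        fields: list[PhaseOffsetField] = []
        acc = chain[0]
        for nxt, kap in zip(chain[1:], plan.kappa):
            if config.phase_search:
                pf = search_phase_offsets(
                    acc, nxt, bins=config.bins, kappa=kap,
                    gamma=config.gamma, pad_factor=config.pad_factor,
                )
            else:
                pf = PhaseOffsetField.constant(0.0)
            fields.append(pf)
            acc = stitch_chain([acc, nxt], [pf], [kap])
        if config.apodization != "none":
            acc = apodize(acc, config.apodization)
        vol = reconstruct_volume(acc)
        vol.provenance.update(
            config=config.model_dump(), calibration=checksum, volume=v
        )
        stitched.append(acc)
        volumes.append(vol)
        all_fields.append(fields)
    log.info("pipeline done: %d stitched volume(s) in %.2fs",
             len(volumes), time.perf_counter() - t_start)

    return PipelineResult(
        stitched=stitched,
        volumes=volumes,
        shifts_um=shifts,
        phase_fields=all_fields,
        motion=motion,
        config=config,
        calibration_checksum=checksum,
    )
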