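"""Explicit finite-difference bioheat solver.

Temperature evolves by simple heat diffusion with a volumetric source:

    rho c_p dT/dt = q + div(k grad T)

discretized on the voxel grid with a seven-point stencil whose face
conductivities are harmonic means ``2 k k_n / (k + k_n)`` of the two
adjacent voxels (exact for the series resistance of dissimilar
materials). The update is explicit, so the time step is bounded by the
usual stability limit; :func:`stability_timestep` evaluates the per-voxel
bound and applies a 0.5 safety factor. Blood perfusion and metabolic
heat are deliberately absent from the model.

The source is the Monte Carlo absorption grid scaled by the laser power
(absorbed watts per voxel divided by voxel volume), switched on and off
by the pulsed heating/cooling schedule. Boundaries default to adiabatic;
fixed-temperature far faces and a convective top surface are available.

Internally everything is SI (m, W, s); temperatures are degrees Celsius
and geometry voxel sizes are converted from mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage

from .geometry import LayeredGeometry
from .photon_transport import AbsorptionGrid

__all__ = [
    "ThermalField",
    "TreatmentSchedule",
    "TemperatureSeries",
    "stability_timestep",
    "step_temperature",
    "run_treatment",
    "probe_series",
    "rmse",
]

_MM = 1.0e-3
STABILITY_SAFETY = 0.5


@dataclass
class TreatmentSchedule:
    """Pulsed laser schedule: power plus heating/cooling cycle durations.

    The laser is on for ``tau_h`` seconds, off for ``tau_c`` seconds,
    repeating until the total elapsed time reaches ``tau_tot`` (the final
    cycle is truncated there, cooling phases included in the total).
    A zero ``tau_c`` gives continuous heating.
    """

    power_mw: float
    tau_h: float
    tau_c: float
    tau_tot: float

    def __post_init__(self) -> None:
        if self.power_mw < 0:
            raise ValueError("laser power must be >= 0")
        if self.tau_h <= 0 or self.tau_c < 0 or self.tau_tot <= 0:
            raise ValueError("schedule durations must be positive (tau_c may be 0)")

    def laser_on(self, t: float) -> bool:
        cycle = self.tau_h + self.tau_c
        return (t % cycle) < self.tau_h - 1.0e-9


@dataclass
class ThermalField:
    """Temperature field (deg C) with per-voxel volumetric properties."""

    T: np.ndarray
    rho: np.ndarray
    cp: np.ndarray
    k: np.ndarray
    voxel_size: tuple[float, float, float]  # mm
    active: np.ndarray
    time: float = 0.0

    @classmethod
    def from_geometry(cls, geom: LayeredGeometry, T_init: float = 37.0) -> "ThermalField":
        return cls(
            T=np.full(geom.shape, float(T_init)),
            rho=geom.rho,
            cp=geom.cp,
            k=geom.k,
            voxel_size=geom.voxel_size,
            active=geom.active.copy(),
            time=0.0,
        )

    def energy(self) -> float:
        """Total thermal energy sum(rho cp T V) over active voxels (J)."""
        dv = np.prod([d * _MM for d in self.voxel_size])
        return float((self.rho * self.cp * self.T)[self.active].sum() * dv)


@dataclass
class TemperatureSeries:
    """Snapshots of the temperature field at regular intervals."""

    times: np.ndarray  # s
    snapshots: np.ndarray | None  # (nt, nx, ny, nz) float32, or None if streamed
    voxel_size: tuple[float, float, float]
    schedule: TreatmentSchedule | None = None
    meta: dict = field(default_factory=dict)


@njit(cache=True)
def _step_kernel(T, Tn, q, inv_rc, Cxm, Cxp, Cym, Cyp, Czm, Czp, Eb, EbT, dt, src):
    nx, ny, nz = T.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                rc = inv_rc[i, j, k]
                if rc == 0.0:
                    Tn[i, j, k] = T[i, j, k]
                    continue
                t0 = T[i, j, k]
                acc = src * q[i, j, k] + EbT[i, j, k] - Eb[i, j, k] * t0
                if Cxm[i, j, k] > 0.0:
                    acc += Cxm[i, j, k] * (T[i - 1, j, k] - t0)
                if Cxp[i, j, k] > 0.0:
                    acc += Cxp[i, j, k] * (T[i + 1, j, k] - t0)
                if Cym[i, j, k] > 0.0:
                    acc += Cym[i, j, k] * (T[i, j - 1, k] - t0)
                if Cyp[i, j, k] > 0.0:
                    acc += Cyp[i, j, k] * (T[i, j + 1, k] - t0)
                if Czm[i, j, k] > 0.0:
                    acc += Czm[i, j, k] * (T[i, j, k - 1] - t0)
                if Czp[i, j, k] > 0.0:
                    acc += Czp[i, j, k] * (T[i, j, k + 1] - t0)
                Tn[i, j, k] = t0 + dt * rc * acc


class _Stencil:
    """Precomputed stencil coefficients (W m^-3 K^-1) for one field."""

    def __init__(self, fld: ThermalField, boundary="adiabatic") -> None:
        k = np.where(fld.active, fld.k, 0.0)
        d = [v * _MM for v in fld.voxel_size]
        shape = k.shape
        self.inv_rc = np.where(fld.active, 1.0 / (fld.rho * fld.cp), 0.0)
        self.C = []
        for axis in range(3):
            for sign in (-1, +1):
                kn = np.zeros_like(k)
                sl_this = [slice(None)] * 3
                sl_nb = [slice(None)] * 3
                if sign < 0:
                    sl_this[axis] = slice(1, None)
                    sl_nb[axis] = slice(None, -1)
                else:
                    sl_this[axis] = slice(None, -1)
                    sl_nb[axis] = slice(1, None)
                kn[tuple(sl_this)] = k[tuple(sl_nb)]
                num = 2.0 * k * kn
                den = k + kn
                face_k = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), 0.0)
                self.C.append(face_k / d[axis] ** 2)
        self.Eb = np.zeros(shape)
        self.EbT = np.zeros(shape)
        self._apply_boundary(fld, boundary, d)

    def _apply_boundary(self, fld: ThermalField, boundary, d) -> None:
        specs = boundary if isinstance(boundary, (list, tuple)) else [boundary]
        face_slices = {
            "x-": (0, np.s_[0, :, :]),
            "x+": (0, np.s_[-1, :, :]),
            "y-": (1, np.s_[:, 0, :]),
            "y+": (1, np.s_[:, -1, :]),
            "z-": (2, np.s_[:, :, 0]),
            "z+": (2, np.s_[:, :, -1]),
        }
        for spec in specs:
            if spec == "adiabatic" or spec is None:
                continue
            if not isinstance(spec, dict):
                raise ValueError(f"unrecognized boundary spec {spec!r}")
            kind = spec.get("type")
            if kind == "fixed":
                faces = spec.get("faces", "far")
                if faces == "far":
                    faces = ["x-", "x+", "y-", "y+", "z+"]
                elif faces == "all":
                    faces = list(face_slices)
                T_fix = float(spec["T"])
                for f in faces:
                    axis, sl = face_slices[f]
                    # wall at half a voxel from the boundary voxel center
                    coeff = 2.0 * np.where(fld.active[sl], fld.k[sl], 0.0) / d[axis] ** 2
                    self.Eb[sl] += coeff
                    self.EbT[sl] += coeff * T_fix
            elif kind == "convective_top":
                h = float(spec["h"])
                T_amb = float(spec["T_amb"])
                sl = np.s_[:, :, 0]
                coeff = np.where(fld.active[sl], h / d[2], 0.0)
                self.Eb[sl] += coeff
                self.EbT[sl] += coeff * T_amb
            else:
                raise ValueError(f"unrecognized boundary type {kind!r}")

    def rate_coefficient(self) -> np.ndarray:
        """Per-voxel total outflow coefficient / (rho cp), in 1/s."""
        total = self.Eb.copy()
        for c in self.C:
            total += c
        return total * self.inv_rc

    def step(self, T, Tn, q, dt, source_on: bool) -> None:
        _step_kernel(
            T, Tn, q, self.inv_rc, *self.C, self.Eb, self.EbT, dt, 1.0 if source_on else 0.0
        )


def stability_timestep(
    fld_or_geom, *, boundary="adiabatic", safety: float = STABILITY_SAFETY
) -> float:
    """Largest stable explicit step (s), times the safety factor.

    Per voxel the explicit scheme is stable while
    ``dt <= rho cp / sum(face conductances / d^2)``; the minimum over
    voxels is returned scaled by ``safety`` (default 0.5). A domain with
    no conductive coupling at all has an unbounded step, which is
    rejected.
    """
    fld = (
        fld_or_geom
        if isinstance(fld_or_geom, ThermalField)
        else ThermalField.from_geometry(fld_or_geom)
    )
    rate = _Stencil(fld, boundary).rate_coefficient()
    rate = rate[fld.active]
    if rate.size == 0 or rate.max() <= 0.0:
        raise ValueError("no conductive coupling anywhere: stable dt is unbounded")
    return safety / float(rate.max())


def step_temperature(
    fld: ThermalField, source_q: np.ndarray | float, dt: float, boundary="adiabatic"
) -> ThermalField:
    """Advance the field by one explicit step.

    ``source_q`` is the volumetric heat source in W/m^3 (array or
    scalar). Steps exceeding the stability bound (without the safety
    factor) are refused.
    """
    bound = stability_timestep(fld, boundary=boundary, safety=1.0)
    if dt > bound * (1.0 + 1.0e-12):
        raise ValueError(f"dt={dt} s exceeds the explicit stability bound {bound} s")
    q = np.broadcast_to(np.asarray(source_q, dtype=np.float64), fld.T.shape)
    stencil = _Stencil(fld, boundary)
    Tn = np.empty_like(fld.T)
    stencil.step(fld.T, Tn, np.ascontiguousarray(q), dt, True)
    return ThermalField(
        T=Tn,
        rho=fld.rho,
        cp=fld.cp,
        k=fld.k,
        voxel_size=fld.voxel_size,
        active=fld.active,
        time=fld.time + dt,
    )


def source_from_absorption(
    geom: LayeredGeometry, absorption: AbsorptionGrid, power_mw: float
) -> np.ndarray:
    """Volumetric heat source (W/m^3) for a given laser power.

    The Monte Carlo grid holds the absorbed fraction of launched energy
    per voxel, so ``q = P * fraction / V_voxel`` makes the volume
    integral of q equal the absorbed power.
    """
    v_m3 = geom.voxel_volume_mm3 * _MM**3
    return absorption.deposited * (power_mw * 1.0e-3) / v_m3


def run_treatment(
    geom: LayeredGeometry,
    absorption: AbsorptionGrid,
    schedule: TreatmentSchedule,
    *,
    dt: float | None = None,
    snapshot_interval: float = 1.0,
    T_init: float = 37.0,
    boundary="adiabatic",
    observer=None,
    store_snapshots: bool = True,
) -> TemperatureSeries:
    """Run a pulsed heating/cooling treatment and record snapshots.

    The source alternates on/off per the schedule; snapshots are taken
    every ``snapshot_interval`` seconds starting at t = 0. ``observer``
    (``f(t, T)``) is called at each snapshot, which allows streaming
    metrics without storing the full field stack (set
    ``store_snapshots=False`` for long runs). Deterministic given its
    inputs.
    """
    fld = ThermalField.from_geometry(geom, T_init)
    stencil = _Stencil(fld, boundary)
    dt_max = STABILITY_SAFETY / float(stencil.rate_coefficient()[fld.active].max())
    if dt is None:
        dt = snapshot_interval / int(np.ceil(snapshot_interval / dt_max))
    elif dt > dt_max / STABILITY_SAFETY:
        raise ValueError(f"dt={dt} exceeds the explicit stability bound")
    q = np.ascontiguousarray(source_from_absorption(geom, absorption, schedule.power_mw))

    n_snap = int(np.floor(schedule.tau_tot / snapshot_interval + 1.0e-9))
    sub = max(1, int(round(snapshot_interval / dt)))
    dt_eff = snapshot_interval / sub
    times = np.arange(n_snap + 1) * snapshot_interval
    snaps = np.empty((n_snap + 1, *fld.T.shape), dtype=np.float32) if store_snapshots else None

    T = fld.T
    Tn = np.empty_like(T)
    t = 0.0
    if store_snapshots:
        snaps[0] = T
    if observer is not None:
        observer(0.0, T)
    for s in range(1, n_snap + 1):
        for _ in range(sub):
            stencil.step(T, Tn, q, dt_eff, schedule.laser_on(t))
            T, Tn = Tn, T
            t += dt_eff
        if store_snapshots:
            snaps[s] = T
        if observer is not None:
            observer(t, T)
    return TemperatureSeries(
        times=times,
        snapshots=snaps,
        voxel_size=geom.voxel_size,
        schedule=schedule,
        meta={"dt": dt_eff, "T_init": T_init, "boundary": str(boundary)},
    )


def probe_series(
    series: TemperatureSeries, locations_mm, mode: str = "nearest"
) -> np.ndarray:
    """Temperature traces at probe points: array of shape (n_times, n_probes).

    ``mode`` is "nearest" (value of the containing voxel) or "trilinear"
    (interpolation between voxel centers). Probes must lie inside the
    domain.
    """
    if series.snapshots is None:
        raise ValueError("series was streamed without stored snapshots")
    locs = np.atleast_2d(np.asarray(locations_mm, dtype=np.float64))
    shape = series.snapshots.shape[1:]
    frac = np.empty_like(locs)
    for a in range(3):
        extent = shape[a] * series.voxel_size[a]
        if np.any(locs[:, a] < 0.0) or np.any(locs[:, a] > extent):
            raise ValueError("probe location outside the domain")
        frac[:, a] = locs[:, a] / series.voxel_size[a] - 0.5
    out = np.empty((series.snapshots.shape[0], locs.shape[0]))
    if mode == "nearest":
        idx = np.clip(np.round(frac).astype(int), 0, np.array(shape) - 1)
        for p, (i, j, k) in enumerate(idx):
            out[:, p] = series.snapshots[:, i, j, k]
    elif mode == "trilinear":
        coords = frac.T
        for s in range(series.snapshots.shape[0]):
            out[s] = ndimage.map_coordinates(
                series.snapshots[s].astype(np.float64), coords, order=1, mode="nearest"
            )
    else:
        raise ValueError(f"unknown probe mode {mode!r}")
    return out


def rmse(sim_trace, measured_trace) -> float:
    """Root-mean-square difference between aligned traces.

    For 2-D inputs (time x probe) the per-probe RMSEs are averaged.
    """
    a = np.asarray(sim_trace, dtype=np.float64)
    b = np.asarray(measured_trace, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"trace shapes differ: {a.shape} vs {b.shape}")
    sq = (a - b) ** 2
    if a.ndim <= 1:
        return float(np.sqrt(sq.mean()))
    return float(np.mean(np.sqrt(sq.mean(axis=0))))
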