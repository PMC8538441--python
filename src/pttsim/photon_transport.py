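"""Monte Carlo photon transport in voxelized turbid media.

Photons are launched at the surface, take exponentially distributed steps
(`hop`), deposit a fraction ``mu_a / mu_tot`` of their weight at each
interaction (`drop`), and scatter into a new direction sampled from the
Henyey-Greenstein phase function (`spin`) until Russian roulette
terminates them or they leave the domain. The deposited grid is
normalized per launched photon, so multiplying by the laser power gives
the volumetric heat source for the bioheat solver.

In heterogeneous voxel grids a single dimensionless optical depth
``-ln(xi)`` is sampled per flight and consumed across voxels in units of
the local ``mu_tot`` (interaction where it is exhausted), which is
unbiased and reduces to the homogeneous step formula within each
material. Layer interfaces are index-matched: no Fresnel reflection or
refraction, directions carry straight across.

The inner loop is a numba kernel driven by a single sequential seeded
random stream: runs with the same seed are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .geometry import LayeredGeometry

__all__ = [
    "Beam",
    "AbsorptionGrid",
    "sample_step",
    "sample_deflection",
    "sample_azimuth",
    "update_direction",
    "deposit_weight",
    "run_monte_carlo",
]

WEIGHT_MIN = 1.0e-4  # roulette threshold
ROULETTE_SURVIVE = 0.1  # survival probability (weight boosted by 1/p)


@dataclass(frozen=True)
class Beam:
    """Incident laser beam: top-hat disc at normal incidence on z = 0.

    ``center_mm`` defaults to the domain center (the tumor axis). A zero
    diameter degenerates to a pencil beam.
    """

    diameter_mm: float = 10.0
    profile: str = "tophat"
    center_mm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.diameter_mm < 0:
            raise ValueError("beam diameter must be >= 0")
        if self.profile != "tophat":
            raise ValueError(f"unsupported beam profile {self.profile!r}")


@dataclass
class AbsorptionGrid:
    """Per-voxel deposited fraction of launched energy.

    ``deposited`` sums (with ``escaped``) to 1 per launched photon up to
    the unbiased roulette noise. Multiplied by the laser power it is the
    absorbed power per voxel.
    """

    deposited: np.ndarray
    escaped: float
    n_photons: int
    beam: Beam
    seed: int

    @property
    def absorbed_fraction(self) -> float:
        return float(self.deposited.sum())


def sample_step(xi, mu_tot):
    """Path length (mm) to the next interaction: ``-ln(xi) / mu_tot``.

    ``xi`` must lie strictly in (0, 1); a non-attenuating medium
    (``mu_tot == 0``) yields an infinite step (straight-line propagation).
    """
    xi = np.asarray(xi, dtype=np.float64)
    if np.any(xi <= 0.0) or np.any(xi >= 1.0):
        raise ValueError("xi must lie strictly in (0, 1)")
    with np.errstate(divide="ignore"):
        out = -np.log(xi) / mu_tot
    return out if out.ndim else float(out)


def sample_deflection(xi, g):
    """Cosine of the scattering deflection angle.

    Henyey-Greenstein inverse CDF for ``g != 0``; the isotropic limit
    ``g == 0`` reduces to ``2 xi - 1``. The mean of the returned cosine
    equals ``g``.
    """
    xi = np.asarray(xi, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    iso = np.abs(g) < 1.0e-9
    g_safe = np.where(iso, 0.5, g)
    frac = (1.0 - g_safe**2) / (1.0 - g_safe + 2.0 * g_safe * xi)
    aniso = (1.0 + g_safe**2 - frac**2) / (2.0 * g_safe)
    out = np.where(iso, 2.0 * xi - 1.0, aniso)
    out = np.clip(out, -1.0, 1.0)
    return out if out.ndim else float(out)


def sample_azimuth(xi):
    """Azimuthal scattering angle, uniform on [0, 2 pi)."""
    xi = np.asarray(xi, dtype=np.float64)
    out = 2.0 * np.pi * xi
    return out if out.ndim else float(out)


def update_direction(direction, cos_theta, psi):
    """Rotate a unit direction by deflection ``cos_theta`` and azimuth ``psi``.

    Standard spherical scattering rotation (special-cased near the poles
    ``|mu_z| ~ 1``); preserves unit norm and satisfies
    ``dot(dir, dir') == cos_theta`` to round-off. Accepts a single
    3-vector or an (..., 3) stack.
    """
    d = np.asarray(direction, dtype=np.float64)
    single = d.ndim == 1
    d = np.atleast_2d(d)
    ct = np.broadcast_to(np.asarray(cos_theta, dtype=np.float64), d.shape[:-1]).copy()
    ps = np.broadcast_to(np.asarray(psi, dtype=np.float64), d.shape[:-1]).copy()
    st = np.sqrt(np.clip(1.0 - ct**2, 0.0, None))
    ux, uy, uz = d[..., 0], d[..., 1], d[..., 2]
    out = np.empty_like(d)

    pole = np.abs(uz) > 0.99999
    den = np.sqrt(np.clip(1.0 - uz**2, 1.0e-30, None))
    cp, sp = np.cos(ps), np.sin(ps)
    out[..., 0] = st * (ux * uz * cp - uy * sp) / den + ux * ct
    out[..., 1] = st * (uy * uz * cp + ux * sp) / den + uy * ct
    out[..., 2] = -st * cp * den + uz * ct
    # pole special case: any azimuthal frame works
    out[pole, 0] = (st * cp)[pole]
    out[pole, 1] = (st * sp)[pole]
    out[pole, 2] = (np.sign(uz) * ct)[pole]
    out /= np.linalg.norm(out, axis=-1, keepdims=True)
    return out[0] if single else out


def deposit_weight(W, mu_a, mu_tot):
    """Weight deposited at one interaction: ``delta_W = W mu_a / mu_tot``."""
    if np.any(np.asarray(mu_a) < 0) or np.any(np.asarray(mu_tot) <= 0):
        raise ValueError("require mu_tot > 0 and mu_a >= 0")
    return W * mu_a / mu_tot


@njit(cache=True)
def _rand_open() -> float:
    xi = np.random.random()
    while xi <= 0.0:
        xi = np.random.random()
    return xi


@njit(cache=True)
def _trace_photons(
    mu_a, mu_s, g, active, dx, dy, dz, n_photons, seed, cx, cy, radius, w_min, p_survive
):
    np.random.seed(seed)
    nx, ny, nz = mu_a.shape
    dep = np.zeros((nx, ny, nz))
    escaped = 0.0
    for _ in range(n_photons):
        if radius > 0.0:
            r = radius * math.sqrt(np.random.random())
            phi = 2.0 * math.pi * np.random.random()
            x = cx + r * math.cos(phi)
            y = cy + r * math.sin(phi)
        else:
            x, y = cx, cy
        z = 0.0
        ux, uy, uz = 0.0, 0.0, 1.0
        w = 1.0
        ix = min(max(int(x / dx), 0), nx - 1)
        iy = min(max(int(y / dy), 0), ny - 1)
        iz = 0
        tau = -math.log(_rand_open())
        alive = True
        while alive:
            if not active[ix, iy, iz]:
                escaped += w
                break
            mt = mu_a[ix, iy, iz] + mu_s[ix, iy, iz]
            # distance to the voxel boundary along the flight direction
            if ux > 0.0:
                tx = ((ix + 1) * dx - x) / ux
            elif ux < 0.0:
                tx = (ix * dx - x) / ux
            else:
                tx = 1.0e30
            if uy > 0.0:
                ty = ((iy + 1) * dy - y) / uy
            elif uy < 0.0:
                ty = (iy * dy - y) / uy
            else:
                ty = 1.0e30
            if uz > 0.0:
                tz = ((iz + 1) * dz - z) / uz
            elif uz < 0.0:
                tz = (iz * dz - z) / uz
            else:
                tz = 1.0e30
            tb = tx
            axis = 0
            if ty < tb:
                tb = ty
                axis = 1
            if tz < tb:
                tb = tz
                axis = 2
            if tb < 0.0:
                tb = 0.0
            ti = tau / mt if mt > 0.0 else 1.0e30
            if ti < tb:
                # interact inside this voxel
                x += ux * ti
                y += uy * ti
                z += uz * ti
                dw = w * mu_a[ix, iy, iz] / mt
                dep[ix, iy, iz] += dw
                w -= dw
                if w <= 0.0:
                    break
                gg = g[ix, iy, iz]
                xi = np.random.random()
                if abs(gg) > 1.0e-9:
                    frac = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * xi)
                    ct = (1.0 + gg * gg - frac * frac) / (2.0 * gg)
                    if ct > 1.0:
                        ct = 1.0
                    elif ct < -1.0:
                        ct = -1.0
                else:
                    ct = 2.0 * xi - 1.0
                psi = 2.0 * math.pi * np.random.random()
                st = math.sqrt(1.0 - ct * ct)
                cp = math.cos(psi)
                sp = math.sin(psi)
                if abs(uz) > 0.99999:
                    ux = st * cp
                    uy = st * sp
                    uz = ct if uz > 0.0 else -ct
                else:
                    den = math.sqrt(1.0 - uz * uz)
                    nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
                    nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
                    nuz = -st * cp * den + uz * ct
                    norm = math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
                    ux, uy, uz = nux / norm, nuy / norm, nuz / norm
                tau = -math.log(_rand_open())
                if w < w_min:
                    if np.random.random() < p_survive:
                        w /= p_survive
                    else:
                        alive = False
            else:
                # cross into the neighbouring voxel
                tau -= mt * tb
                x += ux * tb
                y += uy * tb
                z += uz * tb
                if axis == 0:
                    if ux > 0.0:
                        ix += 1
                        x = ix * dx
                    else:
                        x = ix * dx
                        ix -= 1
                elif axis == 1:
                    if uy > 0.0:
                        iy += 1
                        y = iy * dy
                    else:
                        y = iy * dy
                        iy -= 1
                else:
                    if uz > 0.0:
                        iz += 1
                        z = iz * dz
                    else:
                        z = iz * dz
                        iz -= 1
                if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
                    escaped += w
                    alive = False
    return dep, escaped


def run_monte_carlo(
    geom: LayeredGeometry,
    beam: Beam | None = None,
    n_photons: int = 100_000,
    seed: int = 0,
    *,
    weight_min: float = WEIGHT_MIN,
    roulette_survive: float = ROULETTE_SURVIVE,
) -> AbsorptionGrid:
    """Trace ``n_photons`` through the geometry and tally absorbed energy.

    Photons launch uniformly over the top-hat beam disc at the surface,
    travelling in +z. Returns the deposited-fraction grid normalized per
    launched photon; ``escaped`` holds the weight that left the domain.
    Deterministic for a given seed.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if not geom.active.any():
        raise ValueError("geometry has no active voxels")
    if beam is None:
        bdict = geom.meta.get("beam", {})
        beam = Beam(diameter_mm=float(bdict.get("diameter_mm", 10.0)))
    if beam.diameter_mm > min(geom.extents_mm[0], geom.extents_mm[1]):
        raise ValueError("beam wider than the domain")
    cx, cy = beam.center_mm if beam.center_mm is not None else (
        geom.extents_mm[0] / 2.0,
        geom.extents_mm[1] / 2.0,
    )
    dep, escaped = _trace_photons(
        np.ascontiguousarray(geom.mu_a),
        np.ascontiguousarray(geom.mu_s),
        np.ascontiguousarray(geom.g),
        np.ascontiguousarray(geom.active),
        geom.voxel_size[0],
        geom.voxel_size[1],
        geom.voxel_size[2],
        int(n_photons),
        int(seed),
        cx,
        cy,
        beam.diameter_mm / 2.0,
        weight_min,
        roulette_survive,
    )
    return AbsorptionGrid(
        deposited=dep / n_photons,
        escaped=escaped / n_photons,
        n_photons=int(n_photons),
        beam=beam,
        seed=int(seed),
    )
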