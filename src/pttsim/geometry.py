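"""Voxelized simulation domains.

The treatment domain is a cuboid voxel grid (default 30 x 30 x 10 mm) with
z pointing downward from the irradiated surface. Four skin layers —
epidermis, papillary dermis, reticular dermis, subcutaneous fat — are
stacked from the surface; a cylindrical tumor (default diameter 10 mm,
length 3.5 mm, top at 0.1 mm depth) is embedded coaxially with the beam
and overrides the layers where it intersects them. Layer thicknesses that
do not resolve on the voxel grid (the 0.08 mm epidermis in particular) are
handled by sub-voxel blending: a z-boundary voxel receives
thickness-weighted optical coefficients (anisotropy weighted by the
scattering contribution) and volume-weighted thermal properties. The
remaining depth below the printed layer stack is filled with subcutaneous
fat.

Voxel centers sit at ``(i + 1/2) * d``; all masks use the voxel-center
(half-open) convention.

Besides the skin stack the module builds the validation phantom — a
GNR-loaded inner cylinder inside a plain acrylamide cylinder — and
homogeneous slabs for solver verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import default_config, gnr_spec_from_config
from .optics import GNRSpec, OpticalProperties, gnr_loaded_tissue

__all__ = [
    "GeometryError",
    "Material",
    "LayeredGeometry",
    "build_skin_stack",
    "build_normal_roi",
    "build_phantom",
    "homogeneous_slab",
    "phantom_probe_locations",
]


class GeometryError(ValueError):
    """Inconsistent or degenerate geometry request."""


@dataclass(frozen=True)
class Material:
    """One voxel material: optical properties plus volumetric thermal ones."""

    name: str
    optics: OpticalProperties
    rho: float  # kg/m^3
    cp: float  # J/(kg K)
    k: float  # W/(m K)


@dataclass
class LayeredGeometry:
    """Voxel grid with per-voxel material ids and region masks.

    ``voxel_size`` is (dx, dy, dz) in mm; ``material_id`` indexes into
    ``materials``. ``active`` marks voxels belonging to the physical body
    (photons escape and heat does not conduct across inactive voxels).
    """

    voxel_size: tuple[float, float, float]
    material_id: np.ndarray
    materials: list[Material]
    tumor_mask: np.ndarray
    normal_roi_mask: np.ndarray | None = None
    active: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.active is None:
            self.active = np.ones(self.material_id.shape, dtype=bool)
        if self.material_id.min() < 0 or self.material_id.max() >= len(self.materials):
            raise GeometryError("every voxel must reference a defined material")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.material_id.shape

    @property
    def extents_mm(self) -> tuple[float, float, float]:
        return tuple(n * d for n, d in zip(self.shape, self.voxel_size))

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    def _lookup(self, attr: str) -> np.ndarray:
        table = np.array([getattr(m, attr) for m in self.materials], dtype=np.float64)
        return table[self.material_id]

    @property
    def mu_a(self) -> np.ndarray:
        table = np.array([m.optics.mu_a for m in self.materials])
        return table[self.material_id]

    @property
    def mu_s(self) -> np.ndarray:
        table = np.array([m.optics.mu_s for m in self.materials])
        return table[self.material_id]

    @property
    def g(self) -> np.ndarray:
        table = np.array([m.optics.g for m in self.materials])
        return table[self.material_id]

    @property
    def rho(self) -> np.ndarray:
        return self._lookup("rho")

    @property
    def cp(self) -> np.ndarray:
        return self._lookup("cp")

    @property
    def k(self) -> np.ndarray:
        return self._lookup("k")

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel center coordinates in mm."""
        return tuple(
            (np.arange(n) + 0.5) * d for n, d in zip(self.shape, self.voxel_size)
        )

    def voxel_index(self, point_mm) -> tuple[int, int, int]:
        """Voxel containing a physical point; raises if outside the domain."""
        idx = []
        for x, d, n in zip(point_mm, self.voxel_size, self.shape):
            i = int(np.floor(x / d))
            if not 0 <= i < n:
                raise GeometryError(f"point {tuple(point_mm)} mm outside the domain")
            idx.append(i)
        return tuple(idx)


def _as_voxel_size(voxel_size) -> tuple[float, float, float]:
    if np.isscalar(voxel_size):
        voxel_size = (voxel_size,) * 3
    vs = tuple(float(v) for v in voxel_size)
    if any(v <= 0 for v in vs):
        raise GeometryError(f"voxel sizes must be positive, got {vs}")
    return vs


def _n_cells(extent: float, d: float) -> int:
    n = int(round(extent / d))
    if n < 1 or abs(n * d - extent) > 1e-9 * max(1.0, extent):
        raise GeometryError(f"voxel size {d} mm does not divide extent {extent} mm")
    return n


def _blend(fractions: dict[str, float], base: dict[str, Material]) -> Material:
    """Thickness-weighted composite of base materials inside one voxel.

    mu_a/mu_s are thickness-weighted (preserving the vertical optical
    depth), g is weighted by each component's scattering contribution,
    rho and the volumetric heat capacity rho*cp are volume-weighted, and
    k is an arithmetic volume average.
    """
    items = [(base[name], w) for name, w in fractions.items() if w > 1e-12]
    wsum = sum(w for _, w in items)
    items = [(m, w / wsum) for m, w in items]
    if len(items) == 1:
        return items[0][0]
    mu_a = sum(m.optics.mu_a * w for m, w in items)
    mu_s = sum(m.optics.mu_s * w for m, w in items)
    if mu_s > 0:
        g = sum(m.optics.g * m.optics.mu_s * w for m, w in items) / mu_s
    else:
        g = sum(m.optics.g * w for m, w in items)
    rho = sum(m.rho * w for m, w in items)
    rhocp = sum(m.rho * m.cp * w for m, w in items)
    k = sum(m.k * w for m, w in items)
    name = "+".join(f"{m.name}:{w:.3f}" for m, w in items)
    return Material(name, OpticalProperties(mu_a, mu_s, g), rho, rhocp / rho, k)


class _MaterialTable:
    """Deduplicating material registry."""

    def __init__(self) -> None:
        self.materials: list[Material] = []
        self._index: dict[tuple, int] = {}

    def add(self, mat: Material) -> int:
        key = (
            round(mat.optics.mu_a, 12),
            round(mat.optics.mu_s, 12),
            round(mat.optics.g, 12),
            round(mat.rho, 9),
            round(mat.cp, 9),
            round(mat.k, 12),
        )
        if key not in self._index:
            self._index[key] = len(self.materials)
            self.materials.append(mat)
        return self._index[key]


def _slab_fractions(slabs: list[tuple[str, float, float]], z0: float, z1: float) -> dict:
    """Fraction of voxel [z0, z1] occupied by each named slab."""
    fr: dict[str, float] = {}
    dz = z1 - z0
    for name, a, b in slabs:
        ov = min(z1, b) - max(z0, a)
        if ov > 1e-12 * dz:
            fr[name] = fr.get(name, 0.0) + ov / dz
    return fr


def build_skin_stack(
    config: dict | None = None,
    *,
    voxel_size=0.25,
    fv: float | None = None,
    roi_shell_fraction: float = 0.5,
) -> LayeredGeometry:
    """Build the four-layer skin domain with the embedded GNR-loaded tumor.

    Parameters
    ----------
    config
        Material configuration (see :mod:`pttsim.config`); defaults to the
        bundled skin model.
    voxel_size
        Scalar or (dx, dy, dz) in mm; must divide the domain extents.
    fv
        Override the GNR volume fraction of the config.
    roi_shell_fraction
        Width of the surrounding normal-tissue region of interest as a
        fraction of the tumor diameter (default: half the diameter).
    """
    cfg = config if config is not None else default_config()
    vs = _as_voxel_size(voxel_size)
    ext = tuple(float(e) for e in cfg["domain"]["extents_mm"])
    shape = tuple(_n_cells(e, d) for e, d in zip(ext, vs))
    nx, ny, nz = shape
    dx, dy, dz = vs

    tumor_cfg = cfg["tumor"]
    t_diam = float(tumor_cfg["diameter_mm"])
    t_len = float(tumor_cfg["length_mm"])
    t_top = float(tumor_cfg["top_depth_mm"])
    if t_diam <= 0 or t_len <= 0:
        raise GeometryError(
            f"tumor must have positive size, got diameter={t_diam}, length={t_len} mm"
        )
    if t_diam > min(ext[0], ext[1]) or t_top + t_len > ext[2]:
        raise GeometryError("tumor does not fit inside the domain")

    gnr = gnr_spec_from_config(cfg, fv=fv)
    tumor_optics = gnr_loaded_tissue(
        OpticalProperties(
            float(tumor_cfg["mu_a"]), float(tumor_cfg["mu_s"]), float(tumor_cfg["g"])
        ),
        gnr,
    )
    base: dict[str, Material] = {}
    slabs_outside: list[tuple[str, float, float]] = []
    z = 0.0
    for layer in cfg["layers"]:
        m = Material(
            layer["name"],
            OpticalProperties(float(layer["mu_a"]), float(layer["mu_s"]), float(layer["g"])),
            float(layer["rho"]),
            float(layer["cp"]),
            float(layer["k"]),
        )
        base[m.name] = m
        z_next = z + float(layer["thickness_mm"])
        slabs_outside.append((m.name, z, z_next))
        z = z_next
    # pad any remaining depth with the deepest layer
    if z < ext[2] - 1e-9:
        name = slabs_outside[-1][0]
        slabs_outside[-1] = (name, slabs_outside[-1][1], ext[2])
    base["tumor"] = Material(
        "tumor", tumor_optics, float(tumor_cfg["rho"]), float(tumor_cfg["cp"]), float(tumor_cfg["k"])
    )
    # inside the tumor radius the tumor overrides the layers over its z-span
    slabs_inside = []
    for name, a, b in slabs_outside:
        if b <= t_top or a >= t_top + t_len:
            slabs_inside.append((name, a, b))
        else:
            if a < t_top:
                slabs_inside.append((name, a, t_top))
            if b > t_top + t_len:
                slabs_inside.append((name, t_top + t_len, b))
    slabs_inside.append(("tumor", t_top, t_top + t_len))

    table = _MaterialTable()
    ids_outside = np.empty(nz, dtype=np.int32)
    ids_inside = np.empty(nz, dtype=np.int32)
    for iz in range(nz):
        z0, z1 = iz * dz, (iz + 1) * dz
        ids_outside[iz] = table.add(_blend(_slab_fractions(slabs_outside, z0, z1), base))
        ids_inside[iz] = table.add(_blend(_slab_fractions(slabs_inside, z0, z1), base))

    xc = (np.arange(nx) + 0.5) * dx - ext[0] / 2.0
    yc = (np.arange(ny) + 0.5) * dy - ext[1] / 2.0
    zc = (np.arange(nz) + 0.5) * dz
    r2 = xc[:, None] ** 2 + yc[None, :] ** 2
    in_radius = r2 <= (t_diam / 2.0) ** 2

    material_id = np.empty(shape, dtype=np.int32)
    material_id[:] = ids_outside[None, None, :]
    material_id[in_radius, :] = ids_inside[None, :]

    in_z = (zc > t_top) & (zc < t_top + t_len)
    tumor_mask = in_radius[:, :, None] & in_z[None, None, :]

    geom = LayeredGeometry(
        voxel_size=vs,
        material_id=material_id,
        materials=table.materials,
        tumor_mask=tumor_mask,
        meta={
            "preset": "skin_default",
            "tumor_diameter_mm": t_diam,
            "tumor_length_mm": t_len,
            "tumor_top_depth_mm": t_top,
            "fv": gnr.fv,
            "beam": dict(cfg.get("beam", {"diameter_mm": 10.0, "profile": "tophat"})),
        },
    )
    geom.normal_roi_mask = build_normal_roi(geom, shell_mm=roi_shell_fraction * t_diam)
    return geom


def build_normal_roi(geom: LayeredGeometry, shell_mm: float | None = None) -> np.ndarray:
    """Mask of normal-tissue voxels within ``shell_mm`` of the tumor surface.

    The region of interest for thermal-hazard scoring extends from the
    tumor boundary outward by half the tumor diameter (by default), in all
    directions, clipped to the domain. Distances are Euclidean, measured
    between voxel centers via a distance transform.
    """
    if not geom.tumor_mask.any():
        raise GeometryError("geometry has no tumor voxels")
    if shell_mm is None:
        shell_mm = 0.5 * float(geom.meta.get("tumor_diameter_mm", 10.0))
    if shell_mm <= 0.0:
        return np.zeros(geom.shape, dtype=bool)
    dist = ndimage.distance_transform_edt(~geom.tumor_mask, sampling=geom.voxel_size)
    return (dist > 0.0) & (dist <= shell_mm) & geom.active


def build_phantom(config: dict | None = None, *, voxel_size=0.5) -> LayeredGeometry:
    """Build the tissue-equivalent validation phantom.

    A GNR-loaded cylinder (default diameter 10 mm, depth 10 mm, volume
    fraction 2e-5) sits coaxially at the top of a plain acrylamide
    cylinder (default 40 mm diameter, 30 mm length). Voxels outside the
    outer cylinder are inactive.
    """
    cfg = config if config is not None else default_config()
    ph = cfg["phantom"]
    vs = _as_voxel_size(voxel_size)
    out_d = float(ph["outer_diameter_mm"])
    out_len = float(ph["outer_length_mm"])
    t_diam = float(ph["tumor_diameter_mm"])
    t_depth = float(ph["tumor_depth_mm"])
    if t_diam <= 0 or t_depth <= 0:
        raise GeometryError("phantom tumor must have positive size")
    if t_diam > out_d or t_depth > out_len:
        raise GeometryError("phantom tumor does not fit inside the outer cylinder")
    ext = (out_d, out_d, out_len)
    shape = tuple(_n_cells(e, d) for e, d in zip(ext, vs))
    nx, ny, nz = shape
    dx, dy, dz = vs

    host_optics = OpticalProperties(float(ph["mu_a"]), float(ph["mu_s"]), float(ph["g"]))
    host = Material("phantom", host_optics, float(ph["rho"]), float(ph["cp"]), float(ph["k"]))
    gnr = gnr_spec_from_config(cfg, fv=float(ph["gnr_fv"]))
    loaded = Material(
        "phantom_gnr", gnr_loaded_tissue(host_optics, gnr), host.rho, host.cp, host.k
    )

    xc = (np.arange(nx) + 0.5) * dx - ext[0] / 2.0
    yc = (np.arange(ny) + 0.5) * dy - ext[1] / 2.0
    zc = (np.arange(nz) + 0.5) * dz
    r2 = xc[:, None] ** 2 + yc[None, :] ** 2
    active = np.broadcast_to((r2 <= (out_d / 2.0) ** 2)[:, :, None], shape).copy()
    in_tumor = (r2 <= (t_diam / 2.0) ** 2)[:, :, None] & (zc < t_depth)[None, None, :]

    material_id = np.zeros(shape, dtype=np.int32)
    material_id[in_tumor] = 1
    geom = LayeredGeometry(
        voxel_size=vs,
        material_id=material_id,
        materials=[host, loaded],
        tumor_mask=in_tumor & active,
        active=active,
        meta={
            "preset": "phantom",
            "tumor_diameter_mm": t_diam,
            "tumor_length_mm": t_depth,
            "fv": gnr.fv,
            "beam": dict(cfg.get("beam", {"diameter_mm": 10.0, "profile": "tophat"})),
        },
    )
    geom.normal_roi_mask = build_normal_roi(geom, shell_mm=0.5 * t_diam)
    return geom


def homogeneous_slab(
    material: Material, extents_mm=(10.0, 10.0, 10.0), voxel_size=0.5
) -> LayeredGeometry:
    """Single-material cuboid, mainly for solver verification.

    The whole slab is flagged as "tumor" so dose metrics remain usable on
    it; no normal-tissue ROI is defined.
    """
    vs = _as_voxel_size(voxel_size)
    shape = tuple(_n_cells(e, d) for e, d in zip(extents_mm, vs))
    return LayeredGeometry(
        voxel_size=vs,
        material_id=np.zeros(shape, dtype=np.int32),
        materials=[material],
        tumor_mask=np.ones(shape, dtype=bool),
        meta={"preset": "homogeneous_slab", "beam": {"diameter_mm": extents_mm[0], "profile": "tophat"}},
    )


def phantom_probe_locations(
    geom: LayeredGeometry, depth_mm: float = 1.0, radii_mm=(0.0, 5.0, 10.0, 15.0)
) -> list[tuple[float, float, float]]:
    """Thermocouple probe coordinates: fixed depth, points along +x radius.

    Mirrors the validation setup of a probe rake at 1 mm depth with four
    radial positions; the exact radial offsets are configurable.
    """
    cx = geom.extents_mm[0] / 2.0
    cy = geom.extents_mm[1] / 2.0
    return [(cx + r, cy, depth_mm) for r in radii_mm]
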