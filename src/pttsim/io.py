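"""HDF5 persistence for geometries, absorption grids and snapshot series."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .geometry import LayeredGeometry, Material
from .heat_solver import TemperatureSeries, TreatmentSchedule
from .optics import OpticalProperties
from .photon_transport import AbsorptionGrid, Beam

__all__ = [
    "save_geometry",
    "load_geometry",
    "save_absorption",
    "load_absorption",
    "save_series",
    "load_series",
]

_MAT_FIELDS = ["mu_a", "mu_s", "g", "rho", "cp", "k"]


def save_geometry(path: str | Path, geom: LayeredGeometry) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("material_id", data=geom.material_id, compression="gzip")
        f.create_dataset("tumor_mask", data=geom.tumor_mask, compression="gzip")
        if geom.normal_roi_mask is not None:
            f.create_dataset("normal_roi_mask", data=geom.normal_roi_mask, compression="gzip")
        f.create_dataset("active", data=geom.active, compression="gzip")
        table = np.array(
            [
                [m.optics.mu_a, m.optics.mu_s, m.optics.g, m.rho, m.cp, m.k]
                for m in geom.materials
            ]
        )
        f.create_dataset("material_table", data=table)
        f.create_dataset(
            "material_names",
            data=np.array([m.name for m in geom.materials], dtype=h5py.string_dtype()),
        )
        f.attrs["voxel_size_mm"] = geom.voxel_size
        f.attrs["meta"] = json.dumps(geom.meta)


def load_geometry(path: str | Path) -> LayeredGeometry:
    with h5py.File(path, "r") as f:
        table = f["material_table"][()]
        names = [n.decode() if isinstance(n, bytes) else n for n in f["material_names"][()]]
        materials = [
            Material(name, OpticalProperties(row[0], row[1], row[2]), row[3], row[4], row[5])
            for name, row in zip(names, table)
        ]
        roi = f["normal_roi_mask"][()] if "normal_roi_mask" in f else None
        return LayeredGeometry(
            voxel_size=tuple(f.attrs["voxel_size_mm"]),
            material_id=f["material_id"][()],
            materials=materials,
            tumor_mask=f["tumor_mask"][()].astype(bool),
            normal_roi_mask=None if roi is None else roi.astype(bool),
            active=f["active"][()].astype(bool),
            meta=json.loads(f.attrs["meta"]),
        )


def save_absorption(path: str | Path, grid: AbsorptionGrid) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("deposited", data=grid.deposited, compression="gzip")
        f.attrs["escaped"] = grid.escaped
        f.attrs["n_photons"] = grid.n_photons
        f.attrs["seed"] = grid.seed
        f.attrs["beam_diameter_mm"] = grid.beam.diameter_mm
        f.attrs["beam_profile"] = grid.beam.profile


def load_absorption(path: str | Path) -> AbsorptionGrid:
    with h5py.File(path, "r") as f:
        return AbsorptionGrid(
            deposited=f["deposited"][()],
            escaped=float(f.attrs["escaped"]),
            n_photons=int(f.attrs["n_photons"]),
            beam=Beam(float(f.attrs["beam_diameter_mm"]), str(f.attrs["beam_profile"])),
            seed=int(f.attrs["seed"]),
        )


def save_series(path: str | Path, series: TemperatureSeries) -> None:
    if series.snapshots is None:
        raise ValueError("cannot save a streamed series without snapshots")
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=series.times)
        f.create_dataset("snapshots", data=series.snapshots, compression="gzip")
        f.attrs["voxel_size_mm"] = series.voxel_size
        if series.schedule is not None:
            f.attrs["schedule"] = json.dumps(vars(series.schedule))
        f.attrs["meta"] = json.dumps(series.meta)


def load_series(path: str | Path) -> TemperatureSeries:
    with h5py.File(path, "r") as f:
        schedule = None
        if "schedule" in f.attrs:
            schedule = TreatmentSchedule(**json.loads(f.attrs["schedule"]))
        return TemperatureSeries(
            times=f["times"][()],
            snapshots=f["snapshots"][()],
            voxel_size=tuple(f.attrs["voxel_size_mm"]),
            schedule=schedule,
            meta=json.loads(f.attrs["meta"]),
        )
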