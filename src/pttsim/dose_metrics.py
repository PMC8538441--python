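"""Treatment-quality metrics.

Hyperthermia in the 43-50 deg C window drives tumor cells into apoptosis
(programmed death) without the spillage associated with necrosis, so a
treatment is scored by how much of the tumor it keeps inside that window
and how little it damages the surrounding normal tissue:

* apoptosis ratio ``theta_A``  — tumor volume fraction with
  43 < T < 50 deg C at one instant;
* thermal hazard value ``theta_H_n`` — hazard-weight-averaged volume of
  the normal-tissue region of interest, using an ordered table of
  temperature bands (weight 1 = undamaged, up to 8 for ablation);
* their time averages over the whole treatment, the *retention* values
  ``theta_A*`` and ``theta_H_n*`` (trapezoidal integration over
  snapshots);
* the effective apoptosis retention ratio
  ``theta_A_eff* = theta_A* / theta_H_n*``, the optimization objective.

Temperature-band boundaries follow the printed hazard table: bands are
left-closed from 43 deg C up, and the apoptosis window is strictly open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import LayeredGeometry
from .heat_solver import TemperatureSeries

__all__ = [
    "HazardWeightTable",
    "DoseReport",
    "DEFAULT_HAZARD_TABLE",
    "APOPTOSIS_BAND",
    "apoptosis_ratio",
    "thermal_hazard",
    "time_average",
    "effective_ratio",
    "evaluate_treatment",
    "DoseRecorder",
]

APOPTOSIS_BAND = (43.0, 50.0)  # strict open interval, deg C


@dataclass(frozen=True)
class HazardWeightTable:
    """Ordered temperature bands mapped to integer hazard weights.

    ``edges[i]`` is the left-closed lower boundary of the band with
    weight ``weights[i + 1]``; temperatures below ``edges[0]`` get
    ``weights[0]``. The default encodes the laser-induced thermal-effect
    ladder: normal/biostimulation (1), hyperthermia and reduced enzyme
    activity (2), protein coagulation (3), welding (4), membrane
    permeabilization (5), vaporization (6), carbonization (7), cutting
    and ablation (8).
    """

    edges: tuple[float, ...] = (43.0, 45.0, 50.0, 70.0, 80.0, 100.0, 150.0, 300.0)
    weights: tuple[int, ...] = (1, 2, 2, 3, 4, 5, 6, 7, 8)

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.edges) + 1:
            raise ValueError("need exactly one more weight than band edges")
        if list(self.edges) != sorted(self.edges):
            raise ValueError("band edges must be sorted ascending")
        if any(b < a for a, b in zip(self.weights, self.weights[1:])):
            raise ValueError("weights must be non-decreasing with temperature")

    def weight_of(self, T) -> np.ndarray:
        """Per-element hazard weight (left-closed bands)."""
        idx = np.searchsorted(np.asarray(self.edges), np.asarray(T, dtype=float), side="right")
        return np.asarray(self.weights, dtype=np.float64)[idx]


DEFAULT_HAZARD_TABLE = HazardWeightTable()


@dataclass
class DoseReport:
    """Per-snapshot metric series and their treatment-time averages."""

    times: np.ndarray
    theta_A: np.ndarray
    theta_H: np.ndarray
    theta_A_star: float
    theta_H_star: float
    theta_A_eff_star: float
    meta: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "theta_A_star": self.theta_A_star,
            "theta_H_star": self.theta_H_star,
            "theta_A_eff_star": self.theta_A_eff_star,
        }


def apoptosis_ratio(T_field: np.ndarray, tumor_mask: np.ndarray) -> float:
    """Fraction of tumor voxels strictly inside the apoptosis window."""
    if not np.any(tumor_mask):
        raise ValueError("tumor mask is empty")
    T = np.asarray(T_field)[tumor_mask]
    lo, hi = APOPTOSIS_BAND
    return float(np.mean((T > lo) & (T < hi)))


def thermal_hazard(
    T_field: np.ndarray,
    normal_roi_mask: np.ndarray,
    weights: HazardWeightTable = DEFAULT_HAZARD_TABLE,
) -> float:
    """Hazard-weighted mean over the normal-tissue region of interest.

    Equals 1 when the whole region is undamaged; grows toward the top
    weight as the region heats through the hazard bands.
    """
    if not np.any(normal_roi_mask):
        raise ValueError("normal-tissue ROI mask is empty")
    T = np.asarray(T_field)[normal_roi_mask]
    return float(weights.weight_of(T).mean())


def time_average(series, times) -> float:
    """Trapezoidal time average of a sampled series over its span."""
    s = np.asarray(series, dtype=np.float64)
    t = np.asarray(times, dtype=np.float64)
    if s.size == 0:
        raise ValueError("empty series")
    if s.size == 1:
        return float(s[0])
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be non-decreasing")
    span = t[-1] - t[0]
    if span <= 0:
        return float(s.mean())
    return float(np.trapezoid(s, t) / span)


def effective_ratio(theta_A_star: float, theta_H_star: float) -> float:
    """Objective ``theta_A* / theta_H_n*`` (hazard value is >= 1)."""
    if theta_H_star < 1.0:
        raise ValueError("thermal hazard retention value must be >= 1")
    return theta_A_star / theta_H_star


class DoseRecorder:
    """Streaming observer computing metric series snapshot by snapshot.

    Usable as the ``observer`` callback of the heat solver so long
    treatments never need the full snapshot stack in memory.
    """

    def __init__(
        self,
        tumor_mask: np.ndarray,
        normal_roi_mask: np.ndarray,
        weights: HazardWeightTable = DEFAULT_HAZARD_TABLE,
    ) -> None:
        if not np.any(tumor_mask):
            raise ValueError("tumor mask is empty")
        if not np.any(normal_roi_mask):
            raise ValueError("normal-tissue ROI mask is empty")
        self.tumor_mask = tumor_mask
        self.normal_roi_mask = normal_roi_mask
        self.weights = weights
        self.times: list[float] = []
        self.theta_A: list[float] = []
        self.theta_H: list[float] = []

    def __call__(self, t: float, T: np.ndarray) -> None:
        self.times.append(float(t))
        self.theta_A.append(apoptosis_ratio(T, self.tumor_mask))
        self.theta_H.append(thermal_hazard(T, self.normal_roi_mask, self.weights))

    def report(self, meta: dict | None = None) -> DoseReport:
        times = np.asarray(self.times)
        tA = np.asarray(self.theta_A)
        tH = np.asarray(self.theta_H)
        a_star = time_average(tA, times)
        h_star = time_average(tH, times)
        return DoseReport(
            times=times,
            theta_A=tA,
            theta_H=tH,
            theta_A_star=a_star,
            theta_H_star=h_star,
            theta_A_eff_star=effective_ratio(a_star, h_star),
            meta=meta or {},
        )


def evaluate_treatment(
    series: TemperatureSeries,
    geom: LayeredGeometry,
    weights: HazardWeightTable = DEFAULT_HAZARD_TABLE,
) -> DoseReport:
    """Compute the full dose report from a stored temperature series."""
    if series.snapshots is None:
        raise ValueError("series has no stored snapshots; use a DoseRecorder instead")
    if geom.normal_roi_mask is None:
        raise ValueError("geometry has no normal-tissue ROI mask")
    rec = DoseRecorder(geom.tumor_mask, geom.normal_roi_mask, weights)
    for t, T in zip(series.times, series.snapshots):
        rec(t, np.asarray(T, dtype=np.float64))
    return rec.report(meta={"n_snapshots": len(series.times)})
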