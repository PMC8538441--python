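"""Treatment-condition sweeps and optimum selection.

The planning grid crosses total treatment time, laser power, GNR volume
fraction and heating/cooling cycle time; each condition is scored by the
starred dose metrics and the best condition per treatment time is the
one maximizing the effective apoptosis retention ratio (ties broken by
lower power, then shorter heating time).

Two exact linearities keep the sweep tractable: the Monte Carlo
absorption grid depends only on the optical properties (hence on the
volume fraction, not the power or schedule), so one transport run per
``fv`` serves every power; and the temperature *rise* of the linear heat
solver is proportional to the power, so one unit-power heat run per
(``fv``, cycle time) covers the whole power axis — metrics for each
power are computed from the rescaled rise. Shorter treatment times are
prefixes of the longest run with the same cycle structure.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_metrics import (
    DEFAULT_HAZARD_TABLE,
    HazardWeightTable,
    effective_ratio,
    time_average,
)
from .geometry import build_skin_stack
from .heat_solver import TreatmentSchedule, run_treatment
from .photon_transport import run_monte_carlo

__all__ = ["ConditionGrid", "run_sweep", "select_optimum"]

_KEY_COLS = ["tau_tot", "power_mw", "fv", "tau_h", "tau_c"]


@dataclass(frozen=True)
class ConditionGrid:
    """The planning grid; defaults span the full study design.

    Treatment times 120-960 s in 120 s steps, powers 0-2000 mW in 50 mW
    steps, volume fractions 1e-3..1e-6 in decade steps, and symmetric
    heating/cooling times of 15, 20, 30 or 60 s.
    """

    tau_tot: tuple = tuple(range(120, 961, 120))
    power_mw: tuple = tuple(range(0, 2001, 50))
    fv: tuple = (1.0e-3, 1.0e-4, 1.0e-5, 1.0e-6)
    tau_hc: tuple = (15.0, 20.0, 30.0, 60.0)

    def __post_init__(self) -> None:
        for name in ("tau_tot", "power_mw", "fv", "tau_hc"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"grid axis {name} is empty")

    @property
    def n_conditions(self) -> int:
        return len(self.tau_tot) * len(self.power_mw) * len(self.fv) * len(self.tau_hc)


class _MaskedRecorder:
    """Observer storing masked float32 snapshots only."""

    def __init__(self, mask: np.ndarray) -> None:
        self.idx = np.nonzero(mask.ravel())
        self.times: list[float] = []
        self.snaps: list[np.ndarray] = []

    def __call__(self, t: float, T: np.ndarray) -> None:
        self.times.append(float(t))
        self.snaps.append(T.ravel()[self.idx].astype(np.float32))


def _metrics_for_power(
    times: np.ndarray,
    rise: np.ndarray,
    in_tumor: np.ndarray,
    in_roi: np.ndarray,
    scale: float,
    T_init: float,
    weights: HazardWeightTable,
) -> tuple[float, float, float]:
    theta_A = np.empty(len(times))
    theta_H = np.empty(len(times))
    for s in range(len(times)):
        T = T_init + scale * rise[s]
        Tt = T[in_tumor]
        theta_A[s] = np.mean((Tt > 43.0) & (Tt < 50.0))
        theta_H[s] = weights.weight_of(T[in_roi]).mean()
    a_star = time_average(theta_A, times)
    h_star = time_average(theta_H, times)
    return a_star, h_star, effective_ratio(a_star, h_star)


def run_sweep(
    grid: ConditionGrid,
    *,
    config: dict | None = None,
    voxel_size=0.5,
    n_photons: int = 100_000,
    seed: int = 0,
    snapshot_interval: float = 2.0,
    T_init: float = 37.0,
    weights: HazardWeightTable = DEFAULT_HAZARD_TABLE,
    power_ref_mw: float | None = None,
    out_csv: str | None = None,
    resume: bool = False,
) -> pd.DataFrame:
    """Score every condition of the grid; returns one row per condition.

    ``out_csv`` enables checkpointing: rows are appended after each
    (fv, cycle-time) block, and with ``resume=True`` already-present
    conditions are skipped on a rerun. Results are deterministic per
    seed and independent of execution order.
    """
    if power_ref_mw is None:
        power_ref_mw = max(max(grid.power_mw), 1.0)
    done: set[tuple] = set()
    rows: list[dict] = []
    if resume and out_csv and os.path.exists(out_csv):
        prev = pd.read_csv(out_csv)
        rows = prev.to_dict("records")
        done = {tuple(r[c] for c in _KEY_COLS) for r in rows}

    tau_max = max(grid.tau_tot)
    for i_fv, fv in enumerate(grid.fv):
        geom = build_skin_stack(config, voxel_size=voxel_size, fv=fv)
        mask = geom.tumor_mask | geom.normal_roi_mask
        in_tumor = geom.tumor_mask.ravel()[np.nonzero(mask.ravel())]
        in_roi = geom.normal_roi_mask.ravel()[np.nonzero(mask.ravel())]
        fv_seed = int(seed) + i_fv
        absorption = run_monte_carlo(geom, n_photons=n_photons, seed=fv_seed)
        for tau_hc in grid.tau_hc:
            todo = [
                (tt, p)
                for tt in grid.tau_tot
                for p in grid.power_mw
                if (float(tt), float(p), float(fv), float(tau_hc), float(tau_hc)) not in done
            ]
            if not todo:
                continue
            rec = _MaskedRecorder(mask)
            schedule = TreatmentSchedule(power_ref_mw, tau_hc, tau_hc, tau_max)
            run_treatment(
                geom,
                absorption,
                schedule,
                snapshot_interval=snapshot_interval,
                T_init=T_init,
                observer=rec,
                store_snapshots=False,
            )
            times = np.asarray(rec.times)
            rise = np.asarray(rec.snaps, dtype=np.float64) - T_init
            block = []
            for tt in sorted({tt for tt, _ in todo}):
                n_keep = int(np.searchsorted(times, tt + 1.0e-9))
                for p in [p for t2, p in todo if t2 == tt]:
                    a_star, h_star, eff = _metrics_for_power(
                        times[:n_keep],
                        rise[:n_keep],
                        in_tumor,
                        in_roi,
                        p / power_ref_mw,
                        T_init,
                        weights,
                    )
                    block.append(
                        {
                            "tau_tot": float(tt),
                            "power_mw": float(p),
                            "fv": float(fv),
                            "tau_h": float(tau_hc),
                            "tau_c": float(tau_hc),
                            "theta_A_star": a_star,
                            "theta_H_star": h_star,
                            "theta_A_eff_star": eff,
                            "seed": fv_seed,
                            "n_photons": int(n_photons),
                        }
                    )
            rows.extend(block)
            if out_csv:
                bdf = pd.DataFrame(block)
                header = not os.path.exists(out_csv)
                bdf.to_csv(out_csv, mode="a", header=header, index=False)
    return pd.DataFrame(rows)


def select_optimum(result: pd.DataFrame, per: str = "tau_tot") -> pd.DataFrame:
    """Best condition per ``per`` value: maximal effective apoptosis
    retention ratio, ties broken by lower power then shorter heating time."""
    if len(result) == 0:
        raise ValueError("empty sweep result")
    ordered = result.sort_values(
        [per, "theta_A_eff_star", "power_mw", "tau_h"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates(subset=per, keep="first").reset_index(drop=True)
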