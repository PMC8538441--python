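"""Declarative material / geometry configuration.

The simulator is driven by a YAML (or JSON-compatible dict) configuration
describing the layer stack, the tumor, the gold-nanorod population and the
beam. A default file encoding the standard four-layer skin model is bundled
with the package; :func:`load_config` merges a user file over it.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path

import yaml

from .optics import GNRSpec, calibrate_efficiency, gnr_effective_radius

__all__ = ["default_config", "load_config", "gnr_spec_from_config"]


def default_config() -> dict:
    """The bundled default configuration as a fresh dict."""
    text = resources.files("pttsim.data").joinpath("skin_default.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: str | Path | None = None) -> dict:
    """Load a configuration file, merged over the bundled defaults.

    Top-level keys of the user file replace the default keys wholesale
    (no deep merge), which keeps override semantics predictable.
    """
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg.update(user)
    return copy.deepcopy(cfg)


def gnr_spec_from_config(cfg: dict, fv: float | None = None) -> GNRSpec:
    """Build the GNR spec, calibrating efficiencies if not given explicitly.

    If the ``gnr`` block lists ``Qa``/``Qs`` those are used directly;
    otherwise they are backed out of the ``calibration`` block (a mixed
    tumor coefficient at a known volume fraction) against the bare-tumor
    baselines.
    """
    gnr = cfg["gnr"]
    tumor = cfg["tumor"]
    if fv is None:
        fv = float(gnr["fv"])
    if "Qa" in gnr and "Qs" in gnr:
        qa, qs = float(gnr["Qa"]), float(gnr["Qs"])
    else:
        cal = gnr["calibration"]
        probe = GNRSpec(
            float(gnr["length_nm"]), float(gnr["diameter_nm"]), 0.0, 0.0, float(cal["fv"])
        )
        r_eff = gnr_effective_radius(probe)
        qa = calibrate_efficiency(
            float(cal["mu_a_mixed"]), float(tumor["mu_a"]), float(cal["fv"]), r_eff
        )
        qs = calibrate_efficiency(
            float(cal["mu_s_mixed"]), float(tumor["mu_s"]), float(cal["fv"]), r_eff
        )
    return GNRSpec(float(gnr["length_nm"]), float(gnr["diameter_nm"]), qa, qs, fv)
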