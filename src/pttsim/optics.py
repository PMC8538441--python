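"""Optical properties of gold-nanorod (GNR) loaded tissue.

Near-infrared photothermal therapy relies on injecting gold nanorods into
the tumor to boost its absorption coefficient at the laser wavelength.
This module models the loaded tumor as a linear mixture: the nanoparticle
population contributes absorption and scattering coefficients

    mu_np = 0.75 * f_v * Q / r_eff

where ``f_v`` is the GNR volume fraction (particle volume / tumor volume),
``Q`` a dimensionless absorption or scattering efficiency, and ``r_eff``
the radius of the sphere with the same volume as one nanorod. The mixed
tissue coefficients are the sums of host-medium and nanoparticle terms;
the scattering anisotropy ``g`` of the mixture is taken from the host
(the nanoparticle term carries no anisotropy information here).

All coefficients are expressed in mm^-1 and particle dimensions in nm;
``r_eff`` is converted to mm internally so the efficiencies stay
dimensionless.

Because published efficiency values for a given rod geometry are usually
obtained from electromagnetic codes (DDA/Mie) that are out of scope here,
:func:`calibrate_efficiency` backs ``Q`` out of a known mixed coefficient
at one volume fraction; the default material configuration ships
efficiencies calibrated that way (see :mod:`pttsim.config`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "OpticalProperties",
    "GNRSpec",
    "gnr_effective_radius",
    "nanoparticle_coefficients",
    "mix_optical_properties",
    "calibrate_efficiency",
    "gnr_loaded_tissue",
]

_NM_PER_MM = 1.0e6


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption ``mu_a`` and scattering ``mu_s`` coefficients (mm^-1) and
    scattering anisotropy ``g`` (mean cosine of the deflection angle)."""

    mu_a: float
    mu_s: float
    g: float

    def __post_init__(self) -> None:
        if self.mu_a < 0.0 or self.mu_s < 0.0:
            raise ValueError(
                f"attenuation coefficients must be >= 0, got mu_a={self.mu_a}, mu_s={self.mu_s}"
            )
        if not -1.0 <= self.g <= 1.0:
            raise ValueError(f"anisotropy factor must lie in [-1, 1], got g={self.g}")

    @property
    def mu_tot(self) -> float:
        """Total attenuation coefficient mu_a + mu_s (mm^-1)."""
        return self.mu_a + self.mu_s


@dataclass(frozen=True)
class GNRSpec:
    """Geometry and optical efficiencies of a gold-nanorod population.

    Parameters
    ----------
    length_nm, diameter_nm
        Rod dimensions; the rod is modelled as a circular cylinder.
    Qa, Qs
        Dimensionless absorption / scattering efficiencies at the working
        wavelength (calibrated, see :func:`calibrate_efficiency`).
    fv
        Volume fraction of nanorods in the host tissue.
    """

    length_nm: float
    diameter_nm: float
    Qa: float
    Qs: float
    fv: float

    def __post_init__(self) -> None:
        if self.length_nm <= 0.0 or self.diameter_nm <= 0.0:
            raise ValueError(
                f"rod dimensions must be positive, got length={self.length_nm} nm, "
                f"diameter={self.diameter_nm} nm"
            )
        if self.fv < 0.0:
            raise ValueError(f"volume fraction must be >= 0, got fv={self.fv}")
        if self.Qa < 0.0 or self.Qs < 0.0:
            raise ValueError(f"efficiencies must be >= 0, got Qa={self.Qa}, Qs={self.Qs}")

    def with_fv(self, fv: float) -> "GNRSpec":
        """Same rod population at a different loading."""
        return GNRSpec(self.length_nm, self.diameter_nm, self.Qa, self.Qs, fv)


def gnr_effective_radius(spec: GNRSpec) -> float:
    """Radius (nm) of the sphere with the same volume as one nanorod.

    The rod is a cylinder of the spec's diameter and length; the effective
    radius is ``(3 V / 4 pi)^(1/3)``.
    """
    volume = math.pi * (spec.diameter_nm / 2.0) ** 2 * spec.length_nm
    return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


def nanoparticle_coefficients(spec: GNRSpec) -> tuple[float, float]:
    """Absorption and scattering coefficients (mm^-1) contributed by the
    nanorod population: ``mu_np = 0.75 f_v Q / r_eff``, linear in ``fv``."""
    r_eff_mm = gnr_effective_radius(spec) / _NM_PER_MM
    scale = 0.75 * spec.fv / r_eff_mm
    return scale * spec.Qa, scale * spec.Qs


def mix_optical_properties(
    medium: OpticalProperties, np_mu_a: float, np_mu_s: float
) -> OpticalProperties:
    """Additively mix nanoparticle coefficients into a host medium.

    Absorption and scattering add; the anisotropy of the mixture equals the
    host anisotropy.
    """
    if np_mu_a < 0.0 or np_mu_s < 0.0:
        raise ValueError("nanoparticle coefficients must be >= 0")
    return OpticalProperties(medium.mu_a + np_mu_a, medium.mu_s + np_mu_s, medium.g)


def calibrate_efficiency(
    mu_mixed: float, mu_medium: float, fv: float, r_eff_nm: float
) -> float:
    """Back out the dimensionless efficiency ``Q`` from one known mixed
    coefficient.

    Inverse of :func:`nanoparticle_coefficients` +
    :func:`mix_optical_properties`: given the mixed-tissue coefficient at
    loading ``fv`` and the bare-medium value, returns the ``Q`` that
    reproduces ``mu_mixed`` exactly.
    """
    if fv <= 0.0:
        raise ZeroDivisionError("calibration requires fv > 0")
    if mu_mixed < mu_medium:
        raise ValueError(
            f"mixed coefficient {mu_mixed} below bare-medium value {mu_medium}: "
            "would imply a negative efficiency"
        )
    r_eff_mm = r_eff_nm / _NM_PER_MM
    return (mu_mixed - mu_medium) * r_eff_mm / (0.75 * fv)


def gnr_loaded_tissue(medium: OpticalProperties, spec: GNRSpec) -> OpticalProperties:
    """Optical properties of host tissue loaded with the given rod population."""
    mu_a_np, mu_s_np = nanoparticle_coefficients(spec)
    return mix_optical_properties(medium, mu_a_np, mu_s_np)
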