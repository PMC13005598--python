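"""Domain types and derived scalar optical quantities.

Shared vocabulary for the diffusion forward model and the Monte Carlo
simulator: bulk optical properties of a turbid medium, the hollow-cylinder
(lumen) geometry of an endoscopic measurement, and the dual isotropic-source
representation of a pencil beam near its point of entry.

Units are CGS throughout: lengths in cm, coefficients in cm**-1, angles in
degrees with the illumination spot fixed at 180 deg on the lumen wall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "OpticalProperties",
    "CylinderGeometry",
    "DualSourceParams",
    "slave_index",
    "diffusion_constants",
    "build_dual_source",
    "chord_length",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of a homogeneous turbid medium.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, cm**-1 (>= 0).
    mu_s : float
        Scattering coefficient, cm**-1 (> 0).
    g : float
        Scattering anisotropy (mean cosine of the single-scattering
        deflection), dimensionless, in [0, 1).
    """

    mu_a: float
    mu_s: float
    g: float

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s <= 0:
            raise ValueError(f"mu_s must be > 0, got {self.mu_s}")
        if not (0 <= self.g < 1):
            raise ValueError(f"g must be in [0, 1), got {self.g}")

    @property
    def mu_s_reduced(self) -> float:
        """Reduced scattering coefficient mu_s * (1 - g), cm**-1."""
        return self.mu_s * (1.0 - self.g)

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s, cm**-1."""
        return self.mu_a + self.mu_s

    @classmethod
    def from_reduced(cls, mu_a: float, mu_s_reduced: float, g: float) -> "OpticalProperties":
        """Build from the reduced scattering coefficient: mu_s = mu_s' / (1 - g)."""
        if not (0 <= g < 1):
            raise ValueError(f"g must be in [0, 1), got {g}")
        return cls(mu_a=mu_a, mu_s=mu_s_reduced / (1.0 - g), g=g)


@dataclass(frozen=True)
class CylinderGeometry:
    """Hollow-cylinder lumen geometry.

    The tissue occupies the shell r_inner <= r <= r_outer around an
    air-filled lumen of radius ``r_inner``; the cylinder axis is infinite
    in principle and truncated at ``axial_halfwidth`` in practice.
    """

    r_inner: float
    r_outer: float = math.inf
    axial_halfwidth: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.r_inner < self.r_outer):
            raise ValueError(
                f"need 0 < r_inner < r_outer, got {self.r_inner}, {self.r_outer}"
            )
        if self.axial_halfwidth <= 0:
            raise ValueError("axial_halfwidth must be > 0")

    def diameter(self) -> float:
        return 2.0 * self.r_inner


@dataclass(frozen=True)
class DualSourceParams:
    """Dual isotropic-source representation of a pencil beam.

    A collimated beam entering a turbid medium is replaced by a *major*
    real source at depth ``ra_major = 1/mu_s'`` (where directionality is
    lost) and a *minor* (slave) source closer to the surface that restores
    accuracy at short source-detector separations.  Each real source has an
    image source across the extrapolated boundary at distance ``z_b``
    outside the physical interface.
    """

    ra_major: float
    ra_minor: float
    eta: float
    n_exponent: float
    s_major: float
    s_minor: float
    diff_coeff: float
    mu_eff: float
    z_b: float
    boundary_factor: float
    z_a: float = field(init=False)
    z_a_minor: float = field(init=False)
    z_b_minor: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "z_a", self.ra_major)
        object.__setattr__(self, "z_a_minor", self.ra_minor)
        object.__setattr__(self, "z_b_minor", self.z_b)


def slave_index(g: float, n: float = 10.0) -> float:
    """Slave-source index eta = [g * exp(1 - g)]**(1/n).

    Weights the minor source relative to the major one; eta -> 1 as the
    scattering becomes fully forward-peaked (g -> 1) and eta = 0 for
    isotropic scattering (g = 0).

    Parameters
    ----------
    g : float
        Scattering anisotropy in [0, 1].
    n : float
        Open model exponent controlling sensitivity to g (default 10).
    """
    if not (0 <= g <= 1):
        raise ValueError(f"g must be in [0, 1], got {g}")
    if n <= 0:
        raise ValueError(f"n must be > 0, got {n}")
    return (g * math.exp(1.0 - g)) ** (1.0 / n)


def diffusion_constants(
    props: OpticalProperties, *, literal: bool = True
) -> tuple[float, float]:
    """Diffusion coefficient D and effective attenuation mu_eff.

    Two conventions for D are supported:

    * ``literal=True`` (default): D = 1 / (mu_a + mu_s'), the convention
      used with the curvature-corrected dual-source model here.
    * ``literal=False``: the standard diffusion-theory
      D = 1 / (3 * (mu_a + mu_s')).

    In both cases mu_eff = sqrt(mu_a / D), the only dimensionally
    consistent form (cm**-1).
    """
    musp = props.mu_s_reduced
    if musp <= 0:
        raise ValueError("mu_s_reduced must be > 0")
    denom = props.mu_a + musp
    diff_coeff = 1.0 / denom if literal else 1.0 / (3.0 * denom)
    mu_eff = math.sqrt(props.mu_a / diff_coeff)
    return diff_coeff, mu_eff


def build_dual_source(
    props: OpticalProperties,
    n: float = 10.0,
    boundary_factor: float = 1.0,
    s_major: float = 1.0,
    *,
    literal_diffusion_const: bool = True,
) -> DualSourceParams:
    """Assemble the dual-source parameter set for a medium.

    The major source sits at depth Ra = 1/mu_s'; the minor source at
    Ra* = (1 - eta) * Ra with strength S* = S * eta * exp(-mu_eff * (Ra + Ra*) / 2).
    The extrapolated boundary lies at z_b = 2 * A * D outside the interface,
    with A = ``boundary_factor``.
    """
    diff_coeff, mu_eff = diffusion_constants(props, literal=literal_diffusion_const)
    ra_major = 1.0 / props.mu_s_reduced
    eta = slave_index(props.g, n)
    ra_minor = (1.0 - eta) * ra_major
    s_minor = s_major * eta * math.exp(-mu_eff * (ra_major + ra_minor) / 2.0)
    z_b = 2.0 * boundary_factor * diff_coeff
    return DualSourceParams(
        ra_major=ra_major,
        ra_minor=ra_minor,
        eta=eta,
        n_exponent=n,
        s_major=s_major,
        s_minor=s_minor,
        diff_coeff=diff_coeff,
        mu_eff=mu_eff,
        z_b=z_b,
        boundary_factor=boundary_factor,
    )


def chord_length(r_inner: float, theta):
    """Line-of-sight (chord) distance across the lumen.

    For a detector at azimuth ``theta`` (degrees) on a lumen wall of radius
    ``r_inner``, with the source at 180 deg, the straight-line distance is
    rho = 2 * R0 * sin((180 - theta) / 2).  Symmetric about theta = 180.

    Accepts scalars or numpy arrays for ``theta``.
    """
    import numpy as np

    if r_inner <= 0:
        raise ValueError("r_inner must be > 0")
    theta = np.asarray(theta, dtype=float)
    rho = 2.0 * r_inner * np.abs(np.sin(np.radians((180.0 - theta) / 2.0)))
    return float(rho) if rho.ndim == 0 else rho
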