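"""Self-calibrated absorption retrieval at the IPL point.

At the iso-pathlength point the detected intensity is independent of the
medium's scattering, so the ratio of intensities measured there for two
media differing only in absorption obeys a modified Beer-Lambert law

    I_t / I_0 = exp(-mu_a * DPF0 * L),

where L is the geometric (arc-length) separation between source and IPL
point and DPF0 - the zero-absorption differential pathlength factor -
converts it into a mean photon pathlength.  A reference of negligible
absorption plus a calibrator of known mu_a yield DPF0; DPF0 then turns an
unknown sample's intensity ratio into its absorption coefficient without
knowing its scattering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "IplMeasurement",
    "Dpf0Result",
    "arc_length",
    "dpf0_from_reference",
    "mu_a_from_dpf0",
]


@dataclass(frozen=True)
class IplMeasurement:
    """One sample's intensity read off at the IPL angle.

    ``sample_diameter`` is the lumen diameter in cm (the geometric D of
    the Beer-Lambert relation, not a diffusion coefficient).
    """

    theta_ipl: float
    sample_diameter: float
    intensity_at_ipl: float

    def __post_init__(self) -> None:
        if not (0 < self.theta_ipl < 360):
            raise ValueError("theta_ipl must be in (0, 360) deg")
        if self.sample_diameter <= 0 or self.intensity_at_ipl <= 0:
            raise ValueError("diameter and intensity must be > 0")


@dataclass(frozen=True)
class Dpf0Result:
    """Zero-absorption differential pathlength factor with an interval."""

    dpf0: float
    interval: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if not (lo <= self.dpf0 <= hi):
            raise ValueError("interval must contain dpf0")


def arc_length(diameter: float, theta_ipl) -> float:
    """Chord separation L = D * sin((180 - theta) / 2) between beam and IPL.

    ``theta_ipl`` in degrees (beam center at 180); monotonically
    decreasing in theta on (0, 180].  Accepts arrays.
    """
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    theta = np.asarray(theta_ipl, dtype=float)
    out = diameter * np.sin(np.radians((180.0 - theta) / 2.0))
    return float(out) if out.ndim == 0 else out


def dpf0_from_reference(
    i_abs: float,
    i_ref: float,
    mu_a_ref: float,
    diameter: float,
    theta_ipl: float,
    *,
    theta_spread: float = 0.0,
    ratio_spread: float = 0.0,
) -> Dpf0Result:
    """Calibrate DPF0 from a known-absorption sample.

    Parameters
    ----------
    i_abs : float
        IPL-point intensity of the absorbing calibrator (known
        ``mu_a_ref``).
    i_ref : float
        IPL-point intensity of the negligible-absorption reference.
    mu_a_ref : float
        Calibrator absorption coefficient, cm**-1.
    diameter, theta_ipl
        Lumen diameter (cm) and IPL angle (deg) fixing the geometric
        separation L.
    theta_spread, ratio_spread
        Half-widths of the IPL-angle (deg) and relative intensity-ratio
        uncertainties; the returned interval is the min/max of DPF0 over
        the corners of that uncertainty rectangle.

    Returns
    -------
    Dpf0Result
        DPF0 = -ln(i_abs / i_ref) / (mu_a_ref * L).
    """
    if i_abs <= 0 or i_ref <= 0:
        raise ValueError("intensities must be > 0")
    if mu_a_ref <= 0:
        raise ValueError("mu_a_ref must be > 0")
    ratio = i_abs / i_ref
    if ratio >= 1.0:
        warnings.warn(
            "calibrator is not dimmer than the reference (ratio >= 1); "
            "DPF0 will be <= 0",
            stacklevel=2,
        )

    def _dpf0(r: float, th: float) -> float:
        return -math.log(r) / (mu_a_ref * arc_length(diameter, th))

    nominal = _dpf0(ratio, theta_ipl)
    corners = [nominal]
    if theta_spread > 0 or ratio_spread > 0:
        for dth in (-theta_spread, theta_spread):
            for dr in (-ratio_spread, ratio_spread):
                r = ratio * (1.0 + dr)
                if r > 0:
                    corners.append(_dpf0(r, theta_ipl + dth))
    return Dpf0Result(dpf0=nominal, interval=(min(corners), max(corners)))


def mu_a_from_dpf0(
    i_sample: float,
    i_ref: float,
    dpf0: float,
    diameter: float,
    theta_ipl: float,
) -> float:
    """Invert the Beer-Lambert relation for an unknown sample.

    mu_a = -ln(i_sample / i_ref) / (DPF0 * L); exact inverse of
    :func:`dpf0_from_reference` on consistent inputs.
    """
    if i_sample <= 0 or i_ref <= 0:
        raise ValueError("intensities must be > 0")
    if dpf0 <= 0:
        raise ValueError("dpf0 must be > 0")
    length = arc_length(diameter, theta_ipl)
    return -math.log(i_sample / i_ref) / (dpf0 * length)
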