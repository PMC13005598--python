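"""Full scattering profile (FSP) container and CSV serialization.

An FSP is a reflected-intensity curve over an exit coordinate around the
illumination point: azimuthal (degrees around the lumen circumference,
beam center at 180 deg) or longitudinal (cm along the cylinder axis).
Families of FSPs from media with different reduced scattering are the raw
material for iso-pathlength (IPL) point detection.

Curve files are plain CSV in long format with columns
``direction, abscissa, intensity, mus_prime, normalization``; one file can
hold a whole curve family.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FspCurve", "read_curves", "write_curves"]

_DIRECTIONS = ("azimuthal", "longitudinal")
_NORMALIZATIONS = ("raw", "unit_area", "reference_point")


@dataclass(frozen=True)
class FspCurve:
    """One full scattering profile.

    Parameters
    ----------
    abscissa : ndarray
        Strictly increasing positions: degrees (azimuthal) or cm
        (longitudinal).
    intensity : ndarray
        Nonnegative intensities, same length as ``abscissa``.
    direction : str
        ``"azimuthal"`` or ``"longitudinal"``.
    mu_s_reduced_label : float
        Reduced scattering coefficient of the medium the curve belongs to,
        cm**-1 (used to label curve-family members).
    normalization : str
        ``"raw"``, ``"unit_area"`` or ``"reference_point"``.
    """

    abscissa: np.ndarray
    intensity: np.ndarray
    direction: str
    mu_s_reduced_label: float = float("nan")
    normalization: str = "raw"

    def __post_init__(self) -> None:
        x = np.asarray(self.abscissa, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "abscissa", x)
        object.__setattr__(self, "intensity", y)
        if x.ndim != 1 or x.size < 2:
            raise ValueError("abscissa must be 1-D with at least 2 points")
        if y.shape != x.shape:
            raise ValueError("abscissa and intensity must have equal length")
        if not np.all(np.diff(x) > 0):
            raise ValueError("abscissa must be strictly increasing")
        if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
            raise ValueError("curve values must be finite")
        if np.any(y < 0):
            raise ValueError("intensities must be >= 0")
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {_DIRECTIONS}")
        if self.normalization not in _NORMALIZATIONS:
            raise ValueError(f"normalization must be one of {_NORMALIZATIONS}")

    def area(self) -> float:
        """Trapezoid integral of the curve over its abscissa."""
        return float(np.trapezoid(self.intensity, self.abscissa))

    def interpolate(self, x: np.ndarray) -> np.ndarray:
        """Linear interpolation of the intensity at positions ``x``."""
        return np.interp(x, self.abscissa, self.intensity)

    def resampled(self, x: np.ndarray) -> "FspCurve":
        """Curve linearly resampled onto the grid ``x``."""
        return replace(self, abscissa=np.asarray(x, float), intensity=self.interpolate(x))

    def scaled(self, factor: float) -> "FspCurve":
        return replace(self, intensity=self.intensity * factor)


def write_curves(curves: list[FspCurve], path: str | Path) -> None:
    """Write a curve family to the common CSV dialect."""
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "direction": c.direction,
                    "abscissa": c.abscissa,
                    "intensity": c.intensity,
                    "mus_prime": c.mu_s_reduced_label,
                    "normalization": c.normalization,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_curves(path: str | Path) -> list[FspCurve]:
    """Read a curve family written by :func:`write_curves`.

    Curves are keyed by (direction, mus_prime); rows within one curve are
    sorted by abscissa.
    """
    df = pd.read_csv(path)
    required = {"direction", "abscissa", "intensity", "mus_prime", "normalization"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"curve CSV missing columns: {sorted(missing)}")
    out: list[FspCurve] = []
    for (direction, musp), grp in df.groupby(["direction", "mus_prime"], sort=True):
        grp = grp.sort_values("abscissa")
        out.append(
            FspCurve(
                abscissa=grp["abscissa"].to_numpy(float),
                intensity=grp["intensity"].to_numpy(float),
                direction=str(direction),
                mu_s_reduced_label=float(musp),
                normalization=str(grp["normalization"].iloc[0]),
            )
        )
    return out
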