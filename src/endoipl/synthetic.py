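"""Synthetic fixtures with known ground truth.

Generates (a) families of smooth curves that cross exactly once at a
prescribed position - stand-ins for FSP families whose IPL location is
known by construction; (b) endoscope-like grayscale frames rendered from
a truth curve with shot and read noise, for exercising the image
pipeline; (c) intensity triples (reference / calibrator / unknown)
obeying the modified Beer-Lambert law, for the absorption-retrieval
round trip.  Everything is seed-deterministic.

The constructed truth values used in tests mirror magnitudes reported
for real endoscopic phantom measurements, but they are inputs here, not
physics outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .absorption import arc_length
from .curves import FspCurve

__all__ = [
    "RenderSpec",
    "make_crossing_family",
    "render_frame",
    "make_absorption_study",
]


@dataclass(frozen=True)
class RenderSpec:
    """Parameters for rendering one synthetic endoscope frame.

    ``poisson_scale`` is the photon count corresponding to unit truth
    intensity (0 disables shot noise); ``read_sd`` the additive Gaussian
    read noise in intensity units (0 disables).
    """

    truth_curve: FspCurve
    view: str
    frame_shape: tuple[int, int] = (256, 256)
    gsd: float = 0.004
    poisson_scale: float = 0.0
    read_sd: float = 0.0
    seed: int = 0
    peak_intensity: float = 1000.0
    intensity_scale: float | None = None
    beam_sigma_px: float = 12.0
    ring_radius_px: float | None = None
    ring_sigma_px: float = 6.0

    def __post_init__(self) -> None:
        if self.view not in ("longitudinal", "azimuthal"):
            raise ValueError("view must be longitudinal or azimuthal")
        if self.poisson_scale < 0 or self.read_sd < 0:
            raise ValueError("noise parameters must be >= 0")


def _trunc_exp_shape(rate: float, t: np.ndarray, t_max: float) -> np.ndarray:
    """Unit-area truncated exponential density on [0, t_max]."""
    norm = (1.0 - np.exp(-rate * t_max)) / rate
    return np.exp(-rate * t) / norm


def make_crossing_family(
    position: float,
    n_curves: int = 4,
    domain: tuple[float, float] | None = None,
    direction: str = "longitudinal",
    *,
    base_rate: float | None = None,
    labels: list[float] | None = None,
) -> list[FspCurve]:
    """Curves with a unique common pairwise crossing at ``position``.

    Two unit-area exponential-decay shapes p and q (the second's rate
    solved so that p and q intersect exactly at ``position``) are blended
    as f_k = (1 - lam_k) p + lam_k q with lam_k spanning [0, 1].  Every
    pair then differs by a multiple of (p - q), so every pair crosses
    exactly once in the domain, precisely at ``position``, and all
    curves have unit area.

    For azimuthal curves the shapes live on |theta - 180| and are
    symmetric about the beam center, so the construction also crosses at
    the mirror position 360 - position.
    """
    if n_curves < 2:
        raise ValueError("need at least two curves")
    if direction == "longitudinal":
        if domain is None:
            domain = (0.0, 2.0)
        lo, hi = domain
        if not (lo < position < hi):
            raise ValueError("position must lie inside the domain")
        x = np.linspace(lo, hi, 600)
        t = x - lo
        t_cross = position - lo
        t_max = hi - lo
    elif direction == "azimuthal":
        if domain is None:
            domain = (90.0, 270.0)
        lo, hi = domain
        if not (lo < position < hi):
            raise ValueError("position must lie inside the domain")
        x = np.linspace(lo, hi, 720)
        t = np.abs(x - 180.0)
        t_cross = abs(position - 180.0)
        if t_cross == 0:
            raise ValueError("crossing cannot sit exactly at the beam center")
        t_max = max(180.0 - lo, hi - 180.0)
    else:
        raise ValueError("direction must be azimuthal or longitudinal")
    if t_max <= 0:
        raise ValueError("degenerate domain")

    # The crossing of two truncated-exponential shapes is bounded above by
    # their means, so the base rate must be slow relative to the requested
    # crossing; 0.5 / t_cross keeps the solution bracketed.
    b1 = base_rate if base_rate is not None else 0.5 / t_cross
    if t_cross >= t_max / 2.0:
        raise ValueError(
            f"crossing at {position} is too close to the domain edge "
            "(must lie in the first half of the decay range)"
        )

    def cross_of(b2: float) -> float:
        c1 = b1 / (1.0 - np.exp(-b1 * t_max))
        c2 = b2 / (1.0 - np.exp(-b2 * t_max))
        return np.log(c2 / c1) / (b2 - b1)

    # solve for the partner rate whose shape crosses p at t_cross
    b2 = brentq(lambda b: cross_of(b) - t_cross, b1 * 1.0001, b1 * 200.0)
    p = _trunc_exp_shape(b1, t, t_max)
    q = _trunc_exp_shape(b2, t, t_max)
    lams = np.linspace(0.0, 1.0, n_curves)
    if labels is None:
        labels = [float(10 + 4 * k) for k in range(n_curves)]
    curves = []
    for lam, lab in zip(lams, labels):
        y = (1.0 - lam) * p + lam * q
        curves.append(
            FspCurve(
                abscissa=x,
                intensity=y,
                direction=direction,
                mu_s_reduced_label=lab,
                normalization="unit_area" if direction == "longitudinal" else "raw",
            )
        )
    return curves


def render_frame(spec: RenderSpec) -> np.ndarray:
    """Render a noisy grayscale frame from a truth curve.

    Longitudinal view: the beam-row profile along columns follows the
    truth curve (in cm via ``gsd``), with Gaussian cross-row falloff.
    Azimuthal view: an annular ring whose angular intensity follows the
    truth curve, Gaussian radial profile, dark lumen interior.
    Shot (Poisson) then read (Gaussian) noise are applied per
    ``spec``; output is a float array, clipped at zero.

    By default each frame is exposed so its truth peak maps to
    ``peak_intensity`` (per-frame automatic gain, as separate captures
    would have).  Passing ``intensity_scale`` instead multiplies the truth
    curve by that fixed factor, keeping a whole rendered family on one
    common absolute scale.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.frame_shape
    truth = spec.truth_curve
    if spec.view == "longitudinal":
        r0, c0 = h / 2.0, w / 2.0
        cols = np.arange(w)
        dist_cm = np.abs(cols - c0) * spec.gsd
        if dist_cm.max() > truth.abscissa[-1] + 1e-9:
            raise ValueError("truth curve domain smaller than the frame extent")
        profile = truth.interpolate(dist_cm)
        if spec.intensity_scale is not None:
            profile = profile * spec.intensity_scale
        else:
            profile = spec.peak_intensity * profile / profile.max()
        rows = np.arange(h)
        falloff = np.exp(-((rows - r0) ** 2) / (2.0 * spec.beam_sigma_px**2))
        img = falloff[:, None] * profile[None, :]
    else:
        r0, c0 = h / 2.0, w / 2.0
        ring_r = spec.ring_radius_px if spec.ring_radius_px else min(h, w) / 4.0
        yy, xx = np.mgrid[0:h, 0:w]
        rad = np.hypot(yy - r0, xx - c0)
        ang = np.degrees(np.arctan2(yy - r0, xx - c0))  # (-180, 180]
        theta = np.mod(ang, 360.0)
        theta = np.clip(theta, truth.abscissa[0], truth.abscissa[-1])
        angular = truth.interpolate(theta)
        if spec.intensity_scale is not None:
            angular = angular * spec.intensity_scale
        else:
            angular = spec.peak_intensity * angular / angular.max()
        radial = np.exp(-((rad - ring_r) ** 2) / (2.0 * spec.ring_sigma_px**2))
        img = radial * angular
    if spec.poisson_scale > 0:
        img = rng.poisson(img * spec.poisson_scale).astype(float) / spec.poisson_scale
    if spec.read_sd > 0:
        img = img + rng.normal(0.0, spec.read_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def make_absorption_study(
    mu_a_truth: float,
    dpf0_truth: float,
    diameter: float,
    theta_ipl: float,
    noise_sd: float = 0.0,
    n_rep: int = 1,
    seed: int = 0,
    *,
    mu_a_calibrator: float = 0.25,
    i0: float = 1000.0,
):
    """Synthetic three-sample intensity workflow at the IPL point.

    Emulates measuring a negligible-absorption reference, a calibrator of
    known absorption, and an unknown sample: each replicate's intensities
    obey I = I0 * exp(-mu_a * DPF0 * L) with multiplicative lognormal
    noise of sigma ``noise_sd``.

    Returns ``(intensities, truth)`` where ``intensities`` is an
    (n_rep, 3) array with columns (reference, calibrator, unknown) and
    ``truth`` records the generating parameters.
    """
    if min(dpf0_truth, diameter, n_rep) <= 0 or mu_a_truth < 0:
        raise ValueError("parameters must be positive (mu_a_truth >= 0)")
    rng = np.random.default_rng(seed)
    length = arc_length(diameter, theta_ipl)
    clean = np.array(
        [
            i0,
            i0 * np.exp(-mu_a_calibrator * dpf0_truth * length),
            i0 * np.exp(-mu_a_truth * dpf0_truth * length),
        ]
    )
    if noise_sd > 0:
        noise = rng.lognormal(mean=0.0, sigma=noise_sd, size=(n_rep, 3))
    else:
        noise = np.ones((n_rep, 3))
    truth = {
        "mu_a_truth": mu_a_truth,
        "dpf0_truth": dpf0_truth,
        "mu_a_calibrator": mu_a_calibrator,
        "diameter": diameter,
        "theta_ipl": theta_ipl,
        "arc_length": length,
    }
    return clean[None, :] * noise, truth
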