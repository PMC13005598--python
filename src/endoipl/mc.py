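"""Monte Carlo photon transport around a cylindrical air hole.

Photons are launched from a single point on the lumen wall, directed
radially into the tissue, and random-walked with exponential step lengths
and Henyey-Greenstein scattering until they either re-enter the lumen
(detected), cross the outer tissue radius (lost), or wander past the
axial truncation bound (lost).  Detected exit positions, tallied in
azimuth and in axial distance, give the simulated full scattering
profiles whose family crossings locate the iso-pathlength point.

Geometry convention: the cylinder axis lies along y; the lumen
cross-section is the circle x**2 + z**2 = r_inner**2.  Photons enter at
(x=0, y=0, z=r_inner) moving along +z (radially outward into the
tissue).  Exit azimuth is reported with the entry point at 180 deg.

Absorption is off by default (unit photon weights, the regime in which
the IPL existence is established); setting mu_a > 0 applies a
pathlength-dependent weight exp(-mu_a * pathlength) at exit.

The hot loop is compiled with numba; the module-level operations
(`sample_step`, `sample_hg_cosine`, `deflect`, `intersect_lumen`,
`propagate`) are plain Python/NumPy and consume the same random stream,
so single-photon trajectories can be cross-checked against the compiled
batch kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .curves import FspCurve
from .optics import CylinderGeometry, OpticalProperties

__all__ = [
    "McConfig",
    "DetectionTally",
    "DetectionRecord",
    "sample_step",
    "sample_hg_cosine",
    "deflect",
    "intersect_lumen",
    "propagate",
    "run_simulation",
]


@dataclass(frozen=True)
class McConfig:
    """Simulation parameters.

    ``azimuthal_band`` restricts the azimuthal tally to exits within
    +/- that axial distance of the entry plane; ``longitudinal_band``
    restricts the longitudinal tally to exits within that many degrees of
    the entry azimuth.  ``longitudinal_max`` bounds the axial tally range
    (the histogram domain), independent of the geometric truncation
    ``geometry.axial_halfwidth``.
    """

    n_photons: int
    seed: int
    geometry: CylinderGeometry
    props: OpticalProperties
    azimuthal_bin: float = 2.0
    axial_bin: float = 0.02
    azimuthal_band: float = 0.05
    longitudinal_band: float = 5.0
    longitudinal_max: float = 2.0
    use_absorption_weight: bool = False

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if min(self.azimuthal_bin, self.axial_bin, self.azimuthal_band,
               self.longitudinal_band, self.longitudinal_max) <= 0:
            raise ValueError("bins and bands must be positive")


@dataclass(frozen=True)
class DetectionRecord:
    """One detected photon: exit azimuth (deg), axial position (cm), weight."""

    exit_azimuth: float
    exit_y: float
    weight: float


@dataclass(frozen=True)
class DetectionTally:
    """Binned exit-photon weights plus bookkeeping counts."""

    azimuthal_edges: np.ndarray
    azimuthal_hist: np.ndarray
    longitudinal_edges: np.ndarray
    longitudinal_hist: np.ndarray
    n_detected: int
    n_lost_outer: int
    n_lost_axial: int
    n_photons: int = field(default=0)

    def __post_init__(self) -> None:
        total = self.n_detected + self.n_lost_outer + self.n_lost_axial
        if self.n_photons and total != self.n_photons:
            raise ValueError("photon bookkeeping does not balance")


def sample_step(mu_t: float, u) -> float | np.ndarray:
    """Exponential free path: step = -ln(u) / mu_t for u ~ U(0, 1)."""
    if mu_t <= 0:
        raise ValueError("mu_t must be > 0")
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("u must lie in (0, 1)")
    out = -np.log(u) / mu_t
    return float(out) if out.ndim == 0 else out


def sample_hg_cosine(g: float, u) -> float | np.ndarray:
    """Henyey-Greenstein polar-angle cosine from a uniform deviate.

    For g > 0, cos(theta) = [1 + g^2 - ((1-g^2)/(1-g+2gu))^2] / (2g);
    for g = 0 the scattering is isotropic, cos(theta) = 2u - 1.  The mean
    over u equals g (the HG first moment).
    """
    if not (0 <= g < 1):
        raise ValueError("g must be in [0, 1)")
    u = np.asarray(u, dtype=float)
    if g == 0:
        out = 2.0 * u - 1.0
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        out = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    out = np.clip(out, -1.0, 1.0)
    return float(out) if out.ndim == 0 else out


def deflect(direction: np.ndarray, cos_theta: float, psi: float) -> np.ndarray:
    """Rotate a unit vector by polar angle arccos(cos_theta), azimuth psi.

    Standard local-frame scattering rotation with the special case for
    directions nearly parallel to the z axis; the result is renormalized
    to unit length.
    """
    ux, uy, uz = (float(v) for v in direction)
    ct = min(1.0, max(-1.0, float(cos_theta)))
    st = math.sqrt(1.0 - ct * ct)
    cp, sp = math.cos(psi), math.sin(psi)
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct * (1.0 if uz >= 0 else -1.0)
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -st * cp * den + uz * ct
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return np.array([nx / norm, ny / norm, nz / norm])


def intersect_lumen(
    p0: np.ndarray, direction: np.ndarray, step: float, r_inner: float
) -> tuple[np.ndarray, float] | None:
    """First crossing of a step segment into the lumen cylinder.

    Solves |p_xz + t * d_xz|^2 = r_inner^2 for t in (0, step]; returns
    (hit_point, distance) for the first inward crossing, or None.  The
    start point must lie in the tissue (outside or on the lumen wall).
    """
    x, y, z = (float(v) for v in p0)
    ux, uy, uz = (float(v) for v in direction)
    c = x * x + z * z - r_inner * r_inner
    if c < -1e-9 * r_inner * r_inner:
        raise ValueError("start point lies inside the lumen")
    a = ux * ux + uz * uz
    if a <= 0.0:
        return None
    b = 2.0 * (x * ux + z * uz)
    disc = b * b - 4.0 * a * c
    if disc <= 0.0:
        return None
    t1 = (-b - math.sqrt(disc)) / (2.0 * a)
    if not (1e-12 < t1 <= step):
        return None
    hit = np.array([x + t1 * ux, y + t1 * uy, z + t1 * uz])
    return hit, t1


def propagate(
    config: McConfig, *, max_steps: int = 50_000_000
) -> DetectionRecord | None:
    """Trace one photon with the module-level operations (reference path).

    Consumes the global ``numpy.random`` legacy stream; seed it with
    ``np.random.seed`` before calling to fix the trajectory.  Returns the
    detection record, or None if the photon is lost.  Intended for
    testing and illustration - `run_simulation` uses the compiled kernel.
    """
    geom = config.geometry
    props = config.props
    mu_t = props.mu_t
    r_in, r_out = geom.r_inner, geom.r_outer
    pos = np.array([0.0, 0.0, r_in])
    direction = np.array([0.0, 0.0, 1.0])
    pathlen = 0.0
    for _ in range(max_steps):
        u = np.random.random()
        while u <= 0.0:
            u = np.random.random()
        s = sample_step(mu_t, u)
        hit = intersect_lumen(pos, direction, s, r_in)
        # outer-boundary crossing distance, if within this step
        x, y, z = pos
        ux, uy, uz = direction
        a = ux * ux + uz * uz
        t_out = math.inf
        if math.isfinite(r_out) and a > 0:
            b = 2.0 * (x * ux + z * uz)
            c = x * x + z * z - r_out * r_out
            disc = b * b - 4.0 * a * c
            if disc > 0:
                t2 = (-b + math.sqrt(disc)) / (2.0 * a)
                if 1e-12 < t2 <= s:
                    t_out = t2
        if hit is not None and hit[1] < t_out:
            point, dist = hit
            pathlen += dist
            alpha = math.degrees(math.atan2(point[0], point[2]))
            weight = (
                math.exp(-props.mu_a * pathlen)
                if config.use_absorption_weight
                else 1.0
            )
            return DetectionRecord(
                exit_azimuth=180.0 + alpha, exit_y=float(point[1]), weight=weight
            )
        if math.isfinite(t_out):
            return None  # lost through the outer boundary
        pos = pos + s * direction
        pathlen += s
        if not np.all(np.isfinite(pos)):
            raise FloatingPointError(f"non-finite photon state {pos}")
        if abs(pos[1]) > geom.axial_halfwidth:
            return None  # lost axially
        ct = sample_hg_cosine(props.g, np.random.random())
        psi = 2.0 * math.pi * np.random.random()
        direction = deflect(direction, ct, psi)
    raise RuntimeError("photon exceeded the step budget")


@njit(cache=True, fastmath=True)
def _batch_kernel(n_photons, seed, r_in, r_out, y_max, mu_t, g):  # pragma: no cover
    np.random.seed(seed)
    status = np.empty(n_photons, np.int8)  # 0 detected, 1 lost outer, 2 lost axial
    exit_phi = np.zeros(n_photons)
    exit_y = np.zeros(n_photons)
    path = np.zeros(n_photons)
    r_in2 = r_in * r_in
    for i in range(n_photons):
        x = 0.0
        y = 0.0
        z = r_in
        ux = 0.0
        uy = 0.0
        uz = 1.0
        plen = 0.0
        st = np.int8(-1)
        while st < 0:
            u = np.random.random()
            while u <= 0.0:
                u = np.random.random()
            s = -np.log(u) / mu_t
            r2 = x * x + z * z
            a = ux * ux + uz * uz
            b = 2.0 * (x * ux + z * uz)
            t_in = -1.0
            # inner hit impossible unless the step can reach radius r_in
            lim_in = r_in + s
            if r2 <= lim_in * lim_in and a > 0.0:
                disc = b * b - 4.0 * a * (r2 - r_in2)
                if disc > 0.0:
                    t1 = (-b - np.sqrt(disc)) / (2.0 * a)
                    if 1e-12 < t1 <= s:
                        t_in = t1
            t_out = -1.0
            lim_out = r_out - s
            if (lim_out <= 0.0 or r2 >= lim_out * lim_out) and a > 0.0:
                disc2 = b * b - 4.0 * a * (r2 - r_out * r_out)
                if disc2 > 0.0:
                    t2 = (-b + np.sqrt(disc2)) / (2.0 * a)
                    if 1e-12 < t2 <= s:
                        t_out = t2
            if t_in > 0.0 and (t_out < 0.0 or t_in < t_out):
                xh = x + t_in * ux
                yh = y + t_in * uy
                zh = z + t_in * uz
                exit_phi[i] = 180.0 + np.degrees(np.arctan2(xh, zh))
                exit_y[i] = yh
                path[i] = plen + t_in
                st = np.int8(0)
                break
            if t_out > 0.0:
                st = np.int8(1)
                break
            x += s * ux
            y += s * uy
            z += s * uz
            plen += s
            if abs(y) > y_max:
                st = np.int8(2)
                break
            u1 = np.random.random()
            if g > 0.0:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u1)
                ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
            else:
                ct = 2.0 * u1 - 1.0
            if ct > 1.0:
                ct = 1.0
            elif ct < -1.0:
                ct = -1.0
            sth = np.sqrt(1.0 - ct * ct)
            psi = 2.0 * np.pi * np.random.random()
            cp = np.cos(psi)
            sp = np.sin(psi)
            if abs(uz) > 0.99999:
                nx = sth * cp
                ny = sth * sp
                nz = ct if uz >= 0.0 else -ct
            else:
                den = np.sqrt(1.0 - uz * uz)
                nx = sth * (ux * uz * cp - uy * sp) / den + ux * ct
                ny = sth * (uy * uz * cp + ux * sp) / den + uy * ct
                nz = -sth * cp * den + uz * ct
            nrm = np.sqrt(nx * nx + ny * ny + nz * nz)
            ux = nx / nrm
            uy = ny / nrm
            uz = nz / nrm
        status[i] = st
    return status, exit_phi, exit_y, path


def run_simulation(config: McConfig) -> tuple[DetectionTally, FspCurve, FspCurve]:
    """Run the batch simulation and bin the detected exits.

    Returns the tally plus the azimuthal and longitudinal FSP curves
    (bin-center abscissas, raw summed weights).  Deterministic for a
    fixed (seed, config) pair.
    """
    geom = config.geometry
    props = config.props
    r_out = geom.r_outer if math.isfinite(geom.r_outer) else 1e30
    status, phi, yy, path = _batch_kernel(
        config.n_photons,
        config.seed,
        geom.r_inner,
        r_out,
        geom.axial_halfwidth,
        props.mu_t,
        props.g,
    )
    detected = status == 0
    n_det = int(detected.sum())
    if n_det == 0:
        raise RuntimeError("no photons detected; tally is empty")
    weights = (
        np.exp(-props.mu_a * path[detected])
        if config.use_absorption_weight
        else np.ones(n_det)
    )
    phi_d = phi[detected]
    y_d = yy[detected]

    n_az = max(1, round(180.0 / config.azimuthal_bin))
    az_mask = np.abs(y_d) <= config.azimuthal_band
    az_hist, az_edges = np.histogram(
        phi_d[az_mask], bins=n_az, range=(90.0, 270.0), weights=weights[az_mask]
    )
    n_lg = max(1, round(config.longitudinal_max / config.axial_bin))
    lg_mask = np.abs(phi_d - 180.0) <= config.longitudinal_band
    lg_hist, lg_edges = np.histogram(
        np.abs(y_d[lg_mask]),
        bins=n_lg,
        range=(0.0, config.longitudinal_max),
        weights=weights[lg_mask],
    )
    tally = DetectionTally(
        azimuthal_edges=az_edges,
        azimuthal_hist=az_hist,
        longitudinal_edges=lg_edges,
        longitudinal_hist=lg_hist,
        n_detected=n_det,
        n_lost_outer=int((status == 1).sum()),
        n_lost_axial=int((status == 2).sum()),
        n_photons=config.n_photons,
    )
    musp = props.mu_s_reduced
    az_curve = FspCurve(
        abscissa=(az_edges[:-1] + az_edges[1:]) / 2.0,
        intensity=az_hist,
        direction="azimuthal",
        mu_s_reduced_label=musp,
    )
    lg_curve = FspCurve(
        abscissa=(lg_edges[:-1] + lg_edges[1:]) / 2.0,
        intensity=lg_hist,
        direction="longitudinal",
        mu_s_reduced_label=musp,
    )
    return tally, az_curve, lg_curve
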