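"""Extraction of FSP curves from endoscope-style grayscale frames.

Longitudinal frames show the laser spot on the lumen wall with the decay
along the cylinder axis resolved across image columns; azimuthal frames
view the lumen head-on, with the wall appearing as a bright ring.  The
routines here locate the beam (or hole) center, average a band (or
annulus) to beat the noise, and emit curves in the package's common FSP
dialect, with pixel positions converted to physical units through the
ground sample distance (GSD, cm per pixel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .curves import FspCurve

__all__ = [
    "EndoscopeFrame",
    "find_beam_center",
    "find_hole_center",
    "longitudinal_profile",
    "azimuthal_profile",
    "load_frame",
]


@dataclass(frozen=True)
class EndoscopeFrame:
    """One grayscale frame plus its scale and viewing direction."""

    pixels: np.ndarray
    gsd: float
    view: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not np.all(np.isfinite(px)) or np.any(px < 0):
            raise ValueError("pixels must be finite and >= 0")
        if self.gsd <= 0:
            raise ValueError("gsd must be > 0")
        if self.view not in ("longitudinal", "azimuthal"):
            raise ValueError("view must be longitudinal or azimuthal")


def load_frame(path, gsd: float, view: str, *, channel: int = 0) -> EndoscopeFrame:
    """Read a TIFF/PNG frame; color images use one channel (default red)."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:
        arr = arr[..., channel]
    return EndoscopeFrame(pixels=arr, gsd=gsd, view=view)


def find_beam_center(frame: EndoscopeFrame, *, percentile: float = 99.5):
    """Subpixel beam center: brightest-region centroid.

    The frame is 3x3 median filtered, pixels above the given percentile
    are selected, and their intensity-weighted centroid is returned as
    (row, col).  If the bright region splits into several disconnected
    blobs of comparable mass a multi-peak warning is emitted (the
    centroid then falls between them).
    """
    px = frame.pixels
    if px.max() == px.min():
        raise ValueError("cannot locate a beam center on a constant frame")
    filt = ndimage.median_filter(px, size=3)
    if filt.max() == filt.min():  # e.g. an isolated hot pixel: filter flattened it
        filt = px
    thresh = np.percentile(filt, percentile)
    mask = filt >= thresh
    if not mask.any():
        mask = filt == filt.max()
    labels, n_blobs = ndimage.label(mask)
    if n_blobs > 1:
        masses = ndimage.sum_labels(filt, labels, index=np.arange(1, n_blobs + 1))
        masses = np.sort(masses)[::-1]
        if masses[1] > 0.5 * masses[0]:
            warnings.warn("multiple bright peaks of comparable mass", stacklevel=2)
    weights = np.where(mask, filt, 0.0)
    total = weights.sum()
    rows, cols = np.mgrid[0 : px.shape[0], 0 : px.shape[1]]
    return (
        float((rows * weights).sum() / total),
        float((cols * weights).sum() / total),
    )


def find_hole_center(frame: EndoscopeFrame, *, percentile: float = 10.0):
    """Centroid of the dark lumen region.

    Pixels below the intensity percentile are labeled into connected
    components; the largest dark component that does not touch the frame
    border (the lumen interior, as opposed to the dark background outside
    the ring) is taken and its unweighted centroid returned as (row, col).
    """
    px = ndimage.median_filter(frame.pixels, size=3)
    # floor the percentile threshold at 10% of the dynamic range so that
    # smooth noiseless frames still yield a usable dark region
    thresh = max(np.percentile(px, percentile),
                 px.min() + 0.1 * (px.max() - px.min()))
    mask = px <= thresh
    if not mask.any():
        raise ValueError("no low-intensity region found")
    labels, n_blobs = ndimage.label(mask)
    border = np.unique(
        np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    )
    areas = ndimage.sum_labels(np.ones_like(px), labels,
                               index=np.arange(1, n_blobs + 1))
    interior = [
        (areas[i - 1], i) for i in range(1, n_blobs + 1) if i not in border
    ]
    if interior:
        _, pick = max(interior)
        mask = labels == pick
    rows, cols = np.mgrid[0 : px.shape[0], 0 : px.shape[1]]
    return float(rows[mask].mean()), float(cols[mask].mean())


def longitudinal_profile(
    frame: EndoscopeFrame,
    center: tuple[float, float] | None = None,
    band_halfwidth_rows: int = 5,
) -> FspCurve:
    """Axial decay profile from a longitudinal frame.

    Averages the rows within ``band_halfwidth_rows`` of the beam row
    (band of 2*h + 1 rows), then folds the two sides of the beam column
    together, returning mean intensity vs distance (cm, via the GSD) from
    the beam center.
    """
    if frame.view != "longitudinal":
        raise ValueError("longitudinal view required")
    if center is None:
        center = find_beam_center(frame)
    r0, c0 = center
    h, w = frame.pixels.shape
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError("center outside the frame")
    lo = int(round(r0)) - band_halfwidth_rows
    hi = int(round(r0)) + band_halfwidth_rows + 1
    if lo < 0 or hi > h:
        raise ValueError("row band exceeds the frame")
    band = frame.pixels[lo:hi].mean(axis=0)
    cols = np.arange(w, dtype=float)
    dist = (cols - c0) * frame.gsd
    # fold: average the two sides on a common one-sided grid
    max_dist = min(c0, w - 1 - c0) * frame.gsd
    n_pts = int(max_dist / frame.gsd)
    grid = np.arange(1, n_pts + 1) * frame.gsd
    left = np.interp(-grid, dist, band)
    right = np.interp(grid, dist, band)
    return FspCurve(
        abscissa=grid,
        intensity=np.maximum((left + right) / 2.0, 0.0),
        direction="longitudinal",
    )


def azimuthal_profile(
    frame: EndoscopeFrame,
    center: tuple[float, float] | None = None,
    *,
    annulus_halfwidth_px: int = 5,
    slice_width_deg: float = 3.0,
) -> FspCurve:
    """Angular intensity profile around the lumen ring.

    Resamples the frame to polar coordinates about the hole center, picks
    the radius with the maximal angular mean as the wall circumference,
    averages an annulus of the given half-width radially, bins the result
    into equal angular slices, and rotates the profile so the brightest
    slice (the beam) sits at 180 deg.
    """
    if frame.view != "azimuthal":
        raise ValueError("azimuthal view required")
    if center is None:
        center = find_hole_center(frame)
    r0, c0 = center
    h, w = frame.pixels.shape
    r_max = int(min(r0, c0, h - 1 - r0, w - 1 - c0))
    if r_max < 3:
        raise ValueError("circle not fully inside the frame")
    n_theta = 720
    thetas = np.radians(np.arange(n_theta) * 360.0 / n_theta)
    radii = np.arange(1, r_max)
    rr, tt = np.meshgrid(radii, thetas, indexing="ij")
    rows = r0 + rr * np.sin(tt)
    cols = c0 + rr * np.cos(tt)
    polar = ndimage.map_coordinates(frame.pixels, [rows, cols], order=1)
    radial_mean = polar.mean(axis=1)
    if radial_mean.max() <= 0 or np.ptp(radial_mean) == 0:
        raise ValueError("no ring detected (flat radial profile)")
    ring_idx = int(np.argmax(radial_mean))
    lo = max(0, ring_idx - annulus_halfwidth_px)
    hi = min(len(radii), ring_idx + annulus_halfwidth_px + 1)
    ring = polar[lo:hi].mean(axis=0)

    n_slices = max(4, int(round(360.0 / slice_width_deg)))
    slice_ids = (np.arange(n_theta) * n_slices // n_theta).astype(int)
    sliced = np.array([ring[slice_ids == s].mean() for s in range(n_slices)])
    width = 360.0 / n_slices
    # beam center: brightest slice, refined to sub-slice precision by a
    # parabolic fit so the realignment is not quantized to the slice width
    smoothed = np.convolve(
        np.concatenate([sliced[-1:], sliced, sliced[:1]]),
        np.ones(3) / 3.0, mode="valid")
    p0 = int(np.argmax(smoothed))
    ym, y0, yp = (smoothed[(p0 + d) % n_slices] for d in (-1, 0, 1))
    denom = ym - 2.0 * y0 + yp
    delta = 0.0 if denom == 0 else float(np.clip(0.5 * (ym - yp) / denom, -0.5, 0.5))
    peak_pos = p0 + delta
    target_pos = 180.0 / width - 0.5  # slice position whose center is 180 deg
    shift = target_pos - peak_pos
    # circular fractional shift by linear interpolation
    src = (np.arange(n_slices) - shift) % n_slices
    lo_idx = np.floor(src).astype(int) % n_slices
    hi_idx = (lo_idx + 1) % n_slices
    frac = src - np.floor(src)
    aligned = (1.0 - frac) * sliced[lo_idx] + frac * sliced[hi_idx]
    centers = (np.arange(n_slices) + 0.5) * width
    return FspCurve(
        abscissa=centers,
        intensity=np.maximum(aligned, 0.0),
        direction="azimuthal",
    )
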