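"""Radial reslicing and intensity-profile extraction for spherical cells.

The profiling procedure mirrors the standard radial-reslice quantification of
oocyte organelle distributions: from the fitted cell centre, intensities are
sampled along 360 rays spaced by 1 degree (bilinear interpolation at
sub-pixel positions, one ray per z-slice), the rays are average-projected
over angle into a radius-by-z image, a band of slices around the equator is
averaged into a single curve of mean intensity versus distance from the
centre, each curve is min-max normalized to [0, 1], and curves are averaged
across oocytes onto a common distance grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .geometry_io import CellRegion, ImageStack

__all__ = [
    "RadialProfile",
    "CohortProfile",
    "radial_reslice",
    "extract_equatorial_profile",
    "normalize_profile",
    "average_profiles",
    "extract_radial_profile",
]


@dataclass
class RadialProfile:
    """Per-oocyte radial intensity curve.

    ``distances`` is a strictly increasing µm grid starting at 0;
    ``normalized`` is None until :func:`normalize_profile` is applied.
    """

    distances: np.ndarray
    raw: np.ndarray
    normalized: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.distances.shape != self.raw.shape:
            raise ValueError("distances and raw must have equal length")
        if self.distances.size and (
            self.distances[0] < 0 or np.any(np.diff(self.distances) <= 0)
        ):
            raise ValueError("distances must be non-negative and strictly increasing")

    @property
    def extent(self) -> float:
        return float(self.distances[-1])


@dataclass
class CohortProfile:
    """Mean ± SD radial curve over a group of oocytes (stage × channel)."""

    distances: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    label: str = ""


def radial_reslice(
    volume: np.ndarray,
    centre_px: tuple[float, float],
    pixel_size: float,
    n_angles: int = 360,
    step_deg: float = 1.0,
    r_max_um: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Average-project rays from the centre across all angles.

    Parameters
    ----------
    volume : (z, y, x) array
        Single-channel intensity volume.
    centre_px : (x, y)
        Ray origin in pixel coordinates (must lie inside the image).
    pixel_size : float
        Lateral calibration in µm; the radial sampling step equals one pixel.
    n_angles, step_deg :
        Number of rays and angular increment (defaults: 360 rays, 1°).
    r_max_um : float, optional
        Ray length; defaults to the distance to the nearest image edge.

    Returns
    -------
    resliced : (z, n_radii) array
        Mean over angles of the sampled rays.
    radii_um : (n_radii,) array
        Distance from the centre for each column.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("volume must be (z, y, x)")
    cx, cy = centre_px
    nz, ny, nx = volume.shape
    if not (0 <= cx <= nx - 1 and 0 <= cy <= ny - 1):
        raise ValueError(f"centre {centre_px} lies outside the image")
    if r_max_um is None:
        r_max_px = min(cx, nx - 1 - cx, cy, ny - 1 - cy)
    else:
        r_max_px = r_max_um / pixel_size
    n_r = int(np.floor(r_max_px)) + 1
    radii_px = np.arange(n_r, dtype=float)
    theta = np.deg2rad(np.arange(n_angles) * step_deg)
    xs = cx + np.cos(theta)[:, None] * radii_px[None, :]
    ys = cy + np.sin(theta)[:, None] * radii_px[None, :]
    coords = np.stack([ys.ravel(), xs.ravel()])
    out = np.empty((nz, n_r))
    for z in range(nz):
        sampled = ndimage.map_coordinates(
            volume[z], coords, order=1, mode="constant", cval=0.0
        )
        out[z] = sampled.reshape(n_angles, n_r).mean(axis=0)
    return out, radii_px * pixel_size


def extract_equatorial_profile(
    resliced: np.ndarray,
    radii_um: np.ndarray,
    z_band: tuple[int, int],
    meta: dict | None = None,
) -> RadialProfile:
    """Average the resliced image over a band of z rows around the equator.

    ``z_band`` is an inclusive (lo, hi) slice-index range; the raw profile is
    the per-radius mean across those rows.
    """
    lo, hi = z_band
    if lo > hi or lo < 0 or hi >= resliced.shape[0]:
        raise ValueError(f"z_band {z_band} outside the resliced stack")
    raw = resliced[lo : hi + 1].mean(axis=0)
    return RadialProfile(np.asarray(radii_um, float), raw, meta=dict(meta or {}))


def normalize_profile(profile: RadialProfile) -> RadialProfile:
    """Min-max normalize a curve: its minimum maps to 0 and maximum to 1."""
    lo, hi = float(profile.raw.min()), float(profile.raw.max())
    if hi <= lo:
        raise ValueError("constant profile: min-max normalization is undefined")
    norm = (profile.raw - lo) / (hi - lo)
    return replace(profile, normalized=norm, meta=dict(profile.meta))


def average_profiles(
    profiles: list[RadialProfile],
    grid: np.ndarray | None = None,
    use: str = "normalized",
    label: str = "",
) -> CohortProfile:
    """Average curves across oocytes onto a common distance grid.

    Each profile is resampled by linear interpolation within its own support;
    distances beyond a profile's extent do not receive a contribution from
    it.  The default grid runs from 0 to the smallest profile extent with the
    smallest sampling step present.  SD uses the n−1 denominator and is 0
    where a single curve contributes.
    """
    if not profiles:
        raise ValueError("average_profiles requires at least one profile")
    curves = []
    for p in profiles:
        y = p.normalized if use == "normalized" else p.raw
        if y is None:
            raise ValueError("profile lacks normalized values; normalize first")
        curves.append((p.distances, np.asarray(y, float)))
    if grid is None:
        extent = min(d[-1] for d, _ in curves)
        step = min(float(np.diff(d).min()) for d, _ in curves)
        grid = np.arange(0.0, extent + step / 2, step)
    grid = np.asarray(grid, dtype=float)
    vals = np.full((len(curves), grid.size), np.nan)
    for i, (d, y) in enumerate(curves):
        inside = (grid >= d[0]) & (grid <= d[-1])
        vals[i, inside] = np.interp(grid[inside], d, y)
    n = np.sum(~np.isnan(vals), axis=0)
    if np.any(n == 0):
        keep = n > 0
        grid, vals, n = grid[keep], vals[:, keep], n[keep]
    mean = np.nanmean(vals, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # ddof=1 at n == 1
        sd = np.nanstd(vals, axis=0, ddof=1)
    sd = np.where(n > 1, sd, 0.0)
    return CohortProfile(grid, mean, sd, n, label=label)


def extract_radial_profile(
    stack: ImageStack,
    region: CellRegion,
    channel: str | int,
    z_halfwidth: int = 2,
    n_angles: int = 360,
    step_deg: float = 1.0,
) -> RadialProfile:
    """Full per-oocyte profiling step: reslice, band-average, attach metadata.

    Rays originate at the equatorial ellipse centre and extend to the mean
    ellipse radius (so the curve stays inside the cell); the equatorial band
    is the equator slice ± ``z_halfwidth`` slices, clipped to the stack.
    """
    vol = stack.channel(channel)
    centre = region.centre_px
    r_mean_um = (region.ellipse.major_um + region.ellipse.minor_um) / 4.0
    resliced, radii = radial_reslice(
        vol, centre, stack.pixel_size_xy, n_angles, step_deg, r_max_um=r_mean_um
    )
    lo = max(region.equator_z - z_halfwidth, 0)
    hi = min(region.equator_z + z_halfwidth, stack.n_z - 1)
    meta = dict(stack.metadata)
    meta.update(
        channel=str(channel), equator_z=region.equator_z, cell_type=region.cell_type
    )
    return extract_equatorial_profile(resliced, radii, (lo, hi), meta=meta)
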