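"""Plasma-membrane peak, intracellular mean, and refractile-body detection.

Mature oocytes exocytose lysosomes, which shows up as a LAMP1 intensity peak
on the plasma membrane of the radial profile while the intracellular signal
drops.  Human oocytes also carry a handful of enlarged, LAMP1-rimmed,
aggregate-containing lysosomal inclusions (refractile bodies) that are
detected here as bright connected components inside the oocyte and counted
per cell with per-body intensity readouts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .geometry_io import CellRegion, ImageStack
from .radial_profiling import RadialProfile

__all__ = [
    "Body",
    "BodyDetection",
    "PMPeak",
    "pm_peak_intensity",
    "intracellular_mean_excluding_pm",
    "detect_refractile_bodies",
    "body_intensity_summary",
]


@dataclass(frozen=True)
class PMPeak:
    """Plasma-membrane peak readout from a radial profile."""

    value: float  # maximum raw intensity in the boundary window
    radius_um: float  # distance at which the maximum occurs
    is_peak: bool  # False when the maximum is within noise of the interior
    background: float
    background_sd: float


@dataclass(frozen=True)
class Body:
    """One detected refractile body."""

    label: int
    centroid_um: tuple[float, float, float]  # (x, y, z)
    diameter_um: float  # volume-equivalent sphere diameter
    n_voxels: int
    mean: dict  # channel -> mean intensity over the body mask
    integrated: dict  # channel -> summed intensity
    positive: dict  # channel -> marker positivity flag


@dataclass
class BodyDetection:
    """Refractile-body detection result for one oocyte."""

    bodies: list[Body]
    count: int  # bodies positive in all required marker channels
    labels: np.ndarray  # (z, y, x) int label image (0 = background)
    required_channels: tuple[str, ...]


def pm_peak_intensity(
    profile: RadialProfile,
    boundary_radius_um: float,
    window_um: float = 3.0,
) -> PMPeak:
    """Maximum raw intensity of the profile near the cell boundary.

    The readout is the maximum of the raw curve within ``boundary_radius_um
    ± window_um``.  The interior of the curve (inside the window) provides a
    background level and SD; the maximum is flagged as a genuine peak only
    when it exceeds background + 2·SD.
    """
    d, y = profile.distances, profile.raw
    sel = np.abs(d - boundary_radius_um) <= window_um
    if not sel.any():
        raise ValueError("boundary window lies outside the profile support")
    idx = np.flatnonzero(sel)
    peak_i = idx[np.argmax(y[idx])]
    interior = y[d < boundary_radius_um - window_um]
    if interior.size == 0:
        interior = y
    bg = float(np.median(interior))
    sd = float(interior.std(ddof=0))
    value = float(y[peak_i])
    return PMPeak(
        value=value,
        radius_um=float(d[peak_i]),
        is_peak=bool(value >= bg + 2 * sd),
        background=bg,
        background_sd=sd,
    )


def intracellular_mean_excluding_pm(
    stack: ImageStack,
    region: CellRegion,
    channel: str | int,
    erosion_um: float = 3.0,
    z_halfwidth: int = 2,
) -> float:
    """Mean cytoplasmic intensity with the plasma-membrane rim excluded.

    A maximal projection over the equatorial band (equator ± ``z_halfwidth``
    slices) is taken, and the mean is computed over the equatorial mask
    eroded by ``erosion_um`` so the membrane signal does not contribute —
    the largest cytoplasmic area that safely excludes the rim.
    """
    if erosion_um < 0:
        raise ValueError("erosion_um must be non-negative")
    lo = max(region.equator_z - z_halfwidth, 0)
    hi = min(region.equator_z + z_halfwidth, stack.n_z - 1)
    proj = stack.channel(channel)[lo : hi + 1].max(axis=0)
    mask = region.mask[region.equator_z]
    r_px = int(round(erosion_um / stack.pixel_size_xy))
    if r_px > 0:
        mask = ndimage.binary_erosion(mask, structure=morphology.disk(r_px))
    if not mask.any():
        raise ValueError("erosion removed the whole cytoplasmic mask")
    return float(proj[mask].mean())


def detect_refractile_bodies(
    stack: ImageStack,
    region: CellRegion,
    detect_channel: str | int,
    marker_channels: tuple[str, ...] = (),
    min_diameter_um: float = 2.0,
    rel_threshold: float = 3.0,
    positivity_factor: float = 2.0,
) -> BodyDetection:
    """Detect and count bright refractile bodies inside the oocyte.

    Candidate bodies are connected components of the detection channel above
    ``rel_threshold`` times the median intra-oocyte intensity, restricted to
    the oocyte mask and filtered by volume-equivalent diameter
    ``min_diameter_um``.  For each marker channel, a body is marker-positive
    when its mean intensity reaches ``positivity_factor`` times the local
    background (median of that channel inside the oocyte, bodies excluded).
    ``count`` is the number of bodies positive in every ``marker_channels``
    entry; thresholds are relative, so detection is invariant to global
    intensity scaling.
    """
    cell = region.mask
    vol = np.asarray(stack.channel(detect_channel), dtype=float)
    inside = vol[cell]
    if inside.size == 0:
        raise ValueError("empty oocyte mask")
    scale = float(np.median(inside))
    binary = (vol > rel_threshold * scale) & cell
    labels, n = ndimage.label(binary)
    voxel_vol = stack.pixel_size_xy**2 * stack.z_step

    channels = set(marker_channels) | {str(detect_channel)}
    channels = [c for c in stack.channel_names if c in channels or c == detect_channel]
    body_free = cell & (labels == 0)
    local_bg = {
        c: float(np.median(stack.channel(c)[body_free])) for c in channels
    }

    bodies: list[Body] = []
    kept_labels = np.zeros_like(labels)
    next_label = 0
    nz, ny, nx = vol.shape
    for lab in range(1, n + 1):
        mask = labels == lab
        n_vox = int(mask.sum())
        diam = 2.0 * (3.0 * n_vox * voxel_vol / (4.0 * np.pi)) ** (1.0 / 3.0)
        if diam < min_diameter_um:
            continue
        zc, yc, xc = ndimage.center_of_mass(mask)
        centroid = (
            (xc - (nx - 1) / 2) * stack.pixel_size_xy,
            (yc - (ny - 1) / 2) * stack.pixel_size_xy,
            (zc - (nz - 1) / 2) * stack.z_step,
        )
        means, integrated, positive = {}, {}, {}
        for c in channels:
            cv = stack.channel(c)[mask]
            means[c] = float(cv.mean())
            integrated[c] = float(cv.sum())
            positive[c] = bool(means[c] >= positivity_factor * local_bg[c])
        next_label += 1
        kept_labels[mask] = next_label
        bodies.append(
            Body(next_label, centroid, float(diam), n_vox, means, integrated, positive)
        )

    required = tuple(marker_channels) if marker_channels else (str(detect_channel),)
    count = sum(all(b.positive.get(c, False) for c in required) for b in bodies)
    return BodyDetection(bodies, count, kept_labels, required)


def body_intensity_summary(detection: BodyDetection, channel: str) -> dict:
    """Per-oocyte total and mean of one channel over all detected bodies."""
    total = sum(b.integrated.get(channel, 0.0) for b in detection.bodies)
    n_vox = sum(b.n_voxels for b in detection.bodies)
    return {
        "total": float(total),
        "mean": float(total / n_vox) if n_vox else 0.0,
        "n_bodies": len(detection.bodies),
    }
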