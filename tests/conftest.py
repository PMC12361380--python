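"""Shared fixtures: coarse-voxel synthetic scenes reused across test modules.

Scenes use 1.0–1.5 µm lateral voxels (vs the 0.4 µm default) so rendering and
segmentation stay fast; geometry and intensity truths are unchanged.
"""

import numpy as np
import pytest

import ooquant as oq

COARSE = dict(pixel_size_um=1.5, psf_sigma_um=1.2)


@pytest.fixture(scope="session")
def gv_scene():
    """GV-like COC: clustered organelles, 10 cumulus cells, planted 0.5 ratio."""
    truth = oq.gv_like_scene(seed=1, oocyte_to_cumulus_ratio=0.5, **COARSE)
    stack, resolved = oq.simulate_oocyte_stack(truth)
    return stack, resolved


@pytest.fixture(scope="session")
def gv_regions(gv_scene):
    stack, _ = gv_scene
    return oq.segment_cells(stack, "lysotracker")


@pytest.fixture(scope="session")
def gv_oocyte(gv_regions):
    return next(r for r in gv_regions if r.cell_type == "oocyte")


@pytest.fixture(scope="session")
def body_scene():
    """MII-like scene with 5 planted 4 µm refractile bodies and 1 sub-threshold."""
    positions = [(20, 0, 0), (-20, 10, 4), (0, -25, -4), (15, 20, 0), (-10, -15, 6)]
    bodies = [
        oq.BodyTruth(p, 4.0, {"lamp1": 4000.0, "proteostat": 4000.0})
        for p in positions
    ]
    bodies.append(oq.BodyTruth((0, 30, 0), 1.0, {"lamp1": 4000.0, "proteostat": 4000.0}))
    channels = (
        oq.ChannelSpec("lamp1", n_puncta=300, cluster_weight=0.0, punctum_amplitude=800),
        oq.ChannelSpec("proteostat", n_puncta=0, punctum_amplitude=0),
    )
    truth = oq.mii_like_scene(
        seed=5,
        channels=channels,
        bodies=tuple(bodies),
        pixel_size_um=1.0,
        psf_sigma_um=0.8,
        n_cumulus=0,
    )
    stack, resolved = oq.simulate_oocyte_stack(truth)
    oocyte = next(
        r for r in oq.segment_cells(stack, "lamp1") if r.cell_type == "oocyte"
    )
    return stack, resolved, oocyte


def make_uniform_disc(value=7.0, radius_px=80, size=201, n_z=5):
    """Flat-intensity disc: ground truth for profile flatness checks."""
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2
    disc = (np.hypot(yy - c, xx - c) < radius_px).astype(float) * value
    return np.repeat(disc[None], n_z, axis=0), (c, c)
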