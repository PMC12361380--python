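"""Stack I/O, rescaling, size-based segmentation and ellipse geometry."""

import warnings

import numpy as np
import pytest
import tifffile
from skimage import draw

import ooquant as oq


@pytest.fixture
def small_stack():
    rng = np.random.default_rng(0)
    vox = rng.uniform(0, 100, size=(4, 32, 32, 2)).astype(np.float32)
    return oq.ImageStack(vox, 0.5, 2.0, ["a", "b"], {"donor": "d1"})


class TestIO:
    def test_round_trip_is_voxel_identical(self, small_stack, tmp_path):
        path = tmp_path / "s.ome.tif"
        oq.write_stack(small_stack, path)
        back = oq.read_stack(path)
        assert np.array_equal(back.voxels, small_stack.voxels)
        assert back.pixel_size_xy == pytest.approx(0.5)
        assert back.z_step == pytest.approx(2.0)
        assert back.channel_names == ["a", "b"]

    def test_calibration_override_wins(self, small_stack, tmp_path):
        path = tmp_path / "s.ome.tif"
        oq.write_stack(small_stack, path)
        back = oq.read_stack(path, pixel_size_xy=0.4)
        assert back.pixel_size_xy == 0.4

    def test_uncalibrated_file_requires_override(self, tmp_path):
        path = tmp_path / "plain.tif"
        tifffile.imwrite(path, np.zeros((8, 8), dtype=np.uint16))
        with pytest.raises(ValueError, match="pixel size"):
            oq.read_stack(path)
        back = oq.read_stack(path, pixel_size_xy=0.4)
        assert back.pixel_size_xy == 0.4

    def test_single_plane_becomes_one_slice_stack(self, tmp_path):
        path = tmp_path / "plane.tif"
        tifffile.imwrite(path, np.ones((8, 9), dtype=np.uint16))
        back = oq.read_stack(path, pixel_size_xy=1.0)
        assert back.voxels.shape == (1, 8, 9, 1)

    def test_invalid_stack_construction(self):
        with pytest.raises(ValueError):
            oq.ImageStack(np.zeros((2, 4, 4, 1)), -1.0, 1.0, ["a"])
        with pytest.raises(ValueError):
            oq.ImageStack(np.full((2, 4, 4, 1), np.nan), 1.0, 1.0, ["a"])
        with pytest.raises(ValueError):
            oq.ImageStack(np.zeros((2, 4, 4, 2)), 1.0, 1.0, ["a"])


class TestRescale:
    def test_identity_when_target_matches(self, small_stack):
        out = oq.rescale_to_common_pixel_size(small_stack, 0.5)
        assert out is small_stack

    def test_halving_pixel_size_doubles_lateral_dims(self, small_stack):
        out = oq.rescale_to_common_pixel_size(small_stack, 0.25)
        nz, ny, nx, nc = small_stack.voxels.shape
        assert out.voxels.shape[0] == nz and out.voxels.shape[3] == nc
        assert abs(out.voxels.shape[1] - 2 * ny) <= 1
        assert abs(out.voxels.shape[2] - 2 * nx) <= 1
        assert out.pixel_size_xy == 0.25
        assert out.metadata["rescaled_from"] == 0.5

    def test_smooth_blob_mean_preserved(self):
        # Band-limited image: interpolation must not shift the cell mean.
        yy, xx = np.mgrid[0:101, 0:101].astype(float)
        blob = 50 * np.exp(-((yy - 50) ** 2 + (xx - 50) ** 2) / (2 * 18**2))
        stack = oq.ImageStack(blob[None, :, :, None], 1.0, 1.0, ["c"])
        out = oq.rescale_to_common_pixel_size(stack, 0.5)
        mask_in = np.hypot(yy - 50, xx - 50) < 30
        yy2, xx2 = np.mgrid[0 : out.voxels.shape[1], 0 : out.voxels.shape[2]]
        mask_out = np.hypot(yy2 * 0.5 - 50, xx2 * 0.5 - 50) < 30
        m_in = float(stack.voxels[0, :, :, 0][mask_in].mean())
        m_out = float(out.voxels[0, :, :, 0][mask_out].mean())
        assert m_out == pytest.approx(m_in, rel=0.01)


class TestSegmentation:
    def test_synthetic_coc_yields_one_oocyte_ten_cumulus(self, gv_regions):
        types = [r.cell_type for r in gv_regions]
        assert types.count("oocyte") == 1
        assert types.count("cumulus") == 10

    def test_oocyte_diameter_matches_planted_cell(self, gv_scene, gv_oocyte):
        _, truth = gv_scene
        assert oq.oocyte_diameter(gv_oocyte) == pytest.approx(
            2 * truth.cell_radius_um, rel=0.03
        )

    def test_blank_image_gives_empty_list(self):
        stack = oq.ImageStack(np.zeros((3, 20, 20, 1)), 1.0, 1.0, ["c"])
        with pytest.warns(UserWarning):
            assert oq.segment_cells(stack, "c") == []

    def test_single_small_disc_is_cumulus(self):
        vox = np.zeros((3, 40, 40, 1))
        rr, cc = draw.disk((20, 20), 5)
        vox[1, rr, cc, 0] = 100.0
        stack = oq.ImageStack(vox, 1.0, 1.0, ["c"])
        regions = oq.segment_cells(stack, "c")
        assert [r.cell_type for r in regions] == ["cumulus"]
        assert regions[0].equivalent_diameter_um == pytest.approx(10.0, abs=2.0)

    def test_labels_invariant_to_intensity_scaling(self, gv_scene, gv_regions):
        stack, _ = gv_scene
        from ooquant.geometry_io import scale_intensities

        scaled = scale_intensities(stack, 3.7)
        regions = oq.segment_cells(scaled, "lysotracker")
        assert [r.cell_type for r in regions] == [r.cell_type for r in gv_regions]


class TestEllipse:
    @staticmethod
    def _disc_region(radius_px, pixel_size, shape=(140, 140)):
        vox = np.zeros((3, *shape, 1))
        rr, cc = draw.disk((shape[0] // 2, shape[1] // 2), radius_px, shape=shape)
        vox[1, rr, cc, 0] = 50.0
        stack = oq.ImageStack(vox, pixel_size, 1.0, ["c"])
        return oq.segment_cells(stack, "c", oocyte_min_diameter=0.0)[0]

    def test_circle_of_known_diameter(self):
        region = self._disc_region(radius_px=55, pixel_size=1.0)
        ell = oq.fit_equatorial_ellipse(region)
        assert ell.major_um == pytest.approx(110.0, abs=2.0)
        assert ell.minor_um == pytest.approx(110.0, abs=2.0)

    @pytest.mark.parametrize("angle_deg", [0.0, 37.0])
    def test_analytic_ellipse_axes_recovered(self, angle_deg):
        yy, xx = np.mgrid[0:161, 0:161].astype(float)
        yy -= 80
        xx -= 80
        th = np.deg2rad(angle_deg)
        u = xx * np.cos(th) + yy * np.sin(th)
        v = -xx * np.sin(th) + yy * np.cos(th)
        mask = (u / 60.0) ** 2 + (v / 50.0) ** 2 <= 1.0  # 120 x 100 px ellipse
        vox = np.zeros((1, 161, 161, 1))
        vox[0, :, :, 0] = mask * 30.0
        stack = oq.ImageStack(vox, 1.0, 1.0, ["c"])
        region = oq.segment_cells(stack, "c", oocyte_min_diameter=0.0)[0]
        ell = oq.fit_equatorial_ellipse(region)
        assert ell.major_um == pytest.approx(120.0, abs=1.2)
        assert ell.minor_um == pytest.approx(100.0, abs=1.2)


@pytest.fixture(scope="module")
def dead_cell_scene():
    truth = oq.gv_like_scene(
        seed=12, n_dead_cumulus=3, pixel_size_um=1.5, psf_sigma_um=1.2
    )
    stack, _ = oq.simulate_oocyte_stack(truth)
    regions = oq.segment_cells(stack, "lysotracker")
    return stack, regions


class TestViabilityFilter:
    def test_dead_cumulus_removed(self, dead_cell_scene):
        stack, regions = dead_cell_scene
        kept = oq.filter_viable_cumulus(regions, stack, "tmre")
        assert sum(r.cell_type == "cumulus" for r in regions) == 10
        assert sum(r.cell_type == "cumulus" for r in kept) == 7
        assert sum(r.cell_type == "oocyte" for r in kept) == 1

    def test_all_viable_pass_through(self, gv_scene, gv_regions):
        stack, _ = gv_scene
        kept = oq.filter_viable_cumulus(gv_regions, stack, "tmre")
        assert len(kept) == len(gv_regions)

    def test_explicit_threshold(self, dead_cell_scene):
        stack, regions = dead_cell_scene
        kept = oq.filter_viable_cumulus(regions, stack, "tmre", min_mean=np.inf)
        assert all(r.cell_type == "oocyte" for r in kept)
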