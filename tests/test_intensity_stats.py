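"""Intensity readouts, per-donor normalization and Welch comparisons."""

import numpy as np
import pandas as pd
import pytest

import ooquant as oq
from ooquant.geometry_io import CellRegion, Ellipse


def _region(mask, cell_type="oocyte", pixel=1.0, z_step=1.0):
    areas = mask.sum(axis=(1, 2))
    eq_z = int(np.argmax(areas))
    return CellRegion(
        label=1,
        mask=mask,
        cell_type=cell_type,
        equator_z=eq_z,
        area_um2=float(areas[eq_z]) * pixel**2,
        equivalent_diameter_um=2 * np.sqrt(areas[eq_z] * pixel**2 / np.pi),
        ellipse=Ellipse(0, 0, 1, 1, 0),
        pixel_size_xy=pixel,
        z_step=z_step,
    )


class TestWholeCellMean:
    def test_uniform_cell_returns_its_value(self):
        vox = np.full((4, 10, 10, 1), 6.5)
        stack = oq.ImageStack(vox, 1.0, 1.0, ["c"])
        mask = np.zeros((4, 10, 10), bool)
        mask[:, 2:8, 2:8] = True
        assert oq.whole_cell_mean(stack, _region(mask), "c") == pytest.approx(6.5)

    def test_projection_maximum_verified_by_bruteforce(self):
        rng = np.random.default_rng(1)
        vox = rng.uniform(0, 50, size=(5, 8, 8, 1))
        stack = oq.ImageStack(vox, 1.0, 1.0, ["c"])
        mask = np.ones((5, 8, 8), bool)
        expected = vox[..., 0].max(axis=0).mean()
        assert oq.whole_cell_mean(stack, _region(mask), "c") == pytest.approx(expected)

    def test_linearity_under_scaling(self):
        rng = np.random.default_rng(2)
        vox = rng.uniform(0, 9, size=(3, 6, 6, 1))
        stack = oq.ImageStack(vox, 1.0, 1.0, ["c"])
        stack2 = oq.ImageStack(vox * 2, 1.0, 1.0, ["c"])
        mask = np.ones((3, 6, 6), bool)
        m1 = oq.whole_cell_mean(stack, _region(mask), "c")
        m2 = oq.whole_cell_mean(stack2, _region(mask), "c")
        assert m2 == pytest.approx(2 * m1)


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=["donor", "cell_id", "stage", "compartment", "channel", "readout"],
    )


class TestPerDonorNormalize:
    def test_median_arithmetic(self):
        df = _records(
            [
                ("d1", "c1", "GV", "oocyte", "lt", 2.0),
                ("d1", "c2", "GV", "oocyte", "lt", 4.0),
                ("d1", "c3", "GV", "oocyte", "lt", 6.0),
                ("d1", "c4", "MII", "oocyte", "lt", 3.0),
            ]
        )
        out = oq.per_donor_normalize(df, {"stage": "GV"})
        assert out.loc[out.stage == "MII", "normalized"].item() == pytest.approx(0.75)

    def test_singleton_reference_normalizes_to_one(self):
        df = _records([("d1", "c1", "GV", "oocyte", "lt", 17.0)])
        out = oq.per_donor_normalize(df, {"stage": "GV"})
        assert out["normalized"].item() == 1.0

    def test_reference_median_is_exactly_one_per_donor(self):
        rng = np.random.default_rng(0)
        rows = []
        for d in ("d1", "d2", "d3"):
            for i in range(5):
                rows.append((d, f"{d}g{i}", "GV", "oocyte", "lt", rng.uniform(1, 9)))
                rows.append((d, f"{d}m{i}", "MII", "oocyte", "lt", rng.uniform(1, 9)))
        out = oq.per_donor_normalize(_records(rows), {"stage": "GV"})
        for _, grp in out.groupby("donor"):
            assert grp.loc[grp.stage == "GV", "normalized"].median() == pytest.approx(1.0)

    def test_donor_without_reference_dropped_with_warning(self):
        df = _records(
            [
                ("d1", "c1", "GV", "oocyte", "lt", 2.0),
                ("d1", "c2", "MII", "oocyte", "lt", 1.0),
                ("d2", "c3", "MII", "oocyte", "lt", 5.0),
            ]
        )
        with pytest.warns(UserWarning, match="d2"):
            out = oq.per_donor_normalize(df, {"stage": "GV"})
        assert set(out["donor"]) == {"d1"}

    def test_zero_reference_rejected(self):
        df = _records([("d1", "c1", "GV", "oocyte", "lt", 0.0)])
        with pytest.raises(ValueError, match="zero reference"):
            oq.per_donor_normalize(df, {"stage": "GV"})


class TestOocyteVsCumulus:
    @staticmethod
    def _stack_and_regions():
        # Oocyte occupies slices 0-8; cumulus only slices 3-5.
        vox = np.zeros((9, 12, 12, 1))
        vox[:, 2:8, 2:8, 0] = 10.0  # oocyte body
        vox[3:6, 9:11, 9:11, 0] = 40.0  # cumulus
        stack = oq.ImageStack(vox, 1.0, 1.0, ["c"])
        oo = np.zeros((9, 12, 12), bool)
        oo[:, 2:8, 2:8] = True
        cc = np.zeros((9, 12, 12), bool)
        cc[3:6, 9:11, 9:11] = True
        return stack, [_region(oo, "oocyte"), _region(cc, "cumulus")]

    def test_only_shared_slices_used(self):
        stack, regions = self._stack_and_regions()
        out = oq.oocyte_vs_cumulus(stack, regions, "c")
        assert out["n_slices"] == 3
        assert out["oocyte"] == pytest.approx(10.0)
        assert out["cumulus"] == pytest.approx(40.0)

    def test_non_qualifying_slices_are_irrelevant(self):
        stack, regions = self._stack_and_regions()
        vox = stack.voxels.copy()
        vox[0] = 999.0  # no cumulus on slice 0: must not matter
        stack2 = oq.ImageStack(vox, 1.0, 1.0, ["c"])
        a = oq.oocyte_vs_cumulus(stack, regions, "c")
        b = oq.oocyte_vs_cumulus(stack2, regions, "c")
        assert a == b

    def test_missing_compartment_rejected(self):
        stack, regions = self._stack_and_regions()
        with pytest.raises(ValueError):
            oq.oocyte_vs_cumulus(stack, regions[:1], "c")

    def test_planted_ratio_recovered_on_scene(self, gv_scene, gv_regions):
        stack, truth = gv_scene
        out = oq.oocyte_vs_cumulus(stack, gv_regions, "lysotracker")
        assert out["oocyte"] / out["cumulus"] == pytest.approx(0.5, rel=0.10)


class TestPairedTreatment:
    @staticmethod
    def _df(values, ids=None):
        ids = ids or [f"c{i}" for i in range(len(values))]
        return pd.DataFrame({"cell_id": ids, "readout": values})

    def test_null_effect_ratio_is_one(self):
        before = self._df([3.0, 5.0, 8.0])
        out = oq.paired_treatment_effect(before, before.copy())
        assert np.allclose(out["ratio"], 1.0)

    def test_unmatched_cells_dropped(self):
        before = self._df([3.0, 5.0], ids=["a", "b"])
        after = self._df([6.0, 7.0], ids=["a", "z"])
        with pytest.warns(UserWarning, match="unmatched"):
            out = oq.paired_treatment_effect(before, after)
        assert len(out) == 1
        assert out["ratio"].item() == pytest.approx(2.0)

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError):
            oq.paired_treatment_effect(
                self._df([1.0], ids=["a"]), self._df([1.0], ids=["b"])
            )

    def test_planted_treatment_effect_recovered_on_scenes(self):
        # Same scene re-imaged with 3x oocyte / 1.5x cumulus probe retention.
        ratios_oo, ratios_cc = [], []
        for seed in (21, 22):
            base = oq.gv_like_scene(
                seed=seed, pixel_size_um=1.5, psf_sigma_um=1.2,
                oocyte_to_cumulus_ratio=0.5,
                metadata={"cell_id": f"c{seed}", "donor": "d1"},
            )
            s_before, resolved = oq.simulate_oocyte_stack(base)
            s_after, _ = oq.simulate_oocyte_stack(
                oq.with_gains(resolved, 3.0, 1.5, noise_seed=seed + 500)
            )
            regions_b = oq.segment_cells(s_before, "lysotracker")
            regions_a = oq.segment_cells(s_after, "lysotracker")
            b = oq.oocyte_vs_cumulus(s_before, regions_b, "lysotracker")
            a = oq.oocyte_vs_cumulus(s_after, regions_a, "lysotracker")
            ratios_oo.append(a["oocyte"] / b["oocyte"])
            ratios_cc.append(a["cumulus"] / b["cumulus"])
        assert np.mean(ratios_oo) == pytest.approx(3.0, rel=0.10)
        assert np.mean(ratios_cc) == pytest.approx(1.5, rel=0.10)
        assert np.mean(ratios_oo) > np.mean(ratios_cc)


class TestWelch:
    def test_matches_closed_form_satterthwaite(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        res = oq.welch_t_test(a, b)
        # Independent hand computation from the textbook formulas.
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        from scipy import stats as ss

        p = 2 * ss.t.sf(abs(t), df)
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_identical_groups_null(self):
        a = np.array([1.0, 2.0, 3.0])
        res = oq.welch_t_test(a, a)
        assert res.t == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 2, 12)
        r1 = oq.welch_t_test(a, b)
        r2 = oq.welch_t_test(10 * a, 10 * b)
        assert r1.t == pytest.approx(r2.t, rel=1e-12)
        assert r1.df == pytest.approx(r2.df, rel=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            oq.welch_t_test([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            oq.welch_t_test([1.0, 1.0], [2.0, 2.0])


class TestDonorAverage:
    def test_singleton_equals_record(self):
        df = pd.DataFrame(
            {"donor": ["d1"], "stage": ["GV"], "channel": ["lt"], "normalized": [0.7]}
        )
        out = oq.donor_average(df)
        assert out["mean_normalized"].item() == 0.7

    def test_two_donor_arithmetic(self):
        df = pd.DataFrame(
            {
                "donor": ["d1", "d1", "d2"],
                "stage": ["GV", "GV", "GV"],
                "channel": ["lt"] * 3,
                "normalized": [1.0, 3.0, 5.0],
            }
        )
        out = oq.donor_average(df).set_index("donor")
        assert out.loc["d1", "mean_normalized"] == pytest.approx(2.0)
        assert out.loc["d2", "mean_normalized"] == pytest.approx(5.0)
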