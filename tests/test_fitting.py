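"""Tests for IDIF extraction and voxel-wise Patlak/2TCM/SUV fitting."""

import numpy as np
import pytest

import dynpet as dp
from dynpet.fitting import STATUS_FAILED, STATUS_MASKED, STATUS_OK


def _single_voxel(series, schedule):
    return dp.DynamicImage(np.asarray(series).reshape(1, 1, 1, -1), schedule,
                           (3.0, 3.0, 6.0))


@pytest.fixture(scope="module")
def free_settings():
    return dp.FitSettings(fg_fraction=0.0)


class TestExtractIdif:
    def test_homogeneous_blood_recovered_exactly(self, small_phantom, schedule,
                                                 feng_inp):
        truth = dp.synthesize_ground_truth(small_phantom, schedule, feng_inp)
        mask = small_phantom.mask(small_phantom.arterial_label)
        inp, info = dp.extract_idif(truth, mask, erosion_radius=0)
        t = np.arange(0.0, 3601.0)
        blood = dp.frame_average(t, feng_inp.cb_at(t / 60.0), schedule)
        np.testing.assert_allclose(inp.cp[1:], blood.frame_values, rtol=1e-12)
        assert info["warnings"] == []

    def test_over_erosion_falls_back_with_warning(self, small_phantom, schedule,
                                                  feng_inp):
        truth = dp.synthesize_ground_truth(small_phantom, schedule, feng_inp)
        mask = small_phantom.mask(small_phantom.arterial_label)
        inp, info = dp.extract_idif(truth, mask, erosion_radius=50)
        assert len(info["warnings"]) == 1
        assert info["n_voxels_used"] == info["n_voxels_input"]

    def test_empty_mask_rejected(self, small_phantom, schedule, feng_inp):
        truth = dp.synthesize_ground_truth(small_phantom, schedule, feng_inp)
        with pytest.raises(ValueError, match="empty"):
            dp.extract_idif(truth, np.zeros(truth.shape3, dtype=bool))


class TestPatlakVoxelwise:
    def test_exact_linear_model_recovered(self, schedule, feng_inp,
                                          free_settings):
        """A voxel built as Ki*intCp + vb*Cp recovers (0.02, 0.1) exactly."""
        mids = schedule.mid_min
        series = 0.02 * feng_inp.cumint_cp_at(mids) + 0.1 * feng_inp.cp_at(mids)
        maps = dp.fit_patlak_voxelwise(_single_voxel(series, schedule),
                                       feng_inp, free_settings)
        assert maps["Ki"][0, 0, 0] == pytest.approx(0.02, abs=1e-4)
        assert maps["vb"][0, 0, 0] == pytest.approx(0.1, abs=1e-4)
        assert maps.status[0, 0, 0] == STATUS_OK

    def test_all_zero_voxel_ok(self, schedule, feng_inp, free_settings):
        maps = dp.fit_patlak_voxelwise(_single_voxel(np.zeros(41), schedule),
                                       feng_inp, free_settings)
        assert maps["Ki"][0, 0, 0] == 0.0
        assert maps["vb"][0, 0, 0] == 0.0
        assert maps.status[0, 0, 0] == STATUS_OK

    def test_closed_form_equals_generic_lstsq(self, schedule, feng_inp,
                                              free_settings):
        rng = np.random.default_rng(0)
        mids = schedule.mid_min
        series = (0.01 * feng_inp.cumint_cp_at(mids)
                  + 0.2 * feng_inp.cp_at(mids)) * (1 + 0.05 * rng.standard_normal(41))
        maps = dp.fit_patlak_voxelwise(_single_voxel(series, schedule),
                                       feng_inp, free_settings)
        sel = mids >= free_settings.t_star_min
        x = feng_inp.cumint_cp_at(mids[sel]) / feng_inp.cp_at(mids[sel])
        y = series[sel] / feng_inp.cp_at(mids[sel])
        A = np.column_stack([x, np.ones_like(x)])
        slope, inter = np.linalg.lstsq(A, y, rcond=None)[0]
        assert maps["Ki"][0, 0, 0] == pytest.approx(slope, abs=1e-10)
        assert maps["vb"][0, 0, 0] == pytest.approx(inter, abs=1e-10)

    def test_air_masked_by_default(self, schedule, feng_inp):
        data = np.zeros((2, 1, 1, 41))
        data[0, 0, 0] = feng_inp.cp_at(schedule.mid_min)
        dyn = dp.DynamicImage(data, schedule, (3.0, 3.0, 6.0))
        maps = dp.fit_patlak_voxelwise(dyn, feng_inp)  # default 1% foreground
        assert maps.status[1, 0, 0] == STATUS_MASKED
        assert np.isnan(maps["Ki"][1, 0, 0])

    def test_too_few_frames_fails(self, feng_inp, free_settings):
        sched = dp.FrameSchedule.from_durations(np.full(4, 60.0))
        series = np.ones(4)
        settings = dp.FitSettings(t_star_min=3.0, fg_fraction=0.0)
        maps = dp.fit_patlak_voxelwise(_single_voxel(series, sched), feng_inp,
                                       settings)
        assert maps.status[0, 0, 0] == STATUS_FAILED


class TestTcm2Voxelwise:
    def test_heart_parameters_recovered(self, schedule, feng_inp, table1,
                                        free_settings):
        row = table1.loc["heart"]
        p = dp.KineticParams(row.K1, row.k2, row.k3, row.vb)
        tac = dp.tissue_tac(p, feng_inp, schedule)
        maps = dp.fit_2tcm_voxelwise(_single_voxel(tac.frame_values, schedule),
                                     feng_inp, free_settings)
        for name, truth in zip(("K1", "k2", "k3", "vb"),
                               (p.K1, p.k2, p.k3, p.vb)):
            assert maps[name][0, 0, 0] == pytest.approx(truth, rel=0.01), name

    def test_blood_only_voxel(self, schedule, feng_inp, free_settings):
        t = np.arange(0.0, 3601.0)
        blood = dp.frame_average(t, feng_inp.cb_at(t / 60.0), schedule)
        maps = dp.fit_2tcm_voxelwise(
            _single_voxel(0.3 * blood.frame_values, schedule), feng_inp,
            free_settings)
        assert maps["K1"][0, 0, 0] < 1e-4
        assert maps["vb"][0, 0, 0] == pytest.approx(0.3, rel=0.01)

    def test_derived_ki_is_exact_macro_identity(self, schedule, feng_inp,
                                                table1, free_settings):
        row = table1.loc["bone"]
        p = dp.KineticParams(row.K1, row.k2, row.k3, row.vb)
        tac = dp.tissue_tac(p, feng_inp, schedule)
        maps = dp.fit_2tcm_voxelwise(_single_voxel(tac.frame_values, schedule),
                                     feng_inp, free_settings)
        k1, k2, k3 = (maps[n][0, 0, 0] for n in ("K1", "k2", "k3"))
        assert maps["Ki"][0, 0, 0] == dp.macro_ki(k1, k2, k3)

    def test_determinism(self, schedule, feng_inp, free_settings):
        rng = np.random.default_rng(9)
        series = np.abs(rng.standard_normal(41)).cumsum() / 10.0
        dyn = _single_voxel(series, schedule)
        a = dp.fit_2tcm_voxelwise(dyn, feng_inp, free_settings)
        b = dp.fit_2tcm_voxelwise(dyn, feng_inp, free_settings)
        for n in a.params:
            np.testing.assert_array_equal(a[n], b[n])

    def test_patlak_vs_2tcm_ki_consistency(self, schedule, feng_inp, table1,
                                           free_settings):
        """On noise-free model data the two Ki estimates agree per label.

        The Patlak voxel slope estimates (1-vb)*Ki, so the comparison is on
        that scale.
        """
        for name in ("heart", "liver", "tumor_border"):
            row = table1.loc[name]
            p = dp.KineticParams(row.K1, row.k2, row.k3, row.vb)
            tac = dp.tissue_tac(p, feng_inp, schedule)
            dyn = _single_voxel(tac.frame_values, schedule)
            pat = dp.fit_patlak_voxelwise(dyn, feng_inp, free_settings)
            tcm = dp.fit_2tcm_voxelwise(dyn, feng_inp, free_settings)
            ki_pat = pat["Ki"][0, 0, 0]
            ki_tcm = (1 - tcm["vb"][0, 0, 0]) * tcm["Ki"][0, 0, 0]
            assert abs(ki_pat - ki_tcm) / ki_tcm < 0.03, name


class TestSuvMap:
    def test_uniform_frame_uniform_map(self, schedule):
        data = np.zeros((3, 3, 2, 41))
        data[..., -1] = 5.0
        maps = dp.compute_suv_map(dp.DynamicImage(data, schedule, (3, 3, 6)))
        assert np.unique(maps["SUV"]).size == 1

    def test_linear_in_weight(self, schedule):
        data = np.full((1, 1, 1, 41), 4.0)
        dyn = dp.DynamicImage(data, schedule, (3, 3, 6))
        a = dp.compute_suv_map(dyn, 240.0, 60.0)["SUV"][0, 0, 0]
        b = dp.compute_suv_map(dyn, 240.0, 120.0)["SUV"][0, 0, 0]
        assert b == pytest.approx(2.0 * a)
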