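"""Unit and property tests for the kinetic model layer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad, solve_ivp

import dynpet as dp
from dynpet.kinetics import FENG_DEFAULTS, exp_convolve


class TestSchedule:
    def test_default_protocol(self, schedule):
        assert schedule.n_frames == 41
        assert schedule.total_s == 3600.0
        # cumulative sum of the first 12 x 10 s frames
        assert schedule.start_s[12] == 120.0

    def test_contiguity_enforced(self):
        with pytest.raises(ValueError, match="contiguous"):
            dp.FrameSchedule(np.array([0.0, 15.0]), np.array([10.0, 10.0]))
        with pytest.raises(ValueError, match="positive"):
            dp.FrameSchedule(np.array([0.0, 10.0]), np.array([10.0, -1.0]))

    def test_text_and_json_round_trip(self, schedule, tmp_path):
        schedule.to_text(tmp_path / "s.txt")
        back = dp.FrameSchedule.from_text(tmp_path / "s.txt")
        np.testing.assert_allclose(back.start_s, schedule.start_s)
        schedule.to_json(tmp_path / "s.json")
        back = dp.FrameSchedule.from_json(tmp_path / "s.json")
        np.testing.assert_allclose(back.dur_s, schedule.dur_s)


class TestFengInput:
    def test_zero_at_injection(self):
        assert dp.feng_input_function(0.0) == 0.0

    def test_decays_to_zero(self):
        assert dp.feng_input_function(1e4) < 1e-6

    def test_peak_matches_grid_oracle(self):
        t = np.linspace(0.0, 5.0, 200001)
        cp = dp.feng_input_function(t)
        # closed-form stationarity at the grid argmax
        i = int(np.argmax(cp))
        h = t[1] - t[0]
        dcp = (cp[i + 1] - cp[i - 1]) / (2 * h)
        assert abs(dcp) < 1e-3 * cp[i]
        assert 30 < cp[i] < 50  # kBq/mL scale of a 4 MBq/kg bolus

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            dp.feng_input_function(-1.0)

    def test_rate_ordering_enforced(self):
        with pytest.raises(ValueError):
            dp.feng_input_function(1.0, l1=0.1, l2=0.2, l3=0.01)


class TestTcm2:
    def test_no_extraction_gives_scaled_blood(self, feng_inp):
        p = dp.KineticParams(0.0, 0.2, 0.1, 0.1)
        t = np.linspace(0, 60, 601)
        c = dp.tcm2_tissue_concentration(p, feng_inp, t)
        np.testing.assert_allclose(c, 0.1 * feng_inp.cb_at(t), rtol=1e-12)

    def test_pure_trapping_is_integral(self, feng_inp):
        p = dp.KineticParams(0.05, 0.0, 0.1, 0.0)
        t = np.arange(0, 3601) / 60.0
        c = dp.tcm2_tissue_concentration(p, feng_inp, t)
        np.testing.assert_allclose(c, 0.05 * feng_inp.cumint_cp_at(t),
                                   rtol=1e-9, atol=1e-12)

    def test_matches_ode_oracle(self, feng_inp, liver_params):
        """Analytic-convolution solution vs a stiff ODE integrator (1 s grid)."""
        p = liver_params
        t = np.arange(0, 3601) / 60.0

        def rhs(tt, y):
            cp = float(feng_inp.cp_at(tt))
            return [p.K1 * cp - (p.k2 + p.k3) * y[0], p.k3 * y[0]]

        sol = solve_ivp(rhs, (0, 60), [0.0, 0.0], t_eval=t, method="LSODA",
                        rtol=1e-9, atol=1e-12)
        ode = (1 - p.vb) * (sol.y[0] + sol.y[1]) + p.vb * feng_inp.cb_at(t)
        ours = dp.tcm2_tissue_concentration(p, feng_inp, t)
        m = t > 0.5
        assert np.max(np.abs(ours[m] - ode[m]) / ode[m]) < 1e-4

    def test_degenerate_limit_warns(self, feng_inp):
        p = dp.KineticParams(0.1, 0.0, 0.0, 0.0)
        t = np.linspace(0, 10, 601)
        with pytest.warns(dp.DegenerateKineticsWarning):
            c = dp.tcm2_tissue_concentration(p, feng_inp, t)
        np.testing.assert_allclose(c, 0.1 * feng_inp.cumint_cp_at(t), rtol=1e-9)

    def test_mass_conservation(self, feng_inp, liver_params):
        """With vb=0, tissue content equals K1*int Cp - k2*int C1."""
        p = dp.KineticParams(liver_params.K1, liver_params.k2,
                             liver_params.k3, 0.0)
        t = np.arange(0, 3601) / 60.0
        alpha = p.k2 + p.k3
        c1 = p.K1 * exp_convolve(t, feng_inp.cp_at(t), alpha)
        ct = dp.tcm2_tissue_concentration(p, feng_inp, t)
        h = t[1] - t[0]
        int_c1 = np.concatenate([[0.0], np.cumsum(0.5 * (c1[1:] + c1[:-1]) * h)])
        balance = p.K1 * feng_inp.cumint_cp_at(t) - p.k2 * int_c1
        m = t > 1.0
        assert np.max(np.abs(ct[m] - balance[m]) / balance[m]) < 1e-4

    @settings(max_examples=25, deadline=None)
    @given(K1=st.floats(0.0, 1.0), k2=st.floats(0.0, 2.0),
           k3=st.floats(0.001, 2.0), vb=st.floats(0.0, 1.0))
    def test_non_negative_output(self, feng_inp_g, K1, k2, k3, vb):
        p = dp.KineticParams(K1, k2, k3, vb)
        t = np.linspace(0, 60, 361)
        c = dp.tcm2_tissue_concentration(p, feng_inp_g, t)
        assert np.all(c >= -1e-12)


@pytest.fixture(scope="module")
def feng_inp_g():
    return dp.InputFunction.from_feng()


class TestMacroKi:
    def test_liver_row_rounds_to_tabulated(self):
        assert round(dp.macro_ki(0.10, 0.34, 0.04), 3) == 0.011

    def test_limits(self):
        assert dp.macro_ki(0.3, 0.2, 0.0) == 0.0
        assert dp.macro_ki(0.3, 0.0, 0.5) == pytest.approx(0.3)
        with pytest.raises(dp.DegenerateKineticsError):
            dp.macro_ki(0.3, 0.0, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(K1=st.floats(0.001, 1.0), k2=st.floats(0.0, 2.0),
           k3=st.floats(0.001, 2.0), a=st.floats(0.1, 10.0),
           b=st.floats(0.1, 10.0))
    def test_homogeneity_and_rate_scaling(self, K1, k2, k3, a, b):
        ki = dp.macro_ki(K1, k2, k3)
        assert dp.macro_ki(a * K1, k2, k3) == pytest.approx(a * ki, rel=1e-12)
        assert dp.macro_ki(K1, b * k2, b * k3) == pytest.approx(ki, rel=1e-12)


class TestFrameAverage:
    def test_constant_and_linear(self, schedule):
        t = np.arange(0.0, 3601.0)
        tac = dp.frame_average(t, np.full_like(t, 7.5), schedule)
        np.testing.assert_allclose(tac.frame_values, 7.5)
        tac = dp.frame_average(t, 0.01 * t, schedule)
        np.testing.assert_allclose(tac.frame_values, 0.01 * schedule.mid_s,
                                   rtol=1e-12)

    def test_matches_quadrature_oracle(self, schedule):
        t = np.arange(0.0, 3600.2, 0.2)  # fine step for the steep bolus rise
        curve = dp.feng_input_function(t / 60.0)
        tac = dp.frame_average(t, curve, schedule)
        for i in [0, 3, 12, 25, 40]:
            ref, _ = quad(lambda s: dp.feng_input_function(s / 60.0),
                          schedule.start_s[i], schedule.end_s[i], limit=200)
            ref /= schedule.dur_s[i]
            assert abs(tac.frame_values[i] - ref) / ref < 1e-3

    def test_rejects_bad_grid(self, schedule):
        t = np.arange(0.0, 1000.0)
        with pytest.raises(ValueError, match="cover"):
            dp.frame_average(t, t, schedule)
        t = np.arange(0.0, 3601.0, 5.0)
        with pytest.raises(ValueError, match="step"):
            dp.frame_average(t, t, schedule)


class TestPatlak:
    def test_blood_only_voxel(self, schedule, feng_inp):
        tac = dp.frame_average(np.arange(0.0, 3601.0),
                               0.1 * feng_inp.cb_at(np.arange(3601.0) / 60.0),
                               schedule)
        x, y, used = dp.patlak_transform(tac, feng_inp)
        late = schedule.mid_min >= 20
        np.testing.assert_allclose(y[late], 0.1, rtol=5e-3)
        fit = dp.fit_patlak_line(x[late], y[late])
        assert abs(fit.Ki_slope) < 1e-4

    def test_pure_trapping_exact_line(self, schedule, feng_inp):
        t = np.arange(0.0, 3601.0)
        curve = 0.02 * feng_inp.cumint_cp_at(t / 60.0)
        # evaluate at mid-times directly to bypass frame-average smoothing
        mids = schedule.mid_min
        tac = dp.TissueTAC(0.02 * feng_inp.cumint_cp_at(mids), schedule)
        x, y, used = dp.patlak_transform(tac, feng_inp)
        np.testing.assert_allclose(y[used], 0.02 * x[used], rtol=1e-9)

    def test_slope_converges_to_macro_ki(self, schedule, feng_inp, table1):
        """Late-window graphical slope of the blood-free tissue response."""
        late = schedule.mid_min >= 20
        for name, row in table1.iterrows():
            p = dp.KineticParams(row.K1, row.k2, row.k3, 0.0)
            tac = dp.tissue_tac(p, feng_inp, schedule)
            x, y, _ = dp.patlak_transform(tac, feng_inp)
            fit = dp.fit_patlak_line(x[late], y[late])
            assert abs(fit.Ki_slope - p.ki) / p.ki < 0.02, name

    def test_voxel_slope_is_one_minus_vb_times_ki(self, schedule, feng_inp,
                                                  liver_params):
        """The measured voxel signal dilutes the influx slope by (1 - vb)."""
        p = liver_params
        tac = dp.tissue_tac(p, feng_inp, schedule)
        x, y, _ = dp.patlak_transform(tac, feng_inp)
        late = schedule.mid_min >= 20
        fit = dp.fit_patlak_line(x[late], y[late])
        assert fit.Ki_slope == pytest.approx((1 - p.vb) * p.ki, rel=0.02)
        # this is how the tabulated Patlak reference relates to the 2TCM one
        assert round((1 - p.vb) * p.ki, 3) == 0.007

    def test_zero_cp_frames_reported(self, schedule):
        inp = dp.InputFunction(np.array([0.0, 1.0, 60.0]),
                               np.array([0.0, 10.0, 5.0]))
        tac = dp.TissueTAC(np.ones(41), schedule)
        x, y, used = dp.patlak_transform(tac, inp)
        assert used.all()  # positive Cp everywhere on this base


class TestSuv:
    def test_unit_dilution(self):
        # 240 MBq in 60 kg at 1 g/mL -> 4 kBq/mL is SUV 1 at t = 0
        assert dp.suv(4.0, 240.0, 60.0, t_min=0.0) == pytest.approx(1.0)

    def test_one_half_life_doubles(self):
        assert dp.suv(4.0, 240.0, 60.0, t_min=110.0) == pytest.approx(2.0)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            dp.suv(1.0, 0.0, 60.0)
        with pytest.raises(ValueError):
            dp.suv(1.0, 240.0, -1.0)


class TestExpConvolve:
    @pytest.mark.parametrize("uniform", [True, False])
    def test_matches_closed_form_exponential(self, uniform):
        """Both code paths against the exact convolution of e^{-l t}."""
        alpha, l = 0.7, 0.05
        if uniform:
            t = np.arange(0, 1201) / 20.0
        else:
            rng = np.random.default_rng(5)
            t = np.concatenate([[0.0], np.cumsum(rng.uniform(0.01, 0.1, 1200))])
        c = np.exp(-l * t)
        y = exp_convolve(t, c, alpha)
        exact = (np.exp(-l * t) - np.exp(-alpha * t)) / (alpha - l)
        np.testing.assert_allclose(y, exact, rtol=2e-4, atol=1e-8)

    def test_alpha_zero_is_running_integral(self, feng_inp):
        t = np.arange(0, 601) / 60.0
        y = exp_convolve(t, feng_inp.cp_at(t), 0.0)
        np.testing.assert_allclose(y, feng_inp.cumint_cp_at(t), rtol=1e-9,
                                   atol=1e-9)
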