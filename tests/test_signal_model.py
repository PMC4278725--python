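import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import liverdce as l
from liverdce.signal_model import forward_signal


def make_series(y, dt=1.0):
    t = np.arange(len(y)) * dt
    return l.TimeSeries(t, np.asarray(y, float))


class TestForwardModels:
    def test_zero_conc_leaves_t10(self, relax_blood):
        assert relax_blood.t1_of_conc(0.0) == pytest.approx(1.2)

    def test_relaxivity_arithmetic(self):
        # 1 mmol/L at T10 = 1.2 s, r1 = 6.3: T1 = 1/(1/1.2 + 6.3) s
        relax = l.RelaxationParams(t10=1.2, r1=6.3)
        assert relax.t1_of_conc(1.0) == pytest.approx(1.0 / (1.0 / 1.2 + 6.3))
        assert relax.t1_of_conc(1.0) == pytest.approx(0.140187, abs=1e-6)

    def test_spgr_vanishes_at_zero_flip(self, relax_blood):
        acq = l.AcquisitionParams("spgr", tr=0.003, te=0.001, flip_angle_deg=1e-9)
        assert l.spgr_signal(5.0, 100.0, acq, relax_blood) == pytest.approx(0.0, abs=1e-6)

    def test_sat_recovery_limits(self, relax_blood):
        acq = l.AcquisitionParams("sat_recovery", 0.0023, 0.0009, 12.0, recovery_time=0.12)
        # conc = 0: S = M0 (1 - exp(-TS/T10)) = M0 (1 - exp(-0.1))
        assert l.sat_recovery_signal(0.0, 1.0, acq, relax_blood) == pytest.approx(
            1 - np.exp(-0.1)
        )
        assert l.sat_recovery_signal(0.0, 1.0, acq, relax_blood) == pytest.approx(
            0.09516, abs=1e-5
        )
        # huge concentration: full recovery toward M0
        assert l.sat_recovery_signal(1e6, 1.0, acq, relax_blood) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("kind", ["spgr", "sat_recovery"])
    def test_monotone_in_concentration(self, kind, acq_pre, acq_main, relax_blood):
        acq = acq_pre if kind == "sat_recovery" else acq_main
        conc = np.linspace(0, 20, 400)
        sig = forward_signal(conc, 50.0, acq, relax_blood)
        assert np.all(np.diff(sig) > 0)

    def test_spgr_saturation_slope_drops(self, acq_main, relax_blood):
        # relative signal gain per unit conc at 8 mmol/L is far below 0.5 mmol/L
        def slope(c, h=1e-4):
            lo = l.spgr_signal(c - h, 1.0, acq_main, relax_blood)
            hi = l.spgr_signal(c + h, 1.0, acq_main, relax_blood)
            return (hi - lo) / (2 * h)

        assert slope(8.0) < slope(0.5)

    def test_non_finite_inputs_rejected(self, acq_main, relax_blood):
        with pytest.raises(ValueError, match="conc"):
            l.spgr_signal(np.nan, 1.0, acq_main, relax_blood)
        with pytest.raises(ValueError, match="t10"):
            l.RelaxationParams(t10=np.inf, r1=6.3)
        with pytest.raises(ValueError, match="recovery_time"):
            l.AcquisitionParams("sat_recovery", 0.002, 0.001, 12.0, recovery_time=None)


class TestInversion:
    @pytest.mark.parametrize("kind", ["spgr", "sat_recovery"])
    @pytest.mark.parametrize("r1", [3.0, 6.3, 8.0])
    def test_round_trip(self, kind, r1, acq_pre, acq_main):
        relax = l.RelaxationParams(t10=1.2, r1=r1)
        acq = acq_pre if kind == "sat_recovery" else acq_main
        # up to 15 mmol/L: the well-conditioned range of both forward maps
        # (the asymptotic corner is covered by the acceptance round trip)
        conc = np.concatenate([[0.0, 0.0, 0.0], np.linspace(0.01, 15, 40)])
        sig = forward_signal(conc, 77.0, acq, relax)
        series = make_series(sig)
        out = l.signal_to_concentration(series, 3, acq, relax)
        np.testing.assert_allclose(out.series.y, conc, rtol=1e-9, atol=1e-9)
        assert out.n_saturated == 0

    def test_forward_inverse_single_value(self, acq_main, relax_blood):
        sig = l.spgr_signal(np.array([0.0, 0.0, 0.0, 2.5]), 10.0, acq_main, relax_blood)
        out = l.signal_to_concentration(make_series(sig), 3, acq_main, relax_blood)
        assert out.series.y[-1] == pytest.approx(2.5, rel=1e-9)

    def test_constant_baseline_gives_zero(self, acq_main, relax_blood):
        out = l.signal_to_concentration(make_series([5.0, 5.0]), 1, acq_main, relax_blood)
        np.testing.assert_array_equal(out.series.y, [0.0, 0.0])

    def test_below_baseline_clamped_and_counted(self, acq_main, relax_blood):
        out = l.signal_to_concentration(make_series([5.0, 5.0, 4.8, 5.2]), 2, acq_main, relax_blood)
        assert out.series.y[2] == 0.0
        assert out.n_clamped == 1

    def test_saturated_sample_flagged(self, acq_main, relax_blood):
        conc_max = 50.0
        smax = float(forward_signal(conc_max, 10.0, acq_main, relax_blood))
        sig = np.array([l.spgr_signal(0.0, 10.0, acq_main, relax_blood)] * 3 + [smax * 1.01])
        out = l.signal_to_concentration(make_series(sig), 3, acq_main, relax_blood, conc_max)
        assert out.n_saturated == 1
        assert out.series.y[-1] == conc_max

    def test_requires_positive_baseline(self, acq_main, relax_blood):
        with pytest.raises(ValueError, match="baseline"):
            l.signal_to_concentration(make_series([0.0, 0.0, 1.0]), 2, acq_main, relax_blood)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        conc=st.floats(0.0, 20.0),
        r1=st.floats(3.0, 8.0),
        t10=st.floats(0.3, 2.0),
    )
    def test_round_trip_property(self, conc, r1, t10):
        relax = l.RelaxationParams(t10=t10, r1=r1)
        acq = l.default_mainbolus_acquisition()
        sig = forward_signal(np.array([0.0, conc]), 42.0, acq, relax)
        out = l.signal_to_concentration(make_series(sig), 1, acq, relax)
        assert out.series.y[1] == pytest.approx(conc, rel=1e-9, abs=1e-9)


class TestBloodToPlasma:
    def test_zero_hematocrit_is_identity(self):
        s = make_series([0.0, 1.0, 2.0])
        np.testing.assert_array_equal(l.blood_to_plasma(s, 0.0).y, s.y)

    def test_scaling_values(self):
        s = make_series([1.0, 1.0])
        assert l.blood_to_plasma(s, 0.45).y[0] == pytest.approx(1 / 0.55)
        s2 = make_series([0.0, 2.0])
        np.testing.assert_allclose(l.blood_to_plasma(s2, 0.5).y, [0.0, 4.0])

    def test_rejects_hematocrit_of_one(self):
        with pytest.raises(ValueError, match="hematocrit"):
            l.blood_to_plasma(make_series([1.0, 1.0]), 1.0)
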