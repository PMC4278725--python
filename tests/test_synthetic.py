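from dataclasses import replace

import numpy as np
import pytest

import liverdce as l
from liverdce.signal_model import spgr_signal
from liverdce.synthetic import MASTER_DT


class TestImpulseAif:
    def test_pure_gamma_peak_location(self):
        t = np.arange(0, 120, MASTER_DT)
        shape = l.AifShape(recirc_fraction=0.0, arrival=8.0, shape=3.0, scale=2.3)
        h = l.impulse_aif(t, shape)
        # closed form: gamma-variate peaks at arrival + shape*scale
        assert t[np.argmax(h.y)] == pytest.approx(8.0 + 3.0 * 2.3, abs=2 * MASTER_DT)
        assert h.y.max() == pytest.approx(shape.amplitude, rel=1e-6)

    def test_zero_amplitude_zero_curve(self):
        t = np.arange(0, 60, MASTER_DT)
        h = l.impulse_aif(t, l.AifShape(amplitude=0.0))
        np.testing.assert_array_equal(h.y, 0.0)

    def test_finite_positive_integral_and_bounded_recirculation(self):
        t = np.arange(0, 120, MASTER_DT)
        h = l.impulse_aif(t, l.AifShape())
        area = np.trapezoid(h.y, t)
        assert 0 < area < np.inf
        # recirculation bump stays well below the first-pass peak
        peak_i = np.argmax(h.y)
        late = h.y[t > t[peak_i] + 10]
        assert late.max() < 0.4 * h.y.max()

    def test_non_physical_shape_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            l.AifShape(shape=-1.0)
        with pytest.raises(ValueError, match="recirculation"):
            l.AifShape(recirc_fraction=0.7)


class TestMakeInputs:
    def test_portal_later_and_lower(self):
        ca, cpv = l.make_inputs(l.SubjectGroundTruth(), l.InjectionProtocol())
        assert cpv.y.max() < ca.y.max()
        assert ca.t[np.argmax(cpv.y)] > ca.t[np.argmax(ca.y)]

    def test_mass_conservation_through_dispersion(self):
        truth = l.SubjectGroundTruth()
        ca, cpv = l.make_inputs(truth, l.InjectionProtocol(), t_max=400.0)
        assert np.trapezoid(cpv.y, cpv.t) == pytest.approx(
            np.trapezoid(ca.y, ca.t), rel=0.01
        )

    def test_no_dispersion_gives_pure_delay(self):
        truth = replace(l.SubjectGroundTruth(), portal=l.PortalShape(delay=4.0, dispersion=0.0))
        ca, cpv = l.make_inputs(truth, l.InjectionProtocol())
        shifted = np.interp(ca.t - 4.0, ca.t, ca.y, left=0.0)
        np.testing.assert_allclose(cpv.y, shifted, atol=1e-12)

    def test_dose_linearity(self):
        p1 = l.InjectionProtocol()
        p2 = l.InjectionProtocol(main_dose_mmol_per_kg=0.1)  # double dose, same rate
        truth = l.SubjectGroundTruth()
        ca1, _ = l.make_inputs(truth, p1)
        ca2, _ = l.make_inputs(truth, p2)
        # double volume at the same rate: double area (peak grows slightly less)
        assert np.trapezoid(ca2.y, ca2.t) == pytest.approx(
            2 * np.trapezoid(ca1.y, ca1.t), rel=1e-6
        )


class TestGenerateSubject:
    def test_same_seed_bit_identical(self):
        a = l.generate_subject(l.SubjectGroundTruth(seed=42))
        b = l.generate_subject(l.SubjectGroundTruth(seed=42))
        for name in ("prebolus_si", "mainbolus_aorta_si", "portal_si", "liver_si"):
            np.testing.assert_array_equal(getattr(a, name).y, getattr(b, name).y)

    def test_different_seed_differs(self):
        a = l.generate_subject(l.SubjectGroundTruth(seed=1))
        b = l.generate_subject(l.SubjectGroundTruth(seed=2))
        assert not np.array_equal(a.prebolus_si.y, b.prebolus_si.y)

    def test_noise_free_conversion_round_trip(self, clean_subject, acq_pre):
        truth = clean_subject.truth
        relax = l.RelaxationParams(t10=truth.t10_blood, r1=truth.r1)
        conv = l.signal_to_concentration(clean_subject.prebolus_si, 25, acq_pre, relax)
        true_vals = clean_subject.true_prebolus_aorta_blood.resample(conv.series.t)
        err = np.max(np.abs(conv.series.y - true_vals.y))
        assert err <= 1e-6 * true_vals.y.max()

    def test_acquisition_grids_match_protocols(self, default_subject):
        s = default_subject
        assert s.prebolus_si.uniform_step() == pytest.approx(0.2)
        assert s.prebolus_si.duration == pytest.approx(60.0, abs=0.2)
        assert s.mainbolus_aorta_si.uniform_step() == pytest.approx(3.2)
        assert len(s.mainbolus_aorta_si) == 3 + 64

    def test_main_peak_in_saturating_regime(self, default_subject, acq_main, relax_blood):
        # the aortic peak must lie beyond the concentration at which the
        # SPGR slope has fallen to half its slope at zero
        def slope(c, h=1e-4):
            return (spgr_signal(c + h, 1.0, acq_main, relax_blood)
                    - spgr_signal(c - h, 1.0, acq_main, relax_blood)) / (2 * h)

        c = np.linspace(0.01, 20, 500)
        slopes = np.array([slope(x) for x in c])
        c_half = c[np.argmax(slopes < 0.5 * slope(1e-3))]
        assert default_subject.true_mainbolus_aorta_blood.y.max() > c_half


class TestGenerateCohort:
    def test_empty_cohort(self):
        subs, retests = l.generate_cohort(0, 1)
        assert subs == [] and retests == []

    def test_zero_variability_identical_truths(self):
        subs, _ = l.generate_cohort(3, 7, variability={})
        k = [s.truth.kinetic for s in subs]
        assert k[0].k1a == k[1].k1a == k[2].k1a
        assert subs[0].truth.seed != subs[1].truth.seed

    def test_cohort_mean_flow_near_default(self):
        subs, _ = l.generate_cohort(20, 11)
        fa = np.array([6000 * s.truth.kinetic.k1a for s in subs])
        default_fa = 6000 * l.SubjectGroundTruth().kinetic.k1a
        # log-normal with sd 0.3: mean = default * exp(0.3^2/2), sem = sd/sqrt(20)
        expected = default_fa * np.exp(0.3**2 / 2)
        assert abs(fa.mean() - expected) <= 3 * fa.std(ddof=1) / np.sqrt(20)

    def test_retest_shares_truth_new_noise(self):
        subs, retests = l.generate_cohort(2, 5, retest=True)
        assert subs[0].truth.kinetic == retests[0].truth.kinetic
        assert subs[0].truth.seed + 10**6 == retests[0].truth.seed
        assert not np.array_equal(subs[0].prebolus_si.y, retests[0].prebolus_si.y)
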