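from dataclasses import replace

import numpy as np
import pytest

import liverdce as l


@pytest.fixture(scope="session")
def acq_pre():
    return l.default_prebolus_acquisition()


@pytest.fixture(scope="session")
def acq_main():
    return l.default_mainbolus_acquisition()


@pytest.fixture(scope="session")
def relax_blood():
    return l.RelaxationParams(t10=1.2, r1=6.3)


@pytest.fixture(scope="session")
def protocol():
    return l.InjectionProtocol()


@pytest.fixture(scope="session")
def default_subject():
    """One default synthetic subject (seed 0), shared across tests."""
    return l.generate_subject(l.SubjectGroundTruth())


@pytest.fixture(scope="session")
def clean_subject():
    """Default subject with noise and inflow oscillations switched off."""
    truth = replace(l.SubjectGroundTruth(), noise_sd=0.0, inflow_amplitude=0.0)
    return l.generate_subject(truth)


def gamma_curve(t, amp=5.0, t0=8.0, alpha=3.0, beta=2.0):
    """Simple gamma-variate test bolus (peak = amp at t0 + alpha*beta)."""
    x = np.asarray(t, float) - t0
    y = np.zeros_like(x)
    p = x > 0
    y[p] = amp * (x[p] / (alpha * beta)) ** alpha * np.exp(alpha - x[p] / beta)
    return y


@pytest.fixture(scope="session")
def measure_subject(acq_pre, acq_main):
    """Closure running the measurement chain of the pipeline on a subject."""

    def _measure(sub):
        t = sub.truth
        rb = l.RelaxationParams(t10=t.t10_blood, r1=t.r1)
        rl = l.RelaxationParams(t10=t.t10_liver, r1=t.r1)
        pre = l.signal_to_concentration(sub.prebolus_si, 25, acq_pre, rb).series
        aif_pre = l.reconstruct_aif(l.blood_to_plasma(pre, t.hematocrit), sub.protocol)
        aif_main = l.blood_to_plasma(
            l.signal_to_concentration(sub.mainbolus_aorta_si, 3, acq_main, rb).series,
            t.hematocrit,
        )
        portal = l.blood_to_plasma(
            l.signal_to_concentration(sub.portal_si, 3, acq_main, rb).series,
            t.hematocrit,
        )
        liver = l.signal_to_concentration(sub.liver_si, 3, acq_main, rl).series
        return aif_pre, aif_main, portal, liver

    return _measure
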