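"""Fit the dual-input single-compartment liver model.

Runs the full measurement chain of one noiseless subject (signals ->
concentrations -> reconstructed AIF) and fits (k1a, k1p, k2, tau_a,
tau_p), then derives the seven clinical perfusion parameters.
"""

from dataclasses import replace

import liverdce as l

truth = replace(l.SubjectGroundTruth(), noise_sd=0.0, inflow_amplitude=0.0)
sub = l.generate_subject(truth)

rb = l.RelaxationParams(t10=truth.t10_blood, r1=truth.r1)
rl = l.RelaxationParams(t10=truth.t10_liver, r1=truth.r1)
acq_pre, acq_main = l.default_prebolus_acquisition(), l.default_mainbolus_acquisition()

pre = l.signal_to_concentration(sub.prebolus_si, 25, acq_pre, rb).series
aif = l.reconstruct_aif(l.blood_to_plasma(pre, truth.hematocrit), sub.protocol)
portal = l.blood_to_plasma(
    l.signal_to_concentration(sub.portal_si, 3, acq_main, rb).series, truth.hematocrit
)
liver = l.signal_to_concentration(sub.liver_si, 3, acq_main, rl).series

fit = l.fit_dual_input(aif, portal, liver, l.FitOptions(frame_average=3.2))

print(f"{'':8s} {'true':>8s} {'fitted':>8s}")
for name in ("k1a", "k1p", "k2", "tau_a", "tau_p"):
    print(f"{name:8s} {getattr(truth.kinetic, name):8.4f} {getattr(fit.params, name):8.4f}")
p = fit.perfusion
print(f"\nFa {p.fa:6.1f}  Fp {p.fp:6.1f}  Ft {p.ft:6.1f} mL/min/100mL")
print(f"ART {p.art:5.1f}%  PV {p.pv:5.1f}%  DV {p.dv:6.1f}%  MTT {p.mtt:5.1f} s")
print(f"sse {fit.sse:.2e}, converged={fit.converged}")
# With noiseless data the rates come back within ~2% and the delays land
# exactly on the 0.5 s search grid nodes of their true values.
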