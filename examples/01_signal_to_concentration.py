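"""Convert an MR signal-intensity curve to gadolinium concentration.

Builds a synthetic aortic signal with the 3D SPGR sequence settings,
inverts it back to concentration, and shows that the inversion is exact
while the raw signal badly under-represents the peak (the saturation
problem the pre-bolus technique works around).
"""

import numpy as np

import liverdce as l

# a first-pass-like concentration curve peaking at 6 mmol/L in blood
t = np.arange(0, 60, 0.5)
conc = 6.0 * np.exp(-0.5 * ((t - 18) / 4.0) ** 2)
conc[t < 8] = 0.0

acq = l.default_mainbolus_acquisition()          # SPGR, TR 2.96 ms, 12 deg
relax = l.RelaxationParams(t10=1.2, r1=6.3)      # blood T1 1.2 s

signal = l.spgr_signal(conc, 500.0, acq, relax)
series = l.TimeSeries(t, np.asarray(signal), "a.u.")

result = l.signal_to_concentration(series, n_baseline=5, acq=acq, relax=relax)
plasma = l.blood_to_plasma(result.series, hematocrit=0.42)

baseline = signal[:5].mean()
print(f"signal enhancement at peak : {signal.max() / baseline:6.2f} x baseline")
print(f"true blood peak            : {conc.max():6.2f} mmol/L")
print(f"recovered blood peak       : {result.series.y.max():6.2f} mmol/L")
print(f"plasma peak (Hct 0.42)     : {plasma.y.max():6.2f} mmol/L")
print(f"clamped/saturated samples  : {result.n_clamped}/{result.n_saturated}")
# The signal grew ~8x while concentration grew from 0 to 6 mmol/L: the
# SPGR response is deeply saturated at the peak, but inverting the signal
# equation still recovers the exact concentration of each sample.
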