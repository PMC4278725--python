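"""Measure AIF shape parameters and the main-bolus degradation.

For one default synthetic subject, measures Cpeak, TTP, upslope, AUC60
and FWHM of the reconstructed pre-bolus AIF and of the AIF measured
directly from the main-bolus acquisition (3.2 s resolution, saturating
SPGR signal).
"""

import liverdce as l

sub = l.generate_subject(l.SubjectGroundTruth(seed=1))
truth = sub.truth

rb = l.RelaxationParams(t10=truth.t10_blood, r1=truth.r1)
pre = l.signal_to_concentration(
    sub.prebolus_si, 25, l.default_prebolus_acquisition(), rb
).series
aif_pre = l.reconstruct_aif(l.blood_to_plasma(pre, truth.hematocrit), sub.protocol)
aif_main = l.blood_to_plasma(
    l.signal_to_concentration(
        sub.mainbolus_aorta_si, 3, l.default_mainbolus_acquisition(), rb
    ).series,
    truth.hematocrit,
)

print(f"{'parameter':10s} {'pre-bolus':>10s} {'main bolus':>10s}")
for label, series, nb in (("pre", aif_pre, 25), ("main", aif_main, 3)):
    trise = l.detect_trise(series, nb, k_sd=3.0)
    p = l.shape_parameters(series, trise)
    if label == "pre":
        pre_p = p
    else:
        for name, unit in (("cpeak", "mmol/L"), ("ttp", "s"), ("upslope", "mmol/(L*s)"),
                           ("auc60", "mmol*s/L"), ("fwhm", "s")):
            print(f"{name:10s} {getattr(pre_p, name):10.2f} {getattr(p, name):10.2f}  {unit}")
# The pre-bolus AIF keeps the sharp, high first-pass peak; the main-bolus
# AIF loses peak height and gains width to the 3.2 s temporal footprint
# and the saturating signal response.
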