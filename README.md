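# liverdce

Quantitative liver perfusion from dynamic contrast-enhanced (DCE) MRI,
built around a dual-bolus acquisition: a low-dose **pre-bolus** test
injection imaged at high temporal resolution (0.2 s) is used to
reconstruct the arterial input function (AIF) of the subsequent full-dose
**main bolus**, whose own aortic signal is degraded by coarse temporal
sampling (3.2 s) and by saturation of the spoiled-gradient-echo signal at
first-pass gadolinium concentrations.

The package is for researchers analysing ROI-averaged abdominal DCE-MRI
curves who want the complete, tested quantification chain:

1. **Signal models** — SPGR: `S = M0 sin α (1−E1)/(1−E1 cos α)` with
   `E1 = exp(−TR/T1)`, and saturation-recovery TurboFLASH:
   `S = M0 (1−exp(−TS/T1))`, where `1/T1(C) = 1/T10 + r1·C`.
   Signal → concentration inversion by bracketed root finding, with M0
   calibrated from pre-contrast baseline samples; plasma correction
   `C_p = C_b/(1−Hct)`.
2. **AIF reconstruction** — under a linear time-invariant assumption the
   full-dose AIF is a sum of scaled, time-shifted copies of the pre-bolus
   response: `C_a(t) = (r_m/r_p) Σ_k w_k C_p(t − k·T_p)`, with a
   fractional last copy when `T_m/T_p` is not an integer.
3. **Shape metrics** — Cpeak, TTP, upslope = Cpeak/TTP, AUC60, FWHM of
   the first-pass peak, with a baseline-threshold arrival detector.
4. **Kinetic model** — the dual-input single-compartment liver model
   `dC_L/dt = k1a C_a(t−τ_a) + k1p C_p(t−τ_p) − k2 C_L`, solved by
   exponential-kernel convolution and fitted by an exhaustive delay-grid
   search with bounded nonlinear least squares; derived parameters
   Fa = 6000·k1a, Fp = 6000·k1p, Ft = Fa+Fp, ART = 100·Fa/Ft,
   PV = 100·Fp/Ft, DV = 100·(k1a+k1p)/k2, MTT = 1/k2.
5. **Reproducibility statistics** — pair coefficients of variation
   (CV = 100·(|x−y|/√2)/mean) and Bland–Altman 95% limits of agreement.
6. **Synthetic subjects** — a generator producing ground-truth cohorts
   with realistic bolus morphology, portal delay/dispersion, compartmental
   liver uptake, sequence-accurate signal saturation, temporal-footprint
   averaging, noise and inflow oscillations, so every stage is testable
   without patient data.

## Worked example

`examples/04_kinetic_fit.py` simulates one noiseless subject, runs the
full chain (signals → concentrations → reconstructed AIF → fit) and
prints:

```
             true   fitted
k1a        0.0090   0.0090
k1p        0.0700   0.0708
k2         0.0500   0.0504
tau_a      2.0000   2.0000
tau_p      4.0000   4.0000

Fa   54.1  Fp  425.1  Ft  479.2 mL/min/100mL
ART  11.3%  PV  88.7%  DV  158.4%  MTT  19.8 s
```

The rates (1/s) return within ~1–2% and the delays (s) land exactly on
the 0.5 s search grid; Fa/Fp/Ft are hepatic arterial/portal/total flows,
ART/PV the arterial and portal fractions, DV the tracer distribution
volume, MTT the mean transit time. `examples/02_reconstruct_aif.py`
shows the reconstruction itself: a 1.5 mmol/L pre-bolus plasma response
scales to the 8.1 mmol/L full-dose AIF with a maximum error of 0.25% of
the peak. The other examples cover signal conversion, shape metrics and
the cohort-level comparison study.

A config-driven CLI wraps the same library calls:

```sh
liverdce run-all --config cfg.yaml --out results/
liverdce simulate | convert | reconstruct | metrics | fit | report ...
```

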