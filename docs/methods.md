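# Methods

## The measurement problem

Liver perfusion quantification from DCE-MRI needs the arterial input
function (AIF) — the plasma gadolinium concentration in a feeding artery —
at the temporal resolution of the first-pass bolus (seconds) and without
amplitude distortion. A full-dose bolus measured with a 3D abdominal
acquisition fails on both counts: the dynamic frame time (3.2 s here)
under-samples and time-averages the sharp peak, and the spoiled
gradient-echo (SPGR) signal is strongly sublinear at first-pass blood
concentrations (several mmol/L), so the peak region carries little signal
gradient per unit concentration. The dual-bolus strategy sidesteps both:
a small pre-bolus (1.3 mL at 4.1 mL/s) is imaged with a 2D
saturation-recovery TurboFLASH at 0.2 s resolution, where concentrations
stay in the near-linear regime, and the full-dose AIF is reconstructed
from that response.

## Signal models and inversion

SPGR (main bolus): `S = M0 sin α (1−E1)/(1−E1 cos α)`, `E1 = exp(−TR/T1)`.
Saturation-recovery (pre-bolus): `S = M0 (1−exp(−TS/T1))`, modelled as an
ideal saturation recovery at the k-space centre (no readout-pulse
correction; a stated simplification). Gadolinium acts through
`1/T1(C) = 1/T10 + r1·C`.

Sequence settings default to the acquisition protocol: TR 2.3/2.96 ms,
TE 0.91/0.95 ms, flip 12°, TS 120 ms, pre-contrast blood T1 1.2 s. The
T2*/TE decay factor is treated as constant (TE ≈ 1 ms) and cancels in the
baseline-normalised inversion; this also means the package's simulated
main-bolus degradation is milder than what T2*-contaminated patient data
show. The relaxivity of the agent is configurable, default
r1 = 6.3 L/(mmol·s) (gadobenate dimeglumine at 1.5 T); every numerical
property of the chain holds for r1 anywhere in [3, 8].

Inversion calibrates M0 from the mean of the pre-contrast samples
(3 samples for the main bolus — its three pre-contrast volumes; 25 for
the pre-bolus) and solves `forward(C) = S` per sample with Brent
bracketed root finding on [0, 50] mmol/L. Both forward maps are strictly
increasing, so the root is unique; the solver is run essentially to
machine precision (signal residual ≲ 1e−13, far inside the 1e−12
budget). Samples below baseline invert to 0 and are counted; samples
above the model's value at the bracket top are clamped there and flagged
as saturated. One caveat is intrinsic: at the saturation-recovery
asymptote (TS·R1 ≳ 19, i.e. ~19 mmol/L at r1 = 8) a 1e−9 relative
concentration change moves the float64 signal by less than one ulp, so
no inverse can resolve concentration to 1e−9 there; the acceptance test
asserts the round trip wherever the forward map's conditioning supports
it and the signal-domain residual everywhere.

## AIF reconstruction

Treating injection → aortic concentration as linear and time-invariant,
the response to the main injection (rate r_m, duration T_m = dose/rate)
is synthesised from the pre-bolus response C_p (rate r_p, duration T_p):

    C_a(t) = (r_m/r_p) · Σ_{k=0}^{n−1} w_k · C_p(t − k·T_p),  n = ⌈T_m/T_p⌉

with w_k = 1 except a fractional last copy w_{n−1} = frac(T_m/T_p), which
preserves the delivered dose exactly; a config switch selects integer
rounding instead. Shifted copies are evaluated by linear interpolation on
the 0.2 s grid (shift error is bounded by the tests at ≲0.3% of peak),
zero before t = 0. The output keeps the input's grid and 60 s span — no
tail is extrapolated. The summation also averages out the inflow
oscillations of the 2D pre-bolus acquisition.

## Shape metrics

Arrival (Trise) is the first crossing of baseline mean + k_sd·SD
(default k_sd = 3, estimated from the pre-contrast samples) that persists
for ≥2 consecutive samples — the persistence rule rejects single-sample
noise spikes at 0.2 s resolution — refined by linear interpolation to the
threshold. Then Cpeak = max (earliest sample on ties, for determinism),
TTP = Tpeak − Trise, upslope = Cpeak/TTP (flagged undefined when
TTP = 0), AUC60 = trapezoidal integral over [Trise, Trise+60 s]
(integrated to the series end and flagged truncated when the curve stops
early — always the case for the 60 s pre-bolus series, by ~Trise
seconds of near-zero tail), and FWHM from the half-maximum crossings
adjacent to the peak (so a recirculation bump above half-max cannot
extend it), censored at a series edge when a crossing does not exist.

## Kinetic model and fitting

The liver is one well-mixed compartment with dual supply:

    dC_L/dt = k1a·C_a(t−τ_a) + k1p·C_p(t−τ_p) − k2·C_L(t)

solved as an exponential-kernel convolution on an internal uniform grid
(step = min input step, capped at 0.2 s) with the exponentially weighted
trapezoidal recursion `C[i] = E·C[i−1] + dt/2·(u[i] + E·u[i−1])`,
`E = exp(−k2·dt)` — second-order accurate and unconditionally stable;
against an independent stiff ODE integration it agrees to better than
1e−4 of the peak.

Delays enter non-smoothly, so fitting is an exhaustive grid search over
(τ_a, τ_p) ∈ {0, 0.5, …, 10} × {0, 0.5, …, 15} s with a bounded
trust-region least-squares solve of (k1a, k1p, k2) at each node
(bounds k1a, k1p ∈ [0, 0.2] /s, k2 ∈ [1e−4, 1] /s, fixed initialisation
(0.005, 0.03, 0.05), tolerances 1e−10, ≤500 evaluations per node); the
smallest SSE wins and ties break to the lexicographically smallest
delays, so the fit is deterministic. A channel whose input is
identically zero is pinned to its lower bound rather than left at the
initial guess. The residual runs over the liver samples inside the time
span common to all three curves: pre-bolus-derived AIFs cover 60 s, so
those fits use the first ~19 liver frames, while main-bolus fits use the
full series — the realistic asymmetry of the dual-bolus design.

Two numerical choices matter at the 3.2 s frame rate. First, inputs
sampled at the frame rate are upsampled to the internal grid with
shape-preserving PCHIP rather than linear chords: chords through 3.2 s
portal samples alone bias k1a by ~6%. Second, each dynamic frame is a
~3.2 s time average of the signal, so an optional observation-model
option (`FitOptions.frame_average`, used by the pipeline) degrades
high-resolution inputs (the reconstructed AIF) to the same temporal
footprint; frame-rate inputs already carry it. With both, the full
noiseless chain recovers all three rates within ~1.7% and on-grid delays
exactly.

Identifiability has a hard floor: the arterial channel is a small
fraction of the inflow and nearly collinear with the portal channel once
the delays are free. At Gaussian noise of 2% of the liver peak the
Cramér–Rao bound for k1a is ≈18% (relative) for 67 frames at 3.2 s, so
median k1a errors around 12–13% are the attainable optimum of this
measurement design, not an estimator deficiency; k1p and k2 are
recovered with ~2–3% median error under the same noise.

Rates convert to clinical parameters by 60 s/min × 100 mL/100 mL:
Fa = 6000·k1a, Fp = 6000·k1p, Ft = Fa+Fp, ART = 100·Fa/Ft,
PV = 100·Fp/Ft, DV = 100·(k1a+k1p)/k2, MTT = 1/k2. ART/PV are flagged
undefined (NaN) when Ft = 0. Hematocrit correction is applied to the
aortic and portal inputs only; the liver curve stays tissue
concentration (configurable).

## Reproducibility statistics

For a measurement pair the CV uses the sample-SD-of-a-pair convention
standard in test-retest imaging, CV = 100·(|x−y|/√2)/mean — the paper-
style alternative |x−y|/mean differs by √2 and is a config choice.
Bland–Altman agreement uses per-subject differences in percent of the
pair mean (absolute mode available): bias = mean(d), limits of agreement
= bias ± 1.96·SD(d) with the n−1 sample SD. Pairs with non-positive
means are excluded and counted. Paired Wilcoxon p-values are reported
alongside the agreement tables as a routine delegated statistic.

## Synthetic subjects

The generator stands in for the patient cohort; its defaults are the
study conditions of every cohort-level test.

* **Aortic impulse response**: gamma-variate
  `(x/αθ)^α exp(α − x/θ)` (peak at arrival + α·θ) with α = 3.0,
  θ = 2.3 s, arrival 8 s, plus a recirculation bump (fraction 0.25 of
  the first pass, dispersed with an 8 s exponential kernel, delayed
  12 s). Amplitude 1.35 (mmol/L)/mmol of injected dose. Convolved with
  each injection's rectangular dose-rate profile these defaults put the
  full-dose plasma AIF at Cpeak ≈ 8 mmol/L, TTP ≈ 8 s, FWHM ≈ 9 s,
  AUC60 ≈ 100 mmol·s/L — the middle of the reported patient range — and
  the main-bolus blood peak (~4.7 mmol/L) far beyond the concentration
  where the SPGR slope has halved, so the saturation phenomenon is
  genuinely present.
* **Portal input**: the aortic curve delayed 4 s and dispersed with a 6 s
  exponential kernel (splanchnic transit); mass-conserving.
* **Liver**: the compartment model with defaults k1a = 0.009,
  k1p = 0.07, k2 = 0.05 /s, τ_a = 2 s, τ_p = 4 s (flows within the
  reported cohort range; note the reported cohort *means* of flow, MTT
  and DV are mutually inconsistent because means of ratios are not
  ratios of means — these defaults reproduce the flow and MTT scale and
  give DV ≈ 158%).
* **Acquisition**: pre-bolus sampled at 0.2 s for 60 s through the
  saturation-recovery model, multiplied by an inflow oscillation
  (1 + a·sin(2πt/T), a = 0.03, T = 1 s, the cardiac-cycle artifact of 2D
  aortic imaging); main bolus through the SPGR model, averaged over each
  3.2 s frame (the temporal footprint of the 3D acquisition) and sampled
  as 3 pre-contrast + 64 dynamic volumes.
* **Noise**: additive Gaussian, SD = 0.5% of the pre-contrast baseline
  signal on every sample — the high-SNR regime of ROI-averaged curves
  (hundreds of voxels); Gaussian rather than Rician for the same reason.
  Noise interacts strongly with the 3-sample M0 calibration of the main
  bolus: near saturation a ±1% M0 error maps to roughly ∓8% peak
  concentration, which is the dominant main-bolus variance source and
  the mechanism behind its poorer test-retest reproducibility.
* **Seeding**: subject seed = master seed + index; retest replicates
  share the truth with a +10^6 seed offset. Same seed ⇒ bit-identical
  subjects.
* **Cohorts**: per-subject truths drawn log-normally around the defaults
  (rate CVs 0.3, shape/timing CVs 0.1–0.25, hematocrit 0.08, clipped to
  physical ranges). For noiseless parameter-recovery studies the true
  delays are quantised to the fit's 0.5 s delay grid
  (`generate_cohort(snap_delays=0.5)`): with off-grid delays the grid
  search itself biases k1a by ~10%+, which would measure the grid, not
  the chain.

### What the generator does not emulate

T2* decay (the dominant real-world main-bolus peak destroyer), B1 and
flip-angle errors, partial-volume and inflow effects on the 3D
acquisition, respiratory motion, and the slow equilibrium tail of real
AIFs. Consequently the simulated main-bolus AIF degradation (peak deficit
~5–10%, AUC60 deficit ~2–5%) is much milder than the patient-data
contrast, and passing the directional cohort tests here demonstrates the
pipeline's sensitivity to the temporal-footprint + saturation mechanism,
not the full clinical effect size.

## Degenerate inputs and edge behaviour

Non-finite inputs are rejected naming the offending field; hematocrit ≥ 1,
zero injection rates, non-uniform reconstruction grids and empty resample
targets are errors. A main injection shorter than the pre-bolus is
handled as a single dose-scaled copy. All-zero curves raise a "no bolus
detected" error in arrival detection. Pipeline subjects that fail any
stage are quarantined with the reason; the run aborts only if every
subject fails. Fixed seeds make `run-all` byte-identical across runs.

## Problem sizes

Cohort-level checks use 20 subjects (plus 20 retest replicates);
parameter-recovery checks use 5 noiseless subjects and 20 noisy
replicates; the agreement pipeline example uses 10 subjects with both
AIF variants fitted. These sizes put Monte-Carlo error comfortably below
the asserted margins while keeping any single study to minutes on one
CPU.
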