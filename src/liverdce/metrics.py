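"""Bolus shape descriptors of a concentration-time curve.

Five parameters characterise an arterial input function: peak
concentration ``Cpeak``, time to peak ``TTP = Tpeak - Trise``, upslope
``Cpeak / TTP``, the 60-second area under the curve from bolus arrival
``AUC60``, and the full width at half maximum of the first-pass peak
``FWHM``.  ``Trise`` (bolus arrival) is the first threshold crossing above
the pre-contrast baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import TimeSeries

__all__ = ["ShapeParams", "NoBolusError", "detect_trise", "shape_parameters"]


class NoBolusError(ValueError):
    """The curve never rises above the baseline threshold."""


@dataclass
class ShapeParams:
    """The five AIF shape parameters plus the timing anchors.

    Flags record degenerate situations instead of propagating infinities:
    ``upslope`` is NaN when TTP = 0; ``auc60`` is integrated only to the
    series end (and flagged) when the curve stops before Trise + 60 s;
    ``fwhm`` is censored at a series edge when the curve never drops below
    half maximum on that side of the peak.
    """

    cpeak: float          # mmol/L
    tpeak: float          # s
    trise: float          # s
    ttp: float            # s
    upslope: float        # mmol/(L*s), NaN when undefined
    auc60: float          # mmol*s/L
    fwhm: float           # s
    upslope_defined: bool = True
    auc60_truncated: bool = False
    fwhm_left_censored: bool = False
    fwhm_right_censored: bool = False


def detect_trise(series: TimeSeries, n_baseline: int, k_sd: float = 3.0) -> float:
    """Bolus arrival time: first sustained crossing of the baseline threshold.

    The threshold is ``mean + k_sd * sd`` of the first ``n_baseline``
    samples.  The crossing must persist for at least 2 consecutive samples
    (rejects single-sample noise spikes); the reported time is linearly
    interpolated between the last sub-threshold and first supra-threshold
    sample.
    """
    if n_baseline < 1 or n_baseline >= len(series):
        raise ValueError("n_baseline must be in [1, len(series))")
    base = series.y[:n_baseline]
    sd = float(np.std(base, ddof=1)) if n_baseline >= 2 else 0.0
    thr = float(np.mean(base)) + k_sd * sd

    y, t = series.y, series.t
    above = y > thr
    for i in range(n_baseline, len(y) - 1):
        if above[i] and above[i + 1]:
            if y[i - 1] < thr:
                # refine by interpolating the segment crossing the threshold
                f = (thr - y[i - 1]) / (y[i] - y[i - 1])
                return float(t[i - 1] + f * (t[i] - t[i - 1]))
            return float(t[i])
    raise NoBolusError("no bolus detected")


def _cross_time(t0, y0, t1, y1, level) -> float:
    """Time where the segment (t0,y0)-(t1,y1) crosses ``level``."""
    if y1 == y0:
        return float(t0)
    return float(t0 + (level - y0) / (y1 - y0) * (t1 - t0))


def shape_parameters(series: TimeSeries, trise: float, window: float = 60.0) -> ShapeParams:
    """Compute the five shape parameters given the arrival time ``trise``."""
    t, y = series.t, series.y
    i_peak = int(np.argmax(y))          # earliest index on ties
    cpeak = float(y[i_peak])
    tpeak = float(t[i_peak])
    ttp = tpeak - trise

    upslope_defined = ttp > 0
    upslope = cpeak / ttp if upslope_defined else float("nan")

    # --- AUC60: trapezoidal integral over [trise, trise + window] -------
    t_end = trise + window
    truncated = t[-1] < t_end
    if truncated:
        t_end = float(t[-1])
    mask = (t > trise) & (t < t_end)
    tt = np.concatenate(([trise], t[mask], [t_end]))
    yy = np.concatenate(
        ([np.interp(trise, t, y)], y[mask], [np.interp(t_end, t, y)])
    )
    auc60 = float(np.trapezoid(yy, tt))

    # --- FWHM of the first-pass peak ------------------------------------
    half = cpeak / 2.0
    left_censored = right_censored = False
    j = i_peak
    while j > 0 and y[j - 1] >= half:
        j -= 1
    if j == 0:
        t_before = float(t[0])
        left_censored = True
    else:
        t_before = _cross_time(t[j - 1], y[j - 1], t[j], y[j], half)
    j = i_peak
    while j < len(y) - 1 and y[j + 1] >= half:
        j += 1
    if j == len(y) - 1:
        t_after = float(t[-1])
        right_censored = True
    else:
        t_after = _cross_time(t[j], y[j], t[j + 1], y[j + 1], half)
    fwhm = t_after - t_before

    return ShapeParams(
        cpeak=cpeak,
        tpeak=tpeak,
        trise=trise,
        ttp=ttp,
        upslope=upslope,
        auc60=auc60,
        fwhm=fwhm,
        upslope_defined=upslope_defined,
        auc60_truncated=truncated,
        fwhm_left_censored=left_censored,
        fwhm_right_censored=right_censored,
    )
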