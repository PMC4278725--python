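"""MR signal models and signal-to-concentration inversion.

Two forward models are supported:

* spoiled gradient echo (SPGR / FLASH), used for the main-bolus 3D
  acquisition::

      S = M0 * sin(a) * (1 - E1) / (1 - E1 * cos(a)),   E1 = exp(-TR / T1)

* saturation-recovery TurboFLASH, used for the high-temporal-resolution
  pre-bolus acquisition, modelled as an ideal saturation recovery at the
  centre of k-space::

      S = M0 * (1 - exp(-TS / T1))

In both, gadolinium shortens T1 through the longitudinal relaxivity r1::

      1 / T1(C) = 1 / T10 + r1 * C

The inversion calibrates M0 from pre-contrast baseline samples and solves
the forward model for C sample by sample with bracketed root finding, so
one code path serves both sequence kinds.  T2'/TE decay is neglected: with
TE around 1 ms the exp(-TE/T2*) factor is ~1 and cancels in the
baseline-normalised inversion anyway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .timeseries import TimeSeries

__all__ = [
    "AcquisitionParams",
    "RelaxationParams",
    "ConversionResult",
    "spgr_signal",
    "sat_recovery_signal",
    "forward_signal",
    "signal_to_concentration",
    "blood_to_plasma",
]

SEQUENCE_KINDS = ("spgr", "sat_recovery")


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"non-finite value in field '{name}'")
    return value


@dataclass(frozen=True)
class AcquisitionParams:
    """Sequence timing of one acquisition.

    ``recovery_time`` (TS) is the delay between the saturation pulse and
    the k-space centre; it is required for (and only meaningful for) the
    saturation-recovery kind.
    """

    sequence_kind: str
    tr: float                     # repetition time [s]
    te: float                     # echo time [s] (kept for provenance; decay neglected)
    flip_angle_deg: float
    recovery_time: float | None = None   # TS [s], sat_recovery only

    def __post_init__(self) -> None:
        if self.sequence_kind not in SEQUENCE_KINDS:
            raise ValueError(
                f"sequence_kind must be one of {SEQUENCE_KINDS}, got {self.sequence_kind!r}"
            )
        _check_finite("tr", self.tr)
        _check_finite("te", self.te)
        _check_finite("flip_angle_deg", self.flip_angle_deg)
        if self.tr <= 0:
            raise ValueError("TR must be > 0")
        if not (0 < self.flip_angle_deg <= 90):
            raise ValueError("flip angle must be in (0, 90] degrees")
        if self.sequence_kind == "sat_recovery":
            if self.recovery_time is None:
                raise ValueError("recovery_time (TS) required for sat_recovery")
            _check_finite("recovery_time", self.recovery_time)
            if self.recovery_time <= 0:
                raise ValueError("recovery_time (TS) must be > 0")


@dataclass(frozen=True)
class RelaxationParams:
    """Pre-contrast T1 and contrast-agent relaxivity.

    ``t10`` is the tissue/blood longitudinal relaxation time before
    contrast arrival (1.2 s for blood at 1.5 T); ``r1`` the longitudinal
    relaxivity of the agent in L/(mmol*s).
    """

    t10: float
    r1: float = 6.3

    def __post_init__(self) -> None:
        _check_finite("t10", self.t10)
        _check_finite("r1", self.r1)
        if self.t10 <= 0:
            raise ValueError("T10 must be > 0")
        if self.r1 <= 0:
            raise ValueError("r1 must be > 0")

    def t1_of_conc(self, conc):
        """T1 shortened by gadolinium: 1/T1 = 1/T10 + r1*C."""
        return 1.0 / (1.0 / self.t10 + self.r1 * np.asarray(conc, dtype=float))


def spgr_signal(conc, m0: float, acq: AcquisitionParams, relax: RelaxationParams):
    """Steady-state spoiled gradient echo signal for concentration ``conc``."""
    conc = np.asarray(conc, dtype=float)
    if not np.all(np.isfinite(conc)):
        raise ValueError("non-finite value in field 'conc'")
    _check_finite("m0", m0)
    alpha = math.radians(acq.flip_angle_deg)
    e1 = np.exp(-acq.tr / relax.t1_of_conc(conc))
    return m0 * math.sin(alpha) * (1.0 - e1) / (1.0 - e1 * math.cos(alpha))


def sat_recovery_signal(conc, m0: float, acq: AcquisitionParams, relax: RelaxationParams):
    """Ideal saturation-recovery signal after recovery time TS."""
    if acq.sequence_kind != "sat_recovery":
        raise ValueError("sat_recovery_signal requires sequence_kind='sat_recovery'")
    conc = np.asarray(conc, dtype=float)
    if not np.all(np.isfinite(conc)):
        raise ValueError("non-finite value in field 'conc'")
    _check_finite("m0", m0)
    return m0 * (1.0 - np.exp(-acq.recovery_time / relax.t1_of_conc(conc)))


def forward_signal(conc, m0: float, acq: AcquisitionParams, relax: RelaxationParams):
    """Dispatch to the forward model matching ``acq.sequence_kind``."""
    if acq.sequence_kind == "spgr":
        return spgr_signal(conc, m0, acq, relax)
    return sat_recovery_signal(conc, m0, acq, relax)


@dataclass
class ConversionResult:
    """Outcome of a signal-to-concentration inversion.

    ``n_clamped``: samples whose inverted concentration was negative
    (noise below baseline) and were clamped to 0.  ``n_saturated``:
    samples above the forward model's value at ``conc_max``, set to
    ``conc_max`` and flagged.
    """

    series: TimeSeries
    m0: float
    n_clamped: int = 0
    n_saturated: int = 0


def signal_to_concentration(
    series: TimeSeries,
    n_baseline: int,
    acq: AcquisitionParams,
    relax: RelaxationParams,
    conc_max: float = 50.0,
) -> ConversionResult:
    """Invert a signal-intensity series to gadolinium concentration.

    M0 is calibrated so the forward model at C=0 reproduces the mean of
    the first ``n_baseline`` (pre-contrast) samples.  Each sample is then
    inverted with bracketed root finding on [0, conc_max]; the forward
    models are strictly increasing in C so the root is unique.
    """
    if n_baseline < 1:
        raise ValueError("n_baseline must be >= 1")
    if n_baseline > len(series):
        raise ValueError("n_baseline exceeds series length")
    baseline = float(np.mean(series.y[:n_baseline]))
    if baseline <= 0:
        raise ValueError("baseline mean must be > 0")
    unit0 = float(forward_signal(0.0, 1.0, acq, relax))
    m0 = baseline / unit0
    s_max = float(forward_signal(conc_max, m0, acq, relax))

    conc = np.empty_like(series.y)
    n_clamped = 0
    n_saturated = 0
    for i, s in enumerate(series.y):
        if s <= baseline:
            conc[i] = 0.0
            if s < baseline:
                n_clamped += 1
            continue
        if s >= s_max:
            conc[i] = conc_max
            n_saturated += 1
            continue
        conc[i] = brentq(
            lambda c: forward_signal(c, m0, acq, relax) - s,
            0.0,
            conc_max,
            xtol=1e-14,
            rtol=8.9e-16,
        )
    out = series.copy(y=conc, y_units="mmol/L")
    return ConversionResult(series=out, m0=m0, n_clamped=n_clamped, n_saturated=n_saturated)


def blood_to_plasma(series: TimeSeries, hematocrit: float) -> TimeSeries:
    """Convert whole-blood to plasma concentration: C_p = C_b / (1 - Hct)."""
    hematocrit = _check_finite("hematocrit", hematocrit)
    if not (0 <= hematocrit < 1):
        raise ValueError("hematocrit must be in [0, 1)")
    return series.copy(y=series.y / (1.0 - hematocrit))
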