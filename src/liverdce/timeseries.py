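"""Sampled time–value curves: the universal currency of the pipeline.

Every stage of the quantification chain (signal conversion, AIF
reconstruction, shape metrics, kinetic fitting) consumes and produces
:class:`TimeSeries` objects — a time axis in seconds paired with values in
either arbitrary signal units (``a.u.``) or gadolinium concentration
(``mmol/L``).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSeries",
    "read_timeseries",
    "write_timeseries",
    "boxcar_average",
]

#: exact header required by the on-disk CSV dialect
CSV_HEADER = ("time_s", "value")


@dataclass
class TimeSeries:
    """A sampled curve ``y(t)`` with a strictly increasing time axis.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, strictly increasing, length >= 2.
    y : array of float
        Sample values, same length as ``t``.
    y_units : str
        ``"a.u."`` for raw MR signal intensity, ``"mmol/L"`` for
        gadolinium concentration.
    """

    t: np.ndarray
    y: np.ndarray
    y_units: str = "a.u."

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.y.ndim != 1:
            raise ValueError("time and value arrays must be one-dimensional")
        if len(self.t) != len(self.y):
            raise ValueError(
                f"length mismatch: {len(self.t)} times vs {len(self.y)} values"
            )
        if len(self.t) < 2:
            raise ValueError("a time series needs at least 2 samples")
        if not np.all(np.isfinite(self.t)):
            raise ValueError("non-finite value in field 't'")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite value in field 'y'")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time axis must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    # -- grid helpers -----------------------------------------------------

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def min_step(self) -> float:
        return float(np.min(np.diff(self.t)))

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        """True if sampled on a uniform grid (relative step tolerance)."""
        dt = np.diff(self.t)
        return bool(np.all(np.abs(dt - dt[0]) <= rtol * dt[0]))

    def uniform_step(self, rtol: float = 1e-6) -> float:
        if not self.is_uniform(rtol):
            raise ValueError("time series is not uniformly sampled")
        return float(self.t[1] - self.t[0])

    # -- operations -------------------------------------------------------

    def resample(
        self, new_times: np.ndarray, extrapolate_zero_left: bool = False
    ) -> "TimeSeries":
        """Linearly interpolate onto ``new_times``.

        Values at original sample points are preserved exactly.  Times
        before the first sample are allowed only with
        ``extrapolate_zero_left=True`` (pre-arrival region, filled with 0);
        times past the last sample are rejected.
        """
        new_times = np.asarray(new_times, dtype=float)
        if new_times.size == 0:
            raise ValueError("resample target grid is empty")
        if new_times[-1] > self.t[-1] + 1e-12:
            raise ValueError(
                f"resample target extends past series end "
                f"({new_times[-1]:g} > {self.t[-1]:g} s)"
            )
        if new_times[0] < self.t[0] - 1e-12 and not extrapolate_zero_left:
            raise ValueError(
                "resample target precedes series start; pass "
                "extrapolate_zero_left=True for the pre-arrival region"
            )
        y_new = np.interp(new_times, self.t, self.y, left=0.0 if extrapolate_zero_left else self.y[0])
        return TimeSeries(new_times.copy(), y_new, self.y_units)

    def shifted_values(self, delay: float) -> np.ndarray:
        """Values of the delayed curve ``y(t - delay)`` on the own grid.

        The curve is taken to be 0 before its first sample (causal input).
        """
        return np.interp(self.t - delay, self.t, self.y, left=0.0)

    def copy(self, y: np.ndarray | None = None, y_units: str | None = None) -> "TimeSeries":
        return TimeSeries(
            self.t.copy(),
            self.y.copy() if y is None else np.asarray(y, dtype=float),
            self.y_units if y_units is None else y_units,
        )


def read_timeseries(path) -> TimeSeries:
    """Read the two-column CSV dialect (header ``time_s,value``)."""
    with open(path, "r", newline="") as fh:
        return _read_timeseries_file(fh, str(path))


def _read_timeseries_file(fh, name: str) -> TimeSeries:
    reader = csv.reader(fh)
    try:
        header = next(reader)
    except StopIteration:
        raise ValueError(f"{name}: empty file, expected header 'time_s,value'")
    if [h.strip() for h in header] != list(CSV_HEADER):
        raise ValueError(
            f"{name}: bad header {header!r}, expected 'time_s,value'"
        )
    t, y = [], []
    for lineno, row in enumerate(reader, start=2):
        if not row:
            continue
        if len(row) != 2:
            raise ValueError(f"{name}: line {lineno}: expected 2 fields, got {len(row)}")
        try:
            t.append(float(row[0]))
            y.append(float(row[1]))
        except ValueError:
            raise ValueError(f"{name}: line {lineno}: non-numeric row {row!r}")
    return TimeSeries(np.array(t), np.array(y))


def write_timeseries(series: TimeSeries, path) -> None:
    """Write the CSV dialect; round-trips :func:`read_timeseries` exactly.

    Values are written with ``repr``, the shortest string that restores the
    float64 bit pattern, so a write/read cycle is lossless.
    """
    with open(path, "w", newline="") as fh:
        fh.write("time_s,value\n")
        for ti, yi in zip(series.t, series.y):
            fh.write(f"{float(ti)!r},{float(yi)!r}\n")


def timeseries_to_csv_text(series: TimeSeries) -> str:
    buf = io.StringIO()
    buf.write("time_s,value\n")
    for ti, yi in zip(series.t, series.y):
        buf.write(f"{float(ti)!r},{float(yi)!r}\n")
    return buf.getvalue()


def boxcar_average(series: TimeSeries, width: float) -> TimeSeries:
    """Moving average over a centred window of ``width`` seconds.

    Models the temporal footprint of an acquisition that integrates the
    signal over its scan time.  Requires a uniform grid; the window edges
    beyond the series are padded with the edge values.
    """
    dt = series.uniform_step()
    n = max(1, int(round(width / dt)))
    if n <= 1:
        return series.copy()
    kernel = np.ones(n) / n
    padded = np.concatenate(
        [np.full(n // 2, series.y[0]), series.y, np.full(n - 1 - n // 2, series.y[-1])]
    )
    y = np.convolve(padded, kernel, mode="valid")
    return series.copy(y=y)
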