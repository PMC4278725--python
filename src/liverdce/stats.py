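"""Agreement and test-retest reproducibility statistics.

Two measurements of the same quantity (pre-bolus vs main-bolus method, or
visit 1 vs visit 2) are compared with:

* the two-measurement coefficient of variation, using the
  sample-SD-of-a-pair convention standard in test-retest imaging::

      CV = 100 * (|x - y| / sqrt(2)) / ((x + y) / 2)

* Bland-Altman 95% limits of agreement on per-subject percent
  differences d_i = 100*(x_i - y_i)/pair mean: bias = mean(d),
  limits = bias +/- 1.96 * SD(d) (sample SD, n-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "cv_pair",
    "bland_altman",
    "test_retest_cv",
]


@dataclass
class PairedMeasurements:
    """Matched measurements of one parameter by two methods or visits."""

    subject_ids: list
    x: np.ndarray
    y: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.subject_ids) == len(self.x) == len(self.y)):
            raise ValueError("subject_ids, x and y must have equal lengths")
        if len(self.x) < 1:
            raise ValueError("need at least one pair")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("paired measurements must be finite")


@dataclass
class AgreementReport:
    """Between-method agreement of one parameter across a cohort."""

    label: str
    mean_cv_pct: float
    cv_min_pct: float
    cv_max_pct: float
    bias_pct: float
    loa_low_pct: float
    loa_high_pct: float
    n_used: int
    n_excluded: int = 0   # pairs with non-positive mean, dropped


def cv_pair(x: float, y: float) -> float:
    """Coefficient of variation of a measurement pair, in percent.

    Sample SD of {x, y} is |x - y|/sqrt(2); CV is that SD over the pair
    mean.  Returns NaN (undefined) when the pair mean is not positive.
    """
    mean = (x + y) / 2.0
    if mean <= 0:
        return float("nan")
    return 100.0 * (abs(x - y) / np.sqrt(2.0)) / mean


def bland_altman(pairs: PairedMeasurements, mode: str = "percent") -> AgreementReport:
    """Bland-Altman bias and 95% limits of agreement plus the mean pair CV.

    ``mode='percent'`` (default) expresses differences as percent of the
    pair mean; ``mode='absolute'`` uses raw differences (the report fields
    then carry the parameter's own units).
    """
    if mode not in ("percent", "absolute"):
        raise ValueError("mode must be 'percent' or 'absolute'")
    if len(pairs.x) < 2:
        raise ValueError("Bland-Altman requires at least 2 pairs")
    mean = (pairs.x + pairs.y) / 2.0
    ok = mean > 0
    n_excluded = int(np.sum(~ok))
    x, y, mean = pairs.x[ok], pairs.y[ok], mean[ok]
    if len(x) < 2:
        raise ValueError("fewer than 2 pairs with positive mean")
    if mode == "percent":
        d = 100.0 * (x - y) / mean
    else:
        d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    cvs = 100.0 * (np.abs(x - y) / np.sqrt(2.0)) / mean
    return AgreementReport(
        label=pairs.label,
        mean_cv_pct=float(np.mean(cvs)),
        cv_min_pct=float(np.min(cvs)),
        cv_max_pct=float(np.max(cvs)),
        bias_pct=bias,
        loa_low_pct=bias - 1.96 * sd,
        loa_high_pct=bias + 1.96 * sd,
        n_used=int(len(x)),
        n_excluded=n_excluded,
    )


def test_retest_cv(
    visit1: pd.DataFrame,
    visit2: pd.DataFrame,
    id_col: str = "subject_id",
    param_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Per-parameter mean and range of test-retest CVs across subjects.

    Both tables must contain the same subjects (one row each); parameters
    default to every shared numeric column besides the id.
    """
    ids1 = set(visit1[id_col])
    ids2 = set(visit2[id_col])
    if ids1 != ids2:
        missing = sorted(map(str, ids1.symmetric_difference(ids2)))
        raise ValueError(f"unmatched subjects across visits: {', '.join(missing)}")
    if param_cols is None:
        param_cols = [
            c for c in visit1.columns
            if c != id_col and c in visit2.columns
            and pd.api.types.is_numeric_dtype(visit1[c])
        ]
    v1 = visit1.set_index(id_col).sort_index()
    v2 = visit2.set_index(id_col).sort_index()
    rows = []
    for col in param_cols:
        cvs = np.array([cv_pair(a, b) for a, b in zip(v1[col], v2[col])])
        cvs = cvs[np.isfinite(cvs)]
        rows.append(
            {
                "parameter": col,
                "mean_cv_pct": float(np.mean(cvs)) if len(cvs) else float("nan"),
                "cv_min_pct": float(np.min(cvs)) if len(cvs) else float("nan"),
                "cv_max_pct": float(np.max(cvs)) if len(cvs) else float("nan"),
                "n": int(len(cvs)),
            }
        )
    return pd.DataFrame(rows)
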