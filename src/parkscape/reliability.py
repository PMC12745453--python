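"""Observer-reliability metrics for systematic behavioral observation.

Dual-coded observation sessions give an n_targets x n_raters matrix of
counts (e.g. participants per plot-session per observer).  Reliability
is summarized by single-measure intraclass correlation coefficients
computed from the two-way ANOVA mean squares, and by percent agreement
on paired categorical codes.

Forms (Shrout & Fleiss nomenclature):

* ICC(1,1) -- one-way random effects
* ICC(2,1) -- two-way random effects, absolute agreement (default; the
  standard choice for observer reliability in park observation work)
* ICC(3,1) -- two-way mixed effects, consistency
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior import round_half_up

__all__ = ["RatingMatrix", "agreement_by_stratum", "icc", "percent_agreement"]

ICC_FORMS = ("ICC1_1", "ICC2_1", "ICC3_1")


@dataclass(frozen=True)
class RatingMatrix:
    """Complete n_targets x n_raters ratings (no missing cells)."""

    values: np.ndarray
    target_labels: tuple[str, ...] = ()
    rater_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("rating matrix needs >= 2 targets and >= 2 raters")
        if not np.all(np.isfinite(arr)):
            raise ValueError("rating matrix has missing/non-finite cells; "
                             "apply listwise deletion upstream")
        object.__setattr__(self, "values", arr)

    @classmethod
    def from_wide_csv(cls, path) -> "RatingMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float),
                   tuple(map(str, df.index)), tuple(map(str, df.columns)))


def _mean_squares(m: np.ndarray) -> dict[str, float]:
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((m - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    ss_within = ss_total - ss_rows
    return {
        "msr": ss_rows / (n - 1),
        "msc": ss_cols / (k - 1),
        "mse": max(0.0, ss_err) / ((n - 1) * (k - 1)),
        "msw": ss_within / (n * (k - 1)),
    }


def icc(m: RatingMatrix, form: str = "ICC2_1") -> dict[str, float]:
    """Single-measure intraclass correlation from ANOVA mean squares.

    Returns ``{"form", "icc", "ms_between", "ms_within"}``; the ICC is
    NaN (with a warning) when the matrix carries no variance at all.
    """
    if form not in ICC_FORMS:
        raise ValueError(f"form must be one of {ICC_FORMS}, got {form!r}")
    arr = m.values
    n, k = arr.shape
    ms = _mean_squares(arr)
    msr, msc, mse, msw = ms["msr"], ms["msc"], ms["mse"], ms["msw"]
    if np.ptp(arr) == 0:
        warnings.warn("zero total variance: ICC undefined", stacklevel=2)
        value = float("nan")
    elif form == "ICC1_1":
        value = (msr - msw) / (msr + (k - 1) * msw)
    elif form == "ICC2_1":
        value = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    else:  # ICC3_1
        value = (msr - mse) / (msr + (k - 1) * mse)
    return {"form": form, "icc": float(value),
            "ms_between": msr, "ms_within": msw, "ms_error": mse,
            "ms_raters": msc, "n_targets": n, "n_raters": k}


def percent_agreement(codes_a: Sequence, codes_b: Sequence) -> float:
    """Share of paired observations coded identically, in percent.

    Rounded half-up to one decimal for reporting; symmetric in the two
    observers.
    """
    a, b = list(codes_a), list(codes_b)
    if len(a) != len(b):
        raise ValueError("observers must supply equally many paired codes")
    if not a:
        raise ValueError("no paired observations")
    matches = sum(x == y for x, y in zip(a, b))
    return round_half_up(100.0 * matches / len(a), 1)


def agreement_by_stratum(
    codes_a: Sequence,
    codes_b: Sequence,
    strata: Sequence,
) -> pd.DataFrame:
    """Percent agreement computed separately within each stratum."""
    if not (len(codes_a) == len(codes_b) == len(strata)):
        raise ValueError("codes and strata must align")
    df = pd.DataFrame({"a": list(codes_a), "b": list(codes_b),
                       "stratum": list(strata)})
    rows = [
        {"stratum": s, "n_pairs": len(sub),
         "agreement_pct": percent_agreement(sub["a"], sub["b"])}
        for s, sub in df.groupby("stratum")
    ]
    return pd.DataFrame(rows)
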