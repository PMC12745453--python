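"""Correlation screening, collinearity filtering and linear models.

The analysis chain linking landscape composition to behavior intensity:

1. rank-correlation screening of each feature against each index,
2. variance-inflation-factor (VIF) filtering of the candidate features
   (VIF_j = 1 / (1 - R2_j) from regressing feature j on the others;
   features at or above the threshold are dropped worst-first), and
3. ordinary least squares with intercept for each of OBI/EBI/LBI/SBI.

The reference prediction equations estimated by the original seven-park
field study ship with the package (:func:`reference_models`) so new
parks can be mapped without refitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import reference
from .landscape import FeatureVector, LandscapeProfile, profiles_to_frame
from .reference import FEATURES, OUTCOMES

__all__ = [
    "RegressionModel",
    "correlation_screen",
    "fit_model",
    "full_reference_models",
    "model_report",
    "models_from_json",
    "models_to_json",
    "predict",
    "reference_models",
    "vif_filter",
]


@dataclass(frozen=True)
class RegressionModel:
    """A linear prediction equation for one intensity index.

    ``coefficients`` maps landscape features to slopes (MET.persons per
    unit fraction); ``diagnostics`` may carry per-term ``se``/``t``/``p``
    maps plus ``r2``, ``adj_r2`` and ``f_pvalue``.
    """

    outcome: str
    intercept: float
    coefficients: Mapping[str, float]
    diagnostics: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}, got {self.outcome!r}")
        bad = set(self.coefficients) - set(FEATURES)
        if bad:
            raise ValueError(f"coefficients on unknown features: {sorted(bad)}")
        r2 = self.diagnostics.get("r2")
        adj = self.diagnostics.get("adj_r2")
        # NaN R2 is legal (zero-variance outcome); bounds apply otherwise
        if r2 is not None and r2 == r2 and not 0 <= r2 <= 1 + 1e-12:
            raise ValueError(f"R2 out of [0, 1]: {r2}")
        if (r2 is not None and adj is not None and r2 == r2 and adj == adj
                and adj > r2 + 1e-12):
            raise ValueError("adjusted R2 cannot exceed R2")

    @property
    def features(self) -> list[str]:
        return list(self.coefficients)


def predict(
    model: RegressionModel,
    x: FeatureVector | Mapping[str, float],
    floor_at_zero: bool = False,
) -> float:
    """Evaluate ``intercept + sum(coef_f * x_f)`` for one feature vector.

    Predictions may legitimately be negative (two of the reference
    equations have negative intercepts); ``floor_at_zero`` clamps them
    for presentation if wanted.
    """
    get = x.fractions.get if isinstance(x, FeatureVector) else x.get
    total = model.intercept
    for f, coef in model.coefficients.items():
        v = get(f)
        if v is None:
            raise KeyError(f"feature vector missing required feature {f!r}")
        total += coef * float(v)
    return max(0.0, total) if floor_at_zero else total


def _design_frame(profiles: Sequence[LandscapeProfile] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(profiles, pd.DataFrame):
        return profiles
    return profiles_to_frame(profiles)


def correlation_screen(
    profiles: Sequence[LandscapeProfile] | pd.DataFrame,
    scores: pd.DataFrame,
    method: str = "spearman",
) -> pd.DataFrame:
    """Correlate every landscape feature with every intensity index.

    Returns rows of (feature, outcome, coefficient, p_value, method).
    ``spearman`` (average-rank ties) is the default; ``pearson`` is
    available for comparison with published tables.  Constant features
    yield missing coefficients with a warning.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"method must be spearman or pearson, got {method!r}")
    X = _design_frame(profiles)
    merged = X.merge(scores, on="plot_id") if "plot_id" in scores.columns else X.join(scores)
    if len(merged) < 3:
        raise ValueError("need at least 3 paired observations")
    rows = []
    for feature in FEATURES:
        x = merged[feature].to_numpy(dtype=float)
        constant = np.ptp(x) == 0
        if constant:
            warnings.warn(f"feature {feature!r} is constant; correlation undefined",
                          stacklevel=2)
        for outcome in OUTCOMES:
            if outcome not in merged.columns:
                continue
            y = merged[outcome].to_numpy(dtype=float)
            if constant:
                r, p = np.nan, np.nan
            elif method == "spearman":
                r, p = stats.spearmanr(x, y)
            else:
                r, p = stats.pearsonr(x, y)
            rows.append({"feature": feature, "outcome": outcome,
                         "coefficient": float(r), "p_value": float(p),
                         "method": method})
    return pd.DataFrame(rows)


def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF of column j: regress it (with intercept) on the other columns."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    design = sm.add_constant(others, has_constant="add")
    fit = sm.OLS(y, design).fit()
    r2 = min(fit.rsquared, 1.0)
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def vif_filter(
    profiles: Sequence[LandscapeProfile] | pd.DataFrame,
    candidates: Sequence[str] | None = None,
    threshold: float = 10.0,
) -> tuple[list[str], pd.Series, list[str]]:
    """Iteratively drop the worst-VIF feature until all pass the threshold.

    Returns (retained features, final per-feature VIFs, drop log).
    Exactly collinear features (infinite VIF) are dropped immediately.
    A single surviving feature trivially has VIF 1.
    """
    X = _design_frame(profiles)
    retained = list(candidates if candidates is not None else FEATURES)
    n = len(X)
    if n < len(retained) + 2:
        raise ValueError(
            f"need at least {len(retained) + 2} observations for "
            f"{len(retained)} candidates, have {n}"
        )
    dropped: list[str] = []
    while len(retained) > 1:
        mat = X[retained].to_numpy(dtype=float)
        vifs = np.array([_vif_one(mat, j) for j in range(len(retained))])
        worst = int(np.argmax(vifs))
        if vifs[worst] < threshold:
            break
        feat = retained.pop(worst)
        dropped.append(feat)
    mat = X[retained].to_numpy(dtype=float)
    final = (np.array([_vif_one(mat, j) for j in range(len(retained))])
             if len(retained) > 1 else np.ones(len(retained)))
    return retained, pd.Series(final, index=retained, name="vif"), dropped


def fit_model(
    profiles: Sequence[LandscapeProfile] | pd.DataFrame,
    scores: pd.DataFrame,
    outcome: str,
    features: Sequence[str],
) -> RegressionModel:
    """OLS fit of one intensity index on the given landscape features."""
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}")
    X = _design_frame(profiles)
    merged = X.merge(scores, on="plot_id") if "plot_id" in scores.columns else X.join(scores)
    n = len(merged)
    if n <= len(features) + 1:
        raise ValueError(f"need n > {len(features) + 1} observations, have {n}")
    design = sm.add_constant(merged[list(features)], has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient; run vif_filter first"
        )
    fit = sm.OLS(merged[outcome].astype(float), design.astype(float)).fit()
    terms = ["const", *features]

    def _clean(v: float) -> float:
        return float(v) if np.isfinite(v) else float("nan")

    diagnostics = {
        "se": {t: float(fit.bse[t]) for t in terms},
        "t": {t: float(fit.tvalues[t]) for t in terms},
        "p": {t: float(fit.pvalues[t]) for t in terms},
        "r2": _clean(fit.rsquared),
        "adj_r2": _clean(fit.rsquared_adj),
        "f_pvalue": _clean(fit.f_pvalue) if len(features) else np.nan,
        "n": n,
    }
    return RegressionModel(
        outcome=outcome,
        intercept=float(fit.params["const"]),
        coefficients={f: float(fit.params[f]) for f in features},
        diagnostics=diagnostics,
    )


def _models_from_terms(
    terms_by_outcome: Mapping[str, Mapping[str, float]],
    with_se: bool = False,
) -> dict[str, RegressionModel]:
    models = {}
    for outcome, terms in terms_by_outcome.items():
        diag = dict(reference.MODEL_DIAGNOSTICS[outcome])
        diag = {"r2": diag["r2"], "adj_r2": diag["adj_r2"],
                "f_pvalue": diag["f_pvalue"]}
        if with_se:
            coef = {k: v[0] for k, v in terms.items() if k != "const"}
            intercept = terms["const"][0]
            diag["se"] = {k: v[1] for k, v in terms.items()}
        else:
            coef = {k: v for k, v in terms.items() if k != "const"}
            intercept = terms["const"]
        models[outcome] = RegressionModel(
            outcome=outcome, intercept=intercept, coefficients=coef,
            diagnostics=diag,
        )
    return models


def reference_models() -> dict[str, RegressionModel]:
    """The published reduced prediction equations (significant terms only).

    OBI = 281.63 + 857.13*sky + 1040.91*pavement - 1736.40*rough_ground
    EBI = -167.14 + 762.37*tree + 1462.50*pavement
          - 1553.52*rough_ground - 27547.01*resting_facility
    LBI = 119.00 + 585.04*shrub
    SBI = -106.58 + 1261.75*sky
    """
    return _models_from_terms(reference.REDUCED_MODEL_TERMS)


def full_reference_models() -> dict[str, RegressionModel]:
    """The complete fitted term sets (including non-significant terms)."""
    return _models_from_terms(reference.FULL_MODEL_TERMS, with_se=True)


def model_report(models: Mapping[str, RegressionModel]) -> pd.DataFrame:
    """Flat per-term report table (estimate, SE, t, p per model term)."""
    rows = []
    for outcome in OUTCOMES:
        if outcome not in models:
            continue
        m = models[outcome]
        se = m.diagnostics.get("se", {})
        tv = m.diagnostics.get("t", {})
        pv = m.diagnostics.get("p", {})
        for term in ["const", *m.coefficients]:
            est = m.intercept if term == "const" else m.coefficients[term]
            rows.append({
                "outcome": outcome,
                "term": "(Constant)" if term == "const" else term,
                "estimate": est,
                "std_error": se.get(term, np.nan),
                "t_value": tv.get(term, np.nan),
                "p_value": pv.get(term, np.nan),
                "r2": m.diagnostics.get("r2", np.nan),
                "adj_r2": m.diagnostics.get("adj_r2", np.nan),
            })
    return pd.DataFrame(rows)


def models_to_json(models: Mapping[str, RegressionModel], path) -> None:
    payload = {
        outcome: {
            "outcome": m.outcome,
            "intercept": m.intercept,
            "coefficients": dict(m.coefficients),
            "diagnostics": m.diagnostics,
        }
        for outcome, m in models.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def models_from_json(path) -> dict[str, RegressionModel]:
    with open(path) as fh:
        payload = json.load(fh)
    return {
        outcome: RegressionModel(
            outcome=d["outcome"], intercept=d["intercept"],
            coefficients=d["coefficients"], diagnostics=d.get("diagnostics", {}),
        )
        for outcome, d in payload.items()
    }
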