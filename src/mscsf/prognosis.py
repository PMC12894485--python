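"""Cross-scale conversion models and the disability-prognosis chain.

The prognostic validation cannot compare severity scores directly (the
validation cohort lacks the clinical inputs of MS-DSS and CombiWISE), so
the CSF-predicted severity score is propagated to a predicted follow-up
EDSS through two fitted maps:

1. a linear model ``slope_cw = a + b * msdss`` converting severity to an
   annualized CombiWISE progression slope (fitted on a training cohort
   with observed slopes), and
2. a monotone quadratic ``edss = q(cw) = c0 + c1*cw + c2*cw**2`` relating
   the continuous CombiWISE scale (0-100) to EDSS (0-10), fitted on
   cross-sectional visit pairs.

Predicted change in EDSS is computed on the CombiWISE scale — the
per-interval change is usually smaller than the 0.5-point EDSS increment,
so the granular scale carries the arithmetic — and mapped back through the
quadratic: delta_edss = q(cw_base + slope*interval) - q(cw_base). The
predicted follow-up EDSS is baseline + delta, clamped to [0, 10], and is
deliberately NOT snapped to the clinical half-point grid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import spearmanr

__all__ = [
    "ConversionModels",
    "RegressionReport",
    "fit_msdss_slope_model",
    "fit_combiwise_edss_model",
    "edss_to_combiwise",
    "predict_followup_edss",
    "evaluate_prognosis",
    "multivariate_followup_model",
    "mri_baseline_edss",
]


@dataclass
class ConversionModels:
    """Fitted severity->slope line and CombiWISE<->EDSS quadratic."""

    # linear part: slope_cw = a + b * msdss
    a: Optional[float] = None
    b: Optional[float] = None
    a_se: Optional[float] = None
    b_se: Optional[float] = None
    linear_r2: Optional[float] = None
    n_linear: Optional[int] = None
    # quadratic part: edss = c0 + c1*cw + c2*cw^2 on [cw_min, cw_max]
    c0: Optional[float] = None
    c1: Optional[float] = None
    c2: Optional[float] = None
    cw_min: Optional[float] = None
    cw_max: Optional[float] = None
    quadratic_r2: Optional[float] = None
    n_quadratic: Optional[int] = None
    conversion_mode: str = "quadratic"  # or "linear"

    def q(self, cw):
        """Forward CombiWISE -> EDSS map."""
        cw = np.asarray(cw, dtype=float)
        return self.c0 + self.c1 * cw + self.c2 * cw**2

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class RegressionReport:
    """OLS summary for the prognostic evaluations."""

    terms: pd.DataFrame  # index: term; columns: estimate, se, p
    r_squared: float
    n: int
    spearman_rho: Optional[float] = None
    spearman_p: Optional[float] = None
    r2_base: Optional[float] = None
    r2_augmented: Optional[float] = None
    p_gain: Optional[float] = None

    def __post_init__(self):
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("R^2 outside [0, 1]")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "terms"}
        d["terms"] = {
            t: {"estimate": float(r["estimate"]), "se": float(r["se"]), "p": float(r["p"])}
            for t, r in self.terms.iterrows()
        }
        return d


def fit_msdss_slope_model(
    msdss, observed_slopes, models: Optional[ConversionModels] = None, min_n: int = 10
) -> ConversionModels:
    """OLS of observed CombiWISE slope on the severity score."""
    x = np.asarray(msdss, dtype=float)
    y = np.asarray(observed_slopes, dtype=float)
    if x.size != y.size:
        raise ValueError("msdss and slopes must align")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs to fit the slope model")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: msdss is constant")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    out = models if models is not None else ConversionModels()
    out.a, out.b = float(fit.params[0]), float(fit.params[1])
    out.a_se, out.b_se = float(fit.bse[0]), float(fit.bse[1])
    out.linear_r2 = float(fit.rsquared)
    out.n_linear = int(x.size)
    return out


def fit_combiwise_edss_model(
    cw,
    edss,
    models: Optional[ConversionModels] = None,
    min_n: int = 20,
    min_span: float = 30.0,
) -> ConversionModels:
    """Least-squares quadratic relating CombiWISE to EDSS.

    The monotone domain is computed from the fitted coefficients (where
    the derivative c1 + 2*c2*cw stays positive), intersected with [0, 100];
    a warning is raised if the curve turns inside the observed range.
    """
    x = np.asarray(cw, dtype=float)
    y = np.asarray(edss, dtype=float)
    if x.size != y.size:
        raise ValueError("cw and edss must align")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} visit pairs")
    if np.ptp(x) < min_span:
        raise ValueError(
            f"CombiWISE span {np.ptp(x):.1f} < {min_span}: cannot anchor the curve"
        )
    X = np.column_stack([np.ones_like(x), x, x**2])
    fit = sm.OLS(y, X).fit()
    c0, c1, c2 = (float(v) for v in fit.params)
    out = models if models is not None else ConversionModels()
    out.c0, out.c1, out.c2 = c0, c1, c2
    lo, hi = 0.0, 100.0
    if abs(c2) > 1e-12:
        turn = -c1 / (2.0 * c2)
        if c2 > 0:
            lo = max(lo, turn)
        else:
            hi = min(hi, turn)
    if lo > x.min() + 1e-9 or hi < x.max() - 1e-9:
        warnings.warn(
            "fitted quadratic is non-monotone inside the observed CombiWISE range; "
            f"monotone domain restricted to [{lo:.2f}, {hi:.2f}]",
            stacklevel=2,
        )
    out.cw_min, out.cw_max = float(lo), float(hi)
    out.quadratic_r2 = float(fit.rsquared)
    out.n_quadratic = int(x.size)
    return out


def edss_to_combiwise(edss: float, models: ConversionModels) -> float:
    """Invert the fitted quadratic on its monotone domain.

    Returns the unique root of ``c2*x^2 + c1*x + (c0 - edss)`` inside
    [cw_min, cw_max]; an EDSS outside the attainable image is clamped to
    the nearest domain endpoint with a warning.
    """
    c0, c1, c2 = models.c0, models.c1, models.c2
    lo, hi = models.cw_min, models.cw_max
    e_lo, e_hi = models.q(lo), models.q(hi)
    if edss < min(e_lo, e_hi) - 1e-12 or edss > max(e_lo, e_hi) + 1e-12:
        warnings.warn(
            f"EDSS {edss} outside attainable range [{e_lo:.3f}, {e_hi:.3f}]; clamped",
            stacklevel=2,
        )
        return lo if edss < min(e_lo, e_hi) else hi
    if abs(c2) < 1e-12:
        return float((edss - c0) / c1)
    disc = c1**2 - 4.0 * c2 * (c0 - edss)
    disc = max(disc, 0.0)
    r1 = (-c1 + math.sqrt(disc)) / (2.0 * c2)
    r2 = (-c1 - math.sqrt(disc)) / (2.0 * c2)
    eps = 1e-9
    candidates = [r for r in (r1, r2) if lo - eps <= r <= hi + eps]
    if not candidates:
        return lo if abs(models.q(lo) - edss) < abs(models.q(hi) - edss) else hi
    return float(min(candidates, key=lambda r: abs(models.q(r) - edss)))


def predict_followup_edss(
    msdss_pred,
    baseline_edss,
    interval_years,
    models: ConversionModels,
    participant_id=None,
    baseline_source: str = "clinician",
) -> pd.DataFrame:
    """Propagate CSF-predicted severity to a predicted follow-up EDSS.

    Per participant: slope_cw = a + b*msdss; delta_cw = slope * interval;
    cw_base = q^{-1}(baseline); predicted = q(clamp(cw_base + delta_cw)),
    clamped to [0, 10]. All intermediates are returned. Rows with missing
    severity, baseline, or interval are skipped with the reason recorded
    in the ``skipped`` attribute of the returned frame.
    """
    msdss = np.asarray(msdss_pred, dtype=float)
    base = np.asarray(baseline_edss, dtype=float)
    ivl = np.asarray(interval_years, dtype=float)
    if not (msdss.size == base.size == ivl.size):
        raise ValueError("inputs must align")
    ids = (
        list(participant_id)
        if participant_id is not None
        else [f"P{i:04d}" for i in range(msdss.size)]
    )
    if models.a is None or models.c0 is None:
        raise ValueError("ConversionModels must have both linear and quadratic parts fitted")

    rows, skipped = [], []
    for i in range(msdss.size):
        reason = None
        if np.isnan(msdss[i]):
            reason = "missing msdss_pred"
        elif np.isnan(base[i]):
            reason = "missing baseline_edss"
        elif np.isnan(ivl[i]):
            reason = "missing interval_years"
        elif ivl[i] < 0:
            reason = "negative interval"
        if reason:
            skipped.append({"participant_id": ids[i], "reason": reason})
            continue
        slope_cw = models.a + models.b * msdss[i]
        delta_cw = slope_cw * ivl[i]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cw_base = edss_to_combiwise(float(base[i]), models)
        cw_follow = float(np.clip(cw_base + delta_cw, models.cw_min, models.cw_max))
        if models.conversion_mode == "linear":
            # slope-only linear conversion: dEDSS/dCW evaluated at cw_base
            deriv = models.c1 + 2.0 * models.c2 * cw_base
            delta_edss = deriv * (cw_follow - cw_base)
        else:
            delta_edss = float(models.q(cw_follow) - models.q(cw_base))
        predicted = float(np.clip(base[i] + delta_edss, 0.0, 10.0))
        rows.append(
            {
                "participant_id": ids[i],
                "baseline_source": baseline_source,
                "baseline_edss": float(base[i]),
                "msdss_pred": float(msdss[i]),
                "slope_cw": float(slope_cw),
                "delta_cw": float(delta_cw),
                "cw_base": cw_base,
                "delta_edss": delta_edss,
                "predicted_followup_edss": predicted,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "participant_id", "baseline_source", "baseline_edss", "msdss_pred",
            "slope_cw", "delta_cw", "cw_base", "delta_edss", "predicted_followup_edss",
        ],
    )
    out.attrs["skipped"] = skipped
    return out


def _ols_report(y, X: pd.DataFrame) -> tuple:
    fit = sm.OLS(np.asarray(y, float), sm.add_constant(X)).fit()
    terms = pd.DataFrame(
        {"estimate": fit.params, "se": fit.bse, "p": fit.pvalues}
    )
    return fit, terms


def evaluate_prognosis(predictions: pd.DataFrame, measured_followup) -> RegressionReport:
    """Compare predicted and measured follow-up EDSS.

    Reports the Spearman correlation between predicted and measured
    follow-up, plus the nested OLS pair on identical cases:
    measured ~ baseline (base model) and measured ~ baseline + delta_edss
    (augmented). ``p_gain`` is the two-sided t-test on the added term,
    identical to the single-degree-of-freedom nested F-test.
    """
    measured = np.asarray(measured_followup, dtype=float)
    if len(predictions) != measured.size:
        raise ValueError("predictions and measured follow-up must align")
    keep = ~np.isnan(measured)
    preds = predictions.loc[keep].reset_index(drop=True)
    y = measured[keep]
    if len(preds) < 10:
        raise ValueError(f"need >= 10 complete cases, got {len(preds)}")

    rho, rho_p = spearmanr(preds["predicted_followup_edss"], y)
    base = preds[["baseline_edss"]]
    fit_base, _ = _ols_report(y, base)

    delta = preds["delta_edss"]
    if np.ptp(delta.to_numpy()) == 0:
        r2_aug = float(fit_base.rsquared)
        p_gain = None
        fit_aug, terms = fit_base, _ols_report(y, base)[1]
    else:
        aug = preds[["baseline_edss", "delta_edss"]]
        fit_aug, terms = _ols_report(y, aug)
        r2_aug = float(fit_aug.rsquared)
        p_gain = float(fit_aug.pvalues["delta_edss"])

    return RegressionReport(
        terms=terms,
        r_squared=float(fit_aug.rsquared),
        n=len(preds),
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        r2_base=float(fit_base.rsquared),
        r2_augmented=r2_aug,
        p_gain=p_gain,
    )


def multivariate_followup_model(
    baseline_edss, age, progms_probability, measured_followup
) -> RegressionReport:
    """OLS of follow-up EDSS on baseline EDSS, age, and the CSF-predicted
    progressive-MS probability (the staging classifier's continuous
    output), on complete cases."""
    df = pd.DataFrame(
        {
            "baseline_edss": np.asarray(baseline_edss, float),
            "age": np.asarray(age, float),
            "progms_probability": np.asarray(progms_probability, float),
            "followup_edss": np.asarray(measured_followup, float),
        }
    ).dropna()
    if len(df) < 10:
        raise ValueError(f"need >= 10 complete cases, got {len(df)}")
    X = df[["baseline_edss", "age", "progms_probability"]]
    fit, terms = _ols_report(df["followup_edss"], X)
    if fit.condition_number > 1e6:
        warnings.warn(
            f"collinear design (condition number {fit.condition_number:.2g})",
            stacklevel=2,
        )
    rho, rho_p = spearmanr(fit.fittedvalues, df["followup_edss"])
    return RegressionReport(
        terms=terms,
        r_squared=float(fit.rsquared),
        n=len(df),
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
    )


def mri_baseline_edss(mri_scores: pd.DataFrame, weights: dict) -> pd.Series:
    """Configurable linear imaging->EDSS model (stand-in for the published
    semiquantitative-MRI disability predictor).

    ``weights``: {"intercept": w0, score_name: w, ...}. Every non-intercept
    weight must have a matching score column; the combination is clamped
    to [0, 10].
    """
    w0 = float(weights.get("intercept", 0.0))
    est = np.full(len(mri_scores), w0)
    for name, w in weights.items():
        if name == "intercept":
            continue
        if name not in mri_scores.columns:
            raise KeyError(f"MRI score component {name!r} missing")
        col = mri_scores[name].to_numpy(float)
        if np.isnan(col).any():
            raise ValueError(f"MRI score component {name!r} has missing values")
        est = est + w * col
    return pd.Series(np.clip(est, 0.0, 10.0), index=mri_scores.index)
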