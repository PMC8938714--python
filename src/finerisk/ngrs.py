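"""Nongenetic risk score: imputation, weight fitting, and scoring.

Seven epidemiological factors (BMI, waist-to-hip ratio, menopause status,
age at menarche, age at first live birth, family history of breast
cancer, prior benign breast disease) plus a BMI-by-menopause interaction
enter a logistic model of case-control status; the fitted log-OR weights
define the score ``NGRS = sum_k w_k F_k + w_i * BMI * menopause``.

Missing values occur only in the two age-at-event fields and are filled
by deterministic chained regression: each incomplete field is regressed
on the complete covariates among observed rows and predicted for the
missing ones (a reproducible single-imputation variant of chained
equations).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import COHORT_COVARIATES, MISSABLE_COVARIATES, NGRSWeights
from .errors import EvaluationError, ImputationError

logger = logging.getLogger(__name__)

FACTORS = list(COHORT_COVARIATES)
INTERACTION = "bmi_x_menopause"

_COMPLETE_PREDICTORS = ["bmi", "whr", "menopause", "family_history", "benign_breast_disease"]


def impute_missing(cohort: pd.DataFrame) -> tuple:
    """Fill the two age-at-event fields by chained regression prediction.

    Returns the completed table and a log dict with the number imputed per
    field.  Missingness in any other factor is an error, as is a field
    with no observed donor rows.  Predictions are clipped to the observed
    range of the field.
    """
    for col in FACTORS:
        if col in MISSABLE_COVARIATES:
            continue
        if cohort[col].isna().any():
            raise ImputationError(f"unexpected missing values in {col!r}")
    out = cohort.copy()
    log = {}
    predictors = [c for c in _COMPLETE_PREDICTORS if c in out.columns]
    if "age" in out.columns:
        predictors = predictors + ["age"]
    for col in MISSABLE_COVARIATES:
        miss = out[col].isna()
        log[col] = int(miss.sum())
        if not miss.any():
            continue
        obs = out[~miss]
        if len(obs) == 0:
            raise ImputationError(f"all values of {col!r} missing; no donors to fit on")
        X = sm.add_constant(obs[predictors].to_numpy(dtype=float))
        fit = sm.OLS(obs[col].to_numpy(dtype=float), X).fit()
        Xm = sm.add_constant(
            out.loc[miss, predictors].to_numpy(dtype=float), has_constant="add"
        )
        pred = Xm @ fit.params
        out.loc[miss, col] = np.clip(pred, obs[col].min(), obs[col].max())
        # an imputed field joins the predictors for the next one
        predictors = predictors + [col]
    if any(v for v in log.values()):
        logger.info("imputed missing covariates: %s", log)
    return out, log


def _design(cohort: pd.DataFrame) -> pd.DataFrame:
    X = cohort[FACTORS].astype(float).copy()
    X[INTERACTION] = X["bmi"] * X["menopause"]
    return X


def fit_ngrs_weights(training: pd.DataFrame) -> NGRSWeights:
    """Maximum-likelihood logistic weights for the 7 factors + interaction.

    Requires complete covariates and both statuses; non-convergence or
    separation raises :class:`EvaluationError` with diagnostics.
    """
    if training[FACTORS].isna().any().any():
        raise EvaluationError("covariates contain missing values; run impute_missing first")
    y = training["status"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise EvaluationError("both case and control statuses required to fit NGRS weights")
    # fit with BMI centered: the raw bmi*menopause column is almost collinear
    # with the menopause indicator, which wrecks the Newton step.  Centering
    # is an exact reparametrization; coefficients are mapped back below.
    X = _design(training)
    c = float(X["bmi"].mean())
    Xfit = X.copy()
    Xfit["bmi"] = X["bmi"] - c
    Xfit[INTERACTION] = Xfit["bmi"] * Xfit["menopause"]
    Xc = sm.add_constant(Xfit.to_numpy(), has_constant="add")
    try:
        fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    except Exception as exc:
        raise EvaluationError(f"NGRS logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise EvaluationError(f"NGRS logistic fit did not converge: {fit.mle_retvals}")
    if np.abs(fit.params).max() > 50:
        raise EvaluationError("NGRS fit shows signs of separation (extreme weights)")
    names = list(X.columns)
    params = pd.Series(fit.params[1:], index=names)
    cov = pd.DataFrame(fit.cov_params()[1:, 1:], index=names, columns=names)
    # back-transform: bmi_c = bmi - c  =>  raw menopause main effect
    # w_meno - c*w_i, raw intercept shifted by -c*w_bmi
    w = params.copy()
    w["menopause"] = params["menopause"] - c * params[INTERACTION]
    intercept = float(fit.params[0] - c * params["bmi"])
    se = pd.Series(fit.bse[1:], index=names)
    se["menopause"] = float(
        np.sqrt(
            cov.loc["menopause", "menopause"]
            + c**2 * cov.loc[INTERACTION, INTERACTION]
            - 2 * c * cov.loc["menopause", INTERACTION]
        )
    )
    return NGRSWeights(weights=w, intercept=intercept, se=se)


def compute_ngrs(cohort: pd.DataFrame, weights: NGRSWeights) -> pd.DataFrame:
    """Score each individual: weighted factor sum plus the interaction term."""
    if cohort[FACTORS].isna().any().any():
        raise EvaluationError("covariates contain missing values; run impute_missing first")
    X = _design(cohort)
    raw = X.to_numpy() @ weights.weights.reindex(X.columns).to_numpy()
    out = pd.DataFrame({"raw": raw}, index=cohort.index)
    out["status"] = cohort["status"]
    if "partition" in cohort.columns:
        out["partition"] = cohort["partition"]
    return out
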