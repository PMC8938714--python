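"""Risk-score evaluation: OR per SD, AUC with DeLong CI, percentile
groups, group odds ratios, integrated models, and best-panel selection."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, rankdata

from .containers import EvalReport
from .errors import EvaluationError

logger = logging.getLogger(__name__)

#: percentile bin edges supporting top/bottom 1% and 5% groups
DEFAULT_EDGES = (0, 1, 5, 10, 20, 40, 60, 80, 90, 95, 99, 100)
REFERENCE_BIN = (40, 60)


def _check_two_class(status: np.ndarray) -> None:
    if not ((status == 0).any() and (status == 1).any()):
        raise EvaluationError("both case and control statuses required")


def _logit_fit(y: np.ndarray, X: np.ndarray):
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:
        raise EvaluationError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False) or np.abs(fit.params).max() > 50:
        raise EvaluationError("logistic fit did not converge (possible separation)")
    return fit


def or_per_sd(scores: pd.DataFrame, col: str = "standardized"):
    """Odds ratio per SD increase of a standardized score, with Wald CI and p.

    Returns ``(or, (lo, hi), p)`` from a logistic regression of status on
    the score.
    """
    s = scores[col].to_numpy(dtype=float)
    y = scores["status"].to_numpy(dtype=float)
    _check_two_class(y)
    if s.std(ddof=1) == 0:
        raise EvaluationError("score has zero variance")
    fit = _logit_fit(y, sm.add_constant(s))
    b, se = fit.params[1], fit.bse[1]
    ci = (float(np.exp(b - 1.959963984540054 * se)), float(np.exp(b + 1.959963984540054 * se)))
    p = float(np.clip(2 * norm.sf(abs(b / se)), np.finfo(float).tiny, 1.0))
    return float(np.exp(b)), ci, p


# ---------------------------------------------------------------------------
# AUC (Mann-Whitney concordance) with DeLong variance


def _delong(cases: np.ndarray, controls: np.ndarray):
    m, n = len(cases), len(controls)
    ranks_all = rankdata(np.concatenate([cases, controls]))
    rx = rankdata(cases)
    ry = rankdata(controls)
    auc_val = (ranks_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (ranks_all[:m] - rx) / n          # placement of each case among controls
    v01 = 1.0 - (ranks_all[m:] - ry) / m    # placement of each control among cases
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    return float(auc_val), se


def auc(scores: pd.DataFrame, col: str = "standardized"):
    """AUC (ties counted 1/2) with a 95% DeLong confidence interval.

    Returns ``(auc, (lo, hi))``.
    """
    if col not in scores.columns:
        col = "raw"
    s = scores[col].to_numpy(dtype=float)
    y = scores["status"].to_numpy()
    _check_two_class(y)
    a, se = _delong(s[y == 1], s[y == 0])
    z = 1.959963984540054
    ci = (float(np.clip(a - z * se, 0, 1)), float(np.clip(a + z * se, 0, 1)))
    return a, ci


def auc_greater_than_chance(scores: pd.DataFrame, col: str = "standardized"):
    """One-sided test of AUC > 0.5; returns (auc, z, p)."""
    if col not in scores.columns:
        col = "raw"
    s = scores[col].to_numpy(dtype=float)
    y = scores["status"].to_numpy()
    _check_two_class(y)
    a, se = _delong(s[y == 1], s[y == 0])
    if se == 0:
        return a, np.inf if a > 0.5 else -np.inf, 0.0 if a > 0.5 else 1.0
    z = (a - 0.5) / se
    return a, float(z), float(norm.sf(z))


# ---------------------------------------------------------------------------
# percentile groups and group ORs


def percentile_groups(
    scores: pd.DataFrame,
    edges=DEFAULT_EDGES,
    reference=REFERENCE_BIN,
    basis: str = "controls",
    basis_partition: str | None = None,
    col: str = "raw",
) -> pd.DataFrame:
    """Assign each individual to a score-percentile bin.

    Percentile cut points are computed on the basis group (controls by
    default, optionally restricted to one partition; ``basis='all'`` uses
    everyone).  Bins are half-open ``[lo, hi)`` with the last bin closed;
    the ``reference`` bin (default 40th-60th percentile) is flagged.
    Returns a frame indexed like ``scores`` with columns ``group``,
    ``pct_lo``, ``pct_hi``, ``is_reference``.
    """
    edges = list(edges)
    if edges[0] != 0 or edges[-1] != 100 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing from 0 to 100")
    if tuple(reference) not in set(zip(edges, edges[1:])):
        raise ValueError(f"reference bin {reference} is not one of the bins")
    base = scores
    if basis_partition is not None:
        base = base[base["partition"] == basis_partition]
    if basis == "controls":
        base = base[base["status"] == 0]
    elif basis != "all":
        raise ValueError("basis must be 'controls' or 'all'")
    if len(base) == 0:
        raise EvaluationError("empty percentile basis group")
    cuts = np.percentile(base[col].to_numpy(dtype=float), edges[1:-1])
    idx = np.searchsorted(cuts, scores[col].to_numpy(dtype=float), side="right")
    lo = np.asarray(edges[:-1])[idx]
    hi = np.asarray(edges[1:])[idx]
    out = pd.DataFrame(
        {
            "group": [f"[{a},{b})" for a, b in zip(lo, hi)],
            "pct_lo": lo,
            "pct_hi": hi,
            "is_reference": (lo == reference[0]) & (hi == reference[1]),
        },
        index=scores.index,
    )
    out["status"] = scores["status"]
    out.attrs["cutpoints"] = cuts
    out.attrs["edges"] = edges
    return out


def group_or(assignment: pd.DataFrame) -> pd.DataFrame:
    """Per-percentile-group odds ratios versus the reference bin.

    One logistic regression with indicator variables for every
    non-reference group (reference omitted).  Groups that are empty or
    single-status are flagged non-estimable.  Returns one row per bin:
    ``pct_lo``, ``pct_hi``, ``n_case``, ``n_control``, ``odds_ratio``,
    ``ci_low``, ``ci_high``, ``p``, ``is_reference``, ``estimable``.
    """
    ref_rows = assignment[assignment["is_reference"]]
    if len(ref_rows) == 0:
        raise EvaluationError("no individuals in the reference bin")
    y_ref = ref_rows["status"]
    if not ((y_ref == 0).any() and (y_ref == 1).any()):
        raise EvaluationError("reference bin must contain both statuses")
    bins = (
        assignment.groupby(["pct_lo", "pct_hi"], sort=True)
        .agg(n_case=("status", "sum"), n=("status", "size"),
             is_reference=("is_reference", "first"), group=("group", "first"))
        .reset_index()
    )
    bins["n_control"] = bins["n"] - bins["n_case"]
    estimable = {}
    dummies = []
    for _, row in bins.iterrows():
        g = row["group"]
        if row["is_reference"]:
            continue
        ok = row["n_case"] > 0 and row["n_control"] > 0
        estimable[g] = ok
        if ok:
            dummies.append(g)
        else:
            logger.warning("group %s has no %s; OR undefined", g,
                           "cases" if row["n_case"] == 0 else "controls")
    X = np.column_stack(
        [np.ones(len(assignment))]
        + [(assignment["group"] == g).to_numpy(dtype=float) for g in dummies]
    )
    keep = np.ones(len(assignment), dtype=bool)
    for g, ok in estimable.items():
        if not ok:
            keep &= (assignment["group"] != g).to_numpy()
    fit = _logit_fit(assignment["status"].to_numpy(dtype=float)[keep], X[keep])
    z = 1.959963984540054
    records = []
    for _, row in bins.iterrows():
        g = row["group"]
        rec = {
            "group": g, "pct_lo": row["pct_lo"], "pct_hi": row["pct_hi"],
            "n_case": int(row["n_case"]), "n_control": int(row["n_control"]),
            "is_reference": bool(row["is_reference"]),
        }
        if row["is_reference"]:
            rec.update(odds_ratio=1.0, ci_low=1.0, ci_high=1.0, p=np.nan, estimable=True)
        elif estimable.get(g, False):
            j = dummies.index(g) + 1
            b, se = fit.params[j], fit.bse[j]
            rec.update(
                odds_ratio=float(np.exp(b)),
                ci_low=float(np.exp(b - z * se)),
                ci_high=float(np.exp(b + z * se)),
                p=float(np.clip(2 * norm.sf(abs(b / se)), np.finfo(float).tiny, 1.0)),
                estimable=True,
            )
        else:
            rec.update(odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan, estimable=False)
        records.append(rec)
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# reports, integrated model, selection


def evaluate_score(scores: pd.DataFrame, label: str, partition_name: str = "",
                   panel_n: int | None = None, col: str = "standardized") -> EvalReport:
    """Bundle OR per SD and AUC into an :class:`EvalReport`."""
    orv, orci, p = or_per_sd(scores, col=col)
    a, aci = auc(scores, col=col)
    y = scores["status"]
    return EvalReport(
        label=label, partition=partition_name, or_per_sd=orv, or_ci=orci, p=p,
        auc=a, auc_ci=aci, n_cases=int((y == 1).sum()), n_controls=int((y == 0).sum()),
        panel_n=panel_n,
    )


@dataclass
class IRPMReport:
    """Integrated risk prediction model: joint logistic fit on PRS + NGRS."""

    predictors: pd.DataFrame  # index predictor: or, ci_low, ci_high, p
    auc: float
    auc_ci: tuple
    linear_predictor: pd.Series = field(repr=False, default=None)


def fit_irpm(prs_scores: pd.DataFrame, ngrs_scores: pd.DataFrame,
             col: str = "standardized") -> IRPMReport:
    """Joint logistic model of status on standardized PRS and NGRS.

    Individuals must align between the two score tables.  A constant
    predictor is excluded from the fit (weight 0), so the integrated
    model degenerates gracefully to the informative component.  The
    combined linear predictor is scored and its AUC reported.
    """
    if not prs_scores.index.sort_values().equals(ngrs_scores.index.sort_values()):
        raise EvaluationError("PRS and NGRS score tables cover different individuals")
    ngrs_scores = ngrs_scores.loc[prs_scores.index]
    if not (prs_scores["status"] == ngrs_scores["status"]).all():
        raise EvaluationError("status mismatch between aligned score tables")
    y = prs_scores["status"].to_numpy(dtype=float)
    _check_two_class(y)
    preds = {"PRS": prs_scores[col].to_numpy(dtype=float),
             "NGRS": ngrs_scores[col].to_numpy(dtype=float)}
    active = [k for k, v in preds.items() if np.std(v) > 0]
    for k in preds:
        if k not in active:
            logger.warning("predictor %s is constant; excluded from the integrated model", k)
    X = sm.add_constant(np.column_stack([preds[k] for k in active]))
    fit = _logit_fit(y, X)
    z = 1.959963984540054
    rows = {}
    for k in preds:
        if k in active:
            j = active.index(k) + 1
            b, se = fit.params[j], fit.bse[j]
            rows[k] = {
                "odds_ratio": float(np.exp(b)),
                "ci_low": float(np.exp(b - z * se)),
                "ci_high": float(np.exp(b + z * se)),
                "p": float(np.clip(2 * norm.sf(abs(b / se)), np.finfo(float).tiny, 1.0)),
            }
        else:
            rows[k] = {"odds_ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan}
    lp = X @ fit.params
    lp_scores = pd.DataFrame({"raw": lp, "status": y}, index=prs_scores.index)
    a, aci = auc(lp_scores, col="raw")
    return IRPMReport(pd.DataFrame.from_dict(rows, orient="index"), a, aci,
                      pd.Series(lp, index=prs_scores.index))


def select_best(reports: list, tol: float = 1e-9):
    """The report with the highest AUC; ties go to the smaller panel.

    Mirrors the preference for a compact panel when predictive ability is
    essentially equal.
    """
    if not reports:
        raise ValueError("at least one report required")
    best = max(r.auc for r in reports)
    contenders = [r for r in reports if best - r.auc <= tol]
    contenders.sort(key=lambda r: (r.panel_n if r.panel_n is not None else np.inf, r.label))
    return contenders[0]
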