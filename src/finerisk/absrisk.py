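"""Ten-year absolute risk from percentile-group odds ratios.

Group ORs are treated as relative risks (rare-disease approximation) and
anchored to population age-specific incidence by the constraint that the
proportion-weighted average of the group hazards reproduces the
population hazard at every age:

    h0(t) = h_pop(t) / sum_g pi_g * RR_g,      h_g(t) = h0(t) * RR_g.

Absolute risk over a horizon uses a discrete annual life table with
exponential within-year survival and competing mortality: the
probability of a breast-cancer event in year t is the probability of
surviving all prior years free of both events times the within-year
event probability apportioned to the cause-specific hazard,

    risk = sum_t exp(-sum_{u<t} (h_g + m)(u)) * (1 - exp(-(h_g+m)(t))) * h_g(t)/(h_g+m)(t),

which converges to 1 - exp(-Y*h) as m -> 0 for constant h.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, RateCoverageError


def _rates_series(rates: pd.DataFrame, col: str) -> pd.Series:
    return pd.Series(rates[col].to_numpy(dtype=float), index=rates["age"].to_numpy(dtype=int))


def constrain_hazards(group_rrs, proportions, rates: pd.DataFrame) -> pd.DataFrame:
    """Per-group age-specific incidence hazards constrained to the population rate.

    ``group_rrs`` and ``proportions`` are aligned per-group arrays (or
    Series sharing an index); ``rates`` is an annual-bin table with
    ``age`` and ``incidence`` columns.  Returns a groups x ages DataFrame
    whose pi-weighted column sums equal the population incidence exactly.
    """
    rr = pd.Series(group_rrs, dtype=float)
    pi = pd.Series(proportions, dtype=float)
    if not rr.index.equals(pi.index):
        pi.index = rr.index
    if (rr <= 0).any():
        raise ConfigurationError("relative risks must be positive")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ConfigurationError(f"group proportions must sum to 1 (got {pi.sum():.6f})")
    denom = float((pi * rr).sum())
    if denom <= 0:
        raise ConfigurationError("zero denominator: sum pi_g * RR_g must be positive")
    h_pop = _rates_series(rates, "incidence")
    h0 = h_pop / denom
    return pd.DataFrame(np.outer(rr.to_numpy(), h0.to_numpy()), index=rr.index, columns=h0.index)


def absolute_risk(hazard: pd.Series, mortality: pd.Series, start_age: int, horizon: int = 10) -> float:
    """Probability of the event within ``horizon`` years from ``start_age``.

    ``hazard`` and ``mortality`` are annual rates indexed by age; both
    must cover ``[start_age, start_age + horizon)``.
    """
    ages = np.arange(start_age, start_age + horizon)
    for series, name in ((hazard, "hazard"), (mortality, "mortality")):
        missing = [a for a in ages if a not in series.index]
        if missing:
            raise RateCoverageError(f"{name} rates do not cover ages {missing}")
    h = hazard.loc[ages].to_numpy(dtype=float)
    m = mortality.loc[ages].to_numpy(dtype=float)
    tot = h + m
    surv_prior = np.exp(-np.concatenate([[0.0], np.cumsum(tot)[:-1]]))
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(tot > 0, h / np.where(tot > 0, tot, 1.0), 0.0)
    year_event = frac * (1.0 - np.exp(-tot))
    return float(np.sum(surv_prior * year_event))


def risk_curves(
    group_rrs,
    proportions,
    rates: pd.DataFrame,
    start_ages,
    horizon: int = 10,
    group_bounds: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tidy table of per-group absolute risks across starting ages.

    ``group_bounds`` (optional, indexed like the groups) supplies
    ``pct_lo``/``pct_hi`` columns for the output.  Risk is monotone
    non-decreasing in RR at fixed age by construction.
    """
    hz = constrain_hazards(group_rrs, proportions, rates)
    mort = _rates_series(rates, "mortality")
    rows = []
    for g in hz.index:
        for a in start_ages:
            rec = {"group": g, "age": int(a),
                   "risk": absolute_risk(hz.loc[g], mort, int(a), horizon)}
            if group_bounds is not None:
                rec["percentile_lo"] = group_bounds.loc[g, "pct_lo"]
                rec["percentile_hi"] = group_bounds.loc[g, "pct_hi"]
            rows.append(rec)
    return pd.DataFrame(rows)


def proportions_from_bounds(group_bounds: pd.DataFrame) -> pd.Series:
    """Group population proportions from percentile-bin widths (top 5% -> 0.05)."""
    pi = (group_bounds["pct_hi"] - group_bounds["pct_lo"]) / 100.0
    return pi.astype(float)


def group_risks_from_or(group_or_table: pd.DataFrame, rates: pd.DataFrame,
                        start_ages, horizon: int = 10) -> pd.DataFrame:
    """Convenience: percentile-group OR table -> tidy 10-year risk table.

    Uses the bin-width proportions and treats each estimable group's OR
    as its relative risk; non-estimable groups are dropped with their
    proportion mass renormalized away.
    """
    tab = group_or_table[group_or_table["estimable"]].set_index("group")
    bounds = tab[["pct_lo", "pct_hi"]]
    pi = proportions_from_bounds(bounds)
    pi = pi / pi.sum()
    return risk_curves(tab["odds_ratio"], pi, rates, start_ages, horizon, bounds)
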