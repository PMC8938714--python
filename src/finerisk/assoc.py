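"""Per-SNV association testing, allele harmonization, and fixed-effects meta-analysis.

Association is a per-SNV regression of case-control status (logistic,
Wald test) or a quantitative trait (ordinary least squares) on allelic
dosage, optionally adjusted for covariates.  Studies are combined by
inverse-variance fixed-effects meta-analysis on the log-OR scale after
harmonizing every study to a common effect-allele convention.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm
from scipy.stats import t as t_dist

from .containers import DosageMatrix, SummaryStatSet
from .errors import EvaluationError

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_ambiguous(a1: str, a2: str) -> bool:
    """A/T and C/G pairs are strand-ambiguous."""
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


# ---------------------------------------------------------------------------
# batched simple logistic regression (intercept + dosage), Newton-Raphson


def _batched_logistic(y: np.ndarray, D: np.ndarray, maxiter: int = 40, tol: float = 1e-10):
    """Fit ``logit P(y=1) = a_j + b_j * D[:, j]`` for every column j at once.

    Returns (b, se_b, converged) arrays.  Matches the per-SNV maximum
    likelihood fit of a two-parameter logistic model; used as a fast path
    when no adjustment covariates are requested.
    """
    n, k = D.shape
    a = np.full(k, np.log(y.mean() / (1 - y.mean())))
    b = np.zeros(k)
    conv = np.zeros(k, dtype=bool)
    yc = y[:, None]
    for _ in range(maxiter):
        eta = a[None, :] + D * b[None, :]
        mu = expit(eta)
        w = mu * (1 - mu)
        r = yc - mu
        g0 = r.sum(axis=0)
        g1 = (r * D).sum(axis=0)
        s0 = w.sum(axis=0)
        s1 = (w * D).sum(axis=0)
        s2 = (w * D * D).sum(axis=0)
        det = s0 * s2 - s1 * s1
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        da = (s2 * g0 - s1 * g1) / det
        db = (s0 * g1 - s1 * g0) / det
        step = np.nan_to_num(np.maximum(np.abs(da), np.abs(db)), nan=np.inf)
        a = a + np.nan_to_num(da)
        b = b + np.nan_to_num(db)
        conv = conv | (step < tol)
        if conv.all():
            break
    eta = a[None, :] + D * b[None, :]
    w = expit(eta) * (1 - expit(eta))
    s0 = w.sum(axis=0)
    s1 = (w * D).sum(axis=0)
    s2 = (w * D * D).sum(axis=0)
    det = s0 * s2 - s1 * s1
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.where(det > 0, s0 / det, np.nan))
    return b, se, conv


def single_snv_assoc(
    panel: DosageMatrix,
    cohort: pd.DataFrame,
    adjust: tuple = (),
    trait: str = "status",
    model: str = "logistic",
    study: str | None = None,
) -> SummaryStatSet:
    """Marginal per-SNV association within one cohort.

    Monomorphic SNVs are excluded (their count is logged and recorded in
    ``result.table.attrs['n_monomorphic']``).  ``model='linear'`` fits
    OLS of a quantitative ``trait`` column instead of logistic regression.
    """
    ids = cohort.index.intersection(panel.samples)
    if len(ids) == 0:
        raise EvaluationError("panel and cohort share no individuals")
    sub = panel.subset_samples(ids)
    y = cohort.loc[ids, trait].to_numpy(dtype=float)
    if model == "logistic" and len(np.unique(y)) < 2:
        raise EvaluationError("both case and control statuses required")
    dos = sub.dosages
    variances = dos.var(axis=0)
    poly = variances > 0
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("excluding %d monomorphic SNVs from association", n_mono)
    cols = np.flatnonzero(poly)
    n = len(y)

    if model == "linear" and not adjust:
        d = dos[:, cols]
        dc = d - d.mean(axis=0)
        yc = y - y.mean()
        sxx = (dc * dc).sum(axis=0)
        sxy = (dc * yc[:, None]).sum(axis=0)
        beta = sxy / sxx
        syy = float(yc @ yc)
        sigma2 = (syy - beta * sxy) / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        p = 2 * t_dist.sf(np.abs(beta / se), n - 2)
        b_arr, se_arr, p_arr, keep = beta, se, p, cols
    elif model == "logistic" and not adjust:
        b_arr, se_arr, conv = _batched_logistic(y, dos[:, cols])
        bad = ~conv | ~np.isfinite(se_arr)
        if bad.any():
            logger.warning("%d SNVs failed logistic convergence; excluded", int(bad.sum()))
        keep = cols[~bad]
        b_arr, se_arr = b_arr[~bad], se_arr[~bad]
        p_arr = 2 * norm.sf(np.abs(b_arr / se_arr))
    else:
        covar = cohort.loc[ids, list(adjust)].to_numpy(dtype=float)
        b_l, se_l, keep_l = [], [], []
        for j in cols:
            X = sm.add_constant(np.column_stack([dos[:, j], covar]))
            try:
                if model == "logistic":
                    fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
                else:
                    fit = sm.OLS(y, X).fit()
            except Exception:  # separation / singularity
                continue
            b_l.append(fit.params[1])
            se_l.append(fit.bse[1])
            keep_l.append(j)
        keep = np.asarray(keep_l, dtype=int)
        b_arr, se_arr = np.asarray(b_l), np.asarray(se_l)
        if model == "logistic":
            p_arr = 2 * norm.sf(np.abs(b_arr / se_arr))
        else:
            p_arr = 2 * t_dist.sf(np.abs(b_arr / se_arr), n - X.shape[1])

    meta = sub.snvs.iloc[keep]
    table = pd.DataFrame(
        {
            "a1": meta["effect_allele"].to_numpy(),
            "a2": meta["other_allele"].to_numpy(),
            "freq": dos[:, keep].mean(axis=0) / 2.0,
            "b": b_arr,
            "se": se_arr,
            "p": np.clip(p_arr, np.finfo(float).tiny, 1.0),
            "n": n,
        },
        index=meta.index,
    )
    table.attrs["n_monomorphic"] = n_mono
    label = study if study is not None else str(cohort["study"].iloc[0]) if "study" in cohort else "study"
    return SummaryStatSet(label, table)


# ---------------------------------------------------------------------------
# harmonization


def harmonize_alleles(
    sset: SummaryStatSet,
    target: pd.DataFrame | SummaryStatSet,
    ambiguous_policy: str = "drop",
) -> SummaryStatSet:
    """Reorient summary rows onto a target effect/other allele convention.

    Swapped alleles flip the beta sign and complement the frequency;
    strand flips are resolved through base complements.  Strand-ambiguous
    (A/T, C/G) SNVs are dropped under ``ambiguous_policy='drop'``, or kept
    under ``'keep-if-freq-informative'`` when both frequencies are far
    enough from 0.5 (|f-0.5| > 0.1) to determine orientation.  Policy
    ``'same-strand'`` declares the two sources strand-aligned (e.g. studies
    of one consortium): only exact and swapped matches are accepted and
    ambiguous pairs need no special handling.  Irreconcilable rows are
    dropped with a logged reason; per-category counts land in
    ``result.table.attrs['harmonization']``.
    """
    if ambiguous_policy not in ("drop", "keep-if-freq-informative", "same-strand"):
        raise ValueError(f"unknown ambiguous_policy {ambiguous_policy!r}")
    if isinstance(target, SummaryStatSet):
        tmeta = target.table.rename(columns={"a1": "effect_allele", "a2": "other_allele"})
    else:
        tmeta = target
    counts = {"kept": 0, "flipped": 0, "strand_flipped": 0, "ambiguous_dropped": 0,
              "irreconcilable": 0, "not_in_target": 0}
    rows = []
    for snv, row in sset.table.iterrows():
        if snv not in tmeta.index:
            counts["not_in_target"] += 1
            continue
        t1 = tmeta.at[snv, "effect_allele"]
        t2 = tmeta.at[snv, "other_allele"]
        a1, a2 = row["a1"], row["a2"]
        if ambiguous_policy == "same-strand":
            if (a1, a2) == (t1, t2):
                counts["kept"] += 1
                rows.append((snv, row))
            elif (a1, a2) == (t2, t1):
                new = row.copy()
                new["a1"], new["a2"] = t1, t2
                new["b"], new["freq"] = -row["b"], 1 - row["freq"]
                counts["flipped"] += 1
                rows.append((snv, new))
            else:
                counts["irreconcilable"] += 1
            continue
        if _is_ambiguous(a1, a2):
            if ambiguous_policy == "drop":
                counts["ambiguous_dropped"] += 1
                continue
            t_freq = tmeta["freq"].get(snv, np.nan) if "freq" in tmeta.columns else np.nan
            if abs(row["freq"] - 0.5) <= 0.1 or not np.isfinite(t_freq) or abs(t_freq - 0.5) <= 0.1:
                counts["ambiguous_dropped"] += 1
                continue
            if {a1, a2} != {t1, t2}:
                counts["irreconcilable"] += 1
                continue
            # orientation by frequency agreement
            same = abs(row["freq"] - t_freq) <= abs((1 - row["freq"]) - t_freq)
            new = row.copy()
            if (a1 == t1) == same:
                counts["kept"] += 1
            else:
                new["a1"], new["a2"] = a2, a1
                new["b"], new["freq"] = -row["b"], 1 - row["freq"]
                counts["flipped"] += 1
            new["a1"], new["a2"] = t1, t2
            rows.append((snv, new))
            continue
        if (a1, a2) == (t1, t2):
            counts["kept"] += 1
            rows.append((snv, row))
        elif (a1, a2) == (t2, t1):
            new = row.copy()
            new["a1"], new["a2"] = t1, t2
            new["b"], new["freq"] = -row["b"], 1 - row["freq"]
            counts["flipped"] += 1
            rows.append((snv, new))
        elif (_COMPLEMENT.get(a1), _COMPLEMENT.get(a2)) == (t1, t2):
            new = row.copy()
            new["a1"], new["a2"] = t1, t2
            counts["strand_flipped"] += 1
            rows.append((snv, new))
        elif (_COMPLEMENT.get(a2), _COMPLEMENT.get(a1)) == (t1, t2):
            new = row.copy()
            new["a1"], new["a2"] = t1, t2
            new["b"], new["freq"] = -row["b"], 1 - row["freq"]
            counts["strand_flipped"] += 1
            rows.append((snv, new))
        else:
            logger.debug("SNV %s alleles %s/%s irreconcilable with %s/%s", snv, a1, a2, t1, t2)
            counts["irreconcilable"] += 1
    dropped = counts["ambiguous_dropped"] + counts["irreconcilable"] + counts["not_in_target"]
    if dropped:
        logger.info("harmonization dropped %d rows: %s", dropped, counts)
    if rows:
        table = pd.DataFrame({snv: r for snv, r in rows}).T
        table.index.name = sset.table.index.name
        table = table.astype(sset.table.dtypes.to_dict())
    else:
        table = sset.table.iloc[:0].copy()
    table.attrs["harmonization"] = counts
    return SummaryStatSet(sset.study, table)


# ---------------------------------------------------------------------------
# fixed-effects meta-analysis


def fixed_effects_meta(
    sets: list, harmonize: bool = True, ambiguous_policy: str = "same-strand"
) -> SummaryStatSet:
    """Inverse-variance fixed-effects meta-analysis across studies.

    Per SNV (over the studies where it is present):
    ``b = sum(b_i/se_i^2) / sum(1/se_i^2)``, ``se = 1/sqrt(sum(1/se_i^2))``,
    p from the Wald z statistic, n summed, frequency n-weighted.  All sets
    are harmonized to the first set's allele convention unless
    ``harmonize=False`` (inputs already aligned); the default ambiguous
    policy assumes consortium studies share strand orientation (use
    ``'drop'`` when combining independent external summary data).
    """
    if not sets:
        raise ValueError("at least one summary-stat set required")
    if len(sets) == 1:
        return SummaryStatSet(sets[0].study, sets[0].table.copy())
    ref = sets[0]
    aligned = [ref] + [
        harmonize_alleles(s, ref, ambiguous_policy) if harmonize else s for s in sets[1:]
    ]
    stacked = pd.concat([s.table for s in aligned], keys=range(len(aligned)))
    out_rows = {}
    for snv, grp in stacked.groupby(level=1, sort=False):
        w = 1.0 / grp["se"] ** 2
        b = float((grp["b"] * w).sum() / w.sum())
        se = float(1.0 / np.sqrt(w.sum()))
        n = float(grp["n"].sum())
        freq = float((grp["freq"] * grp["n"]).sum() / n)
        p = float(np.clip(2 * norm.sf(abs(b / se)), np.finfo(float).tiny, 1.0))
        out_rows[snv] = {
            "a1": grp["a1"].iloc[0],
            "a2": grp["a2"].iloc[0],
            "freq": freq,
            "b": b,
            "se": se,
            "p": p,
            "n": n,
        }
    table = pd.DataFrame.from_dict(out_rows, orient="index")
    table.index.name = ref.table.index.name
    label = "meta(" + "+".join(s.study for s in sets) + ")"
    return SummaryStatSet(label, table)
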