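"""Approximate conditional-and-joint analysis from summary statistics.

Given marginal per-SNV regression results and an LD reference panel, the
multiple-regression normal equations are reconstructed and solved:

* per-SNV diagonal ``D_j = (n_j - 1) * var_ref_j`` (centered sum of
  squares of dosage, taken from the reference panel's empirical variance),
* cross products ``(X'X)_jk = r_jk * sqrt(var_j var_k) * (min(n_j, n_k) - 1)``,
* ``(X'y)_j = D_j * b_j``,
* joint betas ``(X'X)^{-1} X'y``; standard errors from the residual
  variance reconstructed from the marginal b, se, D and n.

When the LD reference *is* the association sample and n is uniform, this
reconstruction reproduces full-data multiple regression exactly (the
module's binding contract, enforced by the test suite); with an external
reference it is the usual summary-statistics approximation.  Forward
stepwise selection at a p-value threshold with an r-squared collinearity
guard and backward elimination provides the fine-mapping engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .containers import DosageMatrix, LDReference, Locus, SelectionResult, SummaryStatSet
from .errors import CollinearityError

logger = logging.getLogger(__name__)

R2_GUARD_DEFAULT = 0.9
FREQ_MISMATCH_TOL = 0.2


def build_ld_reference(panel: DosageMatrix, snv_ids=None) -> LDReference:
    """Pairwise dosage correlations and allele frequencies from a panel.

    Zero-variance (monomorphic) SNVs are excluded with a logged reason.
    """
    if panel.n_samples < 2:
        raise ValueError("at least 2 individuals required for an LD reference")
    sub = panel if snv_ids is None else panel.subset_snvs(snv_ids)
    var = sub.dosages.var(axis=0, ddof=1)
    keep = var > 0
    if (~keep).any():
        logger.info("LD reference excludes %d zero-variance SNVs", int((~keep).sum()))
    dos = sub.dosages[:, keep]
    meta = sub.snvs.loc[keep].copy()
    meta["freq"] = dos.mean(axis=0) / 2.0
    meta["var"] = var[keep]
    corr = np.corrcoef(dos, rowvar=False)
    corr = np.atleast_2d(corr)
    return LDReference(meta, corr, sub.n_samples)


def _system(stats: SummaryStatSet, snv_ids: list, ld: LDReference):
    """Reconstructed (X'X, X'y, D, n, Syy) for the requested SNV set."""
    tab = stats.table.loc[snv_ids]
    var = ld.snvs.loc[snv_ids, "var"].to_numpy()
    n = tab["n"].to_numpy(dtype=float)
    b = tab["b"].to_numpy(dtype=float)
    se = tab["se"].to_numpy(dtype=float)
    D = (n - 1.0) * var
    r = ld.submatrix(snv_ids)
    sd = np.sqrt(var)
    n_pair = np.minimum.outer(n, n) - 1.0
    B = r * np.outer(sd, sd) * n_pair
    np.fill_diagonal(B, D)
    Xty = D * b
    Syy = D * (se**2 * (n - 2.0) + b**2)
    return B, Xty, D, n, Syy


def joint_estimates(
    stats: SummaryStatSet,
    snv_ids,
    ld: LDReference,
    r2_guard: float = R2_GUARD_DEFAULT,
) -> pd.DataFrame:
    """Joint multiple-regression estimates for a set of SNVs.

    Returns a DataFrame indexed by SNV id with columns ``b``, ``se``, ``p``.
    Raises :class:`CollinearityError` when any pair exceeds the r-squared
    guard or the system is singular.
    """
    snv_ids = list(snv_ids)
    missing = [s for s in snv_ids if s not in stats.table.index]
    if missing:
        raise KeyError(f"SNVs absent from summary statistics: {missing[:5]}")
    r = ld.submatrix(snv_ids)
    if len(snv_ids) > 1:
        r2 = r**2
        np.fill_diagonal(r2, 0.0)
        j, k = np.unravel_index(np.argmax(r2), r2.shape)
        if r2[j, k] > r2_guard:
            raise CollinearityError(
                f"SNVs {snv_ids[j]} and {snv_ids[k]} have r^2="
                f"{r2[j, k]:.3f} > guard {r2_guard}",
                pair=(snv_ids[j], snv_ids[k]),
            )
    mism = np.abs(
        stats.table.loc[snv_ids, "freq"].to_numpy() - ld.snvs.loc[snv_ids, "freq"].to_numpy()
    )
    if (mism > FREQ_MISMATCH_TOL).any():
        bad = [s for s, m in zip(snv_ids, mism) if m > FREQ_MISMATCH_TOL]
        logger.warning("frequency mismatch > %.1f vs LD reference for %s", FREQ_MISMATCH_TOL, bad)

    B, Xty, D, n, Syy = _system(stats, snv_ids, ld)
    try:
        Binv = np.linalg.inv(B)
    except np.linalg.LinAlgError as exc:
        raise CollinearityError(f"singular joint system for {snv_ids}") from exc
    bj = Binv @ Xty
    k = len(snv_ids)
    n_eff = float(np.median(n))
    df = n_eff - k - 1.0
    sigma2 = (float(np.median(Syy)) - float(bj @ Xty)) / df
    if sigma2 <= 0:
        logger.warning("non-positive reconstructed residual variance; flooring")
        sigma2 = 1e-12
    se = np.sqrt(sigma2 * np.diag(Binv))
    p = np.clip(2 * t_dist.sf(np.abs(bj / se), df), np.finfo(float).tiny, 1.0)
    return pd.DataFrame({"b": bj, "se": se, "p": p}, index=pd.Index(snv_ids, name="snv"))


@dataclass
class ConditionalEstimate:
    """Candidate SNV's effect adjusted for a conditioning set."""

    snv: str
    b: float
    se: float
    p: float
    collinear: bool = False


def conditional_estimates(
    stats: SummaryStatSet,
    candidate: str,
    conditioning: list,
    ld: LDReference,
    r2_guard: float = R2_GUARD_DEFAULT,
) -> ConditionalEstimate:
    """Candidate SNV's conditional effect given already-selected SNVs.

    With an empty conditioning set this is the marginal row.  A candidate
    in r^2 above the guard with any conditioning SNV is flagged collinear
    with p set to 1 (never selectable), mirroring COJO practice.
    """
    if candidate in conditioning:
        raise ValueError(f"candidate {candidate!r} already in conditioning set")
    if not conditioning:
        row = stats.table.loc[candidate]
        return ConditionalEstimate(candidate, float(row["b"]), float(row["se"]), float(row["p"]))
    r = ld.submatrix(list(conditioning) + [candidate])
    if np.max(r[-1, :-1] ** 2) > r2_guard:
        return ConditionalEstimate(candidate, np.nan, np.nan, 1.0, collinear=True)
    try:
        joint = joint_estimates(stats, list(conditioning) + [candidate], ld, r2_guard)
    except CollinearityError:
        return ConditionalEstimate(candidate, np.nan, np.nan, 1.0, collinear=True)
    row = joint.loc[candidate]
    return ConditionalEstimate(candidate, float(row["b"]), float(row["se"]), float(row["p"]))


def _pick_best(table: pd.DataFrame) -> str:
    """Smallest p; ties broken by larger |b| then lexicographic SNV id."""
    t = table.copy()
    t["absb"] = -t["b"].abs()
    t["snv_id"] = t.index
    return t.sort_values(["p", "absb", "snv_id"]).index[0]


def stepwise_select(
    stats: SummaryStatSet,
    ld: LDReference,
    p_threshold: float = 1e-5,
    r2_guard: float = R2_GUARD_DEFAULT,
    locus_id: str = "locus",
    members=None,
    max_rounds: int = 100,
) -> SelectionResult:
    """Forward stepwise conditional selection with backward elimination.

    Starts from the smallest marginal p if below the threshold; repeatedly
    adds the candidate with the smallest conditional p below the threshold
    (collinear candidates skipped), refitting jointly after each addition
    and dropping any selected SNV whose joint p rises to or above the
    threshold.  A locus with no marginal p below the threshold is
    ineligible and returns an empty selection (its lead SNV and marginal
    statistics are still recorded).  Deterministic given its inputs.
    """
    if members is None:
        members = [s for s in stats.table.index if s in ld.snvs.index]
    else:
        members = [s for s in members if s in stats.table.index and s in ld.snvs.index]
    if not members:
        return SelectionResult(locus_id, False, [], _empty_joint(), p_threshold, [])
    marg = stats.table.loc[members]
    mism = np.abs(marg["freq"].to_numpy() - ld.snvs.loc[members, "freq"].to_numpy())
    if (mism > FREQ_MISMATCH_TOL).any():
        bad = [s for s, m in zip(members, mism) if m > FREQ_MISMATCH_TOL]
        logger.warning("dropping %d SNVs with freq mismatch vs LD reference: %s", len(bad), bad[:5])
        members = [s for s in members if s not in set(bad)]
        marg = stats.table.loc[members]
    lead = _pick_best(marg)
    lead_b = float(marg.at[lead, "b"])
    lead_p = float(marg.at[lead, "p"])
    if lead_p >= p_threshold:
        return SelectionResult(
            locus_id, False, [], _empty_joint(), p_threshold, members, lead, lead_b, lead_p
        )

    selected = [lead]
    order = {lead: 0}
    next_order = 1
    for _round in range(max_rounds):
        joint = joint_estimates(stats, selected, ld, r2_guard)
        # backward elimination of SNVs no longer below the threshold
        while len(selected) > 1 and joint["p"].max() >= p_threshold:
            worst = joint["p"].idxmax()
            logger.debug("%s: back-eliminating %s (joint p=%.3g)", locus_id, worst, joint.at[worst, "p"])
            selected.remove(worst)
            joint = joint_estimates(stats, selected, ld, r2_guard)
        candidates = [s for s in members if s not in selected]
        if not candidates:
            break
        cond = []
        for snv in candidates:
            est = conditional_estimates(stats, snv, selected, ld, r2_guard)
            if not est.collinear:
                cond.append({"snv": snv, "b": est.b, "se": est.se, "p": est.p})
        if not cond:
            break
        ctab = pd.DataFrame(cond).set_index("snv")
        best = _pick_best(ctab)
        if ctab.at[best, "p"] >= p_threshold:
            break
        selected.append(best)
        order[best] = next_order
        next_order += 1
    else:
        logger.warning("%s: stepwise hit round cap %d", locus_id, max_rounds)

    joint = joint_estimates(stats, selected, ld, r2_guard)
    joint = joint.assign(order=[order[s] for s in joint.index])
    joint = joint.sort_values("order")
    return SelectionResult(
        locus_id, True, list(joint.index), joint, p_threshold, members, lead, lead_b, lead_p
    )


def _empty_joint() -> pd.DataFrame:
    return pd.DataFrame(columns=["b", "se", "p", "order"], index=pd.Index([], name="snv"))


def define_loci(index_snvs: pd.DataFrame, half_width: int = 500_000, snv_meta: pd.DataFrame | None = None):
    """One window per index SNV; overlapping windows merged.

    ``index_snvs`` is indexed by SNV id with columns ``chrom``, ``pos``
    and ``p``.  Merged windows keep the smallest-p index SNV.  When
    ``snv_meta`` (indexed by SNV id, with ``chrom``/``pos``) is given,
    each locus's ``members`` are filled with the SNVs inside its window.
    """
    loci = []
    for chrom, grp in index_snvs.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        current = None
        for snv, row in grp.iterrows():
            start = max(int(row["pos"]) - half_width, 0)
            end = int(row["pos"]) + half_width
            if current is None or start >= current["end"]:
                if current is not None:
                    loci.append(current)
                current = {"chrom": str(chrom), "start": start, "end": end,
                           "index": snv, "p": row["p"]}
            else:
                current["end"] = max(current["end"], end)
                if row["p"] < current["p"]:
                    current["index"], current["p"] = snv, row["p"]
        if current is not None:
            loci.append(current)
    out = []
    for i, w in enumerate(sorted(loci, key=lambda w: (w["chrom"], w["start"]))):
        members = []
        if snv_meta is not None:
            inside = (snv_meta["chrom"].astype(str) == w["chrom"]) & (
                snv_meta["pos"].ge(w["start"]) & snv_meta["pos"].lt(w["end"])
            )
            members = list(snv_meta.index[inside])
        out.append(
            Locus(
                locus_id=f"L{i + 1:03d}_{w['chrom']}:{w['start']}-{w['end']}",
                index_snv=w["index"],
                chrom=w["chrom"],
                start=w["start"],
                end=w["end"],
                members=members,
            )
        )
    return out
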