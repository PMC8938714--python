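"""Polygenic risk score panels and per-individual scoring.

A weight panel is a list of (SNV, effect allele, weight) entries; the PRS
of individual *i* is ``sum_k weight_k * dosage_ik`` with dosages oriented
to each entry's effect allele.  Panels come from two routes: tiered
fine-mapping panels (all selected SNVs; those externally direction-
consistent at p < .05; plus lead SNVs of ineligible loci) and reweighted
versions of an externally reported SNV list (external, internal, or
meta-analysed weights).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .assoc import fixed_effects_meta
from .containers import DosageMatrix, SummaryStatSet, WeightPanel
from .errors import EvaluationError, PanelMismatchError

logger = logging.getLogger(__name__)

TIER_ALL = "finemap_all"
TIER_CONSISTENT = "finemap_consistent"
TIER_PLUS_LEAD = "finemap_plus_lead"


def compute_prs(
    panel: DosageMatrix,
    weights: WeightPanel,
    on_missing: str = "error",
) -> pd.DataFrame:
    """Raw PRS for every individual in the dosage panel.

    Dosages are reoriented when a panel entry's effect allele matches the
    dosage matrix's *other* allele (``2 - d``).  SNVs absent from the
    dosage data (or with incompatible alleles) raise
    :class:`PanelMismatchError` listing the offenders; with
    ``on_missing='impute_freq'`` entries carrying a ``freq`` column
    contribute ``weight * 2 * freq`` instead.
    """
    w = weights.table
    present = w.index.intersection(panel.snvs.index)
    missing = list(w.index.difference(panel.snvs.index))
    aligned = []
    for snv in present:
        ea = w.at[snv, "effect_allele"]
        col = panel.snv_column(snv)
        if ea == panel.snvs.at[snv, "effect_allele"]:
            aligned.append(col * w.at[snv, "weight"])
        elif ea == panel.snvs.at[snv, "other_allele"]:
            aligned.append((2.0 - col) * w.at[snv, "weight"])
        else:
            missing.append(snv)
    offset = 0.0
    if missing:
        if on_missing == "impute_freq" and "freq" in w.columns:
            imputable = [s for s in missing if np.isfinite(w.at[s, "freq"])]
            if len(imputable) < len(missing):
                raise PanelMismatchError(
                    f"{len(missing) - len(imputable)} panel SNVs missing without frequency",
                    missing=[s for s in missing if s not in imputable],
                )
            offset = float(sum(w.at[s, "weight"] * 2.0 * w.at[s, "freq"] for s in imputable))
            logger.info("imputed %d missing panel SNVs at 2*freq", len(imputable))
        else:
            raise PanelMismatchError(
                f"{len(missing)} panel SNVs absent from dosage data: {sorted(missing)[:10]}",
                missing=sorted(missing),
            )
    raw = np.sum(aligned, axis=0) + offset if aligned else np.full(panel.n_samples, offset)
    return pd.DataFrame({"raw": raw}, index=panel.samples)


def attach_cohort(scores: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Join status and partition labels onto a score table."""
    out = scores.loc[scores.index.intersection(cohort.index)].copy()
    out["status"] = cohort.loc[out.index, "status"]
    if "partition" in cohort.columns:
        out["partition"] = cohort.loc[out.index, "partition"]
    return out


def standardize_scores(
    scores: pd.DataFrame,
    reference_partition: str | None = None,
    controls_only: bool = True,
) -> pd.DataFrame:
    """Add a ``standardized`` column: (raw - mean_ref) / sd_ref.

    The reference group defaults to the control participants of
    ``reference_partition`` (or of the whole table when no partition is
    given).  A zero-variance reference raises :class:`EvaluationError`.
    """
    ref = scores
    if reference_partition is not None:
        ref = ref[ref["partition"] == reference_partition]
    if controls_only:
        if "status" not in ref.columns:
            raise EvaluationError("controls-only standardization requires a status column")
        ref = ref[ref["status"] == 0]
    if len(ref) == 0:
        raise EvaluationError("empty standardization reference group")
    mu = float(ref["raw"].mean())
    sd = float(ref["raw"].std(ddof=1))
    if not np.isfinite(sd) or sd == 0.0:
        raise EvaluationError("standardization reference has zero score variance")
    out = scores.copy()
    out["standardized"] = (out["raw"] - mu) / sd
    return out


# ---------------------------------------------------------------------------
# panel construction


def build_tiered_panels(
    selections: list,
    external_stats: SummaryStatSet,
    training_stats: SummaryStatSet,
    threshold: float,
    external_p: float = 0.05,
    lead_p: float = 0.05,
) -> dict:
    """The three tiered fine-mapping panels at one selection threshold.

    tier 1 (``finemap_all``)
        every SNV selected in an eligible locus, weighted by its joint
        estimate;
    tier 2 (``finemap_consistent``)
        tier 1 filtered to SNVs whose external association has the same
        direction as the joint weight with external p < ``external_p``
        (SNVs absent from the external data fail the filter, logged);
    tier 3 (``finemap_plus_lead``)
        tier 2 plus, for each ineligible locus, its lead SNV when the
        training marginal p < ``lead_p``, weighted by the training
        marginal beta.

    ``external_stats`` must already be harmonized to the training
    effect-allele convention.
    """
    entries1 = {}
    for sel in selections:
        if not sel.eligible:
            continue
        for snv, row in sel.joint.iterrows():
            entries1[snv] = {
                "effect_allele": training_stats.table.at[snv, "a1"],
                "weight": float(row["b"]),
            }
    t1 = pd.DataFrame.from_dict(entries1, orient="index")

    kept, unconfirmed = [], []
    for snv, row in t1.iterrows():
        if snv not in external_stats.table.index:
            unconfirmed.append(snv)
            continue
        ext = external_stats.table.loc[snv]
        if np.sign(ext["b"]) == np.sign(row["weight"]) and ext["p"] < external_p:
            kept.append(snv)
        else:
            unconfirmed.append(snv)
    if unconfirmed:
        logger.info("tier-2 filter removed %d SNVs (absent or inconsistent externally)", len(unconfirmed))
    t2 = t1.loc[kept]

    t3 = t2.copy()
    n_leads = 0
    for sel in selections:
        if sel.eligible or sel.lead_snv is None:
            continue
        if sel.lead_p < lead_p and sel.lead_snv not in t3.index:
            t3.loc[sel.lead_snv] = {
                "effect_allele": training_stats.table.at[sel.lead_snv, "a1"],
                "weight": float(sel.lead_b),
            }
            n_leads += 1
    logger.info(
        "tiered panels at threshold %g: %d selected, %d confirmed, +%d lead SNVs",
        threshold, len(t1), len(t2), n_leads,
    )
    mk = lambda tab, tier: WeightPanel(
        tab.copy(), tier=tier, threshold=threshold, source="training_joint",
        label=f"{tier}@{threshold:g}",
    )
    return {
        TIER_ALL: mk(t1, TIER_ALL),
        TIER_CONSISTENT: mk(t2, TIER_CONSISTENT),
        TIER_PLUS_LEAD: mk(t3, TIER_PLUS_LEAD),
    }


def reweight_external_panel(
    snv_ids,
    weight_source: str,
    external_stats: SummaryStatSet | None = None,
    training_stats: SummaryStatSet | None = None,
) -> WeightPanel:
    """Panel over a reported SNV list with external / internal / meta weights.

    SNVs missing from the required data source(s) are dropped with a
    logged count (the panel records how many of the requested SNVs
    survived); an empty intersection is an error.  Sources must share the
    training effect-allele convention.
    """
    if weight_source not in ("external", "internal", "meta"):
        raise ValueError(f"unknown weight_source {weight_source!r}")
    if weight_source in ("external", "meta") and external_stats is None:
        raise ValueError("external_stats required for this weight source")
    if weight_source in ("internal", "meta") and training_stats is None:
        raise ValueError("training_stats required for this weight source")

    snv_ids = list(snv_ids)
    if weight_source == "external":
        src = external_stats
    elif weight_source == "internal":
        src = training_stats
    else:
        both = [s for s in snv_ids
                if s in external_stats.table.index and s in training_stats.table.index]
        src = fixed_effects_meta(
            [external_stats.subset(both), training_stats.subset(both)], harmonize=False
        )
    found = [s for s in snv_ids if s in src.table.index]
    dropped = len(snv_ids) - len(found)
    if dropped:
        logger.info("reweight_external_panel: %d of %d requested SNVs unavailable, dropped",
                    dropped, len(snv_ids))
    if not found:
        raise PanelMismatchError("no requested SNVs available in the weight source", missing=snv_ids)
    tab = pd.DataFrame(
        {
            "effect_allele": src.table.loc[found, "a1"],
            "weight": src.table.loc[found, "b"].astype(float),
            "freq": src.table.loc[found, "freq"].astype(float),
        }
    )
    return WeightPanel(
        tab, tier="external", threshold=None, source=weight_source,
        label=f"external_{weight_source}_{len(found)}",
    )
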