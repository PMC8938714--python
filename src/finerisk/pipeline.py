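"""End-to-end demonstration pipeline on a synthetic multi-study cohort.

The demo mirrors the full analysis flow: simulate a base population and
multi-study case-control cohort; run per-study GWAS and a fixed-effects
meta-analysis of the training studies; define loci and fine-map each at
three thresholds; build tiered PRS panels plus externally reweighted
panels; pick the best panel in the validation set; evaluate it in the
age-matched prospective test set; fit and add the nongenetic risk score;
and convert percentile-group odds ratios into 10-year absolute risks.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import absrisk as ar
from . import assoc, cojo, evalmod, ngrs, prs, synthio
from .containers import SummaryStatSet

logger = logging.getLogger(__name__)

TRAINING_STUDIES = ("study_a", "study_b")
EXTERNAL_STUDY = "external_eur"
PROSPECTIVE_STUDY = "prospective_cohort"
THRESHOLDS = (1e-5, 1e-4, 1e-3)

DEFAULT_SCHEME = {
    "training": synthio.PartitionSpec(1800, 2200, studies=TRAINING_STUDIES),
    "validation": synthio.PartitionSpec(450, 450, studies=TRAINING_STUDIES),
    "prospective_test": synthio.PartitionSpec(180, 360, studies=(PROSPECTIVE_STUDY,), age_caliper=5.0),
    "ngrs_training": synthio.PartitionSpec(200, 700, studies=(PROSPECTIVE_STUDY,)),
}


@dataclass
class DemoResult:
    """Everything the demonstration pipeline computes."""

    config: synthio.SimConfig
    cohort: pd.DataFrame
    truth: pd.DataFrame
    panel: object  # DosageMatrix restricted to sampled individuals
    meta_stats: SummaryStatSet
    external_stats: SummaryStatSet
    selections: dict          # threshold -> list[SelectionResult]
    panels: dict              # label -> WeightPanel
    validation_reports: list
    chosen_label: str
    test_reports: dict        # label -> EvalReport on the prospective test set
    ngrs_weights: object
    irpm: object
    group_ors: pd.DataFrame
    risk_table: pd.DataFrame
    timings: dict = field(default_factory=dict)

    def summary(self) -> dict:
        """Headline numbers for manifests and reporting."""
        chosen = self.test_reports[self.chosen_label]
        irpm_pred = self.irpm.predictors
        top = self.group_ors[self.group_ors["pct_lo"] == 95].iloc[0]
        bottom = self.group_ors[self.group_ors["pct_hi"] == 5].iloc[0]
        age60 = self.risk_table[self.risk_table["age"] == 60]
        n_elig = sum(1 for s in self.selections[min(THRESHOLDS)] if s.eligible)
        tier3_label = f"{prs.TIER_PLUS_LEAD}@{min(THRESHOLDS):g}"
        out = {
            "chosen_panel": self.chosen_label,
            "chosen_panel_n": int(self.panels[self.chosen_label].n),
            "tier3_panel_n": int(self.panels[tier3_label].n),
            "test_auc_tier3": self.test_reports[tier3_label].auc,
            "n_loci_eligible": int(n_elig),
            "n_loci": len(self.selections[min(THRESHOLDS)]),
            "validation_auc_best": max(r.auc for r in self.validation_reports),
            "test_auc_prs": chosen.auc,
            "test_or_per_sd_prs": chosen.or_per_sd,
            "test_auc_ngrs": self.test_reports["ngrs"].auc,
            "test_or_per_sd_ngrs": self.test_reports["ngrs"].or_per_sd,
            "irpm_auc": self.irpm.auc,
            "irpm_or_per_sd_prs": float(irpm_pred.loc["PRS", "odds_ratio"]),
            "irpm_or_per_sd_ngrs": float(irpm_pred.loc["NGRS", "odds_ratio"]),
            "group_or_top5": float(top["odds_ratio"]),
            "group_or_bottom5": float(bottom["odds_ratio"]),
            "risk10y_age60_min": float(age60["risk"].min()),
            "risk10y_age60_max": float(age60["risk"].max()),
        }
        return out


def _study_stats(panel, cohort, studies):
    sets = []
    for study in studies:
        sub = cohort[cohort["study"] == study]
        sets.append(assoc.single_snv_assoc(panel, sub, study=study))
    return sets


def run_demo(seed: int = 2022, config: synthio.SimConfig | None = None,
             scheme: dict | None = None, outdir=None) -> DemoResult:
    """Run the full pipeline on a synthetic cohort; optionally write outputs."""
    t0 = time.time()
    timings = {}
    if config is None:
        config = synthio.SimConfig(seed=seed)
    else:
        config = replace(config, seed=seed)
    scheme = dict(DEFAULT_SCHEME if scheme is None else scheme)
    ss = np.random.SeedSequence(seed)
    r_panel, r_cohort, r_split = (np.random.default_rng(s) for s in ss.spawn(3))

    panel, truth = synthio.simulate_panel(config, r_panel)
    cohort = synthio.simulate_cohort(panel, truth, config, r_cohort)
    cohort = synthio.split_cohort(cohort, scheme, r_split)
    panel = panel.subset_samples(cohort.index)  # drop unsampled base individuals
    timings["simulate"] = time.time() - t0

    # --- per-study GWAS in the training partition, then meta-analysis
    t = time.time()
    training = synthio.partition(cohort, "training")
    study_sets = _study_stats(panel, training, TRAINING_STUDIES)
    meta_stats = assoc.fixed_effects_meta(study_sets, harmonize=True)
    external = cohort[cohort["study"] == EXTERNAL_STUDY]
    external_stats = assoc.single_snv_assoc(panel, external, study=EXTERNAL_STUDY)
    timings["assoc"] = time.time() - t

    # --- loci and fine-mapping at each threshold
    t = time.time()
    ld = cojo.build_ld_reference(panel.subset_samples(training.index))
    index_rows = []
    for locus, grp in panel.snvs.groupby("locus", sort=True):
        in_meta = [s for s in grp.index if s in meta_stats.table.index]
        sub = meta_stats.table.loc[in_meta]
        idx = sub["p"].idxmin()
        index_rows.append({"snv": idx, "chrom": grp.at[idx, "chrom"],
                           "pos": grp.at[idx, "pos"], "p": sub.at[idx, "p"]})
    loci = cojo.define_loci(pd.DataFrame(index_rows).set_index("snv"),
                            half_width=150_000, snv_meta=panel.snvs)
    selections = {}
    for thr in THRESHOLDS:
        selections[thr] = [
            cojo.stepwise_select(meta_stats, ld, p_threshold=thr,
                                 locus_id=loc.locus_id, members=loc.members)
            for loc in loci
        ]
    timings["finemap"] = time.time() - t

    # --- panels: tiered per threshold + externally reweighted list
    t = time.time()
    panels = {}
    for thr in THRESHOLDS:
        tiered = prs.build_tiered_panels(selections[thr], external_stats, meta_stats, thr)
        for p in tiered.values():
            panels[p.label] = p
    # external "reported panel" stand-in: per-locus lead SNVs that reach
    # p < 0.01 in the external study
    ext_list = []
    for loc in loci:
        sub = external_stats.table.loc[[s for s in loc.members if s in external_stats.table.index]]
        if len(sub) and sub["p"].min() < 0.01:
            ext_list.append(sub["p"].idxmin())
    for source in ("external", "internal", "meta"):
        p = prs.reweight_external_panel(ext_list, source, external_stats, meta_stats)
        panels[p.label] = p
    timings["panels"] = time.time() - t

    # --- validation evaluation and panel selection
    t = time.time()
    validation = synthio.partition(cohort, "validation")
    test = synthio.partition(cohort, "prospective_test")
    val_panel = panel.subset_samples(validation.index)
    test_panel = panel.subset_samples(test.index)
    validation_reports = []
    for label, wp in panels.items():
        scores = prs.attach_cohort(prs.compute_prs(val_panel, wp), cohort)
        scores = prs.standardize_scores(scores, "validation")
        validation_reports.append(
            evalmod.evaluate_score(scores, label, "validation", panel_n=wp.n)
        )
    chosen = evalmod.select_best(validation_reports)
    timings["validation"] = time.time() - t

    # --- prospective test: chosen PRS, NGRS, integrated model
    t = time.time()
    test_reports = {}
    test_prs = prs.attach_cohort(prs.compute_prs(test_panel, panels[chosen.label]), cohort)
    test_prs = prs.standardize_scores(test_prs, "prospective_test")
    test_reports[chosen.label] = evalmod.evaluate_score(
        test_prs, chosen.label, "prospective_test", panel_n=panels[chosen.label].n
    )
    # the tier-3 panel at the strictest threshold is the analysis's headline
    # score; always report it on the prospective test set
    tier3_label = f"{prs.TIER_PLUS_LEAD}@{min(THRESHOLDS):g}"
    if tier3_label not in test_reports:
        t3 = prs.attach_cohort(prs.compute_prs(test_panel, panels[tier3_label]), cohort)
        t3 = prs.standardize_scores(t3, "prospective_test")
        test_reports[tier3_label] = evalmod.evaluate_score(
            t3, tier3_label, "prospective_test", panel_n=panels[tier3_label].n
        )
    ngrs_train, _ = ngrs.impute_missing(synthio.partition(cohort, "ngrs_training"))
    weights = ngrs.fit_ngrs_weights(ngrs_train)
    test_complete, _ = ngrs.impute_missing(test)
    test_ngrs = ngrs.compute_ngrs(test_complete, weights)
    test_ngrs = prs.standardize_scores(test_ngrs, "prospective_test")
    test_reports["ngrs"] = evalmod.evaluate_score(test_ngrs, "ngrs", "prospective_test")
    irpm = evalmod.fit_irpm(test_prs, test_ngrs)
    timings["test"] = time.time() - t

    # --- percentile-group ORs on the pooled training partition, absolute risk
    t = time.time()
    pool_panel = panel.subset_samples(training.index)
    pool_scores = prs.attach_cohort(prs.compute_prs(pool_panel, panels[chosen.label]), cohort)
    pool_scores = prs.standardize_scores(pool_scores, "training")
    groups = evalmod.percentile_groups(pool_scores)
    group_ors = evalmod.group_or(groups)
    rates = synthio.shanghai_like_rates()
    risk_table = ar.group_risks_from_or(group_ors, rates, start_ages=(30, 40, 50, 60, 70))
    timings["absrisk"] = time.time() - t
    timings["total"] = time.time() - t0

    result = DemoResult(
        config=config, cohort=cohort, truth=truth, panel=panel, meta_stats=meta_stats,
        external_stats=external_stats, selections=selections, panels=panels,
        validation_reports=validation_reports, chosen_label=chosen.label,
        test_reports=test_reports, ngrs_weights=weights, irpm=irpm,
        group_ors=group_ors, risk_table=risk_table, timings=timings,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir), seed)
    return result


def _write_outputs(result: DemoResult, outdir: Path, seed: int) -> None:
    from . import io as frio

    outdir.mkdir(parents=True, exist_ok=True)
    frio.write_cohort_tsv(result.cohort, outdir / "cohort.tsv")
    frio.write_ma(result.meta_stats, outdir / "training_meta.ma")
    frio.write_ma(result.external_stats, outdir / "external.ma")
    for thr, sels in result.selections.items():
        frio.write_selection_tsv(sels, outdir / f"selection_{thr:g}.tsv")
    for label, wp in result.panels.items():
        frio.write_weight_panel(wp, outdir / f"panel_{label.replace('@', '_at_')}.tsv")
    frio.write_report_json(result.validation_reports, outdir / "validation_reports.json")
    frio.write_report_json(list(result.test_reports.values()), outdir / "test_reports.json")
    result.group_ors.to_csv(outdir / "group_ors.tsv", sep="\t", index=False)
    result.risk_table.to_csv(outdir / "risk_10y.csv", index=False)
    cfg_repr = repr(result.config).encode()
    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_repr).hexdigest(),
        "chosen_panel": result.chosen_label,
        "summary": result.summary(),
        "timings_s": {k: round(v, 2) for k, v in result.timings.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
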