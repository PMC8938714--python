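"""PRS scoring, tiered panel construction, reweighting, standardization."""

import numpy as np
import pandas as pd
import pytest

from finerisk import prs
from finerisk.containers import SelectionResult, WeightPanel
from finerisk.errors import EvaluationError, PanelMismatchError

from conftest import make_panel, make_sumstats


def panel_of(weights, alleles="A", freq=None, **kw):
    snvs = list(weights)
    tab = pd.DataFrame(
        {"effect_allele": np.broadcast_to(np.asarray(alleles, dtype=object), len(snvs)),
         "weight": [weights[s] for s in snvs]},
        index=pd.Index(snvs, name="snv"),
    )
    if freq is not None:
        tab["freq"] = freq
    return WeightPanel(tab, tier=kw.pop("tier", "external"), **kw)


class TestComputePrs:
    def test_hand_summed_score(self):
        dm = make_panel(np.array([[0.0, 1.0, 2.0]]))
        wp = panel_of({"rs001": 0.1, "rs002": -0.2, "rs003": 0.3})
        out = prs.compute_prs(dm, wp)
        assert out["raw"].iloc[0] == pytest.approx(0.4)

    def test_zero_weights_zero_scores(self):
        rng = np.random.default_rng(0)
        dm = make_panel(rng.binomial(2, 0.3, size=(20, 3)).astype(float))
        wp = panel_of({"rs001": 0.0, "rs002": 0.0, "rs003": 0.0})
        assert (prs.compute_prs(dm, wp)["raw"] == 0).all()

    def test_single_snv_weight_one(self):
        dm = make_panel(np.array([[2.0]]))
        assert prs.compute_prs(dm, panel_of({"rs001": 1.0}))["raw"].iloc[0] == 2.0

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(1)
        dm = make_panel(rng.binomial(2, 0.3, size=(50, 4)).astype(float))
        w1 = {f"rs{j + 1:03d}": rng.normal() for j in range(4)}
        w2 = {f"rs{j + 1:03d}": rng.normal() for j in range(4)}
        s1 = prs.compute_prs(dm, panel_of(w1))["raw"]
        s2 = prs.compute_prs(dm, panel_of(w2))["raw"]
        s12 = prs.compute_prs(dm, panel_of({k: w1[k] + w2[k] for k in w1}))["raw"]
        np.testing.assert_allclose(s12, s1 + s2, atol=1e-12)

    def test_effect_allele_flip_preserves_standardized_scores(self):
        # listing the other allele with a negated weight shifts raw scores by
        # a constant (2w) and leaves standardized scores untouched
        rng = np.random.default_rng(2)
        dm = make_panel(rng.binomial(2, 0.4, size=(100, 2)).astype(float))
        w = panel_of({"rs001": 0.3, "rs002": -0.1})
        flipped = w.table.copy()
        flipped.loc["rs001", ["effect_allele", "weight"]] = ["G", -0.3]
        wf = WeightPanel(flipped, tier="external")
        s = prs.compute_prs(dm, w)
        sf = prs.compute_prs(dm, wf)
        np.testing.assert_allclose(sf["raw"] - s["raw"], 2 * 0.3 * -1, atol=1e-12)
        s["status"] = 0
        sf["status"] = 0
        z = prs.standardize_scores(s)["standardized"]
        zf = prs.standardize_scores(sf)["standardized"]
        np.testing.assert_allclose(z, zf, atol=1e-10)

    def test_missing_snv_is_a_hard_error_listing_ids(self):
        dm = make_panel(np.array([[1.0]]))
        wp = panel_of({"rs001": 0.1, "rsX": 0.2, "rsY": 0.3})
        with pytest.raises(PanelMismatchError) as err:
            prs.compute_prs(dm, wp)
        assert set(err.value.missing) == {"rsX", "rsY"}

    def test_missing_snv_frequency_imputation_opt_in(self):
        dm = make_panel(np.array([[1.0], [2.0]]))
        wp = panel_of({"rs001": 0.1, "rsX": 0.5}, freq=[0.3, 0.2])
        out = prs.compute_prs(dm, wp, on_missing="impute_freq")
        np.testing.assert_allclose(out["raw"], [0.1 + 0.5 * 0.4, 0.2 + 0.5 * 0.4])

    def test_incompatible_alleles_count_as_missing(self):
        dm = make_panel(np.array([[1.0]]))  # A/G SNV
        wp = panel_of({"rs001": 0.1}, alleles="T")
        with pytest.raises(PanelMismatchError):
            prs.compute_prs(dm, wp)


class TestStandardize:
    def test_reference_group_becomes_mean0_sd1(self):
        rng = np.random.default_rng(3)
        scores = pd.DataFrame({"raw": rng.normal(5, 2, 200), "status": [0] * 150 + [1] * 50,
                               "partition": "val"})
        out = prs.standardize_scores(scores, "val")
        ref = out[(out["partition"] == "val") & (out["status"] == 0)]
        assert ref["standardized"].mean() == pytest.approx(0, abs=1e-12)
        assert ref["standardized"].std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_closed_form(self):
        scores = pd.DataFrame({"raw": [1.0, 2.0, 3.0], "status": 0})
        out = prs.standardize_scores(scores, controls_only=False)
        np.testing.assert_allclose(out["standardized"], [-1.0, 0.0, 1.0])

    def test_constant_scores_error(self):
        scores = pd.DataFrame({"raw": [1.0, 1.0], "status": 0})
        with pytest.raises(EvaluationError):
            prs.standardize_scores(scores, controls_only=False)


def selection(locus, snvs_betas, eligible=True, lead=None, lead_b=np.nan, lead_p=np.nan,
              threshold=1e-5):
    if eligible:
        joint = pd.DataFrame(
            {"b": list(snvs_betas.values()), "se": 0.05,
             "p": 1e-8, "order": range(len(snvs_betas))},
            index=pd.Index(list(snvs_betas), name="snv"),
        )
        return SelectionResult(locus, True, list(snvs_betas), joint, threshold,
                               list(snvs_betas), lead or list(snvs_betas)[0], lead_b, lead_p)
    empty = pd.DataFrame(columns=["b", "se", "p", "order"], index=pd.Index([], name="snv"))
    return SelectionResult(locus, False, [], empty, threshold, [], lead, lead_b, lead_p)


class TestTieredPanels:
    def test_toy_ledger_sign_filter(self):
        sels = [selection("l1", {"rs1": 0.3, "rs2": -0.2, "rs3": 0.25})]
        training = make_sumstats("train", ["rs1", "rs2", "rs3"], b=[0.3, -0.2, 0.25], se=0.05)
        external = make_sumstats("ext", ["rs1", "rs2", "rs3"],
                                 b=[0.28, -0.15, -0.3], se=0.05, p=[0.001, 0.01, 0.001])
        panels = prs.build_tiered_panels(sels, external, training, 1e-5)
        assert panels[prs.TIER_ALL].n == 3
        assert set(panels[prs.TIER_CONSISTENT].table.index) == {"rs1", "rs2"}

    def test_snv_absent_externally_fails_confirmation(self):
        sels = [selection("l1", {"rs1": 0.3, "rs2": 0.2})]
        training = make_sumstats("train", ["rs1", "rs2"], b=[0.3, 0.2], se=0.05)
        external = make_sumstats("ext", ["rs1"], b=0.3, se=0.05, p=0.001)
        panels = prs.build_tiered_panels(sels, external, training, 1e-5)
        assert list(panels[prs.TIER_CONSISTENT].table.index) == ["rs1"]

    def test_fully_consistent_external_keeps_everything(self):
        sels = [selection("l1", {"rs1": 0.3, "rs2": -0.2})]
        training = make_sumstats("train", ["rs1", "rs2"], b=[0.3, -0.2], se=0.05)
        external = make_sumstats("ext", ["rs1", "rs2"], b=[0.2, -0.1], se=0.05, p=0.01)
        panels = prs.build_tiered_panels(sels, external, training, 1e-5)
        pd.testing.assert_frame_equal(panels[prs.TIER_CONSISTENT].table,
                                      panels[prs.TIER_ALL].table)

    def test_lead_snvs_join_third_tier(self):
        sels = [
            selection("l1", {"rs1": 0.3}),
            selection("l2", None, eligible=False, lead="rs9", lead_b=0.15, lead_p=0.01),
            selection("l3", None, eligible=False, lead="rs8", lead_b=0.1, lead_p=0.2),
        ]
        training = make_sumstats("train", ["rs1", "rs8", "rs9"], b=[0.3, 0.1, 0.15], se=0.05)
        external = make_sumstats("ext", ["rs1"], b=0.2, se=0.05, p=0.01)
        panels = prs.build_tiered_panels(sels, external, training, 1e-5)
        t3 = panels[prs.TIER_PLUS_LEAD]
        assert set(t3.table.index) == {"rs1", "rs9"}  # rs8's lead p >= .05
        assert t3.table.at["rs9", "weight"] == pytest.approx(0.15)

    def test_published_panel_arithmetic(self):
        # 57 externally confirmed fine-mapped SNVs + 54 qualifying lead SNVs
        # must assemble into a 111-SNV third-tier panel
        fm = {f"fm{j}": 0.2 for j in range(60)}
        sels = [selection("big", fm)]
        ineligible = [
            selection(f"null{j}", None, eligible=False, lead=f"lead{j}", lead_b=0.1,
                      lead_p=0.01 if j < 54 else 0.5)
            for j in range(70)
        ]
        all_snvs = list(fm) + [f"lead{j}" for j in range(70)]
        training = make_sumstats("train", all_snvs, b=0.2, se=0.05)
        # 57 of the 60 selected SNVs confirm externally
        ext_b = [0.2] * 57 + [-0.2] * 3
        external = make_sumstats("ext", list(fm), b=ext_b, se=0.05, p=0.001)
        panels = prs.build_tiered_panels(sels + ineligible, external, training, 1e-5)
        assert panels[prs.TIER_CONSISTENT].n == 57
        assert panels[prs.TIER_PLUS_LEAD].n == 111

    def test_tier_membership_nesting(self):
        rng = np.random.default_rng(4)
        snvs = [f"rs{j}" for j in range(12)]
        sels = [selection("l1", {s: rng.normal(0.2, 0.1) for s in snvs[:8]}),
                selection("l2", None, eligible=False, lead="rs10", lead_b=0.1, lead_p=0.02)]
        training = make_sumstats("train", snvs, b=0.2, se=0.05)
        external = make_sumstats("ext", snvs[:6], b=rng.normal(0, 0.2, 6), se=0.1,
                                 p=rng.uniform(0, 0.2, 6))
        panels = prs.build_tiered_panels(sels, external, training, 1e-5)
        t1 = set(panels[prs.TIER_ALL].table.index)
        t2 = set(panels[prs.TIER_CONSISTENT].table.index)
        t3 = set(panels[prs.TIER_PLUS_LEAD].table.index)
        assert t2 <= t1 and t2 <= t3


class TestReweightExternalPanel:
    def test_internal_weights_equal_training_betas(self):
        training = make_sumstats("train", ["rs1", "rs2"], b=[0.3, -0.1], se=0.05)
        wp = prs.reweight_external_panel(["rs1", "rs2"], "internal", training_stats=training)
        np.testing.assert_allclose(wp.table["weight"], [0.3, -0.1])

    def test_meta_of_identical_sources_equals_either(self):
        s = make_sumstats("a", ["rs1", "rs2"], b=[0.3, -0.1], se=0.05)
        s2 = make_sumstats("b", ["rs1", "rs2"], b=[0.3, -0.1], se=0.05)
        wp = prs.reweight_external_panel(["rs1", "rs2"], "meta",
                                         external_stats=s, training_stats=s2)
        np.testing.assert_allclose(wp.table["weight"], [0.3, -0.1])

    def test_requested_minus_found_dropped_with_count(self):
        # 330 requested, 263 available -> a 263-SNV panel
        requested = [f"rs{j}" for j in range(330)]
        available = requested[:263]
        ext = make_sumstats("ext", available, b=0.1, se=0.05)
        wp = prs.reweight_external_panel(requested, "external", external_stats=ext)
        assert wp.n == 263

    def test_empty_intersection_errors(self):
        ext = make_sumstats("ext", ["rs1"], b=0.1, se=0.05)
        with pytest.raises(PanelMismatchError):
            prs.reweight_external_panel(["rsX"], "external", external_stats=ext)
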