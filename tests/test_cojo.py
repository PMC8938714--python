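"""Summary-statistics conditional/joint analysis against full-data oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from finerisk import assoc, cojo
from finerisk.errors import CollinearityError

from conftest import ar_locus_panel, case_control_locus, make_panel


@pytest.fixture(scope="module")
def quant_locus():
    """Quantitative trait on an AR(0.5) locus; LD reference = GWAS sample."""
    panel = ar_locus_panel(5000, 50, maf=0.3, ld=0.5, seed=33)
    rng = np.random.default_rng(8833)  # independent of the genotype stream
    beta = np.zeros(50)
    beta[[10, 30]] = 0.3
    y = panel.dosages @ beta + rng.standard_normal(5000)
    cohort = pd.DataFrame({"y": y, "status": 0, "study": "q"}, index=panel.samples)
    stats = assoc.single_snv_assoc(panel, cohort, trait="y", model="linear")
    ld = cojo.build_ld_reference(panel)
    return panel, y, stats, ld


class TestBuildLDReference:
    def test_duplicated_snv_has_unit_correlation(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.3, size=(200, 2)).astype(float)
        g = np.column_stack([g, g[:, 0]])
        ld = cojo.build_ld_reference(make_panel(g))
        assert ld.corr[0, 2] == pytest.approx(1.0)

    def test_independent_snvs_low_correlation(self):
        panel = ar_locus_panel(5000, 8, maf=0.3, ld=0.0, seed=2)
        ld = cojo.build_ld_reference(panel)
        off = ld.corr[~np.eye(8, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_ar_block_adjacent_correlation(self):
        panel = ar_locus_panel(5000, 10, maf=0.3, ld=0.9, seed=3)
        ld = cojo.build_ld_reference(panel)
        assert np.abs(np.diag(ld.corr, 1) - 0.9).max() < 0.05

    def test_zero_variance_excluded(self):
        rng = np.random.default_rng(4)
        g = rng.binomial(2, 0.3, size=(100, 3)).astype(float)
        g[:, 1] = 2.0
        panel = make_panel(g)
        ld = cojo.build_ld_reference(panel)
        assert panel.snvs.index[1] not in ld.snvs.index
        assert len(ld.snvs) == 2


class TestJointEstimates:
    @pytest.mark.parametrize("subset", [(10,), (10, 30), (5, 10, 11, 30, 45), (0, 10, 20, 30, 40, 49)])
    def test_matches_full_data_multiple_regression(self, quant_locus, subset):
        panel, y, stats, ld = quant_locus
        ids = [panel.snvs.index[j] for j in subset]
        joint = cojo.joint_estimates(stats, ids, ld)
        ols = sm.OLS(y, sm.add_constant(panel.dosages[:, list(subset)])).fit()
        np.testing.assert_allclose(joint["b"], ols.params[1:], rtol=1e-6)
        np.testing.assert_allclose(joint["se"], ols.bse[1:], rtol=1e-6)
        np.testing.assert_allclose(
            joint["p"], np.clip(ols.pvalues[1:], np.finfo(float).tiny, 1.0), rtol=1e-4
        )

    def test_single_snv_equals_marginal(self, quant_locus):
        panel, _, stats, ld = quant_locus
        snv = panel.snvs.index[10]
        joint = cojo.joint_estimates(stats, [snv], ld)
        assert joint.at[snv, "b"] == pytest.approx(stats.table.at[snv, "b"], rel=1e-12)
        assert joint.at[snv, "se"] == pytest.approx(stats.table.at[snv, "se"], rel=1e-12)

    def test_uncorrelated_snvs_keep_marginal_betas(self):
        # identity LD: the joint system decouples exactly
        panel = ar_locus_panel(4000, 6, maf=0.3, ld=0.0, seed=5)
        rng = np.random.default_rng(1005)
        y = panel.dosages[:, 2] * 0.3 + rng.standard_normal(4000)
        cohort = pd.DataFrame({"y": y, "status": 0, "study": "q"}, index=panel.samples)
        stats = assoc.single_snv_assoc(panel, cohort, trait="y", model="linear")
        ld = cojo.build_ld_reference(panel)
        ld.corr = np.eye(6)
        joint = cojo.joint_estimates(stats, list(panel.snvs.index), ld)
        np.testing.assert_allclose(joint["b"], stats.table["b"], rtol=1e-12)

    def test_collinear_pair_raises_with_names(self, quant_locus):
        panel, _, stats, ld = quant_locus
        rng = np.random.default_rng(6)
        g = panel.dosages[:, [10]].repeat(2, axis=1)
        dup = make_panel(g, prefix="dup")
        y = g[:, 0] * 0.3 + rng.standard_normal(len(g))
        cohort = pd.DataFrame({"y": y, "status": 0, "study": "q"}, index=dup.samples)
        dstats = assoc.single_snv_assoc(dup, cohort, trait="y", model="linear")
        dld = cojo.build_ld_reference(dup)
        with pytest.raises(CollinearityError) as err:
            cojo.joint_estimates(dstats, list(dup.snvs.index), dld)
        assert set(err.value.pair) == set(dup.snvs.index)


class TestConditionalEstimates:
    def test_empty_conditioning_returns_marginal(self, quant_locus):
        panel, _, stats, ld = quant_locus
        snv = panel.snvs.index[30]
        est = cojo.conditional_estimates(stats, snv, [], ld)
        assert est.b == pytest.approx(stats.table.at[snv, "b"])
        assert est.p == pytest.approx(stats.table.at[snv, "p"])
        assert not est.collinear

    def test_perfectly_correlated_candidate_flagged(self):
        rng = np.random.default_rng(7)
        base = rng.binomial(2, 0.3, size=(1000, 1)).astype(float)
        panel = make_panel(np.column_stack([base, base]))
        y = base[:, 0] * 0.4 + rng.standard_normal(1000)
        cohort = pd.DataFrame({"y": y, "status": 0, "study": "q"}, index=panel.samples)
        stats = assoc.single_snv_assoc(panel, cohort, trait="y", model="linear")
        ld = cojo.build_ld_reference(panel)
        est = cojo.conditional_estimates(stats, panel.snvs.index[1], [panel.snvs.index[0]], ld)
        assert est.collinear and est.p == 1.0

    def test_ld_shadow_has_no_conditional_signal(self):
        # a pure LD proxy of the causal SNV: marginal signal, no conditional one
        panel = ar_locus_panel(20_000, 2, maf=0.3, ld=0.85, seed=8)
        rng = np.random.default_rng(1008)
        y = panel.dosages[:, 0] * 0.4 + rng.standard_normal(20_000)
        cohort = pd.DataFrame({"y": y, "status": 0, "study": "q"}, index=panel.samples)
        stats = assoc.single_snv_assoc(panel, cohort, trait="y", model="linear")
        ld = cojo.build_ld_reference(panel)
        shadow = panel.snvs.index[1]
        assert stats.table.at[shadow, "p"] < 1e-8
        est = cojo.conditional_estimates(stats, shadow, [panel.snvs.index[0]], ld)
        assert est.p > 0.05


class TestStepwiseSelect:
    def test_locus_below_threshold_is_ineligible(self, quant_locus):
        panel, _, stats, ld = quant_locus
        weak = stats.table.copy()
        weak["p"] = np.maximum(weak["p"], 1e-4)
        from finerisk.containers import SummaryStatSet

        res = cojo.stepwise_select(SummaryStatSet("w", weak), ld, p_threshold=1e-5)
        assert not res.eligible
        assert res.selected == []
        assert res.lead_snv is not None and res.lead_p >= 1e-5

    def test_two_causal_snvs_tagged(self):
        panel, cohort, causal = case_control_locus(seed=41, n=20_000)
        stats = assoc.single_snv_assoc(panel, cohort)
        ld = cojo.build_ld_reference(panel)
        res = cojo.stepwise_select(stats, ld, p_threshold=1e-5)
        assert res.eligible
        corr = pd.DataFrame(ld.corr, index=ld.snvs.index, columns=ld.snvs.index)
        for c in causal:
            assert max(corr.loc[c, s] ** 2 for s in res.selected) > 0.8
        assert (res.joint["p"] < 1e-5).all()

    def test_shadow_pair_yields_single_selection(self):
        panel = ar_locus_panel(20_000, 2, maf=0.3, ld=0.95, seed=9)
        rng = np.random.default_rng(1009)
        y = panel.dosages[:, 0] * 0.4 + rng.standard_normal(20_000)
        cohort = pd.DataFrame({"y": y, "status": 0, "study": "q"}, index=panel.samples)
        stats = assoc.single_snv_assoc(panel, cohort, trait="y", model="linear")
        ld = cojo.build_ld_reference(panel)
        res = cojo.stepwise_select(stats, ld, p_threshold=1e-5)
        assert len(res.selected) == 1

    def test_deterministic_selection_order(self):
        panel, cohort, _ = case_control_locus(seed=43, n=12_000)
        stats = assoc.single_snv_assoc(panel, cohort)
        ld = cojo.build_ld_reference(panel)
        r1 = cojo.stepwise_select(stats, ld, p_threshold=1e-5)
        r2 = cojo.stepwise_select(stats, ld, p_threshold=1e-5)
        assert r1.selected == r2.selected
        pd.testing.assert_frame_equal(r1.joint, r2.joint)

    def test_selected_snvs_below_r2_guard(self):
        panel, cohort, _ = case_control_locus(seed=44, n=15_000, ld=0.7)
        stats = assoc.single_snv_assoc(panel, cohort)
        ld = cojo.build_ld_reference(panel)
        res = cojo.stepwise_select(stats, ld, p_threshold=1e-4)
        if len(res.selected) > 1:
            sub = ld.submatrix(res.selected) ** 2
            np.fill_diagonal(sub, 0)
            assert sub.max() <= cojo.R2_GUARD_DEFAULT

    def test_relaxed_threshold_rarely_shrinks_selection(self):
        wins = 0
        for seed in (51, 52, 53, 54, 55):
            panel, cohort, _ = case_control_locus(seed=seed, n=10_000, m=30, causal=(8, 22))
            stats = assoc.single_snv_assoc(panel, cohort)
            ld = cojo.build_ld_reference(panel)
            strict = cojo.stepwise_select(stats, ld, p_threshold=1e-5)
            relaxed = cojo.stepwise_select(stats, ld, p_threshold=1e-3)
            wins += len(relaxed.selected) >= len(strict.selected)
        assert wins >= 4


class TestDefineLoci:
    def _index(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "p"],
                            index=pd.Index([f"rs{i}" for i in range(len(rows))], name="snv"))

    def test_distant_indices_stay_separate(self):
        loci = cojo.define_loci(self._index([("1", 1_000_000, 1e-9), ("1", 3_000_000, 1e-7)]),
                                half_width=500_000)
        assert len(loci) == 2

    def test_close_indices_merge_keeping_smaller_p(self):
        loci = cojo.define_loci(self._index([("1", 1_000_000, 1e-7), ("1", 1_300_000, 1e-9)]),
                                half_width=500_000)
        assert len(loci) == 1
        assert loci[0].index_snv == "rs1"
        assert loci[0].start == 500_000 and loci[0].end == 1_800_000

    def test_single_index_window(self):
        loci = cojo.define_loci(self._index([("2", 700_000, 1e-8)]), half_width=500_000)
        assert (loci[0].start, loci[0].end) == (200_000, 1_200_000)
        assert loci[0].contains(200_000) and not loci[0].contains(1_200_000)

    def test_members_assigned_from_metadata(self):
        meta = pd.DataFrame({"chrom": ["1", "1", "2"], "pos": [900_000, 2_000_000, 950_000]},
                            index=pd.Index(["a", "b", "c"], name="snv"))
        loci = cojo.define_loci(self._index([("1", 1_000_000, 1e-9)]), half_width=500_000,
                                snv_meta=meta)
        assert loci[0].members == ["a"]
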