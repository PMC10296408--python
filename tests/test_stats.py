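import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fnirs_vhdr.calibration import null_metric_tables
from fnirs_vhdr.reference_cohort import fasd_ages, fasd_clinical_table
from fnirs_vhdr.stats import (
    StatsConfig,
    bh_fdr,
    demographic_summary,
    independent_t,
    mixed_anova,
    paired_t,
    run_full_stats,
    spearman,
)


class TestPairedT:
    def test_identical_samples_give_null_result(self, rng):
        x = rng.normal(size=10)  # internal variation, zero difference
        res = paired_t(x, x.copy())
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_swap_flips_sign(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=8)
        a = paired_t(x, y)
        b = paired_t(y, x)
        assert b.statistic == pytest.approx(-a.statistic)
        assert b.p == pytest.approx(a.p)

    def test_hand_computation(self):
        res = paired_t(np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0]))
        assert res.statistic == pytest.approx(2.0 / (1.0 / np.sqrt(3)), abs=1e-3)
        assert res.df == 2

    def test_zero_variance_named_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t(np.array([1.0, 2.0, 3.0]), np.array([0.0, 1.0, 2.0]))


class TestIndependentT:
    def test_identical_groups(self, rng):
        g = rng.normal(size=10)
        res = independent_t(g, g.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_student(self):
        res = independent_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], welch=False)
        assert res.statistic == pytest.approx(-3.674, abs=1e-3)
        assert res.df == 4

    def test_p_monotone_in_shift(self, rng):
        g1 = rng.normal(size=12)
        g2 = rng.normal(size=12)
        ps = [independent_t(g1 + c, g2).p for c in (1.0, 2.0, 4.0)]
        assert ps[0] > ps[1] > ps[2]

    def test_degenerate_variance_error(self):
        with pytest.raises(ValueError):
            independent_t([1.0, 1.0], [1.0, 1.0])


class TestMixedAnova:
    @staticmethod
    def _table(values, groups):
        rows = []
        for i, ((l, r), g) in enumerate(zip(values, groups)):
            rows.append({"subject": f"s{i}", "group": g, "hemisphere": "left", "value": l})
            rows.append({"subject": f"s{i}", "group": g, "hemisphere": "right", "value": r})
        return pd.DataFrame(rows)

    def test_small_balanced_oracle(self):
        """F values match a hand-computed sums-of-squares decomposition on a
        2 groups x 2 subjects x 2 hemispheres table."""
        values = [(1.0, 2.0), (2.0, 4.0), (4.0, 2.0), (5.0, 3.0)]
        groups = ["A", "A", "B", "B"]
        res = {r.name.split("_")[-1]: r for r in mixed_anova(self._table(values, groups))}
        x = np.array(values)
        grand = x.mean()
        subj = x.mean(axis=1)
        hemi = x.mean(axis=0)
        ss_between = 2 * ((subj - grand) ** 2).sum()
        ga, gb = x[:2].mean(), x[2:].mean()
        ss_group = 2 * 2 * ((ga - grand) ** 2 + (gb - grand) ** 2)
        ss_subj = ss_between - ss_group
        ss_within = ((x - subj[:, None]) ** 2).sum()
        ss_hemi = 4 * ((hemi - grand) ** 2).sum()
        ss_int = sum(
            2 * ((x[sl].mean(axis=0) - x[sl].mean() - hemi + grand) ** 2).sum()
            for sl in (slice(0, 2), slice(2, 4))
        )
        ss_err = ss_within - ss_hemi - ss_int
        assert res["group"].statistic == pytest.approx((ss_group / 1) / (ss_subj / 2))
        assert res["hemisphere"].statistic == pytest.approx((ss_hemi / 1) / (ss_err / 2))
        assert res["interaction"].statistic == pytest.approx((ss_int / 1) / (ss_err / 2))

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        values = rng.normal(size=(12, 2)).tolist()
        groups = ["A"] * 6 + ["B"] * 6
        table = self._table(values, groups)
        ours = {r.name.split("_")[-1]: r for r in mixed_anova(table)}
        table2 = table.copy()
        pg = pingouin.mixed_anova(
            data=table2, dv="value", within="hemisphere", subject="subject", between="group"
        ).set_index("Source")
        assert ours["group"].statistic == pytest.approx(pg.loc["group", "F"], rel=1e-6)
        assert ours["hemisphere"].statistic == pytest.approx(pg.loc["hemisphere", "F"], rel=1e-6)
        assert ours["interaction"].statistic == pytest.approx(pg.loc["Interaction", "F"], rel=1e-6)
        assert ours["group"].p == pytest.approx(pg.loc["group", "p_unc"], rel=1e-6)

    def test_location_invariance(self, rng):
        values = rng.normal(size=(10, 2))
        groups = ["A"] * 5 + ["B"] * 5
        a = mixed_anova(self._table(values.tolist(), groups))
        b = mixed_anova(self._table((values + 100.0).tolist(), groups))
        for ra, rb in zip(a, b):
            assert rb.statistic == pytest.approx(ra.statistic, rel=1e-9, abs=1e-9)

    def test_duplicated_hemispheres_zero_f(self, rng):
        vals = rng.normal(size=10)
        values = [(v, v) for v in vals]
        groups = ["A"] * 5 + ["B"] * 5
        res = {r.name.split("_")[-1]: r for r in mixed_anova(self._table(values, groups))}
        assert res["hemisphere"].statistic == 0.0
        assert res["hemisphere"].p == 1.0

    def test_incomplete_subject_dropped(self, rng):
        table = self._table(rng.normal(size=(6, 2)).tolist(), ["A"] * 3 + ["B"] * 3)
        table = table.drop(index=0)  # s0 loses its left hemisphere
        res = mixed_anova(table)
        assert res[0].n == 5


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman(x, np.exp(x)).statistic == pytest.approx(1.0)
        assert spearman(x, -(x**3)).statistic == pytest.approx(-1.0)

    def test_hand_rank_formula(self):
        res = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.statistic == pytest.approx(0.8)

    def test_pairwise_deletion_and_minimum_n(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 1.0, 3.0, np.nan, 5.0]
        res = spearman(x, y)
        assert res.n == 3
        with pytest.raises(ValueError):
            spearman([1.0, np.nan, 3.0], [np.nan, 2.0, 3.0])

    def test_invariance_under_monotone_transform(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = spearman(x, y).statistic
        assert spearman(np.exp(x), y).statistic == pytest.approx(base)
        assert spearman(x, y**3).statistic == pytest.approx(base)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_step_up_hand_example(self):
        adj = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_bounds_and_monotonicity(self, ps):
        p = np.array(ps)
        adj = bh_fdr(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= np.minimum(1.0, p * p.size) + 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestDemographics:
    def test_reference_cohort_summary(self):
        median, sd, median_r, sd_r = demographic_summary(fasd_ages())
        assert median_r == 4.5
        assert sd_r == 1.17

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            demographic_summary([5.0])
        median, sd, *_ = demographic_summary([1, 1, 1, 1])
        assert median == 1.0
        assert sd == 0.0
        with pytest.raises(ValueError):
            demographic_summary([])


class TestRunFullStats:
    def test_structure_and_families(self, rng):
        metrics, clinical = null_metric_tables(rng=rng)
        res = run_full_stats(metrics, clinical)
        assert set(res.columns) >= {"test", "family", "statistic", "df", "p", "p_adj"}
        assert set(res["family"]) == {
            "reliability", "amplitude", "latency", "lateralization", "correlations"}
        assert (res["p_adj"] >= res["p"] - 1e-12).all()
        assert (res["p_adj"] <= 1.0).all()
        assert (res["family"] == "correlations").sum() == 8

    def test_deterministic_rerun(self, rng):
        metrics, clinical = null_metric_tables(rng=rng)
        a = run_full_stats(metrics, clinical)
        b = run_full_stats(metrics, clinical)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_columns_named(self, rng):
        metrics, clinical = null_metric_tables(rng=rng)
        broken = metrics[metrics.metric != "peak_left"]
        with pytest.raises(ValueError, match="peak_left"):
            run_full_stats(broken, clinical)

    def test_missing_clinical_values_reduce_n(self, rng):
        metrics, _ = null_metric_tables(rng=rng)
        clinical = fasd_clinical_table().copy()
        clinical["subject_id"] = [f"ASD{i + 1:02d}" for i in range(12)]
        res = run_full_stats(metrics, clinical).set_index("test")
        assert int(res.loc["corr_LI_AQ_tot", "n"]) == 11  # one AQ value missing
        assert int(res.loc["corr_LI_VABS_tot", "n"]) == 11
        assert int(res.loc["corr_LI_ADOS_TOT", "n"]) == 11
        assert int(res.loc["corr_LI_nv_IQ", "n"]) == 12
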