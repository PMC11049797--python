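import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from beecolor.group_statistics import (
    boxcox_transform,
    check_assumptions,
    run_inference,
    tukey_hsd,
    two_way_anova,
)

GROUPS = ("30gray", "30yellow", "34gray", "34yellow")


def _factorial(rng, n=30, means=(0, 0, 0, 0), sd=1.0):
    values, colony, temp = [], [], []
    for mu, g in zip(means, GROUPS):
        values.append(rng.normal(mu, sd, n))
        colony += [g[2:]] * n
        temp += [int(g[:2])] * n
    return np.concatenate(values), np.array(colony), np.array(temp)


class TestBoxCox:
    def test_fixed_lambda_definitions(self, rng):
        x = rng.uniform(1, 10, 50)
        np.testing.assert_allclose(boxcox_transform(x, lmbda=1).transformed, x - 1)
        np.testing.assert_allclose(boxcox_transform(x, lmbda=0).transformed, np.log(x))

    def test_mle_recovers_log_for_lognormal(self, rng):
        x = np.exp(rng.normal(0, 0.6, 500))
        res = boxcox_transform(x)
        assert -0.3 <= res.lmbda <= 0.3
        assert np.isfinite(res.log_likelihood)

    def test_transform_is_monotone(self, rng):
        x = np.sort(rng.uniform(0.1, 30, 100))
        t = boxcox_transform(x).transformed
        assert (np.diff(t) >= 0).all()

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            boxcox_transform(np.array([1.0, 0.0, 2.0]))


class TestAssumptions:
    def test_identical_groups_give_unit_variance_ratio(self):
        x = np.tile(np.array([1.0, 2.0, 3.0, 4.0]), 4)
        groups = np.repeat(GROUPS, 4)
        rep = check_assumptions(x, groups)
        assert rep.variance_max_ratio == pytest.approx(1.0)

    def test_shapiro_detects_exponential_departure(self):
        rng = np.random.default_rng(11)
        rejections = sum(
            st.shapiro(rng.exponential(1.0, 50)).pvalue < 0.05 for _ in range(40)
        )
        assert rejections >= 36  # > 90% power at n=50
        # and the wrapper reports the same quantity on grouped data
        values, colony, temp = _factorial(rng, n=20)
        groups = np.array([f"{t}{c}" for c, t in zip(colony, temp)])
        rep = check_assumptions(np.exp(values * 2), groups)
        assert rep.shapiro_residuals_p < 0.05

    def test_normal_data_rarely_rejected(self, rng):
        rejections = 0
        for _ in range(40):
            values, colony, temp = _factorial(rng, n=25)
            groups = np.array([f"{t}{c}" for c, t in zip(colony, temp)])
            rep = check_assumptions(values, groups)
            rejections += rep.shapiro_residuals_p < 0.05
        assert rejections <= 8  # nominal 5% level, generous margin

    def test_levene_alternative_and_small_group_error(self, rng):
        values, colony, temp = _factorial(rng, n=10)
        groups = np.array([f"{t}{c}" for c, t in zip(colony, temp)])
        rep = check_assumptions(values, groups, method="levene")
        assert 0 <= rep.variance_p <= 1
        with pytest.raises(ValueError, match="n=2 < 3"):
            check_assumptions(np.arange(4.0), np.array(["a", "a", "b", "b"]))


class TestTwoWayAnova:
    def test_type_i_equals_type_ii_when_balanced(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        values, colony, temp = _factorial(rng, n=12, means=(0, 1, 0.5, 1.5))
        report = two_way_anova(values, colony, temp)
        df = pd.DataFrame(
            {"value": values, "colony": colony, "temperature": temp.astype(str)}
        )
        model = smf.ols("value ~ C(colony) * C(temperature)", data=df).fit()
        typ1 = sm.stats.anova_lm(model, typ=1)
        np.testing.assert_allclose(
            report.terms["F"].to_numpy(), typ1["F"].to_numpy()[:3], rtol=1e-10
        )
        assert report.residual_df == 4 * 12 - 4

    def test_detects_main_effect_and_respects_null_factor(self, rng):
        hits_a, hits_b = 0, 0
        for _ in range(20):
            # colony shifted by 1.5 SD, temperature exactly null
            values, colony, temp = _factorial(
                rng, n=50, means=(0, 1.5, 0, 1.5), sd=1.0
            )
            rep = two_way_anova(values, colony, temp)
            hits_a += rep.p_origin < 0.001
            hits_b += rep.p_temperature < 0.05
        assert hits_a >= 19
        assert hits_b <= 4  # ~5% false positive rate

    def test_empty_or_thin_cells_rejected(self):
        with pytest.raises(ValueError, match="factorial"):
            two_way_anova(
                np.arange(7.0),
                np.array(["g", "g", "g", "g", "y", "y", "y"]),
                np.array([30, 30, 34, 34, 30, 30, 30]),
            )
        with pytest.raises(ValueError, match="n >= 2"):
            two_way_anova(
                np.arange(7.0),
                np.array(["g", "g", "g", "g", "y", "y", "y"]),
                np.array([30, 30, 34, 34, 30, 30, 34]),
            )


class TestTukey:
    def test_six_contrasts_for_four_groups(self, rng):
        values, colony, temp = _factorial(rng, n=10)
        groups = np.array([f"{t}{c}" for c, t in zip(colony, temp)])
        table = tukey_hsd(values, groups)
        assert len(table) == 6
        assert set(table.columns) >= {"group1", "group2", "estimate", "p_adj"}

    def test_large_separation_is_significant(self, rng):
        values, colony, temp = _factorial(rng, n=50, means=(0, 5, 0, 5))
        groups = np.array([f"{t}{c}" for c, t in zip(colony, temp)])
        table = tukey_hsd(values, groups)
        row = table.set_index(["group1", "group2"]).loc[("30gray", "30yellow")]
        assert row["p_adj"] < 0.001

    def test_adjusted_p_not_below_unadjusted_t(self, rng):
        values, colony, temp = _factorial(rng, n=15, means=(0, 0.5, 1.0, 0.2))
        groups = np.array([f"{t}{c}" for c, t in zip(colony, temp)])
        table = tukey_hsd(values, groups)
        # pooled-MSE pairwise t-test p-values as the unadjusted reference
        k = len(GROUPS)
        n = 15
        mse = np.mean(
            [values[groups == g].var(ddof=1) for g in GROUPS]
        )
        df = k * n - k
        for _, row in table.iterrows():
            tstat = abs(row["estimate"]) / np.sqrt(mse * 2 / n)
            p_unadj = 2 * st.t.sf(tstat, df)
            assert row["p_adj"] >= p_unadj - 1e-12

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError, match="n < 2"):
            tukey_hsd(np.arange(5.0), np.array(["a", "a", "b", "b", "c"]))


class TestRunInference:
    @staticmethod
    def _tables(rng, skewed=False, n=25):
        values, colony, temp = _factorial(rng, n=n, means=(440, 455, 445, 458), sd=20)
        if skewed:
            # right-skewed multiplicative noise around the index scale
            values = np.exp(rng.normal(np.log(450.0), 0.3, values.size))
        ids = [f"s{i}" for i in range(values.size)]
        indices = pd.DataFrame({"specimen_id": ids, "index": values})
        meta = pd.DataFrame(
            {"specimen_id": ids, "colony": colony, "temperature": temp}
        )
        return indices, meta

    def test_normal_input_skips_boxcox(self, rng):
        indices, meta = self._tables(rng)
        report = run_inference(indices, meta)
        assert report.anova.transform == "none"
        assert report.anova.boxcox_lambda is None
        assert any("transform: none" in line for line in report.log)

    def test_skewed_input_triggers_boxcox(self, rng):
        indices, meta = self._tables(rng, skewed=True)
        report = run_inference(indices, meta)
        assert report.anova.transform == "boxcox"
        assert report.anova.boxcox_lambda is not None

    def test_report_structure(self, rng):
        indices, meta = self._tables(rng)
        report = run_inference(indices, meta)
        d = report.to_dict()
        terms = {row["term"] for row in d["anova"]}
        assert terms == {"colony", "temperature", "colony:temperature"}
        assert len(d["tukey"]) == 6
        for key in ("p_origin", "p_temperature", "p_interaction"):
            assert 0 <= getattr(report.anova, key.replace("p_", "p_")) <= 1

    def test_transform_can_be_forced(self, rng):
        indices, meta = self._tables(rng)
        forced = run_inference(indices, meta, transform="always")
        assert forced.anova.transform == "boxcox"
        never = run_inference(indices, meta, transform="never")
        assert never.anova.transform == "none"
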