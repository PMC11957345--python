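import math

import numpy as np
import pytest
from scipy import integrate

from thgswell.stats import (
    GroupSample,
    f_sf,
    gg_epsilon,
    group_report,
    mixed_rm_anova_gg,
    one_way_anova,
    t_sf,
    two_sample_t,
)


def t_density(x, df):
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    return c * (1 + x * x / df) ** (-(df + 1) / 2)


def f_density(x, d1, d2):
    logc = (
        (d1 / 2) * math.log(d1 / d2)
        + math.lgamma((d1 + d2) / 2) - math.lgamma(d1 / 2) - math.lgamma(d2 / 2)
    )
    return math.exp(logc) * x ** (d1 / 2 - 1) * (1 + d1 * x / d2) ** (-(d1 + d2) / 2)


class TestSurvivalFunctions:
    def test_zero_statistic_gives_p_one(self):
        assert t_sf(0.0, 5) == pytest.approx(1.0)
        assert f_sf(0.0, 3, 12) == pytest.approx(1.0)

    def test_published_t_value(self):
        assert t_sf(1.921, 6) == pytest.approx(0.1031, abs=5e-5)

    def test_cauchy_quantile(self):
        # t(12.706, 1) brackets the classical 95% two-tailed point
        assert t_sf(12.706, 1) == pytest.approx(0.0500, abs=5e-5)

    def test_published_f_value(self):
        assert f_sf(0.982, 3, 12) == pytest.approx(0.4337, abs=5e-4)

    @pytest.mark.parametrize("t,df", [(0.5, 3.0), (1.921, 6.0), (2.5, 7.3)])
    def test_f_equals_squared_t(self, t, df):
        assert f_sf(t * t, 1.0, df) == pytest.approx(t_sf(t, df), rel=1e-10)

    @pytest.mark.parametrize("t,df", [(0.7, 2.5), (1.5, 6.0), (3.0, 11.7)])
    def test_t_sf_matches_quadrature_oracle(self, t, df):
        oracle, _ = integrate.quad(t_density, t, np.inf, args=(df,))
        assert t_sf(t, df) == pytest.approx(2 * oracle, abs=1e-8)

    @pytest.mark.parametrize("F,d1,d2", [(0.982, 3.0, 12.0), (2.978, 1.196, 7.173),
                                         (1.5, 2.5, 9.0)])
    def test_f_sf_matches_quadrature_oracle(self, F, d1, d2):
        oracle, _ = integrate.quad(f_density, F, np.inf, args=(d1, d2))
        assert f_sf(F, d1, d2) == pytest.approx(oracle, abs=1e-8)

    def test_invalid_dfs_rejected(self):
        with pytest.raises(ValueError):
            t_sf(1.0, 0.0)
        with pytest.raises(ValueError):
            f_sf(1.0, -1.0, 5.0)


class TestTwoSampleT:
    def test_identical_samples(self):
        r = two_sample_t([1, 2, 3], [1, 2, 3])
        assert r.statistic == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_hand_computed_pooled_example(self):
        r = two_sample_t([1, 2, 3], [2, 3, 4], variant="pooled")
        assert r.statistic == pytest.approx(-1.2247, abs=1e-4)
        assert r.df1 == 4

    def test_welch_df_never_exceeds_pooled(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.normal(0, 1, 6)
            y = rng.normal(0, 3, 9)
            pooled = two_sample_t(x, y, "pooled")
            welch = two_sample_t(x, y, "welch")
            assert welch.df1 <= pooled.df1 + 1e-12

    def test_matches_scipy(self):
        from scipy import stats as sps

        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 2, 5)
        ours = two_sample_t(x, y, "welch")
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [2.0, 3.0])


class TestOneWayAnova:
    def test_degenerate_identical_data(self):
        r = one_way_anova([[2.0, 2.0], [2.0, 2.0]])
        assert r.statistic == 0.0 and r.p == 1.0

    def test_two_groups_reduce_to_squared_t(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 7), rng.normal(1, 1, 5)
        anova = one_way_anova([x, y])
        t = two_sample_t(x, y, "pooled")
        assert anova.statistic == pytest.approx(t.statistic ** 2, rel=1e-10)
        assert anova.p == pytest.approx(t.p, rel=1e-10)

    def test_matches_scipy(self):
        from scipy import stats as sps

        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1, 6) for m in (0, 0.5, 1)]
        ours = one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-10)

    def test_type_i_error_near_nominal(self):
        """4 groups × n = 4 under the null, 2000 reps: rejection rate at
        α = 0.05 stays within 0.05 ± 0.01."""
        rng = np.random.default_rng(4)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            groups = rng.standard_normal((4, 4))
            if one_way_anova(groups).p < 0.05:
                rejections += 1
        assert abs(rejections / reps - 0.05) <= 0.01


def _cs_cov(k, var=2.0, rho=0.5):
    S = np.full((k, k), rho * var)
    np.fill_diagonal(S, var)
    return S


class TestGreenhouseGeisser:
    def test_compound_symmetry_gives_unit_epsilon(self):
        for k in (3, 4, 6):
            assert gg_epsilon(_cs_cov(k)) == pytest.approx(1.0, abs=1e-12)

    def test_lower_bound_on_random_covariances(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            k = rng.integers(3, 6)
            A = rng.standard_normal((k, k + 2))
            eps = gg_epsilon(A @ A.T)
            assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_mixed_anova_matches_longhand_oracle(self):
        """3 levels × 8 donors (two groups of 4): F, ε and p computed
        independently step by step."""
        y = np.array([
            [10.0, 12.0, 15.0],
            [11.0, 12.5, 14.0],
            [9.0, 11.0, 12.0],
            [10.5, 13.0, 16.0],
            [8.0, 8.5, 9.5],
            [7.5, 9.0, 9.0],
            [8.2, 8.8, 10.1],
            [7.9, 9.5, 10.4],
        ])
        groups = np.array(["A"] * 4 + ["B"] * 4)
        res = mixed_rm_anova_gg(y, groups)

        # --- longhand decomposition ---
        n, k, g = 8, 3, 2
        grand = y.mean()
        ss_total = ((y - grand) ** 2).sum()
        subj = y.mean(axis=1)
        ss_subj = k * ((subj - grand) ** 2).sum()
        ga, gb = y[:4], y[4:]
        ss_group = k * 4 * (ga.mean() - grand) ** 2 + k * 4 * (gb.mean() - grand) ** 2
        ss_level = n * ((y.mean(axis=0) - grand) ** 2).sum()
        ss_cells = 4 * ((ga.mean(axis=0) - grand) ** 2).sum() \
            + 4 * ((gb.mean(axis=0) - grand) ** 2).sum()
        ss_inter = ss_cells - ss_group - ss_level
        ss_err_w = ss_total - ss_subj - ss_level - ss_inter
        F_level = (ss_level / (k - 1)) / (ss_err_w / ((n - g) * (k - 1)))
        pooled = ((ga - ga.mean(0)).T @ (ga - ga.mean(0))
                  + (gb - gb.mean(0)).T @ (gb - gb.mean(0))) / (n - g)
        d = np.trace(pooled) / k
        m = pooled.mean()
        r = pooled.mean(axis=1)
        eps = k ** 2 * (d - m) ** 2 / (
            (k - 1) * ((pooled ** 2).sum() - 2 * k * (r ** 2).sum() + k ** 2 * m ** 2)
        )
        assert res["within"].statistic == pytest.approx(F_level, rel=1e-10)
        assert res["within"].epsilon == pytest.approx(eps, rel=1e-10)
        assert res["within"].df1 == pytest.approx(eps * (k - 1), rel=1e-10)
        assert res["within"].p == pytest.approx(
            f_sf(F_level, eps * (k - 1), eps * (n - g) * (k - 1)), rel=1e-12)

    def test_cross_check_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(6)
        n, k = 10, 3
        y = rng.normal(0, 1, (n, k)) + rng.normal(0, 1, (n, 1))
        groups = np.array(["A"] * 5 + ["B"] * 5)
        rows = [
            {"donor": i, "group": groups[i], "level": j, "y": y[i, j]}
            for i in range(n) for j in range(k)
        ]
        df = pd.DataFrame(rows)
        ref = pg.mixed_anova(df, dv="y", within="level", subject="donor",
                             between="group", correction=True)
        res = mixed_rm_anova_gg(y, groups)
        within = ref[ref.Source == "level"].iloc[0]
        inter = ref[ref.Source == "Interaction"].iloc[0]
        assert res["within"].statistic == pytest.approx(within.F, rel=1e-6)
        assert res["interaction"].statistic == pytest.approx(inter.F, rel=1e-6)

    def test_gg_correction_is_conservative_for_large_f(self):
        # shrinking both dfs raises the upper-tail p whenever F >= 1, which
        # is the regime where the correction matters
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(60):
            y = rng.normal(0, 1, (9, 4)) * rng.uniform(0.5, 2, size=4)
            y[:, 2] += rng.uniform(0, 1.0)
            groups = np.array(["A"] * 5 + ["B"] * 4)
            w = mixed_rm_anova_gg(y, groups)["within"]
            if w.statistic < 2.0:
                continue
            uncorrected = f_sf(w.statistic, 3.0, (9 - 2) * 3.0)
            assert w.p >= uncorrected - 1e-12
            checked += 1
        assert checked >= 10

    def test_incomplete_rows_rejected(self):
        y = np.array([[1.0, np.nan, 2.0], [1.0, 2.0, 3.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError):
            mixed_rm_anova_gg(y, ["A", "A", "B"])


class TestGroupReport:
    @staticmethod
    def _samples(seed=0, effect=2.5e5):
        rng = np.random.default_rng(seed)
        samples = []
        for i in range(5):
            samples.append(GroupSample(
                donor=f"ms{i}", group="MS",
                densities={125: 0.6e5 + effect + rng.normal(0, 1.6e5),
                           133: 0.7e5 + effect + rng.normal(0, 1.6e5),
                           140: 0.8e5 + effect + rng.normal(0, 1.6e5)}))
        for i in range(6):
            samples.append(GroupSample(
                donor=f"hc{i}", group="non-MS",
                densities={125: 0.6e5 + rng.normal(0, 0.2e5),
                           133: 0.65e5 + rng.normal(0, 0.2e5),
                           140: 0.7e5 + rng.normal(0, 0.2e5)}))
        return samples

    def test_single_group_single_level_summary(self):
        samples = [GroupSample(donor=str(i), group="MS", densities={125: v})
                   for i, v in enumerate([1.0, 2.0, 3.0])]
        report = group_report(samples)
        row = report["summary"].iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["std"] == pytest.approx(1.0)
        assert row["n"] == 3

    def test_contains_design_comparisons(self):
        samples = self._samples()
        for i in range(3):
            samples.append(GroupSample(
                donor=f"alln{i}", group="MS", treatment="ALLN",
                densities={125: 1.0e5, 133: 1.1e5, 140: 1.0e5}))
        report = group_report(samples)
        assert {"baseline", "sodium", "sodium_interaction", "alln"} <= \
            set(report["tests"])
        assert report["tests"]["sodium"].epsilon is not None

    def test_label_swap_negates_t(self):
        samples = self._samples()
        swapped = [GroupSample(s.donor, {"MS": "non-MS", "non-MS": "MS"}[s.group],
                               s.treatment, s.densities) for s in samples]
        a = group_report(samples)["tests"]["baseline"]
        b = group_report(swapped)["tests"]["baseline"]
        assert a.statistic == pytest.approx(-b.statistic, rel=1e-10)
        assert a.p == pytest.approx(b.p, rel=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            group_report([])
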