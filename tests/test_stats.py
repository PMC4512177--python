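"""Group statistics: effect sizes, ANOVA family, savings contrasts."""

import numpy as np
import pandas as pd
import pytest

from eyeblink.stats import (
    DataError,
    UsageError,
    ancova_age_tukey,
    build_learning_curves,
    cohens_dprime,
    last_four_mean,
    oneway_anova_bonferroni,
    paired_t,
    rm_anova_2way,
    savings_summary,
    simulate_null_metric_curves,
    unpaired_t,
)


class TestCohensDprime:
    def test_identical_groups_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert cohens_dprime(a, a.copy()) == 0.0

    def test_unit_shift_unit_sd(self, rng):
        a = rng.normal(0, 1, 100000)
        b = a + 1.0
        assert cohens_dprime(a, b) == pytest.approx(1.0, abs=0.02)

    def test_matches_direct_formula(self, rng):
        for _ in range(20):
            a, b = rng.normal(0, 2, 13), rng.normal(1, 3, 9)
            sp = np.sqrt(
                ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                / (a.size + b.size - 2)
            )
            assert cohens_dprime(a, b) == pytest.approx(abs(a.mean() - b.mean()) / sp, abs=1e-12)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(UsageError):
            cohens_dprime(np.ones(5), np.ones(5) * 2)


class TestEffectSizeIdentity:
    def test_t_equals_dprime_root_n_half(self, rng):
        """For equal n, |t| = d' * sqrt(n/2) exactly."""
        for _ in range(100):
            n = int(rng.integers(3, 40))
            a, b = rng.normal(0, 1, n), rng.normal(0.5, 2, n)
            t = abs(unpaired_t(a, b).statistic)
            d = cohens_dprime(a, b)
            assert abs(t - d * np.sqrt(n / 2)) < 1e-9


class TestRMAnova:
    def _df(self, y_by_group):
        rows = []
        for g, mat in y_by_group.items():
            for i, row in enumerate(mat):
                for s, v in enumerate(row):
                    rows.append(dict(subject_id=f"{g}{i}", group=g, session=s, value=v))
        return pd.DataFrame(rows)

    def test_identical_groups_zero_f(self):
        mat = np.arange(12.0).reshape(3, 4)
        res = rm_anova_2way(self._df({"a": mat, "b": mat.copy()}))
        assert res["group"].statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_pingouin_on_balanced_data(self, rng):
        pg = pytest.importorskip("pingouin")
        df = simulate_null_metric_curves((5, 7), 6, rng)
        mine = rm_anova_2way(df)
        ref = pg.mixed_anova(
            data=df, dv="value", within="session", subject="subject_id", between="group"
        ).set_index("Source")
        assert mine["group"].statistic == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert mine["session"].statistic == pytest.approx(ref.loc["session", "F"], rel=1e-9)
        assert mine["interaction"].statistic == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9
        )
        assert mine["group"].p_value == pytest.approx(ref.loc["group", "p_unc"], rel=1e-9)

    def test_missing_sessions_excluded_with_warning(self, rng):
        df = simulate_null_metric_curves((4, 4), 5, rng)
        df = df[~((df.subject_id == "a0") & (df.session == 3))]
        with pytest.warns(UserWarning, match="missing sessions"):
            res = rm_anova_2way(df)
        assert res["group"].df[1] == 5  # 7 complete subjects minus 2 groups

    def test_type_i_error_sane_at_reduced_n(self, rng):
        rej = sum(
            rm_anova_2way(simulate_null_metric_curves((6, 6), 6, rng))["group"].p_value < 0.05
            for _ in range(200)
        )
        assert 0.01 <= rej / 200 <= 0.12


class TestOnewayBonferroni:
    def test_identical_groups(self):
        g = {k: np.array([1.0, 2.0, 3.0]) for k in "abc"}
        res = oneway_anova_bonferroni(g, planned_pairs=[("a", "b"), ("a", "c")])
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert all(d["p_adj"] == 1.0 for d in res.extra["pairwise"].values())

    def test_bonferroni_doubles_raw_p(self, rng):
        g = {
            "a": rng.normal(0, 1, 10),
            "b": rng.normal(0.5, 1, 10),
            "c": rng.normal(1, 1, 10),
        }
        res = oneway_anova_bonferroni(g, planned_pairs=[("a", "b"), ("a", "c")])
        for pair, d in res.extra["pairwise"].items():
            assert d["p_adj"] == pytest.approx(min(1.0, 2 * d["p_raw"]), abs=1e-12)

    def test_omnibus_matches_scipy(self, rng):
        from scipy.stats import f_oneway

        g = {k: rng.normal(i, 1, 8) for i, k in enumerate("abc")}
        res = oneway_anova_bonferroni(g)
        F, p = f_oneway(*g.values())
        assert res.statistic == pytest.approx(F, rel=1e-12)
        assert res.df == (2, 21)

    def test_single_group_rejected(self):
        with pytest.raises(UsageError):
            oneway_anova_bonferroni({"a": np.ones(3)})


class TestAncova:
    def _df(self, rng, shift=0.0, slope=0.0, n=12):
        rows = []
        for g, mu in (("a", 0.0), ("b", shift)):
            ages = rng.uniform(60, 120, n)
            for age in ages:
                rows.append(
                    dict(group=g, age_days=age, value=mu + slope * age + rng.normal(0, 1))
                )
        return pd.DataFrame(rows)

    def test_identical_groups_near_zero_f(self, rng):
        df = self._df(rng, shift=0.0)
        df2 = df.copy()
        df2.loc[df2.group == "b", "value"] = df.loc[df.group == "a", "value"].to_numpy()
        df2.loc[df2.group == "b", "age_days"] = df.loc[df.group == "a", "age_days"].to_numpy()
        res = ancova_age_tukey(df2)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_constant_age_reduces_to_oneway(self, rng):
        from scipy.stats import f_oneway

        df = self._df(rng, shift=1.0)
        df["age_days"] = 90.0
        res = ancova_age_tukey(df)
        F, p = f_oneway(
            df[df.group == "a"]["value"].to_numpy(), df[df.group == "b"]["value"].to_numpy()
        )
        assert res.statistic == pytest.approx(F, rel=1e-9)

    def test_age_confound_removed_by_adjustment(self):
        """Groups differing only through a shared age slope: the adjusted
        group effect should rarely be significant."""
        rng = np.random.default_rng(7)
        sig = 0
        B = 200
        for _ in range(B):
            rows = []
            for g, ages in (("a", rng.uniform(60, 90, 10)), ("b", rng.uniform(90, 120, 10))):
                for age in ages:
                    rows.append(dict(group=g, age_days=age, value=0.02 * age + rng.normal(0, 1)))
            if ancova_age_tukey(pd.DataFrame(rows)).p_value < 0.05:
                sig += 1
        assert sig / B <= 0.10

    def test_reports_tukey_pairs(self, rng):
        res = ancova_age_tukey(self._df(rng, shift=3.0))
        assert ("a", "b") in res.extra["tukey"]
        assert 0.0 <= res.extra["tukey"][("a", "b")] <= 1.0


class TestLearningCurves:
    def _metrics(self, n_sub=3, phases=(("acquisition", 12),)):
        rows = []
        for i in range(n_sub):
            for ph, ns in phases:
                for s in range(ns):
                    rows.append(
                        dict(
                            subject_id=f"s{i}", group="g", phase=ph, session=s,
                            probability=0.1 + 0.03 * s, amplitude=0.2, percent_cr=50.0,
                        )
                    )
        return pd.DataFrame(rows)

    def test_row_order_is_irrelevant(self, rng):
        df = self._metrics()
        shuffled = df.sample(frac=1.0, random_state=1)
        a = build_learning_curves(df)
        b = build_learning_curves(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_duplicates_rejected(self):
        df = self._metrics()
        with pytest.raises(DataError):
            build_learning_curves(pd.concat([df, df.iloc[[0]]]))

    def test_last_four_mean_arithmetic(self):
        df = self._metrics(n_sub=1)
        df.loc[df.session >= 8, "probability"] = [0.4, 0.5, 0.6, 0.7]
        out = last_four_mean(build_learning_curves(df), "acquisition")
        assert out["probability"].iloc[0] == pytest.approx(0.55)

    def test_too_few_sessions_rejected(self):
        df = self._metrics(phases=(("extinction", 3),))
        with pytest.raises(UsageError):
            last_four_mean(df, "extinction")


class TestSavings:
    def _curves(self, acq12, ext4, rea3, n=6, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            for ph, ns, last_val in (
                ("acquisition", 12, acq12), ("extinction", 4, ext4), ("reacquisition", 3, rea3)
            ):
                for s in range(ns):
                    v = last_val if s == ns - 1 else last_val / 2
                    rows.append(
                        dict(
                            subject_id=f"s{i}", group="g", phase=ph, session=s,
                            percent_cr=v + jitter * rng.normal(),
                        )
                    )
        return pd.DataFrame(rows)

    def test_identical_values_give_null_result(self):
        out = savings_summary(self._curves(50.0, 50.0, 50.0))
        r = out["g"]["acquisition_vs_extinction"]
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_extinction_detected(self):
        out = savings_summary(self._curves(60.0, 5.0, 55.0, n=10, jitter=4.0))
        assert out["g"]["acquisition_vs_extinction"].p_value < 0.05

    def test_savings_detected(self):
        out = savings_summary(self._curves(60.0, 5.0, 55.0, n=10, jitter=4.0))
        r = out["g"]["extinction_vs_reacquisition"]
        assert r.p_value < 0.05 and r.statistic < 0  # reacquisition higher

    def test_never_acquired_group_skipped(self):
        out = savings_summary(self._curves(1.0, 1.0, 1.0), never_acquired_groups=("g",))
        assert "skipped" in out["g"]

    def test_paired_t_length_mismatch(self):
        with pytest.raises(UsageError):
            paired_t(np.ones(3), np.ones(4))
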