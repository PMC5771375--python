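"""Inferential layer: effect sizes, Welch tests, Holm, Williams, reliability,
and the split-plot ANOVA (cross-checked against pingouin and hand sums)."""

import numpy as np
import pandas as pd
import pytest

from magdiff.stats import (
    cohens_d,
    holm_adjust,
    mixed_anova,
    pearson_r,
    spearman_brown,
    split_half_reliability,
    welch_t,
    williams_test,
)


class TestPearson:
    def test_identity_and_null(self, rng):
        x = rng.normal(size=100)
        r, p = pearson_r(x, x)
        assert r == pytest.approx(1.0)
        y = rng.normal(size=10_000)
        x2 = rng.normal(size=10_000)
        r2, _ = pearson_r(x2, y)
        assert abs(r2) < 0.03

    def test_pairwise_deletion_and_degenerate(self):
        x = [1.0, 2.0, 3.0, np.nan, 5.0]
        y = [2.0, 4.0, 6.0, 8.0, np.nan]
        r, _ = pearson_r(x, y)
        assert r == pytest.approx(1.0)
        r, p = pearson_r([1, 1, 1], [1, 2, 3])
        assert np.isnan(r) and np.isnan(p)


class TestHolm:
    def test_hand_computations(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])
        np.testing.assert_allclose(holm_adjust([0.001, 0.001, 0.5]), [0.003, 0.003, 0.5])
        np.testing.assert_allclose(holm_adjust([0.2]), [0.2])

    def test_order_invariance_and_dominance(self, rng):
        p = rng.uniform(size=12)
        adj = holm_adjust(p)
        perm = rng.permutation(12)
        np.testing.assert_allclose(holm_adjust(p[perm]), adj[perm])
        assert np.all(adj >= p)
        assert np.all(adj <= 1)

    def test_rejects_bad_pvalues(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestWilliams:
    def test_equal_correlations_give_zero(self):
        res = williams_test(0.3, 0.3, 0.5, 100)
        assert res.t == pytest.approx(0.0)
        assert res.df == 97

    def test_antisymmetry(self):
        a = williams_test(0.4, 0.1, 0.3, 80)
        b = williams_test(0.1, 0.4, 0.3, 80)
        assert a.t == pytest.approx(-b.t)

    def test_matches_independent_textbook_formula(self):
        r_jk, r_jh, r_kh, n = -0.21, -0.03, 0.3, 279
        res = williams_test(r_jk, r_jh, r_kh, n)
        # independent re-derivation, written out long-hand
        R = (
            1
            - r_jk * r_jk
            - r_jh * r_jh
            - r_kh * r_kh
            + 2 * r_jk * r_jh * r_kh
        )
        mean_r = 0.5 * (r_jk + r_jh)
        expected = (r_jk - r_jh) * np.sqrt(
            ((n - 1) * (1 + r_kh))
            / (2 * R * (n - 1) / (n - 3) + mean_r**2 * (1 - r_kh) ** 3)
        )
        assert res.t == pytest.approx(expected, abs=1e-10)
        assert res.t < 0  # symbolic caution correlates more negatively

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            williams_test(1.0, 0.3, 0.3, 50)
        with pytest.raises(ValueError):
            williams_test(0.2, 0.3, 0.3, 3)


class TestCohensD:
    def test_group_summary_rows(self):
        # symbolic drift rate row: the canonical medium-large ability deficit
        assert cohens_d(2.44, 0.9, 272, 1.92, 0.62, 81).d == pytest.approx(0.62, abs=0.005)
        # near-equal accuracy row
        assert cohens_d(0.88, 0.1, 272, 0.87, 0.1, 81).d == pytest.approx(0.10, abs=0.005)

    def test_ci_reproduces_reported_bounds(self):
        es = cohens_d(2.44, 0.9, 272, 1.92, 0.62, 81)
        assert es.ci_low == pytest.approx(0.36, abs=0.005)
        assert es.ci_up == pytest.approx(0.87, abs=0.005)
        assert es.ci_low <= es.d <= es.ci_up

    def test_zero_and_antisymmetry(self):
        assert cohens_d(1.0, 0.5, 30, 1.0, 0.5, 40).d == 0.0
        a = cohens_d(1.2, 0.4, 30, 1.0, 0.5, 40)
        b = cohens_d(1.0, 0.5, 40, 1.2, 0.4, 30)
        assert a.d == pytest.approx(-b.d)
        assert a.ci_low == pytest.approx(-b.ci_up)


class TestWelch:
    def test_zero_for_equal_summaries(self):
        res = welch_t(1.0, 0.5, 30, 1.0, 0.5, 30)
        assert res.t == 0.0
        assert res.df == pytest.approx(2 * (30 - 1))

    def test_symbolic_drift_row_from_rounded_summaries(self):
        res = welch_t(2.44, 0.9, 272, 1.92, 0.62, 81)
        assert res.t == pytest.approx(5.9, abs=0.1)
        assert res.df == pytest.approx(190, abs=5)
        assert res.p < 1e-6

    def test_matches_scipy(self, rng):
        from scipy import stats as sps

        x = rng.normal(0, 1, 40)
        y = rng.normal(0.5, 2, 25)
        mine = welch_t(x.mean(), x.std(ddof=1), 40, y.mean(), y.std(ddof=1), 25)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert mine.t == pytest.approx(ref.statistic, abs=1e-10)
        assert mine.p == pytest.approx(ref.pvalue, abs=1e-10)


class TestSpearmanBrown:
    def test_formula(self):
        assert spearman_brown(0.5) == pytest.approx(2 / 3)
        assert spearman_brown(1.0) == 1.0
        assert spearman_brown(0.0) == 0.0


class TestMixedAnova:
    def test_hand_computed_four_subject_table(self):
        # 2 con, 2 dys; values chosen for easy hand sums
        values = pd.DataFrame({"symbolic": [4.0, 6.0, 1.0, 3.0], "nonsymbolic": [2.0, 4.0, 1.0, 1.0]})
        groups = np.array(["con", "con", "dys", "dys"])
        res = mixed_anova(values, groups)
        # hand decomposition: GM=2.75; subject means 3,5,1,2
        # SS_between = 2*((0.25)^2+(2.25)^2+(1.75)^2+(0.75)^2) = 2*8.75 = 17.5
        # group means of subj means: con 4, dys 1.5 -> SS_group = 2*(2*1.25^2+2*1.25^2)=12.5
        # d = y1-y2 = (2,2,0,2), dbar=1.5 -> SS_task = 4*1.5^2/2 = 4.5
        # group dbars: con 2, dys 1 -> SS_inter = (2*(0.5)^2+2*(0.5)^2)/2 = 0.5
        # SS_err_within = (0 + 0 + (0-1)^2+(2-1)^2)/2 = 1.0
        tab = res.table.set_index("effect")
        assert tab.loc["group", "SS"] == pytest.approx(12.5, abs=1e-10)
        assert tab.loc["task", "SS"] == pytest.approx(4.5, abs=1e-10)
        assert tab.loc["group x task", "SS"] == pytest.approx(0.5, abs=1e-10)
        # SS_total = SS_between-subjects + SS_within = 17.5 + 6.0
        assert res.ss_total == pytest.approx(23.5, abs=1e-10)
        # eta^2 uses the total SS over both strata
        assert tab.loc["group", "eta2"] == pytest.approx(12.5 / res.ss_total)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        n1, n2 = 14, 9
        g = np.array(["con"] * n1 + ["dys"] * n2)
        y1 = rng.normal(2.4, 0.9, n1 + n2) - 0.4 * (g == "dys")
        y2 = rng.normal(1.7, 0.7, n1 + n2) - 0.2 * (g == "dys")
        mine = mixed_anova(pd.DataFrame({"symbolic": y1, "nonsymbolic": y2}), g)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n1 + n2), 2),
                "task": ["symbolic", "nonsymbolic"] * (n1 + n2),
                "group": np.repeat(g, 2),
                "y": np.ravel(np.column_stack([y1, y2])),
            }
        )
        ref = pg.mixed_anova(
            data=long, dv="y", within="task", subject="subject", between="group"
        ).set_index("Source")
        tab = mine.table.set_index("effect")
        assert tab.loc["group", "F"] == pytest.approx(ref.loc["group", "F"], rel=1e-8)
        assert tab.loc["task", "F"] == pytest.approx(ref.loc["task", "F"], rel=1e-8)
        assert tab.loc["group x task", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-8
        )
        assert tab.loc["group", "eta2_partial"] == pytest.approx(
            ref.loc["group", "np2"], rel=1e-8
        )

    def test_zero_within_difference_kills_task_effect(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 2.5, 1.5])
        values = pd.DataFrame({"symbolic": y, "nonsymbolic": y})
        groups = np.array(["con", "con", "con", "dys", "dys", "dys"])
        res = mixed_anova(values, groups)
        tab = res.table.set_index("effect")
        assert tab.loc["task", "SS"] == 0.0
        assert tab.loc["group x task", "SS"] == 0.0

    def test_type_one_error_rate_under_null(self, rng):
        rejections = 0
        reps = 500
        for _ in range(reps):
            y1 = rng.normal(size=30)
            y2 = rng.normal(size=30)
            g = np.array(["con"] * 18 + ["dys"] * 12)
            res = mixed_anova(pd.DataFrame({"s": y1, "n": y2}), g)
            rejections += res.table.set_index("effect").loc["group", "p"] < 0.05
        rate = rejections / reps
        assert 0.02 < rate < 0.09  # ~ alpha = 0.05

    def test_missing_cell_dropped(self):
        values = pd.DataFrame(
            {"s": [1.0, 2.0, np.nan, 4.0, 1.0, 0.5], "n": [1.0, 1.5, 2.0, 3.0, 0.5, 1.0]}
        )
        g = np.array(["con", "con", "con", "dys", "dys", "dys"])
        res = mixed_anova(values, g)
        assert res.table.attrs["n_subjects"] == 5
        assert res.table.attrs["n_dropped"] == 1


class TestSplitHalfReliability:
    def test_spearman_brown_applied(self, rng):
        from magdiff.synthetic import PopulationConfig, simulate_study
        from magdiff.preprocessing import preprocess

        cfg = PopulationConfig(n_con=8, n_dys=4)
        trials, _, _ = simulate_study(cfg, 5)
        clean, _ = preprocess(trials)
        tab = split_half_reliability(
            clean, parameters=("t0",), fit_kwargs={"n_restarts": 2, "maxfev": 200}
        )
        assert set(tab["task"]) == {"symbolic", "nonsymbolic"}
        for _, row in tab.iterrows():
            if np.isfinite(row["r_half"]):
                assert row["reliability"] == pytest.approx(
                    spearman_brown(row["r_half"])
                )
            assert row["n_subjects"] <= 12
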