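"""Delay statistics: group comparisons, Type II ANOVA, contrasts, power, kappa."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dentdelay.stats import (
    PowerSpec,
    bonferroni,
    cohens_kappa,
    compare_groups,
    compute_delays,
    dunn_test,
    fit_delay_model,
    marked_delay,
    n_per_group,
    pattern_kruskal,
    power_two_sample_t,
    severity_anova,
    summary_difference,
    type2_anova,
)


def delays_frame(control, agenesis, sex=None):
    rows = []
    for i, v in enumerate(control):
        rows.append({"id": f"c{i}", "group": "control", "sex": "female", "ca": 10.0,
                     "da": 10.0 + v, "delay": v})
    for i, v in enumerate(agenesis):
        rows.append({"id": f"a{i}", "group": "agenesis", "sex": "male", "ca": 10.0,
                     "da": 10.0 + v, "delay": v})
    df = pd.DataFrame(rows)
    if sex is not None:
        df["sex"] = sex
    return df


class TestComputeDelays:
    def test_delay_is_da_minus_ca(self):
        df = pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "group": ["control", "agenesis", "control"],
                "sex": ["female", "male", "male"],
                "ca": [11.0, 12.0, 10.0],
                "da": [12.0, 12.0, np.nan],
            }
        )
        out = compute_delays(df)
        assert list(out["delay"]) == pytest.approx([1.0, 0.0])
        assert out.attrs["n_skipped_missing_da"] == 1


class TestGroupComparison:
    def test_identical_groups(self):
        df = delays_frame([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        c = compare_groups(df)
        assert c.delta == pytest.approx(0.0)
        assert c.p == pytest.approx(1.0)

    def test_raw_and_summary_agree(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0.5, 1.0, 40), rng.normal(-0.2, 1.1, 35)
        df = delays_frame(a, b)
        raw = compare_groups(df)
        summ = summary_difference(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
        )
        for attr in ("delta", "t", "df", "p"):
            assert getattr(raw, attr) == pytest.approx(getattr(summ, attr), abs=1e-9)
        assert raw.ci95 == pytest.approx(summ.ci95, abs=1e-9)

    def test_welch_differs_under_unequal_variance(self):
        rng = np.random.default_rng(4)
        df = delays_frame(rng.normal(0, 0.2, 20), rng.normal(0, 2.0, 60))
        student = compare_groups(df, welch=False)
        welch = compare_groups(df, welch=True)
        assert student.df == 78
        assert welch.df != student.df

    def test_ci_contains_delta_and_matches_scipy_p(self):
        rng = np.random.default_rng(5)
        df = delays_frame(rng.normal(0.4, 1, 25), rng.normal(0, 1, 30))
        c = compare_groups(df)
        lo, hi = c.ci95
        assert lo <= c.delta <= hi
        t, p = sps.ttest_ind(
            df.loc[df.group == "control", "delay"],
            df.loc[df.group == "agenesis", "delay"],
        )
        assert c.t == pytest.approx(t)
        assert c.p == pytest.approx(p)


class TestMarkedDelay:
    def test_cutoff_from_rounded_published_moments(self):
        # control with mean 0.54, SD 1.07 exactly -> cutoff 0.54 - 2*1.07 = -1.60
        control = [0.54 - 1.07, 0.54, 0.54 + 1.07]
        df = delays_frame(control, [-2.0, -1.0, 0.0])
        res = marked_delay(df)
        assert res.cutoff == pytest.approx(-1.60, abs=1e-12)

    def test_no_one_below_cutoff(self):
        df = delays_frame([0.0, 0.1, 0.2, 0.3], [0.05, 0.15, 0.25])
        res = marked_delay(df)
        assert all(b == 0 for b, _ in res.counts.values())
        assert res.chi2 == 0.0

    def test_yates_statistic_matches_textbook_formula(self):
        rng = np.random.default_rng(6)
        df = delays_frame(rng.normal(0.5, 1, 80), rng.normal(-1.5, 1, 70))
        res = marked_delay(df)
        (a, n1), (b, n2) = res.counts["agenesis"], res.counts["control"]
        table = np.array([[a, n1 - a], [b, n2 - b]])
        N = table.sum()
        (r1, r2), (c1, c2) = table.sum(1), table.sum(0)
        det = abs(table[0, 0] * table[1, 1] - table[0, 1] * table[1, 0])
        expected = N * max(det - N / 2, 0) ** 2 / (r1 * r2 * c1 * c2)
        assert res.chi2 == pytest.approx(expected, rel=1e-12)


class TestTypeTwoAnova:
    @staticmethod
    def _oracle(df, terms):
        """Brute-force nested-RSS Type II via statsmodels formula OLS."""
        import statsmodels.formula.api as smf

        def rss(term_list):
            if not term_list:
                formula = "delay ~ 1"
            else:
                formula = "delay ~ " + " + ".join(":".join(t) for t in term_list)
            return smf.ols(formula, df).fit().ssr

        full_rss = rss(terms)
        out = {}
        for t in terms:
            base = [u for u in terms if not set(t) <= set(u)]
            out[":".join(t)] = rss(base) - rss(base + [t])
        return out, full_rss

    def test_twelve_row_fixture_matches_brute_force(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {
                "agenesis": [0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1],
                "sex": [0, 0, 0, 1, 1, 1, 0, 0, 1, 1, 0, 1],
                "ca": rng.uniform(6, 15, 12).round(1),
            }
        )
        df["delay"] = (
            0.5 - 0.8 * df.agenesis + 0.2 * df.sex + 0.05 * df.ca
            + rng.normal(0, 0.3, 12)
        )
        terms = [
            ("agenesis",), ("sex",), ("ca",),
            ("agenesis", "sex"), ("agenesis", "ca"), ("sex", "ca"),
            ("agenesis", "sex", "ca"),
        ]
        ours = type2_anova(df, "delay", ["agenesis", "sex", "ca"], terms=terms)
        oracle, full_rss = self._oracle(df, terms)
        for _, row in ours.iterrows():
            if row["term"] == "Residual":
                assert row["sum_sq"] == pytest.approx(full_rss, abs=1e-8)
            else:
                assert row["sum_sq"] == pytest.approx(oracle[row["term"]], abs=1e-8)

    def test_balanced_orthogonal_type2_equals_type1(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(8)
        cells = [(a, b) for a in (0, 1) for b in (0, 1)]
        df = pd.DataFrame(
            [{"A": a, "B": b} for a, b in cells for _ in range(5)]
        )
        df["delay"] = rng.normal(0, 1, len(df)) + 0.5 * df.A - 0.3 * df.B
        ours = type2_anova(df, "delay", ["A", "B"])
        seq = anova_lm(smf.ols("delay ~ A * B", df).fit(), typ=1)
        for term in ("A", "B", "A:B"):
            ss2 = float(ours.loc[ours.term == term, "sum_sq"].iloc[0])
            assert ss2 == pytest.approx(float(seq.loc[term, "sum_sq"]), abs=1e-10)

    def test_invariant_to_factor_order(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(
            {
                "agenesis": rng.integers(0, 2, 60),
                "sex": rng.integers(0, 2, 60),
                "ca": rng.uniform(6, 15, 60),
            }
        )
        df["delay"] = rng.normal(0, 1, 60)
        a = type2_anova(df, "delay", ["agenesis", "sex", "ca"])
        b = type2_anova(df, "delay", ["ca", "sex", "agenesis"])
        sa = a.set_index("term")["sum_sq"]
        sb = b.set_index("term")["sum_sq"]
        for term_a, s in sa.items():
            if term_a == "Residual":
                continue
            match = [t for t in sb.index if set(t.split(":")) == set(term_a.split(":"))]
            assert sb[match[0]] == pytest.approx(s, abs=1e-10)

    def test_rank_deficiency_reported(self):
        df = pd.DataFrame(
            {
                "agenesis": [0, 1] * 10,
                "sex": [0, 1] * 10,  # perfectly collinear with agenesis
                "ca": np.linspace(6, 15, 20),
            }
        )
        df["delay"] = np.random.default_rng(0).normal(size=20)
        with pytest.raises(ValueError, match="rank-deficient"):
            type2_anova(df, "delay", ["agenesis", "sex", "ca"])

    def test_null_pvalues_roughly_uniform(self):
        """Under a null model the agenesis-term p-values are uniform."""
        rng = np.random.default_rng(10)
        pvals = []
        for _ in range(200):
            df = pd.DataFrame(
                {
                    "group": rng.permutation(["control"] * 30 + ["agenesis"] * 30),
                    "sex": rng.choice(["female", "male"], 60),
                    "ca": rng.uniform(6, 15, 60),
                }
            )
            df["delay"] = rng.normal(0, 1, 60)
            res = fit_delay_model(df.assign(id=np.arange(60).astype(str)))
            pvals.append(float(res.anova.loc[res.anova.term == "agenesis", "p"].iloc[0]))
        assert sps.kstest(pvals, "uniform").pvalue > 1e-3


class TestFitDelayModel:
    def test_recovers_injected_interaction(self):
        rng = np.random.default_rng(11)
        n = 400
        df = pd.DataFrame(
            {
                "id": np.arange(n).astype(str),
                "group": rng.permutation(["control"] * (n // 2) + ["agenesis"] * (n // 2)),
                "sex": rng.choice(["female", "male"], n),
                "ca": rng.uniform(6, 15, n),
            }
        )
        agen = (df.group == "agenesis").astype(float)
        male = (df.sex == "male").astype(float)
        df["delay"] = 0.5 - 0.9 * agen + 0.4 * agen * male + rng.normal(0, 0.3, n)
        res = fit_delay_model(df)
        anova = res.anova.set_index("term")
        assert anova.loc["agenesis", "p"] < 1e-6
        assert anova.loc["agenesis:sex", "p"] < 1e-3
        assert anova.loc["sex:ca", "p"] > 0.001  # no such effect injected
        assert (anova["sum_sq"].dropna() >= -1e-9).all()


class TestSeverityAnova:
    def test_all_levels_identical(self):
        rng = np.random.default_rng(12)
        base = rng.normal(0, 1, 20)
        df = pd.DataFrame(
            {
                "severity": np.repeat(["control", "mild", "moderate"], 20),
                "delay": np.concatenate([base, base, base]),
            }
        )
        _, pairwise = severity_anova(df)
        assert (pairwise["p_adj"] > 0.999).all()

    def test_two_level_tukey_equals_t_test(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(
            {
                "severity": np.repeat(["control", "mild"], 25),
                "delay": np.concatenate(
                    [rng.normal(0.5, 1, 25), rng.normal(0.0, 1, 25)]
                ),
            }
        )
        _, pairwise = severity_anova(df)
        t, p = sps.ttest_ind(
            df.loc[df.severity == "control", "delay"],
            df.loc[df.severity == "mild", "delay"],
        )
        assert pairwise.loc[0, "p_adj"] == pytest.approx(p, abs=1e-9)

    def test_gradient_pattern_each_level_differs_from_control_only(self):
        """A uniform group delay separates every severity level from control
        while the levels stay mutually indistinguishable."""
        rng = np.random.default_rng(14)
        df = pd.DataFrame(
            {
                "severity": np.concatenate(
                    [
                        np.repeat("control", 200),
                        np.repeat("mild", 120),
                        np.repeat("moderate", 60),
                        np.repeat("oligodontia", 20),
                    ]
                ),
            }
        )
        delay = np.where(df.severity == "control", 0.54, -0.23)
        df["delay"] = delay + rng.normal(0, 0.4, len(df))
        _, pairwise = severity_anova(df)
        vs_control = pairwise[
            (pairwise.level_a == "control") | (pairwise.level_b == "control")
        ]
        between = pairwise[
            (pairwise.level_a != "control") & (pairwise.level_b != "control")
        ]
        assert (vs_control["p_adj"] < 0.05).all()
        assert (between["p_adj"] > 0.05).all()

    def test_singleton_level_dropped_with_warning(self):
        df = pd.DataFrame(
            {
                "severity": ["control"] * 10 + ["mild"] * 10 + ["oligodontia"],
                "delay": np.r_[np.linspace(0, 1, 10), np.linspace(-1, 0, 10), [-2.0]],
            }
        )
        with pytest.warns(UserWarning, match="oligodontia"):
            omnibus, _ = severity_anova(df)
        assert omnibus.loc[0, "k"] == 2


class TestPatternKruskal:
    def test_identical_distributions_h_near_zero(self):
        df = pd.DataFrame(
            {
                "pattern_label": np.repeat(["control", "35", "45"], 3),
                "delay": [1.0, 2.0, 3.0] * 3,
            }
        )
        H, p, _ = pattern_kruskal(df)
        assert H == pytest.approx(0.0, abs=1e-9)

    def test_hand_ranked_three_groups(self):
        """No ties: H and Dunn z match the textbook rank formulas."""
        groups = [np.array([1.0, 2.0]), np.array([3.0, 4.0]), np.array([5.0, 6.0])]
        df = pd.DataFrame(
            {
                "pattern_label": np.repeat(["a", "b", "c"], 2),
                "delay": np.concatenate(groups),
            }
        )
        H, p, dunn = pattern_kruskal(df)
        # ranks 1..6; mean ranks 1.5, 3.5, 5.5; H = 12/(6*7) * sum n (Rbar - 3.5)^2
        assert H == pytest.approx(12 / 42 * (2 * 4 + 0 + 2 * 4), abs=1e-9)
        z_ab = dunn.set_index(["group_a", "group_b"]).loc[("a", "b"), "z"]
        assert z_ab == pytest.approx((1.5 - 3.5) / np.sqrt((6 * 7 / 12) * 1.0), abs=1e-9)

    def test_bonferroni_definition_and_monotonicity(self):
        p = [0.01, 0.2, 0.9]
        adj = bonferroni(p)
        assert list(adj) == pytest.approx([0.03, 0.6, 1.0])
        assert (adj >= np.asarray(p)).all()

    def test_singletons_flagged(self):
        df = pd.DataFrame(
            {
                "pattern_label": ["control"] * 5 + ["35"] * 4 + ["rare"],
                "delay": np.linspace(0, 1, 10),
            }
        )
        _, _, dunn = pattern_kruskal(df)
        flagged = dunn[(dunn.group_a == "rare") | (dunn.group_b == "rare")]
        assert flagged["singleton"].all()


class TestPower:
    def test_study_design_sample_size(self):
        res = n_per_group(PowerSpec(alpha=0.05, power=0.90, effect_size=0.413))
        # the continuous power-calculator solution is ~124.17 (printed as 124);
        # the smallest integer n whose exact power reaches 0.90 is 125
        assert res.n_continuous == pytest.approx(124.1726, abs=1e-3)
        assert int(res.n_continuous) == 124
        assert res.n_per_group == 125
        assert res.achieved_power >= 0.90

    def test_boundary_minimum_group_size(self):
        res = n_per_group(PowerSpec(alpha=0.05, power=0.5, effect_size=8.0))
        assert res.n_per_group == 2

    @pytest.mark.parametrize("d,power", [(0.3, 0.8), (0.6, 0.95), (1.1, 0.9)])
    def test_returned_n_is_minimal(self, d, power):
        res = n_per_group(PowerSpec(alpha=0.05, power=power, effect_size=d))
        n = res.n_per_group
        assert power_two_sample_t(n, d) >= power
        if n > 2:
            assert power_two_sample_t(n - 1, d) < power

    def test_matches_statsmodels_power(self):
        import statsmodels.stats.power as smp

        ours = power_two_sample_t(50, 0.5)
        theirs = smp.TTestIndPower().power(effect_size=0.5, nobs1=50, alpha=0.05)
        assert ours == pytest.approx(theirs, abs=1e-9)

    def test_zero_effect_unreachable(self):
        with pytest.raises(ValueError):
            n_per_group(PowerSpec(alpha=0.05, power=0.9, effect_size=1e-9))


class TestKappa:
    def test_identical_ratings(self):
        res = cohens_kappa(list("ABCDEFGH"), list("ABCDEFGH"))
        assert res.kappa == pytest.approx(1.0)

    def test_chance_level_agreement(self):
        res = cohens_kappa(["A", "A", "B", "B"], ["A", "B", "A", "B"])
        assert res.kappa == pytest.approx(0.0)
        assert res.observed_agreement == pytest.approx(res.chance_agreement)

    def test_two_by_two_worked_table(self):
        # a=20 (A,A), b=5 (A,B), c=10 (B,A), d=15 (B,B) -> kappa = 0.4
        r1 = ["A"] * 25 + ["B"] * 25
        r2 = ["A"] * 20 + ["B"] * 5 + ["A"] * 10 + ["B"] * 15
        res = cohens_kappa(r1, r2)
        assert res.kappa == pytest.approx(0.4, abs=1e-12)
        assert res.observed_agreement == pytest.approx(0.7)
        assert res.chance_agreement == pytest.approx(0.5)

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(15)
        r1 = rng.choice(list("ABCDEFGH"), 200)
        r2 = np.where(rng.random(200) < 0.7, r1, rng.choice(list("ABCDEFGH"), 200))
        assert cohens_kappa(r1, r2).kappa == pytest.approx(
            cohen_kappa_score(r1, r2), abs=1e-12
        )

    def test_disjoint_categories_handled(self):
        res = cohens_kappa(["A", "A"], ["B", "B"])
        assert -1.0 <= res.kappa <= 0.0
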