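import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from statescape.exceptions import (
    DegenerateDataError,
    ParameterError,
    ValidationError,
)
from statescape.stats import (
    by_fdr,
    correlation_matrix,
    estimate_m_eff,
    fit_mixed_lm,
    insightfulness_model,
    median_split_test,
    mixed_anova,
    paired_t,
    welch_t,
)

from _oracles import (
    by_fdr_stepup,
    kendall_tau_enumerated,
    mixed_anova_sums_of_squares,
    welch_from_formulas,
)


def balanced_table(rng, n_per_group=10, group_effect=0.0, session_effect=0.0,
                   interaction=0.0, subject_sd=1.0, noise_sd=1.0):
    rows = []
    for g, gname in enumerate(("active", "control")):
        for i in range(n_per_group):
            sid = f"{gname}-{i}"
            subject_offset = rng.normal(0, subject_sd)
            for t in (1, 2):
                y = (
                    group_effect * g
                    + session_effect * (t - 1)
                    + interaction * g * (t - 1)
                    + subject_offset
                    + rng.normal(0, noise_sd)
                )
                rows.append({"subject_id": sid, "group": gname,
                             "session": t, "value": y})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_constant_dv_degenerate(self):
        rng = np.random.default_rng(0)
        table = balanced_table(rng)
        table["value"] = 1.0
        with pytest.raises(DegenerateDataError):
            mixed_anova(table, dv="value")

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            table = balanced_table(rng, n_per_group=8, group_effect=0.5,
                                   session_effect=0.3, interaction=0.4)
            res = mixed_anova(table, dv="value")
            oracle = mixed_anova_sums_of_squares(
                table["value"].to_numpy(), table["group"].to_numpy(),
                table["session"].to_numpy(), table["subject_id"].to_numpy(),
            )
            for effect in ("between", "within", "interaction"):
                f_expected, df1, df2 = oracle[effect]
                assert res[effect].statistic == pytest.approx(f_expected, rel=1e-6)
                assert res[effect].df == df1
                assert res[effect].df2 == df2
                p_expected = sps.f.sf(f_expected, df1, df2)
                assert res[effect].p == pytest.approx(p_expected, rel=1e-6)

    def test_power_for_planted_session_effect(self):
        # planted within-subject shift of 1.5 residual sd: high power
        rng = np.random.default_rng(2)
        hits = 0
        reps = 60
        for _ in range(reps):
            table = balanced_table(rng, n_per_group=18, session_effect=1.5,
                                   noise_sd=1.0)
            res = mixed_anova(table, dv="value")
            hits += res["within"].p < 0.05
        assert hits >= int(0.9 * reps)

    def test_missing_cell_design_error(self):
        rng = np.random.default_rng(3)
        table = balanced_table(rng)
        from statescape.exceptions import DesignError

        with pytest.raises(DesignError):
            mixed_anova(table[~((table.group == "active") & (table.session == 2))],
                        dv="value")


class TestTTests:
    def test_paired_identical_samples(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_paired_constant_nonzero_difference(self):
        with pytest.raises(DegenerateDataError):
            paired_t([1, 2, 3, 4], [2, 3, 4, 5])

    def test_welch_against_formula_oracle(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [3.0, 4.0, 5.0, 6.0, 10.0]
        t_expected, df_expected = welch_from_formulas(x, y)
        res = welch_t(x, y)
        assert res.statistic == pytest.approx(t_expected, rel=1e-12)
        assert res.df == pytest.approx(df_expected, rel=1e-12)
        p_expected = 2 * sps.t.sf(abs(t_expected), df_expected)
        assert res.p == pytest.approx(p_expected, rel=1e-9)

    def test_welch_zero_variance_both(self):
        with pytest.raises(DegenerateDataError):
            welch_t([1, 1, 1], [2, 2, 2])

    def test_sample_size_preconditions(self):
        with pytest.raises(ParameterError):
            welch_t([1.0], [1.0, 2.0])
        with pytest.raises(ParameterError):
            paired_t([1.0, 2.0], [1.0])


class TestCorrelationMatrix:
    @staticmethod
    def table(rng, n=20):
        x = rng.normal(size=n)
        return pd.DataFrame({
            "m1": x + rng.normal(0, 0.5, n),
            "m2": rng.normal(size=n),
            "s1": x + rng.normal(0, 0.5, n),
            "s2": rng.normal(size=n),
        })

    def test_kendall_perfect_concordance(self):
        t = pd.DataFrame({"m1": [1, 2, 3, 4, 5], "s1": [2, 4, 6, 8, 10],
                          "s2": [5, 4, 3, 2, 1]})
        res = correlation_matrix(t, ["m1"], ["s1", "s2"], method="kendall")
        assert res.r.loc["m1", "s1"] == pytest.approx(1.0)
        assert res.r.loc["m1", "s2"] == pytest.approx(-1.0)

    def test_kendall_enumerated_oracle(self):
        x = [1, 2, 3, 4, 5]
        y = [1, 3, 2, 5, 4]
        expected = kendall_tau_enumerated(x, y)
        assert expected == pytest.approx(0.6)
        t = pd.DataFrame({"m1": x, "s1": y, "s2": [2, 1, 4, 3, 5]})
        res = correlation_matrix(t, ["m1"], ["s1", "s2"], method="kendall")
        assert res.r.loc["m1", "s1"] == pytest.approx(expected)

    def test_corrected_never_below_raw(self):
        rng = np.random.default_rng(4)
        t = self.table(rng)
        res = correlation_matrix(t, ["m1", "m2"], ["s1", "s2"])
        off_diag = ~np.eye(len(res.variables), dtype=bool)
        assert (res.p_corrected.to_numpy()[off_diag]
                >= res.p_raw.to_numpy()[off_diag] - 1e-15).all()
        assert 1.0 <= res.m_eff <= 2.0

    def test_constant_column_flagged(self):
        rng = np.random.default_rng(5)
        t = self.table(rng)
        t["m2"] = 3.0
        res = correlation_matrix(t, ["m1", "m2"], ["s1", "s2"])
        assert np.isnan(res.r.loc["m2", "s1"])

    def test_pearson_mode(self):
        rng = np.random.default_rng(6)
        t = self.table(rng, n=30)
        res = correlation_matrix(t, ["m1"], ["s1", "s2"], method="pearson")
        r_expected = sps.pearsonr(t["m1"], t["s1"]).statistic
        assert res.r.loc["m1", "s1"] == pytest.approx(r_expected)


class TestMEff:
    def test_identity_matrix(self):
        assert estimate_m_eff(np.eye(10)) == pytest.approx(10.0)

    def test_rank_one_matrix(self):
        assert estimate_m_eff(np.ones((10, 10))) == pytest.approx(1.0)

    def test_equicorrelated_closed_form(self):
        m, rho = 4, 0.5
        corr = np.full((m, m), rho)
        np.fill_diagonal(corr, 1.0)
        # eigenvalues 2.5, 0.5, 0.5, 0.5 -> Var = 1 -> 1 + 3 * (1 - 1/4)
        assert estimate_m_eff(corr) == pytest.approx(3.25)

    def test_non_symmetric_rejected(self):
        m = np.eye(3)
        m[0, 1] = 0.5
        with pytest.raises(ValidationError):
            estimate_m_eff(m)

    def test_li_ji_variant_bounds(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(50, 6))
        corr = np.corrcoef(x, rowvar=False)
        for method in ("nyholt", "li_ji"):
            m_eff = estimate_m_eff(corr, method=method)
            assert 1.0 <= m_eff <= 6.0

    @given(st.integers(2, 8), st.floats(0.0, 0.95))
    @settings(max_examples=30, deadline=None)
    def test_bounds_property(self, m, rho):
        corr = np.full((m, m), rho)
        np.fill_diagonal(corr, 1.0)
        m_eff = estimate_m_eff(corr)
        assert 1.0 <= m_eff <= m


class TestByFdr:
    def test_single_p(self):
        assert by_fdr([0.04])[0] == pytest.approx(0.04)

    def test_worked_example(self):
        adjusted = by_fdr([0.01, 0.02, 0.03])
        assert np.allclose(adjusted, [0.055, 0.055, 0.055])
        assert np.allclose(adjusted, by_fdr_stepup([0.01, 0.02, 0.03]))

    def test_all_ones(self):
        assert np.allclose(by_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            by_fdr([0.1, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_matches_stepup_oracle_and_monotone(self, pvals):
        adjusted = by_fdr(pvals)
        assert np.allclose(adjusted, by_fdr_stepup(pvals), atol=1e-12)
        assert (adjusted >= np.asarray(pvals) - 1e-15).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adjusted[order]) >= -1e-15).all()

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=10),
           st.randoms(use_true_random=False))
    @settings(max_examples=30, deadline=None)
    def test_permutation_invariance(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        base = by_fdr(pvals)
        shuffled = by_fdr([pvals[i] for i in perm])
        assert np.allclose([base[i] for i in perm], shuffled, atol=1e-12)


def mixed_lm_table(rng, n_subjects=36, subject_sd=1.0, beta_score=0.5,
                   beta_session=0.5, beta_inter=0.0, noise_sd=1.0):
    rows = []
    for i in range(n_subjects):
        score = rng.normal()
        offset = rng.normal(0, subject_sd)
        for t in (0, 1):
            y = (beta_score * score + beta_session * t + beta_inter * score * t
                 + offset + rng.normal(0, noise_sd))
            rows.append({"subject_id": f"s{i}", "score": score,
                         "session": t, "y": y})
    return pd.DataFrame(rows)


class TestMixedLM:
    def test_zero_random_variance_r2_agreement(self):
        rng = np.random.default_rng(8)
        deltas = []
        for _ in range(30):
            table = mixed_lm_table(rng, subject_sd=0.0)
            res = fit_mixed_lm(table, "y", "score * session")
            deltas.append(abs(res.conditional_r2 - res.marginal_r2))
        assert np.median(deltas) < 0.02

    def test_interaction_recovery(self):
        rng = np.random.default_rng(9)
        estimates = []
        for _ in range(40):
            table = mixed_lm_table(rng, beta_inter=1.0, noise_sd=0.5)
            res = fit_mixed_lm(table, "y", "score * session")
            estimates.append(res.params.loc["score:session", "coef"])
        assert np.mean(estimates) == pytest.approx(1.0, abs=0.1)

    def test_conditional_at_least_marginal(self):
        rng = np.random.default_rng(10)
        table = mixed_lm_table(rng, subject_sd=2.0)
        res = fit_mixed_lm(table, "y", "score * session")
        assert res.conditional_r2 >= res.marginal_r2
        assert not res.singular

    def test_singular_fit_flagged(self):
        rng = np.random.default_rng(11)
        table = mixed_lm_table(rng, subject_sd=0.0, noise_sd=3.0)
        # with zero subject variance some fits collapse; flag must be set
        flags = []
        for seed in range(6):
            t = mixed_lm_table(np.random.default_rng(100 + seed), subject_sd=0.0)
            flags.append(fit_mixed_lm(t, "y", "score * session").singular)
        assert any(flags)


class TestMedianSplit:
    @staticmethod
    def table(values, pre, post):
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(len(values))],
            "split": values, "pre": pre, "post": post,
        })

    def test_constant_split_flags_empty_group(self):
        n = 8
        t = self.table([1.0] * n, np.arange(n, dtype=float),
                       np.arange(n, dtype=float) + np.random.default_rng(0).normal(size=n))
        res = median_split_test(t, "split", "pre", "post")
        assert res["high"].insufficient_data
        assert not res["low"].insufficient_data

    def test_odd_n_tie_convention(self):
        n = 9
        rng = np.random.default_rng(1)
        t = self.table(np.arange(n, dtype=float), rng.normal(size=n),
                       rng.normal(size=n))
        res = median_split_test(t, "split", "pre", "post")
        # median element goes to the lower group: sizes differ by exactly 1
        assert res["low"].df + 1 == 5 - 1 + 1  # 5 low pairs -> df 4
        assert res["low"].df - res["high"].df == 1

    def test_planted_decrease_detected_in_low_group(self):
        rng = np.random.default_rng(2)
        hits = 0
        reps = 100
        for _ in range(reps):
            split = rng.normal(size=20)
            med = np.median(split)
            pre = rng.normal(size=20)
            # decrease (pre > post) planted only in the low subgroup
            post = pre - 1.5 * (split <= med) + rng.normal(0, 0.5, size=20)
            t = self.table(split, pre, post)
            res = median_split_test(t, "split", "pre", "post")
            hits += (res["low"].p < 0.05 and res["low"].statistic > 0)
        assert hits >= 80


class TestInsightfulnessModel:
    @staticmethod
    def table(rng, n=36, noise=0.0, beta_d=0.5):
        dereal = rng.normal(size=n)
        d_om = np.abs(rng.normal(size=n))
        insight = 2.0 + 1.0 * dereal + beta_d * d_om + rng.normal(0, noise, n) \
            if noise > 0 else 2.0 + 1.0 * dereal + beta_d * d_om
        return pd.DataFrame({
            "positive_derealization": dereal,
            "d_OM1_OM2": d_om,
            "insightfulness": insight,
        })

    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(3)
        res = insightfulness_model(self.table(rng, noise=0.0))
        assert res.full_adj_r2 > 0.999

    def test_full_beats_reduced_with_planted_term(self):
        rng = np.random.default_rng(4)
        wins = []
        for _ in range(50):
            res = insightfulness_model(self.table(rng, noise=0.5, beta_d=1.0))
            wins.append(res.full_adj_r2 - res.reduced_adj_r2)
        assert np.median(wins) > 0

    def test_permuted_outcome_uniform_p(self):
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(300):
            t = self.table(rng, noise=1.0, beta_d=0.0)
            t["insightfulness"] = rng.permutation(t["insightfulness"].to_numpy())
            pvals.append(insightfulness_model(t).full_f_p)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
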