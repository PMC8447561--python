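"""Group comparisons, Spearman matrices, outcome tables, LASSO, ROC/AUC."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipophen.stats import (
    LassoOutcomeModel, StatsError, cluster_outcome_table, compare_signature_auc,
    continuous_cluster_score, group_compare, lasso_select, roc_auc,
    spearman_matrix,
)


class TestGroupCompare:
    def _frame(self, a, b, name="x"):
        return pd.DataFrame({
            name: list(a) + list(b),
            "grp": ["g1"] * len(a) + ["g2"] * len(b),
        })

    def test_small_cell_triggers_fisher(self):
        t = pd.DataFrame({"x": [1] * 3 + [0] * 12 + [1] * 9 + [0] * 6,
                          "grp": ["a"] * 15 + ["b"] * 15})
        res = group_compare(t, "grp", ["x"], family_size=1)[0]
        assert res.test == "fisher_exact"

    def test_large_cells_use_chi_square(self):
        t = pd.DataFrame({"x": [1] * 10 + [0] * 10 + [1] * 5 + [0] * 15,
                          "grp": ["a"] * 20 + ["b"] * 20})
        res = group_compare(t, "grp", ["x"], family_size=1)[0]
        assert res.test == "chi_square"

    def test_identical_distributions_p_one(self):
        res = group_compare(self._frame([1.5, 2.5, 3.5], [1.5, 2.5, 3.5]),
                            "grp", ["x"], family_size=1)[0]
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_triplets_exact_p(self):
        # all C(6,3)=20 rank splits: the observed split is one of the two
        # most extreme -> two-sided p = 2/20 = 0.1
        res = group_compare(self._frame([1.25, 2.5, 3.75], [4.5, 5.5, 6.5]),
                            "grp", ["x"], family_size=1)[0]
        assert res.test == "wilcoxon_rank_sum"
        assert res.p_value == pytest.approx(0.1)

    def test_degenerate_variable_warns_p_one(self):
        with pytest.warns(UserWarning, match="single distinct"):
            res = group_compare(self._frame([7, 7, 7], [7, 7, 7]),
                                "grp", ["x"], family_size=1)[0]
        assert res.p_value == 1.0

    def test_bonferroni_threshold_exact(self):
        res = group_compare(self._frame([1.5, 2.5], [3.5, 4.5]),
                            "grp", ["x"], family_size=47)[0]
        assert res.threshold == 0.05 / 47

    @given(st.integers(0, 5000))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_exact_branch_matches_enumeration(self, seed):
        """Rank-sum p equals full enumeration of rank assignments (n<=8/arm)."""
        rng = np.random.default_rng(seed)
        na, nb = int(rng.integers(2, 9)), int(rng.integers(2, 9))
        # +0.25 keeps ranks while marking the variable as continuous
        vals = rng.permutation(np.arange(1, na + nb + 1)) + 0.25
        a, b = vals[:na], vals[na:]
        res = group_compare(self._frame(a, b), "grp", ["x"], family_size=1)[0]
        # enumeration oracle: distribution of the rank sum of arm 1
        ranks = np.arange(1, na + nb + 1)
        obs = sum(sorted(np.concatenate([a, b])).index(v) + 1 for v in a)
        sums = [sum(c) for c in itertools.combinations(ranks, na)]
        mean = (na * (na + nb + 1)) / 2
        tail = sum(1 for s in sums if abs(s - mean) >= abs(obs - mean) - 1e-12)
        p_exact = min(1.0, tail / len(sums))
        assert res.p_value == pytest.approx(p_exact, abs=1e-10)

    def test_exact_and_asymptotic_agree_near_crossover(self, rng):
        from scipy.stats import mannwhitneyu
        a = rng.normal(size=25)
        b = rng.normal(loc=0.5, size=25)
        pe = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        pa = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert abs(pe - pa) < 0.01


class TestSpearmanMatrix:
    def test_self_correlation_one(self):
        t = pd.DataFrame({"x": [1.0, 4.0, 2.0, 8.0]})
        m = spearman_matrix(t, ["x"], ["x"])
        assert m.rho.loc["x", "x"] == pytest.approx(1.0)

    def test_monotone_decreasing_minus_one(self):
        t = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [9.0, 4.0, 1.0]})
        m = spearman_matrix(t, ["x"], ["y"])
        assert m.rho.loc["x", "y"] == pytest.approx(-1.0)

    def test_insufficient_pairs_recorded(self):
        t = pd.DataFrame({"x": [1.0, np.nan, np.nan],
                          "y": [2.0, 3.0, np.nan]})
        m = spearman_matrix(t, ["x"], ["y"])
        assert math.isnan(m.rho.loc["x", "y"])
        assert ("x", "y") in m.reasons

    def test_planted_sign_structure(self):
        from lipophen.simulate import default_derivation_config, generate_cohort
        table, _ = generate_cohort(default_derivation_config(n=500, seed=21))
        frame = table.to_frame()
        m = spearman_matrix(frame, ["hdl_c", "triglycerides"], ["icam1"])
        assert m.rho.loc["hdl_c", "icam1"] < 0
        assert m.rho.loc["triglycerides", "icam1"] > 0


class TestOutcomeTable:
    def _series(self, counts_by_cluster):
        labels, outcomes = [], []
        for cluster, counts in counts_by_cluster.items():
            for outcome, k in counts.items():
                for _ in range(k):
                    labels.append(cluster)
                    outcomes.append(outcome)
        ids = [f"p{i}" for i in range(len(labels))]
        return (pd.Series(labels, index=ids), pd.Series(outcomes, index=ids))

    def test_58_patient_cluster_percentages(self):
        labels, outcomes = self._series({
            "hypo": {"rapid_recovery": 26, "cci": 23, "early_death": 9}})
        t = cluster_outcome_table(labels, outcomes)
        assert t.percentages.loc["hypo"].tolist() == [44.8, 39.7, 15.5]

    def test_60_patient_cluster_percentages(self):
        labels, outcomes = self._series({
            "normo": {"rapid_recovery": 33, "cci": 19, "early_death": 8}})
        t = cluster_outcome_table(labels, outcomes)
        assert t.percentages.loc["normo"].tolist() == [55.0, 31.7, 13.3]

    def test_percentages_sum_to_100(self, derivation_run):
        for _, row in derivation_run.outcome_table.percentages.iterrows():
            assert row[["rapid_recovery", "cci", "early_death"]].sum() == \
                pytest.approx(100.0, abs=0.1)

    def test_missing_outcome_is_error(self):
        labels = pd.Series(["a", "a"], index=["p1", "p2"])
        outcomes = pd.Series(["cci", None], index=["p1", "p2"])
        with pytest.raises(StatsError, match="p2"):
            cluster_outcome_table(labels, outcomes)

    def test_empty_input_is_error(self):
        with pytest.raises(StatsError):
            cluster_outcome_table(pd.Series(dtype=object),
                                  pd.Series(dtype=object))


class TestLasso:
    @pytest.fixture(scope="class")
    def planted(self):
        from lipophen.simulate import generate_planted_effect_cohort
        return generate_planted_effect_cohort(n=400, or_per_sd=0.2, seed=7)

    def test_huge_penalty_selects_nothing(self, planted):
        X, y = planted
        model = LassoOutcomeModel(cv_folds=3, n_lambdas=4, seed=0)
        cand, D = model._design(X)
        mu, sd = D.mean(), D.std(ddof=1)
        Z = ((D - mu) / sd).to_numpy()
        coef = model._fit_l1(Z, y.to_numpy(), lam=10.0)
        assert (coef == 0.0).all()

    def test_zero_penalty_matches_unpenalized_mle(self, planted):
        import statsmodels.api as sm
        X, y = planted
        sub = ["apoa1", "sofa_total", "charlson"]
        model = LassoOutcomeModel(candidates=sub)
        cand, D = model._design(X)
        Z = ((D - D.mean()) / D.std(ddof=1)).to_numpy()
        ours = model._fit_l1(Z, y.to_numpy(), lam=0.0)
        ref = sm.Logit(y.to_numpy(), sm.add_constant(Z)).fit(disp=0)
        assert np.allclose(ours, ref.params[1:], atol=1e-6)

    def test_selection_path_shrinks_with_penalty(self, planted):
        X, y = planted
        fit = lasso_select(X, list(X.columns), y, cv_folds=3, seed=0,
                           n_lambdas=12)
        dfs = fit.path.sort_values("lambda", ascending=False)["df"].tolist()
        assert all(a <= b for a, b in zip(dfs, dfs[1:]))

    def test_planted_protective_effect_recovered(self, planted):
        X, y = planted
        fit = lasso_select(X, list(X.columns), y, cv_folds=5, seed=0)
        assert "apoa1" in fit.selected
        row = fit.odds_ratios.set_index("variable").loc["apoa1"]
        assert row["odds_ratio"] < 1.0
        assert row["ci_low"] <= row["odds_ratio"] <= row["ci_high"]

    def test_refit_reports_or_with_ci(self, planted):
        X, y = planted
        fit = lasso_select(X, list(X.columns), y, cv_folds=3, seed=1)
        assert (fit.odds_ratios["odds_ratio"] > 0).all()
        assert (fit.odds_ratios["ci_low"] <= fit.odds_ratios["odds_ratio"]).all()


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]).auc == 1.0

    def test_constant_scores_half(self):
        assert roc_auc([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1]).auc == 0.5

    def test_worked_example(self):
        # 3 of 4 positive-negative pairs concordant
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]).auc == 0.75

    def test_curve_endpoints(self, rng):
        res = roc_auc(rng.normal(size=30), rng.integers(0, 2, 30))
        assert res.points.iloc[0].tolist() == [0.0, 0.0]
        assert res.points.iloc[-1].tolist() == [1.0, 1.0]

    def test_one_class_is_error(self):
        with pytest.raises(StatsError):
            roc_auc([1.0, 2.0], [1, 1])

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_matches_brute_force_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        scores = np.round(rng.normal(size=n), 1)     # induce ties
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        pos, neg = scores[y == 1], scores[y == 0]
        brute = sum(1.0 if p > q else 0.5 if p == q else 0.0
                    for p in pos for q in neg) / (len(pos) * len(neg))
        assert roc_auc(scores, y).auc == pytest.approx(brute, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = rng.normal(size=80)
        y = rng.integers(0, 2, 80)
        assert roc_auc(scores, y).auc == pytest.approx(
            roc_auc_score(y, scores), abs=1e-12)

    def test_binary_predictor_closed_form(self):
        pred = np.array([1, 1, 0, 0, 1, 0])
        y = np.array([1, 0, 0, 1, 1, 0])
        sens = ((pred == 1) & (y == 1)).sum() / (y == 1).sum()
        spec = ((pred == 0) & (y == 0)).sum() / (y == 0).sum()
        assert roc_auc(pred, y).auc == pytest.approx((sens + spec) / 2)


class TestSignatureAucComparison:
    def test_membership_identical_to_outcome_gives_one(self):
        y = pd.Series([1, 0, 1, 0], index=list("abcd"))
        rocs = compare_signature_auc(y, y.astype(float), y.astype(float), y)
        assert all(r.auc == 1.0 for r in rocs)

    def test_three_predictors_on_synthetic_cohort(self, derivation_cohort,
                                                  derivation_run):
        table, _ = derivation_cohort
        frame = table.to_frame()
        y = pd.Series([p.outcome != "rapid_recovery" for p in table.patients],
                      index=frame.index).astype(int)
        membership = (derivation_run.phenotype == "hypolipoprotein").astype(int)
        rocs = compare_signature_auc(membership, frame["sofa_total"],
                                     frame["apache2"], y)
        assert [r.predictor for r in rocs] == ["cluster", "sofa", "apache2"]
        assert 0.6 <= rocs[0].auc <= 0.9

    def test_continuous_score_orders_phenotypes(self, derivation_run):
        score = continuous_cluster_score(derivation_run.z_matrix,
                                         derivation_run.phenotype)
        sem = derivation_run.phenotype
        assert score[sem == "hypolipoprotein"].mean() > \
            score[sem == "normolipoprotein"].mean()
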