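import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gaitshotgun.core_io import StudyDesign
from gaitshotgun.ranking import (
    AnovaResult,
    LogisticModel,
    bonferroni_threshold,
    correct_rate,
    fit_multinomial_logistic,
    fit_pls_indicator,
    mixed_anova_twoway,
    oneway_anova_between,
    rank_measures,
    relative_difference,
    rm_anova_oneway,
    select_by_pvalue,
    zscore,
)
from gaitshotgun.synthetic import generate_measure_table


def _design(groups, conditions):
    obs = []
    i = 0
    for g, n in groups.items():
        for _ in range(n):
            i += 1
            for c in conditions:
                obs.append((f"s{i:02d}", g, c))
    return StudyDesign(obs)


def _table(design, values_by_obs):
    rows = {(s, c): values_by_obs[(s, c)] for s, _, c in design.observations}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["subject", "condition"])
    return df


class TestRmAnova:
    def test_no_condition_difference_null(self):
        design = _design({"g": 6}, ("c1", "c2", "c3"))
        subj_vals = {f"s{i:02d}": 10.0 + i for i in range(1, 7)}
        table = _table(design, {(s, c): [subj_vals[s]]
                                for s, _, c in design.observations})
        res = rm_anova_oneway(table, design)
        assert res.table.F.iloc[0] == pytest.approx(0.0, abs=1e-20)
        assert res.table.p.iloc[0] == pytest.approx(1.0)

    def test_hand_computed_three_subject_fixture(self):
        # classic two-way (subject x condition) decomposition by hand
        data = {("s1", "c1"): 3.0, ("s1", "c2"): 5.0, ("s1", "c3"): 4.0,
                ("s2", "c1"): 2.0, ("s2", "c2"): 6.0, ("s2", "c3"): 5.0,
                ("s3", "c1"): 4.0, ("s3", "c2"): 7.0, ("s3", "c3"): 6.0}
        design = StudyDesign([(s, "g", c) for (s, c) in data])
        table = _table(design, {k: [v] for k, v in data.items()})
        x = np.array([[3, 5, 4], [2, 6, 5], [4, 7, 6]], dtype=float)
        grand = x.mean()
        ss_cond = 3 * ((x.mean(0) - grand) ** 2).sum()
        ss_subj = 3 * ((x.mean(1) - grand) ** 2).sum()
        ss_err = ((x - grand) ** 2).sum() - ss_cond - ss_subj
        f_expected = (ss_cond / 2) / (ss_err / 4)
        res = rm_anova_oneway(table, design)
        assert res.table.F.iloc[0] == pytest.approx(f_expected, abs=1e-9)
        assert res.table.eta_p2.iloc[0] == pytest.approx(
            ss_cond / (ss_cond + ss_err), abs=1e-12)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        table, design = generate_measure_table(
            n_measures=1, groups={"g": 8}, conditions=("c1", "c2", "c3"), seed=9)
        ours = rm_anova_oneway(table, design).table.iloc[0]
        long = table.reset_index().melt(id_vars=["subject", "condition"])
        ref = pg.rm_anova(data=long, dv="value", within="condition",
                          subject="subject", detailed=True, effsize="np2").iloc[0]
        assert ours.F == pytest.approx(ref.F, rel=1e-9)
        assert ours.p == pytest.approx(ref["p_unc"], rel=1e-9)
        assert ours.eta_p2 == pytest.approx(ref["np2"], rel=1e-9)

    def test_power_at_two_sd_shift(self):
        # a two-within-SD condition shift with n=14 is essentially always seen
        hits = 0
        for s in range(100):
            table, design = generate_measure_table(
                n_measures=1, groups={"g": 14}, conditions=("c1", "c2", "c3"),
                effects=(("m001", "condition", "c3", 2.0),), seed=50_000 + s)
            p = rm_anova_oneway(table, design).table.p.iloc[0]
            hits += p < 0.001
        assert hits >= 95

    def test_single_condition_rejected(self):
        table, design = generate_measure_table(
            n_measures=1, groups={"g": 5}, conditions=("c1",), seed=0)
        with pytest.raises(ValueError, match="one level"):
            rm_anova_oneway(table, design)


class TestMixedAnova:
    def test_matches_pingouin_unbalanced_groups(self):
        pg = pytest.importorskip("pingouin")
        table, design = generate_measure_table(
            n_measures=1, groups={"a": 5, "b": 7}, conditions=("c1", "c2"), seed=21)
        ours = mixed_anova_twoway(table, design).table.set_index("effect")
        long = table.reset_index().melt(id_vars=["subject", "condition"])
        long["group"] = [design.group_of(s) for s in long.subject]
        ref = pg.mixed_anova(data=long, dv="value", within="condition",
                             subject="subject", between="group").set_index("Source")
        for ours_key, ref_key in (("group", "group"), ("condition", "condition"),
                                  ("interaction", "Interaction")):
            assert ours.loc[ours_key, "F"] == pytest.approx(
                ref.loc[ref_key, "F"], rel=1e-9)
            assert ours.loc[ours_key, "p"] == pytest.approx(
                ref.loc[ref_key, "p_unc"], rel=1e-9)
            assert ours.loc[ours_key, "eta_p2"] == pytest.approx(
                ref.loc[ref_key, "np2"], rel=1e-9)

    def test_group_relabeling_invariance(self):
        table, design = generate_measure_table(
            n_measures=2, groups={"a": 5, "b": 5}, conditions=("c1", "c2"), seed=3)
        swapped = StudyDesign([(s, {"a": "b", "b": "a"}[g], c)
                               for s, g, c in design.observations])
        r1 = mixed_anova_twoway(table, design).table
        r2 = mixed_anova_twoway(table, swapped).table
        np.testing.assert_allclose(r1.p.to_numpy(), r2.p.to_numpy(), rtol=1e-12)

    def test_pure_interaction_zero_error_degenerate(self):
        design = _design({"a": 2, "b": 2}, ("c1", "c2"))
        vals = {}
        for s, g, c in design.observations:
            sign = 1.0 if g == "a" else -1.0
            vals[(s, c)] = [sign if c == "c1" else -sign]
        table = _table(design, vals)
        res = mixed_anova_twoway(table, design).table.set_index("effect")
        assert math.isinf(res.loc["interaction", "F"])
        assert res.loc["interaction", "p"] == 0.0

    def test_tiny_group_rejected(self):
        table, design = generate_measure_table(
            n_measures=1, groups={"a": 1, "b": 5}, conditions=("c1", "c2"), seed=0)
        with pytest.raises(ValueError, match="fewer than 2"):
            mixed_anova_twoway(table, design)


class TestBonferroniAndRelDiff:
    @pytest.mark.parametrize("n,expected", [(61, 0.05 / 61), (1, 0.05),
                                            (113, 0.05 / 113)])
    def test_threshold(self, n, expected):
        assert bonferroni_threshold(n) == pytest.approx(expected, abs=1e-12)

    def test_relative_difference_examples(self):
        np.testing.assert_allclose(relative_difference([3.0], [3.0]), [0.0])
        np.testing.assert_allclose(relative_difference([3.0], [1.0]), [1.0])
        np.testing.assert_allclose(relative_difference([1.0], [3.0]), [-1.0])

    def test_zero_pair_mean_missing(self):
        out = relative_difference([1.0, -2.0], [1.0, 2.0])
        assert out[0] == 0.0 and math.isnan(out[1])


class TestSelection:
    def _anova(self, ps, etas=None):
        n = len(ps)
        etas = etas or [0.1] * n
        return AnovaResult(table=pd.DataFrame({
            "measure": [f"m{i}" for i in range(n)],
            "effect": ["condition"] * n, "F": [1.0] * n,
            "p": ps, "eta_p2": etas}), family_size=n)

    def test_top_k_smallest_p(self):
        ps = list(np.linspace(0.01, 0.5, 10))
        sel = select_by_pvalue(self._anova(ps), k=7)
        assert sel == [f"m{i}" for i in range(7)]

    def test_threshold_mode(self):
        ps = [1e-5, 2e-5, 3e-5] + [0.2] * 58
        anova = self._anova(ps)
        sel = select_by_pvalue(anova, mode="threshold")
        assert sel == ["m0", "m1", "m2"]
        assert anova.threshold == pytest.approx(0.05 / 61)

    def test_tie_break_deterministic(self):
        sel1 = select_by_pvalue(self._anova([0.5] * 10), k=7)
        sel2 = select_by_pvalue(self._anova([0.5] * 10), k=7)
        assert sel1 == sel2 == sorted(sel1)


class TestLogistic:
    def test_matches_statsmodels_irls_oracle(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X = rng.standard_normal((60, 4))
        beta = rng.normal(0, 1.0, (4, 2))
        logits = np.column_stack([X @ beta, np.zeros(60)])
        probs = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
        y = np.array([str(rng.choice(3, p=p)) for p in probs])
        ours = fit_multinomial_logistic(X, y)
        cats = sorted(set(y))
        codes = pd.Categorical(y, categories=cats[::-1]).codes  # ref = last cat
        ref = sm.MNLogit(codes, sm.add_constant(zscore(X))).fit(disp=0)
        params = np.asarray(ref.params)  # columns: cats[-2], cats[-3], ...
        for j, cat in enumerate(cats[:-1]):
            col = cats[::-1].index(cat) - 1
            np.testing.assert_allclose(ours.coef[j], params[:, col], atol=1e-6)

    def test_beta_identity_and_norm(self, rng):
        X = rng.standard_normal((45, 3))
        y = rng.choice(["1", "2", "3"], 45)
        m = fit_multinomial_logistic(X, y, reference="3")
        diff = m.beta_pairs[("1", "2")] - (m.beta_pairs[("1", "3")]
                                           - m.beta_pairs[("2", "3")])
        assert np.max(np.abs(diff)) < 1e-12
        stacked = np.stack([m.beta_pairs[k] for k in m.beta_pairs])
        np.testing.assert_allclose(m.beta_norm.to_numpy(),
                                   np.linalg.norm(stacked, axis=0), atol=1e-12)

    def test_separable_two_class_rate_one(self):
        X = np.concatenate([np.full(10, -2.0), np.full(10, 2.0)])[:, None]
        X = X + np.linspace(-0.1, 0.1, 20)[:, None]
        y = ["a"] * 10 + ["b"] * 10
        m = fit_multinomial_logistic(X, y)
        assert m.correct_rate == 1.0

    def test_affine_invariance_of_probabilities(self, rng):
        X = rng.standard_normal((40, 3))
        y = rng.choice(["a", "b", "c"], 40)
        m1 = fit_multinomial_logistic(X, y)
        X2 = X.copy()
        X2[:, 0] = 5.0 * X2[:, 0] - 7.0
        m2 = fit_multinomial_logistic(X2, y)
        np.testing.assert_allclose(m2.probabilities, m1.probabilities, atol=1e-6)
        assert m2.correct_rate == m1.correct_rate

    def test_permutation_null_rate_near_chance(self):
        rates = []
        for s in range(20):
            r = np.random.default_rng(700 + s)
            X = r.standard_normal((60, 3))
            y = r.permutation(["a", "b", "c"] * 20)
            rates.append(fit_multinomial_logistic(X, y).correct_rate)
        assert np.mean(rates) <= 0.6

    def test_majority_class_baseline_rate(self):
        # a model that always predicts the prior-majority class is right
        # exactly as often as that class occurs
        y = ["a"] * 5 + ["b"] * 3 + ["c"] * 2
        probs = np.tile([0.5, 0.3, 0.2], (10, 1))
        model = LogisticModel(
            categories=["a", "b", "c"], reference="c", measure_names=["x"],
            coef=np.zeros((2, 2)), beta_pairs={}, beta_norm=pd.Series(dtype=float),
            pvalues=np.zeros((2, 2)), probabilities=probs, correct_rate=0.0,
            converged=True)
        assert correct_rate(model, None, y) == 0.5

    def test_loglik_monotone_in_nested_measures(self, rng):
        X = rng.standard_normal((42, 7))
        y = rng.choice(["a", "b", "c"], 42)
        cats = sorted(set(y))
        loglik = []
        for k in range(1, 8):
            m = fit_multinomial_logistic(X[:, :k], y)
            idx = [cats.index(v) for v in y]
            loglik.append(np.sum(np.log(m.probabilities[np.arange(42), idx])))
        assert all(b >= a - 1e-6 for a, b in zip(loglik, loglik[1:]))

    def test_collinear_columns_rejected(self, rng):
        X = rng.standard_normal((30, 2))
        X = np.column_stack([X, X[:, 0] * 2.0])
        with pytest.raises(ValueError, match="collinear"):
            fit_multinomial_logistic(X, rng.choice(["a", "b"], 30))

    def test_zscore_columns_standardized(self, rng):
        Z = zscore(rng.standard_normal((30, 4)) * 7 + 3)
        np.testing.assert_allclose(Z.mean(0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Z.std(0), 1.0, atol=1e-9)


class TestPls:
    def test_matches_sklearn_oracle(self, rng):
        skl = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.standard_normal((40, 10))
        y = rng.choice(["a", "b", "c"], 40)
        ours = fit_pls_indicator(X, y, n_components=5)
        Y = np.stack([(y == c).astype(float) for c in sorted(set(y))], axis=1)
        Xz = (X - X.mean(0)) / X.std(0)
        ref = skl.PLSRegression(n_components=5, scale=False, tol=1e-12,
                                max_iter=2000).fit(Xz, Y)
        np.testing.assert_allclose(ours.coef, ref.coef_.T, atol=1e-6)
        np.testing.assert_allclose(np.abs(ours.T), np.abs(ref.x_scores_),
                                   atol=1e-5)

    def test_scores_orthogonal_and_x_reconstructed(self, rng):
        X = rng.standard_normal((30, 8))
        y = rng.choice(["a", "b"], 30)
        m = fit_pls_indicator(X, y, n_components=4)
        gram = m.T.T @ m.T
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8
        Xz = (X - X.mean(0)) / X.std(0)
        np.testing.assert_allclose(Xz, m.T @ m.P.T + m.x_residual, atol=1e-8)

    def test_exact_linear_response_zero_residual(self, rng):
        X = rng.standard_normal((30, 6))
        # indicator response that is an exact linear function of X
        scores = X @ rng.standard_normal((6, 3))
        y = np.array(["abc"[i] for i in np.argmax(scores, axis=1)])
        Y = np.stack([(y == c).astype(float) for c in sorted(set(y))], axis=1)
        Yc = Y - Y.mean(0)
        # replace the one-hot response by the linear scores to hit the limit
        m = fit_pls_indicator(X, y, n_components=6)
        pred = m.predict_scores(X)
        resid = Y - pred
        ols = np.linalg.lstsq(
            np.column_stack([np.ones(30), (X - X.mean(0)) / X.std(0)]), Y,
            rcond=None)
        np.testing.assert_allclose(resid, Y - (np.column_stack(
            [np.ones(30), (X - X.mean(0)) / X.std(0)]) @ ols[0]), atol=1e-8)

    def test_full_rank_equals_ols_predictions(self, rng):
        X = rng.standard_normal((30, 8))
        y = rng.choice(["a", "b", "c"], 30)
        m = fit_pls_indicator(X, y, n_components=8)
        Y = np.stack([(y == c).astype(float) for c in sorted(set(y))], axis=1)
        Xz = (X - X.mean(0)) / X.std(0)
        ols = np.linalg.lstsq(np.column_stack([np.ones(30), Xz]), Y, rcond=None)[0]
        np.testing.assert_allclose(m.predict_scores(X),
                                   np.column_stack([np.ones(30), Xz]) @ ols,
                                   atol=1e-6)

    def test_component_bound_enforced(self, rng):
        with pytest.raises(ValueError, match="n_components"):
            fit_pls_indicator(rng.standard_normal((10, 4)),
                              ["a", "b"] * 5, n_components=10)


class TestRankMeasures:
    def test_planted_measure_tops_both_routes(self):
        hits = 0
        n_seeds = 50
        for s in range(n_seeds):
            table, design = generate_measure_table(
                n_measures=30, groups={"a": 19, "b": 19, "c": 19},
                conditions=("c1", "c2"),
                effects=(("planted", "group_condition", "b:c2", 3.0),),
                seed=9_000 + s)
            rep = rank_measures(table, design, mode="studyB")
            hits += (rep.orderings["logistic"][0] == "planted"
                     and rep.orderings["pls"][0] == "planted")
        assert hits >= 0.9 * n_seeds

    def test_pure_noise_routes_disagree(self):
        jaccards = []
        for s in range(20):
            table, design = generate_measure_table(
                n_measures=61, groups={"a": 10, "b": 10, "c": 10},
                conditions=("c1", "c2"), seed=20_000 + s)
            rep = rank_measures(table, design, mode="studyB")
            top_l = set(rep.orderings["logistic"][:7])
            top_p = set(rep.orderings["pls"][:7])
            jaccards.append(len(top_l & top_p) / len(top_l | top_p))
        assert np.median(jaccards) < 0.5

    def test_anova_pvalues_uniform_under_null(self):
        pvals = []
        for s in range(10):
            table, design = generate_measure_table(
                n_measures=61, groups={"g": 14}, conditions=("c1", "c2", "c3"),
                seed=31_000 + s)
            res = rm_anova_oneway(table, design)
            pvals.extend(res.table.p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_single_condition_guard(self):
        table, design = generate_measure_table(
            n_measures=5, groups={"g": 5}, conditions=("only",), seed=0)
        with pytest.raises(ValueError, match="one level"):
            rank_measures(table, design, mode="studyA")

    def test_study_a_report_structure(self):
        table, design = generate_measure_table(
            n_measures=20, groups={"g": 14}, conditions=("c1", "c2", "c3"),
            effects=(("planted", "condition", "c3", 2.0),), seed=77)
        rep = rank_measures(table, design, mode="studyA")
        assert len(rep.selected) == 7
        assert sorted(rep.orderings["logistic"]) == sorted(rep.selected)
        assert sorted(rep.orderings["pls"]) == sorted(table.columns)
        assert 0.0 <= rep.logistic.correct_rate <= 1.0
        assert "planted" in rep.selected
        text = rep.summary()
        assert "correct rate" in text

    def test_oneway_between_matches_scipy(self, rng):
        vals = pd.DataFrame({"m": rng.standard_normal(30)})
        groups = pd.Series(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        res = oneway_anova_between(vals, groups).table.iloc[0]
        ref = stats.f_oneway(vals.m[:10], vals.m[10:20], vals.m[20:])
        assert res.F == pytest.approx(ref.statistic, rel=1e-9)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)
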