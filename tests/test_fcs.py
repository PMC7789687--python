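"""Imputation engine: presets, imputers, chained draws, Rubin pooling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import wavegap as wg
import wavegap.columns as C
from wavegap.fcs import ImputationConfig, dichotomized_target, prepare_target_column
from wavegap.imputers import BayesianLinearImputer, DiscriminantImputer
from wavegap.pooling import pool_rubin


class TestPresets:
    def test_phq_presets_have_eight_item_predictors(self):
        specs, visit = wg.apply_preset("PHQ-BIN")
        predictors = [s for s in specs if s.role == "predictor"]
        target = [s for s in specs if s.role == "target"][0]
        assert len(predictors) == 8
        assert {s.name for s in predictors} == set(C.PHQ_ITEMS) - {C.IDEATION_ITEM}
        assert target.level == "binary"
        assert visit[0] == target.name

    def test_all_ord_has_forty_eight_predictors(self):
        specs, _ = wg.apply_preset("ALL-ORD")
        predictors = [s for s in specs if s.role == "predictor"]
        target = [s for s in specs if s.role == "target"][0]
        assert len(predictors) == 48
        assert target.level == "ordinal4"
        names = {s.name for s in predictors}
        assert C.SLEEP_HOURS in names and C.PTSD_SCREEN in names
        assert set(C.PCL_ITEMS) <= names and set(C.ALC_ITEMS) <= names

    def test_sleep_enters_continuous_and_items_ordinal(self):
        specs, _ = wg.apply_preset("ALL-BIN")
        by_name = {s.name: s for s in specs}
        assert by_name[C.SLEEP_HOURS].level == "continuous"
        assert by_name[C.SLEEP_HOURS].imputation_form == "linear"
        for item in set(C.PHQ_ITEMS) - {C.IDEATION_ITEM}:
            assert by_name[item].level == "ordinal4"

    def test_alternate_target_swaps_item_into_predictors(self):
        specs, _ = wg.apply_preset("PHQ-ORD", target_item=C.TIRED_ITEM)
        names = {s.name for s in specs if s.role == "predictor"}
        assert C.IDEATION_ITEM in names and C.TIRED_ITEM not in names

    def test_unknown_preset_and_ran_rejected(self):
        with pytest.raises(ValueError):
            wg.apply_preset("PHQ-XYZ")
        with pytest.raises(ValueError):
            wg.apply_preset("RAN")

    def test_custom_spec_without_predictors_rejected(self):
        specs = [wg.VariableSpec("y", "binary", "discriminant", "target")]
        table = pd.DataFrame({"y": [0.0, np.nan, 1.0]})
        with pytest.raises(ValueError, match="predictor"):
            wg.fit_fcs(table, specs, ImputationConfig(m_imputations=2))


def _toy_long_table(n, rng, target_from_predictor=True):
    """Minimal two-wave table: binary predictor b, binary target y."""
    pid = np.repeat([f"p{i}" for i in range(n)], 2)
    wave = np.tile(["W1", "W2"], n)
    b = rng.integers(0, 2, size=2 * n).astype(float)
    if target_from_predictor:
        y = b.copy()
    else:
        y = (rng.random(2 * n) < 0.3).astype(float)
    return pd.DataFrame({C.PID: pid, C.WAVE: wave, "b": b, "y": y})


def _mask_w2(table, col="y"):
    out = table.copy()
    rows = out[C.WAVE] == "W2"
    truth = out.loc[rows, col].to_numpy().copy()
    out.loc[rows, col] = np.nan
    return out, rows.to_numpy(), truth


def _specs():
    return [
        wg.VariableSpec("y", "binary", "discriminant", "target"),
        wg.VariableSpec("b", "binary", "discriminant", "predictor"),
    ]


class TestFitFcs:
    def test_no_missing_cells_returns_identical_copies(self, cohort):
        specs, visit = wg.apply_preset("PHQ-ORD")
        cfg = ImputationConfig(m_imputations=3, visit_sequence=visit, seed=1)
        out = wg.fit_fcs(cohort, specs, cfg)
        for tab in out.tables:
            pd.testing.assert_frame_equal(tab, cohort)

    def test_exact_copy_predictor_recovered_with_high_accuracy(self):
        rng = np.random.default_rng(8)
        table = _toy_long_table(400, rng, target_from_predictor=True)
        masked, w2, truth = _mask_w2(table)
        cfg = ImputationConfig(m_imputations=5, visit_sequence=["y"], seed=2)
        out = wg.fit_fcs(masked, _specs(), cfg)
        for vals in out.imputed_values(w2):
            acc = np.mean(vals == truth)
            assert acc >= 0.95

    def test_independent_target_reproduces_marginal_prevalence(self):
        rng = np.random.default_rng(9)
        table = _toy_long_table(600, rng, target_from_predictor=False)
        masked, w2, _ = _mask_w2(table)
        w1_prev = table.loc[table[C.WAVE] == "W1", "y"].mean()
        cfg = ImputationConfig(m_imputations=40, visit_sequence=["y"], seed=3)
        out = wg.fit_fcs(masked, _specs(), cfg)
        prevs = [np.mean(v) for v in out.imputed_values(w2)]
        se = np.sqrt(w1_prev * (1 - w1_prev) / 600 / 40) + 0.01
        assert abs(np.mean(prevs) - w1_prev) < 4 * se

    def test_observed_cells_preserved_bit_exactly(self, masked_cohort, completed_phq_bin):
        masked, _, _ = masked_cohort
        observed = ~masked[C.IDEATION_ITEM].isna()
        for tab in completed_phq_bin.tables:
            assert not tab[completed_phq_bin.target].isna().any()
            pd.testing.assert_frame_equal(
                tab.loc[observed, masked.columns], masked.loc[observed]
            )

    def test_same_seed_reproduces_completed_set(self, masked_cohort):
        masked, _, _ = masked_cohort
        work, _ = prepare_target_column(masked, C.IDEATION_ITEM, "ordinal4")
        specs, visit = wg.apply_preset("PHQ-ORD")
        cfg = ImputationConfig(m_imputations=3, visit_sequence=visit, seed=77)
        a = wg.fit_fcs(work, specs, cfg)
        b = wg.fit_fcs(work, specs, cfg)
        for ta, tb in zip(a.tables, b.tables):
            pd.testing.assert_frame_equal(ta, tb)

    def test_fully_missing_variable_rejected(self):
        table = pd.DataFrame({"y": [np.nan, np.nan], "b": [0.0, 1.0],
                              C.WAVE: ["W1", "W2"], C.PID: ["a", "a"]})
        with pytest.raises(ValueError, match="no observed rows"):
            wg.fit_fcs(table, _specs(), ImputationConfig(m_imputations=2,
                                                         visit_sequence=["y"]))

    def test_m_below_two_rejected(self):
        with pytest.raises(ValueError):
            ImputationConfig(m_imputations=1)

    def test_ordinal_target_dichotomized_after_imputation(self, masked_cohort):
        masked, _, _ = masked_cohort
        work, _ = prepare_target_column(masked, C.IDEATION_ITEM, "ordinal4")
        specs, visit = wg.apply_preset("PHQ-ORD")
        cfg = ImputationConfig(m_imputations=2, visit_sequence=visit, seed=12)
        out = wg.fit_fcs(work, specs, cfg)
        w2 = (masked[C.WAVE] == "W2").to_numpy()
        raw = out.imputed_values(w2)
        binary = dichotomized_target(out, w2)
        for r, b in zip(raw, binary):
            assert set(np.unique(b)) <= {0, 1}
            assert np.array_equal(b, (np.asarray(r, dtype=float) >= 1).astype(int))


class TestDiscriminantImputer:
    def test_posterior_matches_explicit_bayes_rule(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 4, size=(40, 2)).astype(float)
        y = rng.integers(0, 3, size=40)
        imp = DiscriminantImputer(bootstrap=False).fit(X, y)
        classes = np.unique(y)
        priors = np.array([(y == c).mean() for c in classes])
        means = np.vstack([X[y == c].mean(axis=0) for c in classes])
        S = sum((X[y == c] - means[i]).T @ (X[y == c] - means[i])
                for i, c in enumerate(classes)) / (40 - classes.size)
        S[np.diag_indices_from(S)] += 1e-6
        dens = np.column_stack(
            [priors[i] * stats.multivariate_normal.pdf(X, means[i], S)
             for i in range(classes.size)]
        )
        oracle = dens / dens.sum(axis=1, keepdims=True)
        assert np.abs(imp.posterior(X) - oracle).max() < 1e-8

    def test_collinear_predictors_handled_by_rank_reduction(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(60)
        X = np.column_stack([x, x, rng.standard_normal(60)])  # duplicated column
        y = (x > 0).astype(int)
        imp = DiscriminantImputer(bootstrap=False).fit(X, y)
        post = imp.posterior(X)
        assert np.all(np.isfinite(post))
        np.testing.assert_allclose(post.sum(axis=1), 1.0)
        assert imp.rank_ <= X.shape[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            DiscriminantImputer(bootstrap=False).fit(np.zeros((5, 1)), np.zeros(5))

    def test_bootstrap_requires_rng(self):
        with pytest.raises(ValueError):
            DiscriminantImputer().fit(np.zeros((5, 1)), np.array([0, 1, 0, 1, 0]))


class TestBayesianLinearImputer:
    def test_draws_concentrate_on_truth_at_large_n(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20000, 1))
        y = 1.0 + 2.0 * X[:, 0] + 0.5 * rng.standard_normal(20000)
        imp = BayesianLinearImputer().fit(X, y, rng)
        assert abs(imp.beta_[0] - 1.0) < 0.05
        assert abs(imp.beta_[1] - 2.0) < 0.05
        assert abs(imp.sigma_ - 0.5) < 0.02
        draws = imp.draw(np.zeros((5000, 1)), rng)
        assert abs(draws.mean() - 1.0) < 0.05
        assert abs(draws.std() - 0.5) < 0.05


class TestRanAssign:
    def test_extremes(self):
        assert not wg.ran_assign(100, 0.0, 1).any()
        assert wg.ran_assign(100, 1.0, 1).all()

    def test_expected_positive_count_at_study_scale(self):
        draws = wg.ran_assign(63028, 0.0405, np.random.default_rng(5))
        se = np.sqrt(63028 * 0.0405 * (1 - 0.0405))
        assert abs(draws.sum() - 2553) < 4 * se

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            wg.ran_assign(10, 1.5, 1)


class TestPoolRubin:
    def test_degenerate_identical_estimates(self):
        pe = pool_rubin([2.0] * 5, [0.3] * 5)
        assert pe.point == 2.0
        assert pe.between_var == 0.0
        assert pe.total_var == pe.within_var == 0.3
        assert np.isinf(pe.df)

    def test_hand_arithmetic_m2(self):
        pe = pool_rubin([0.0, 1.0], [1.0, 1.0])
        assert pe.point == 0.5
        assert pe.within_var == 1.0
        assert pe.between_var == 0.5
        assert pe.total_var == pytest.approx(1.75)
        assert pe.ci95[0] < 0.5 < pe.ci95[1]

    def test_total_at_least_within(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            q = rng.standard_normal(10)
            w = rng.random(10)
            pe = pool_rubin(q, w)
            assert pe.total_var >= pe.within_var

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            pool_rubin([1.0], [1.0])
        with pytest.raises(ValueError):
            pool_rubin([1.0, np.nan], [1.0, 1.0])
        with pytest.raises(ValueError):
            pool_rubin([1.0, 2.0], [1.0, -1.0])

    def test_normal_mean_interval_coverage(self):
        """Proper marginal imputation of an MCAR normal mean covers ~95%."""
        rng = np.random.default_rng(17)
        reps, n, m, mu = 400, 60, 10, 0.7
        covered = 0
        for _ in range(reps):
            y = mu + rng.standard_normal(n)
            obs = rng.random(n) > 0.4
            est, var = [], []
            for _ in range(m):
                imp = BayesianLinearImputer().fit(
                    np.empty((obs.sum(), 0)), y[obs], rng)
                yi = y.copy()
                yi[~obs] = imp.draw(np.empty(((~obs).sum(), 0)), rng)
                est.append(yi.mean())
                var.append(yi.var(ddof=1) / n)
            pe = pool_rubin(est, var)
            covered += pe.ci95[0] <= mu <= pe.ci95[1]
        assert 0.92 <= covered / reps <= 0.98
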