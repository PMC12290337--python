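"""Conjoint-measurement fitting, nested tests and aggregation."""

import numpy as np
import pytest

from glosstrans import mlcm, synth
from glosstrans.mlcm import ConjointModel, bonferroni_level, lr_test, proportion_matrix
from glosstrans.synth import ConjointTrial, ObserverModel, StimulusGrid


def _simulate(grid, observer, reps, seed):
    design = synth.build_conjoint_design(grid, reps, seed=seed)
    return synth.simulate_conjoint_responses(design, observer, seed=seed + 1)


class TestFit:
    def test_null_data_estimates_near_zero(self, grid44):
        obs = ObserverModel(psi_g=(0.0,) * 4, psi_r=(0.0,) * 4, sigma=1.0)
        trials = _simulate(grid44, obs, reps=20, seed=21)
        fit = ConjointModel(trials).fit("additive")
        n = len(trials)
        assert np.all(np.abs(fit.params) < 0.15)
        # saturating bound: the fitted LL cannot fall below the coin-flip LL
        assert fit.llf >= n * np.log(0.5) - 1e-9
        assert fit.llf <= n * np.log(0.5) + 15.0  # small overfitting gain only

    def test_additive_parameter_recovery(self, additive_trials_40reps, additive_observer):
        """Recovered scales correlate >= 0.98 with the generating truth."""
        fit = ConjointModel(additive_trials_40reps).fit("additive")
        truth = np.concatenate([additive_observer.psi_g, additive_observer.psi_r])
        est = np.concatenate([fit.estimates.psi_g, fit.estimates.psi_r])
        assert np.corrcoef(truth, est)[0, 1] >= 0.98

    def test_free_parameter_counts(self, additive_trials_40reps):
        m = ConjointModel(additive_trials_40reps)
        assert m.fit("independent").n_free_params == 3
        assert m.fit("additive").n_free_params == 6
        assert m.fit("full").n_free_params == 15

    def test_anchoring_convention(self, additive_trials_40reps):
        fit = ConjointModel(additive_trials_40reps).fit("full")
        est = fit.estimates
        assert est.psi_g[0] == 0.0 and est.psi_r[0] == 0.0
        gr = np.asarray(est.psi_gr)
        assert np.allclose(gr[0, :], 0.0) and np.allclose(gr[:, 0], 0.0)

    def test_loglik_invariant_to_trial_order(self, grid44, additive_observer):
        trials = _simulate(grid44, additive_observer, reps=4, seed=31)
        rng = np.random.default_rng(0)
        permuted = [trials[i] for i in rng.permutation(len(trials))]
        f1 = ConjointModel(trials).fit("additive")
        f2 = ConjointModel(permuted).fit("additive")
        assert abs(f1.llf - f2.llf) < 1e-6

    def test_brute_force_lattice_oracle(self):
        """Optimizer LL matches exhaustive lattice search on a 2x2 toy problem."""
        grid = StimulusGrid(2, 2)
        obs = ObserverModel(psi_g=(0.0, 1.0), psi_r=(0.0, -0.5), sigma=1.0)
        trials = _simulate(grid, obs, reps=4, seed=41)  # 24 trials
        model = ConjointModel(trials)
        fit = model.fit("additive")
        # exhaustive enumeration, coarse 0.05-step lattice over [-3, 3]
        coarse = np.arange(-3.0, 3.0001, 0.05)
        lls = np.array([[model.loglike([a, b], "additive") for b in coarse] for a in coarse])
        i, j = np.unravel_index(np.argmax(lls), lls.shape)
        assert fit.llf >= lls[i, j] - 1e-3  # never worse than the lattice
        # refine the enumeration around the coarse best: agreement to 1e-3
        fa = coarse[i] + np.arange(-0.06, 0.0601, 0.002)
        fb = coarse[j] + np.arange(-0.06, 0.0601, 0.002)
        fine = max(model.loglike([a, b], "additive") for a in fa for b in fb)
        assert fit.llf == pytest.approx(fine, abs=1e-3)

    def test_agrees_with_probit_glm(self, grid44, additive_observer):
        """Independent cross-check: statsmodels binomial/probit GLM on the
        same signed-indicator design matrix finds the same LL and scales."""
        sm = pytest.importorskip("statsmodels.api")
        trials = _simulate(grid44, additive_observer, reps=4, seed=51)
        model = ConjointModel(trials)
        fit = model.fit("additive")
        X = model._design("additive")
        glm = sm.GLM(model.y, X, family=sm.families.Binomial(sm.families.links.Probit())).fit()
        assert fit.llf == pytest.approx(glm.llf, abs=1e-4)
        assert np.allclose(fit.params, glm.params, atol=1e-3)

    def test_separation_is_flagged_not_fatal(self):
        """A noiseless observer yields 0/1 proportions; the fit caps and flags."""
        grid = StimulusGrid(3, 1)
        obs = ObserverModel(psi_g=(0.0, 2.0, 4.0), psi_r=(0.0,), sigma=1e-9)
        trials = _simulate(grid, obs, reps=10, seed=61)
        fit = ConjointModel(trials).fit("independent")
        assert fit.separated
        assert np.all(np.abs(fit.params) <= mlcm.PARAM_CAP + 1e-9)

    def test_under_identified_level_raises(self):
        trials = [ConjointTrial(left=(0, 0), right=(1, 0), response=1)] * 5
        with pytest.raises(ValueError):
            ConjointModel(trials, n_gloss=3, n_filter=1).fit("independent")

    def test_responses_required(self, grid44):
        design = synth.build_conjoint_design(grid44, 1, seed=0)
        with pytest.raises(ValueError):
            ConjointModel(design)

    def test_summary_mentions_model_and_scales(self, additive_trials_40reps):
        text = ConjointModel(additive_trials_40reps).fit("additive").summary()
        assert "additive" in text and "psi_g" in text and "Log-likelihood" in text


class TestNestedStructure:
    @pytest.mark.parametrize("seed", [71, 72, 73])
    def test_nested_loglik_monotonicity(self, grid44, additive_observer, seed):
        """LL_independent <= LL_additive <= LL_full on every dataset."""
        trials = _simulate(grid44, additive_observer, reps=4, seed=seed)
        m = ConjointModel(trials)
        lli = m.fit("independent").llf
        lla = m.fit("additive").llf
        llf = m.fit("full").llf
        assert lli <= lla + 1e-6
        assert lla <= llf + 1e-6

    def test_probabilities_depend_only_on_utility_differences(self, additive_trials_40reps):
        """Shifting all per-stimulus utilities by a constant pre-anchoring
        leaves the choice probabilities unchanged."""
        fit = ConjointModel(additive_trials_40reps).fit("full")
        from scipy.stats import norm

        gl = np.array([t.left[0] for t in additive_trials_40reps])
        fl = np.array([t.left[1] for t in additive_trials_40reps])
        gr = np.array([t.right[0] for t in additive_trials_40reps])
        fr = np.array([t.right[1] for t in additive_trials_40reps])
        u = fit.estimates
        shifted = norm.cdf((u.utility(gl, fl) + 7.3) - (u.utility(gr, fr) + 7.3))
        assert np.allclose(fit.predict(additive_trials_40reps), shifted)

    def test_consistency_rmse_shrinks_with_repetitions(self, grid44, additive_observer):
        truth = np.concatenate([additive_observer.psi_g, additive_observer.psi_r])
        rmse = {}
        for reps in (4, 16, 64):
            trials = _simulate(grid44, additive_observer, reps=reps, seed=80 + reps)
            fit = ConjointModel(trials).fit("additive")
            est = np.concatenate([fit.estimates.psi_g, fit.estimates.psi_r])
            rmse[reps] = np.sqrt(np.mean((est - truth) ** 2))
        assert rmse[64] < rmse[4]


class TestLRTest:
    def test_identical_fits_give_zero_statistic(self, additive_trials_40reps):
        m = ConjointModel(additive_trials_40reps)
        f = m.fit("additive")
        # degenerate nesting: compare the additive fit against an equally
        # likely "full" relabelling of itself
        g = m.fit("full")
        res = lr_test(f, g)
        assert res.statistic >= 0.0
        same = mlcm.LRTestResult(0.0, 3, 1.0, "independent", "additive")
        assert same.p_value == 1.0

    def test_df_by_parameter_counting(self, additive_trials_40reps):
        m = ConjointModel(additive_trials_40reps)
        fi, fa, ff = m.fit("independent"), m.fit("additive"), m.fit("full")
        assert lr_test(fi, fa).df == 3
        assert lr_test(fa, ff).df == 9

    def test_non_nested_pair_rejected(self, additive_trials_40reps):
        m = ConjointModel(additive_trials_40reps)
        with pytest.raises(ValueError):
            lr_test(m.fit("additive"), m.fit("independent"))

    def test_different_data_rejected(self, grid44, additive_observer):
        t1 = _simulate(grid44, additive_observer, reps=4, seed=91)
        t2 = _simulate(grid44, additive_observer, reps=4, seed=92)
        with pytest.raises(ValueError):
            lr_test(ConjointModel(t1).fit("independent"), ConjointModel(t2).fit("additive"))

    def test_detects_a_strong_additive_effect(self, grid44, additive_observer):
        trials = _simulate(grid44, additive_observer, reps=4, seed=93)
        m = ConjointModel(trials)
        res = lr_test(m.fit("independent"), m.fit("additive"))
        assert res.p_value < bonferroni_level(0.05, 8)


class TestProportionMatrix:
    def test_single_observation(self):
        trials = [ConjointTrial(left=(1, 0), right=(0, 0), response=1)]
        pm = proportion_matrix(trials, n_gloss=2, n_filter=1)
        assert pm.entries[1, 0] == 1.0 and pm.entries[0, 1] == 0.0

    def test_pools_presentation_sides(self):
        trials = [
            ConjointTrial(left=(1, 0), right=(0, 0), response=1),
            ConjointTrial(left=(0, 0), right=(1, 0), response=0),
            ConjointTrial(left=(1, 0), right=(0, 0), response=0),
            ConjointTrial(left=(0, 0), right=(1, 0), response=1),
        ]
        pm = proportion_matrix(trials, 2, 1)
        assert pm.entries[1, 0] == 0.5
        assert pm.counts[1, 0] == 4

    def test_complementarity(self, grid44, additive_observer):
        trials = _simulate(grid44, additive_observer, reps=2, seed=95)
        pm = proportion_matrix(trials)
        obs = pm.counts > 0
        assert np.allclose((pm.entries + pm.entries.T)[obs], 1.0)

    def test_noiseless_observer_orders_by_gloss(self):
        grid = StimulusGrid(4, 1)
        obs = ObserverModel(psi_g=(0.0, 1.0, 2.0, 3.0), psi_r=(0.0,), sigma=1e-9)
        trials = _simulate(grid, obs, reps=2, seed=96)
        pm = proportion_matrix(trials)
        for a in range(4):
            for b in range(4):
                if a > b:
                    assert pm.entries[a, b] == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            proportion_matrix([])


class TestAggregation:
    def test_bonferroni_levels(self):
        assert bonferroni_level(0.05, 8) == pytest.approx(0.00625)
        assert bonferroni_level(0.05, 1) == 0.05
        assert bonferroni_level(0.01, 4) == pytest.approx(0.0025)
        with pytest.raises(ValueError):
            bonferroni_level(0.05, 0)

    def test_single_observer_normalizes_to_unit_max(self, additive_trials_40reps):
        fit = ConjointModel(additive_trials_40reps).fit("additive")
        agg = mlcm.normalize_and_aggregate([fit])
        assert max(agg["gloss_mean"].max(), agg["filter_mean"].max()) == pytest.approx(1.0)
        assert np.all(agg["gloss_sem"] == 0.0)

    def test_proportional_scales_have_zero_sem(self, additive_trials_40reps):
        fit = ConjointModel(additive_trials_40reps).fit("additive")
        doubled = mlcm.ConjointResults(
            model_name=fit.model_name,
            params=fit.params * 2,
            estimates=ObserverModel(
                psi_g=tuple(2 * v for v in fit.estimates.psi_g),
                psi_r=tuple(2 * v for v in fit.estimates.psi_r),
                sigma=1.0,
            ),
            llf=fit.llf, n_free_params=fit.n_free_params, converged=True,
            separated=False, n_trials=fit.n_trials,
            n_gloss=fit.n_gloss, n_filter=fit.n_filter, data_key=fit.data_key,
        )
        agg = mlcm.normalize_and_aggregate([fit, doubled])
        assert np.allclose(agg["gloss_sem"], 0.0, atol=1e-12)
        assert np.allclose(agg["filter_sem"], 0.0, atol=1e-12)

    def test_cohort_recovers_normalized_truth(self, grid44, additive_observer):
        """8 simulated observers: aggregated curve within 2 SEM of truth."""
        fits = []
        for k in range(8):
            trials = _simulate(grid44, additive_observer, reps=4, seed=200 + 10 * k)
            fits.append(ConjointModel(trials).fit("additive"))
        agg = mlcm.normalize_and_aggregate(fits)
        truth = np.asarray(additive_observer.psi_g) / max(additive_observer.psi_g)
        for lvl in range(4):
            tol = max(2 * agg["gloss_sem"][lvl], 0.02)
            assert abs(agg["gloss_mean"][lvl] - truth[lvl]) <= tol

    def test_nonpositive_observer_excluded(self, additive_trials_40reps):
        fit = ConjointModel(additive_trials_40reps).fit("additive")
        bad = mlcm.ConjointResults(
            model_name=fit.model_name, params=-np.abs(fit.params),
            estimates=ObserverModel(
                psi_g=tuple(-abs(v) for v in fit.estimates.psi_g),
                psi_r=tuple(-abs(v) for v in fit.estimates.psi_r),
                sigma=1.0,
            ),
            llf=fit.llf, n_free_params=fit.n_free_params, converged=True,
            separated=False, n_trials=fit.n_trials,
            n_gloss=fit.n_gloss, n_filter=fit.n_filter, data_key=fit.data_key,
        )
        agg = mlcm.normalize_and_aggregate([fit, bad])
        assert agg["n_observers"] == 1
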