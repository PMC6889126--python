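"""Likelihood computation, calibration fitting, generalization prediction,
and model-comparison bookkeeping."""

import numpy as np
import pytest

from beliefwalk.belief_space import make_initial_amplitudes, make_initial_distribution
from beliefwalk.markov_dynamics import MarkovParams, marginal_rating_probability
from beliefwalk.quantum_dynamics import QuantumParams
from beliefwalk.model_fitting import (
    JointCountTable,
    LIKELIHOOD_FLOOR,
    compare_models,
    fit_calibration,
    generalization_g2,
    generalization_predict,
    make_params,
    n_parameters,
    params_vector,
    predicted_table,
    predicted_tables,
    table_loglik,
)

CATS = ("L", "M", "H")
TIMES = {1: (0.5, 1.5), 2: (1.5, 2.5), 3: (0.5, 2.5)}


def tables_from_probs(model, params, init, lattice, n_per_cond=100_000):
    """Count tables proportional to the model's own predicted probabilities."""
    out = {}
    for cond in (1, 2):
        t1, t2 = TIMES[cond]
        probs = predicted_table(model, params, t1, t2, init, lattice)
        out[cond] = JointCountTable(np.round(probs * n_per_cond), t1, t2)
    return out


class TestCountTable:
    def test_validation(self):
        with pytest.raises(ValueError):
            JointCountTable(np.ones((2, 3)), 0.5, 1.5)
        with pytest.raises(ValueError):
            JointCountTable(-np.ones((3, 3)), 0.5, 1.5)
        with pytest.raises(ValueError):
            JointCountTable(np.ones((3, 3)), 1.5, 0.5)
        t = JointCountTable(np.full((3, 3), 2.0), 0.5, 1.5)
        assert t.n_trials == 18


class TestLoglik:
    def test_perfect_prediction_gives_zero(self, lattice99):
        # sigma = 0 quantum walk from a point mass in M predicts (M, M) with
        # probability one, so observing only (M, M) has log likelihood 0
        point = np.zeros(99)
        point[49] = 1.0
        counts = np.zeros((3, 3))
        counts[1, 1] = 7
        table = JointCountTable(counts, 0.5, 1.5)
        ll = table_loglik("quantum", QuantumParams(3.0, 0.0), table, point, lattice99)
        assert ll == pytest.approx(0.0, abs=1e-9)

    def test_matches_independent_summation(self, lattice99, init99, rng):
        params = MarkovParams(0.42, 30.0)
        counts = rng.integers(0, 20, size=(3, 3))
        table = JointCountTable(counts, 0.5, 1.5)
        probs = predicted_table("markov", params, 0.5, 1.5, init99, lattice99)
        expected = 0.0
        for i in range(3):
            for j in range(3):
                expected += counts[i, j] * np.log(max(probs[i, j], LIKELIHOOD_FLOOR))
        got = table_loglik("markov", params, table, init99, lattice99)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_trial_table_raises(self, lattice99, init99):
        table = JointCountTable(np.zeros((3, 3)), 0.5, 1.5)
        with pytest.raises(ValueError):
            table_loglik("markov", MarkovParams(0.4, 2.0), table, init99, lattice99)

    def test_scaling_counts_scales_loglik(self, lattice99, init99):
        params = MarkovParams(0.42, 30.0)
        probs = predicted_table("markov", params, 0.5, 1.5, init99, lattice99)
        t1 = JointCountTable(np.round(probs * 1000), 0.5, 1.5)
        t2 = JointCountTable(t1.counts * 3, 0.5, 1.5)
        l1 = table_loglik("markov", params, t1, init99, lattice99)
        l2 = table_loglik("markov", params, t2, init99, lattice99)
        assert l2 == pytest.approx(3 * l1, rel=1e-12)


class TestSharedPropagatorPath:
    def test_batched_tables_match_single_calls(self, lattice99, init99):
        for model, params in [
            ("markov", MarkovParams(0.42, 30.0)),
            ("quantum", QuantumParams(6.0, 45.0)),
        ]:
            batch = predicted_tables(model, params, [TIMES[1], TIMES[2], TIMES[3]],
                                     init99, lattice99)
            for tab, cond in zip(batch, (1, 2, 3)):
                t1, t2 = TIMES[cond]
                single = predicted_table(model, params, t1, t2, init99, lattice99)
                assert np.allclose(tab, single, atol=1e-12)
                assert tab.sum() == pytest.approx(1.0, abs=1e-10)


class TestFitCalibration:
    def test_noiseless_self_consistency_markov(self, lattice99, init99):
        true = MarkovParams(0.42, 30.0)
        tables = tables_from_probs("markov", true, init99, lattice99)
        fit = fit_calibration("markov", tables, init99, lattice99, seed=1)
        assert fit.params.mu == pytest.approx(true.mu, abs=0.01)
        assert fit.params.gamma == pytest.approx(true.gamma, rel=0.05)
        assert fit.g2 == pytest.approx(-2 * fit.loglik, abs=1e-9)
        for tab in fit.predicted_tables.values():
            assert tab.sum() == pytest.approx(1.0, abs=1e-10)

    def test_noiseless_self_consistency_quantum(self, lattice99, init99):
        true = QuantumParams(6.0, 40.0)
        tables = tables_from_probs("quantum", true, init99, lattice99)
        fit = fit_calibration("quantum", tables, init99, lattice99, seed=1)
        assert fit.params.mu == pytest.approx(true.mu, abs=0.3)
        assert fit.params.sigma == pytest.approx(true.sigma, rel=0.05)

    def test_optimizer_beats_coarse_grid_search(self, lattice99, init99):
        # independent 20x20 grid-search oracle over the bounded box must not
        # find a better likelihood than the multi-start optimizer
        true = MarkovParams(0.35, 20.0)
        tables = tables_from_probs("markov", true, init99, lattice99, n_per_cond=2000)
        fit = fit_calibration("markov", tables, init99, lattice99, seed=3)
        mus = np.linspace(0.01, 0.99, 20)
        gammas = np.exp(np.linspace(np.log(1e-3), np.log(200.0), 20))
        best_grid = -np.inf
        for m in mus:
            for g in gammas:
                p = MarkovParams(m, g)
                ll = sum(table_loglik("markov", p, t, init99, lattice99)
                         for t in tables.values())
                best_grid = max(best_grid, ll)
        assert fit.loglik >= best_grid - 1e-3

    def test_deterministic_given_seed(self, lattice99, init99):
        tables = tables_from_probs("markov", MarkovParams(0.3, 15.0), init99, lattice99,
                                   n_per_cond=500)
        f1 = fit_calibration("markov", tables, init99, lattice99, seed=7)
        f2 = fit_calibration("markov", tables, init99, lattice99, seed=7)
        assert params_vector("markov", f1.params).tolist() == params_vector("markov", f2.params).tolist()

    def test_unknown_model_and_empty_tables_raise(self, lattice99, init99):
        with pytest.raises(ValueError):
            fit_calibration("diffusion", {}, init99, lattice99)
        with pytest.raises(ValueError):
            fit_calibration("markov", {}, init99, lattice99)


class TestGeneralization:
    def test_predicted_condition3_obeys_no_interference(self, lattice99, init99):
        tables = tables_from_probs("markov", MarkovParams(0.42, 30.0), init99, lattice99,
                                   n_per_cond=1000)
        fit = fit_calibration("markov", tables, init99, lattice99, seed=2)
        tab3 = generalization_predict(fit, TIMES[3], init99, lattice99)
        assert tab3.sum() == pytest.approx(1.0, abs=1e-10)
        for j, c in enumerate(CATS):
            marg = marginal_rating_probability(fit.params, *TIMES[3], c, init99, lattice99)
            assert tab3[:, j].sum() == pytest.approx(marg, abs=1e-12)

    def test_generalization_g2_is_minus_twice_loglik(self, lattice99, init99):
        params = MarkovParams(0.42, 30.0)
        tables = tables_from_probs("markov", params, init99, lattice99, n_per_cond=500)
        fit = fit_calibration("markov", tables, init99, lattice99, seed=2)
        probs3 = predicted_table("markov", fit.params, *TIMES[3], init99, lattice99)
        counts3 = JointCountTable(np.round(probs3 * 500), *TIMES[3])
        g2 = generalization_g2(fit, counts3, init99, lattice99)
        ll = sum(counts3.counts[i, j] * np.log(max(probs3[i, j], LIKELIHOOD_FLOOR))
                 for i in range(3) for j in range(3))
        assert g2 == pytest.approx(-2 * ll, abs=1e-9)


class TestComparison:
    def _fit_pair(self, lattice99, init99):
        tables = tables_from_probs("markov", MarkovParams(0.42, 30.0), init99, lattice99,
                                   n_per_cond=500)
        fa = fit_calibration("markov", tables, init99, lattice99, seed=1)
        fb = fit_calibration("quantum", tables, init99, lattice99, seed=1)
        return fa, fb

    def test_identical_fits_give_pure_penalty(self, lattice99, init99):
        fa, _ = self._fit_pair(lattice99, init99)
        rep = compare_models(fa, fa, n_extra_params=11, n_obs=11 * 1735)
        assert rep.g2_diff == 0.0
        assert rep.bic_diff == pytest.approx(11 * np.log(11 * 1735), abs=1e-9)

    def test_study_scale_penalty_constant(self):
        # one extra parameter per participant at the cohort's total N
        assert 11 * np.log(11 * 1735) == pytest.approx(108.43, abs=0.01)

    def test_signed_difference_convention(self, lattice99, init99):
        fa, fb = self._fit_pair(lattice99, init99)
        rep = compare_models(fa, fb)
        assert rep.g2_diff == pytest.approx(fa.g2 - fb.g2, abs=1e-9)
        assert rep.bic_diff == rep.g2_diff  # no extra parameters

    def test_mismatched_data_rejected(self, lattice99, init99):
        fa, _ = self._fit_pair(lattice99, init99)
        other = tables_from_probs("markov", MarkovParams(0.42, 30.0), init99, lattice99,
                                  n_per_cond=600)
        fc = fit_calibration("markov", other, init99, lattice99, seed=1)
        with pytest.raises(ValueError):
            compare_models(fa, fc)

    def test_parameter_counts(self):
        assert n_parameters("markov") == 2
        assert n_parameters("quantum") == 2
        assert n_parameters("markov_v") == 3

    def test_make_params_round_trip(self):
        for model, vec in [("markov", [0.3, 2.0]), ("quantum", [-5.0, 3.0]),
                           ("markov_v", [0.4, 0.05, 10.0])]:
            p = make_params(model, vec)
            assert params_vector(model, p).tolist() == vec
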