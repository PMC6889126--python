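"""Markov chain dynamics: generator, transition law, joint probabilities,
the no-interference theorem, and the drift-variability mixture."""

import numpy as np
import pytest

from beliefwalk.belief_space import BeliefLattice, make_initial_distribution
from beliefwalk.markov_dynamics import (
    MarkovParams,
    MarkovVParams,
    drift_grid,
    intensity_matrix,
    joint_rating_probability,
    joint_table,
    marginal_rating_probability,
    markov_v_joint_table,
    transition_matrices,
    transition_matrix,
)

from conftest import expm_series

CATS = ("L", "M", "H")


class TestParams:
    def test_alpha_beta_identities(self):
        p = MarkovParams(mu=0.3, gamma=5.0)
        assert p.alpha == pytest.approx(1.5)
        assert p.beta == pytest.approx(3.5)
        assert p.alpha + p.beta == pytest.approx(p.gamma, abs=1e-12)

    @pytest.mark.parametrize("mu,gamma", [(0.0, 1.0), (1.0, 1.0), (0.5, 0.0), (-0.1, 2.0)])
    def test_invalid_parameters_raise(self, mu, gamma):
        with pytest.raises(ValueError):
            MarkovParams(mu, gamma)

    def test_markov_v_validation(self):
        with pytest.raises(ValueError):
            MarkovVParams(0.5, -0.1, 1.0)
        with pytest.raises(ValueError):
            MarkovVParams(0.5, 0.1, 0.0)


class TestGenerator:
    def test_columns_sum_to_zero_and_offdiag_nonnegative(self, lattice6):
        K = intensity_matrix(MarkovParams(0.3, 2.0), lattice6)
        assert np.allclose(K.sum(axis=0), 0.0, atol=1e-12)
        off = K - np.diag(np.diag(K))
        assert np.all(off >= 0)

    def test_interior_and_boundary_structure(self, lattice6):
        p = MarkovParams(0.25, 4.0)  # alpha = 1, beta = 3
        K = intensity_matrix(p, lattice6)
        assert K[0, 1] == pytest.approx(p.alpha)   # downward move
        assert K[2, 1] == pytest.approx(p.beta)    # upward move
        assert K[1, 1] == pytest.approx(-p.gamma)  # interior: both exits
        assert K[0, 0] == pytest.approx(-p.beta)   # bottom state can only move up
        assert K[-1, -1] == pytest.approx(-p.alpha)  # top state can only move down


class TestTransitionLaw:
    def test_time_zero_gives_identity(self, lattice6):
        T = transition_matrix(MarkovParams(0.4, 2.0), 0.0, lattice6)
        assert np.array_equal(T, np.eye(6))

    def test_negative_time_raises(self, lattice6):
        with pytest.raises(ValueError):
            transition_matrix(MarkovParams(0.4, 2.0), -0.1, lattice6)

    def test_two_state_chain_matches_series_oracle(self):
        # conservative 2-state generator with alpha = 1, beta = 0.5
        K = np.array([[-0.5, 1.0], [0.5, -1.0]])
        T = transition_matrices(K, [0.7])[0.7]
        assert np.allclose(T, expm_series(0.7 * K), atol=1e-10)
        assert np.allclose(T.sum(axis=0), 1.0, atol=1e-12)

    def test_small_lattice_matches_series_oracle(self, lattice6):
        p = MarkovParams(0.35, 3.0)
        K = intensity_matrix(p, lattice6)
        for t in (0.5, 1.0, 2.5):
            assert np.allclose(transition_matrix(p, t, lattice6),
                               expm_series(t * K), atol=1e-10)

    def test_stochasticity_over_random_params(self, lattice6, rng):
        for _ in range(25):
            p = MarkovParams(rng.uniform(0.05, 0.95), rng.uniform(0.1, 40.0))
            T = transition_matrix(p, rng.uniform(0.1, 3.0), lattice6)
            assert np.allclose(T.sum(axis=0), 1.0, atol=1e-10)
            assert np.all(T >= -1e-12)

    def test_semigroup_property(self, lattice6):
        p = MarkovParams(0.3, 5.0)
        s, t = 0.6, 1.1
        assert np.allclose(
            transition_matrix(p, s + t, lattice6),
            transition_matrix(p, s, lattice6) @ transition_matrix(p, t, lattice6),
            atol=1e-10,
        )

    def test_shared_base_step_consistent_with_direct_exponential(self, lattice6):
        # the 0.5 s base-step fast path must agree with separate exponentials
        p = MarkovParams(0.42, 30.0)
        K = intensity_matrix(p, lattice6)
        T = transition_matrices(K, [0.5, 1.0, 1.5])
        for t in (0.5, 1.0, 1.5):
            assert np.allclose(T[t], expm_series(t * K), atol=1e-9)

    def test_high_diffusion_symmetric_drift_approaches_uniform(self, lattice6):
        p = MarkovParams(0.5, 500.0)
        init = make_initial_distribution(lattice6, center=3, sd_states=1.0)
        phi = transition_matrix(p, 5.0, lattice6) @ init
        assert np.allclose(phi, 1.0 / 6.0, atol=1e-6)


class TestResponseProbabilities:
    def test_marginals_partition_unity(self, lattice99, init99):
        p = MarkovParams(0.42, 30.0)
        total = sum(marginal_rating_probability(p, 0.5, 1.5, c, init99, lattice99) for c in CATS)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_joint_table_partitions_unity_and_is_nonnegative(self, lattice99, init99):
        tab = joint_table(MarkovParams(0.3, 10.0), 0.5, 2.5, init99, lattice99)
        assert tab.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(tab >= 0)

    def test_small_lattice_joint_matches_enumeration_oracle(self, lattice6):
        p = MarkovParams(0.4, 2.0)
        init = make_initial_distribution(lattice6, center=3, sd_states=1.5)
        t1, t2 = 0.5, 1.5
        K = intensity_matrix(p, lattice6)
        T1, Tdt = expm_series(t1 * K), expm_series((t2 - t1) * K)
        for i, c1 in enumerate(CATS):
            M1 = lattice6.projector(c1)
            for j, c2 in enumerate(CATS):
                M2 = lattice6.projector(c2)
                expected = float(np.sum(M2 @ Tdt @ M1 @ T1 @ init))
                got = joint_rating_probability(p, t1, t2, c1, c2, init, lattice6)
                assert got == pytest.approx(expected, abs=1e-10)

    def test_invalid_time_ordering_raises(self, lattice99, init99):
        p = MarkovParams(0.4, 2.0)
        with pytest.raises(ValueError):
            joint_table(p, 1.5, 0.5, init99, lattice99)
        with pytest.raises(ValueError):
            marginal_rating_probability(p, 1.5, 0.5, "L", init99, lattice99)

    def test_no_interference_over_randomized_draws(self, rng):
        # Chapman-Kolmogorov: summing the joint over the first rating must
        # reproduce the no-measurement marginal to machine precision
        for _ in range(50):
            n = int(rng.choice([6, 9, 21]))
            lat = BeliefLattice(n)
            p = MarkovParams(rng.uniform(0.05, 0.95), rng.uniform(0.1, 50.0))
            t1 = rng.uniform(0.1, 2.0)
            t2 = t1 + rng.uniform(0.1, 2.0)
            init = rng.dirichlet(np.ones(n))
            tab = joint_table(p, t1, t2, init, lat)
            marg = [marginal_rating_probability(p, t1, t2, c, init, lat) for c in CATS]
            assert np.abs(tab.sum(axis=0) - marg).max() < 1e-12


class TestDriftVariability:
    def test_degenerate_mixture_equals_plain_chain(self, lattice99, init99):
        plain = joint_table(MarkovParams(0.42, 30.0), 0.5, 1.5, init99, lattice99)
        mixed = markov_v_joint_table(MarkovVParams(0.42, 0.0, 30.0), 0.5, 1.5, init99, lattice99)
        assert np.abs(mixed - plain).max() < 1e-12

    def test_mixture_partitions_unity(self, lattice99, init99):
        tab = markov_v_joint_table(MarkovVParams(0.4, 0.1, 20.0), 0.5, 1.5, init99, lattice99)
        assert tab.sum() == pytest.approx(1.0, abs=1e-10)

    def test_three_point_grid_matches_hand_weighted_sum(self, lattice6):
        init = make_initial_distribution(lattice6, center=3, sd_states=1.0)
        vp = MarkovVParams(0.5, 0.05, 4.0)
        mus, w = drift_grid(vp.mu_mean, vp.mu_sd, n_grid=3)
        expected = sum(
            wi * joint_table(MarkovParams(m, vp.upsilon), 0.5, 1.5, init, lattice6)
            for m, wi in zip(mus, w)
        )
        got = markov_v_joint_table(vp, 0.5, 1.5, init, lattice6, n_grid=3)
        assert np.allclose(got, expected, atol=1e-14)

    def test_grid_contains_mean_and_weights_normalize(self):
        mus, w = drift_grid(0.4, 0.05, 21)
        assert 0.4 in mus
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all((mus > 0) & (mus < 1))

    def test_grid_clipping_merges_boundary_points(self):
        mus, w = drift_grid(0.05, 0.2, 21)
        assert np.all(mus >= 1e-6) and mus.size == np.unique(mus).size
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_even_grid_size_rejected(self):
        with pytest.raises(ValueError):
            drift_grid(0.5, 0.1, 4)

    def test_small_sd_mixture_converges_to_plain(self, lattice6):
        init = make_initial_distribution(lattice6, center=3, sd_states=1.0)
        plain = joint_table(MarkovParams(0.45, 6.0), 0.5, 1.5, init, lattice6)
        diffs = []
        for sd in (0.05, 0.01, 0.002):
            mixed = markov_v_joint_table(MarkovVParams(0.45, sd, 6.0), 0.5, 1.5, init, lattice6)
            diffs.append(np.abs(mixed - plain).max())
        assert diffs[0] > diffs[1] > diffs[2]
        assert diffs[-1] < 1e-4  # second order in mu_sd
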