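import numpy as np
import pytest

from bayestx.inference import (
    GibbsSchedule,
    SparsityPrior,
    estimate_pi,
    exact_posterior,
    num_expressed_distribution,
    run_gibbs,
    sample_abundances,
    sample_assignments,
    sample_expression_vector,
    sample_num_expressed,
)

from oracles import bz_distribution_bruteforce


class TestEstimatePi:
    def test_single_candidate_covers_all(self):
        values = np.zeros((10, 4))
        values[:, 0] = 1.0
        values[:5, 2] = 0.5
        assert estimate_pi(values).pi == pytest.approx(0.25)

    def test_each_fragment_needs_own_candidate(self):
        assert estimate_pi(np.eye(3)).pi == pytest.approx(1.0)

    def test_single_candidate(self):
        assert estimate_pi(np.ones((5, 1))).pi == pytest.approx(1.0)

    def test_tie_breaks_to_lowest_index(self):
        values = np.ones((4, 2))
        assert estimate_pi(values).pi == pytest.approx(0.5)  # one set suffices

    def test_uncoverable_fragment_rejected(self):
        values = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError):
            estimate_pi(values)


class TestSparsityPrior:
    def test_k_z0_normalizes_truncated_bernoulli(self):
        prior = SparsityPrior(pi=0.3, m=4)
        total = 0.0
        for z_int in range(1, 2**4):
            b = bin(z_int).count("1")
            total += prior.pi**b * (1 - prior.pi) ** (4 - b) * prior.k_z0
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_k_z0_at_least_one(self):
        assert SparsityPrior(pi=0.5, m=1).k_z0 >= 1.0
        assert SparsityPrior(pi=1.0, m=3).k_z0 == pytest.approx(1.0)

    def test_invalid_pi_rejected(self):
        with pytest.raises(ValueError):
            SparsityPrior(pi=0.0, m=2)
        with pytest.raises(ValueError):
            SparsityPrior(pi=1.5, m=2)


class TestNumExpressedDistribution:
    def test_two_candidate_example(self):
        support, probs = num_expressed_distribution(
            np.array([2, 0]), SparsityPrior(pi=0.5, m=2), gamma=1.0, n=2
        )
        assert list(support) == [1, 2]
        assert probs[0] == pytest.approx(0.75, abs=1e-12)
        assert probs[1] == pytest.approx(0.25, abs=1e-12)

    def test_three_candidate_example(self):
        support, probs = num_expressed_distribution(
            np.array([4, 1, 0]), SparsityPrior(pi=0.3, m=3), gamma=1.0, n=5
        )
        assert list(support) == [2, 3]
        assert probs[0] == pytest.approx(0.890909090909, abs=1e-9)
        assert probs[1] == pytest.approx(0.109090909091, abs=1e-9)

    def test_matches_bruteforce_z_enumeration(self, rng):
        for _ in range(30):
            m = int(rng.integers(1, 6))
            n = int(rng.integers(1, 13))
            c = rng.multinomial(n, np.ones(m) / m)
            gamma = float(rng.choice([0.5, 1.0, 2.0]))
            pi = float(rng.choice([0.1, 0.5, 0.9]))
            support, probs = num_expressed_distribution(c, SparsityPrior(pi=pi, m=m), gamma, n)
            oracle = bz_distribution_bruteforce(c, pi, gamma)
            assert abs(probs.sum() - 1.0) <= 1e-12
            for b, p in zip(support, probs):
                assert p == pytest.approx(oracle.get(int(b), 0.0), rel=1e-10, abs=1e-13)

    def test_support_collapses_when_all_occupied(self, rng):
        c = np.array([3, 2, 1])
        b = sample_num_expressed(c, SparsityPrior(pi=0.5, m=3), 1.0, 6, rng)
        assert b == 3

    def test_pi_one_forces_all_expressed(self, rng):
        c = np.array([5, 0, 0])
        support, probs = num_expressed_distribution(c, SparsityPrior(pi=1.0, m=3), 1.0, 5)
        assert probs[list(support).index(3)] == pytest.approx(1.0)


class TestSampleExpressionVector:
    def test_no_extra_slots(self, rng):
        c = np.array([2, 1, 0])
        z = sample_expression_vector(2, c, rng)
        np.testing.assert_array_equal(z, [1, 1, 0])

    def test_all_slots(self, rng):
        z = sample_expression_vector(3, np.array([2, 0, 0]), rng)
        np.testing.assert_array_equal(z, [1, 1, 1])

    def test_out_of_range_asserts(self, rng):
        with pytest.raises(AssertionError):
            sample_expression_vector(0, np.array([2, 0]), rng)

    def test_uniform_choice_from_unoccupied(self, rng):
        c = np.array([3, 0, 0])
        hits = sum(int(sample_expression_vector(2, c, rng)[1]) for _ in range(10_000))
        se = np.sqrt(0.25 * 10_000)
        assert abs(hits - 5000) < 3 * se


class TestSampleAbundances:
    def test_single_expressed(self, rng):
        e = sample_abundances(np.array([0, 1]), np.array([0, 4]), 1.0, rng)
        np.testing.assert_array_equal(e, [0.0, 1.0])

    def test_dirichlet_mean(self, rng):
        total = 0.0
        draws = 30_000
        for _ in range(draws):
            total += sample_abundances(np.array([1, 1]), np.array([2, 0]), 1.0, rng)[0]
        # Dirichlet(3, 1): mean 3/4, var 3/80
        se = np.sqrt(3 / 80 / draws)
        assert abs(total / draws - 0.75) < 3 * se

    def test_simplex_constraint(self, rng):
        for _ in range(100):
            e = sample_abundances(np.array([1, 0, 1]), np.array([3, 0, 0]), 0.7, rng)
            assert e.sum() == pytest.approx(1.0, abs=1e-12)
            assert e[1] == 0.0


class TestSampleAssignments:
    def test_degenerate_abundance(self, rng):
        values = np.ones((5, 2))
        t, c = sample_assignments(np.array([1.0, 0.0]), values, rng)
        assert np.all(t == 0)
        np.testing.assert_array_equal(c, [5, 0])

    @pytest.mark.parametrize(
        "row,e,p_first",
        [((0.9, 0.1), (0.5, 0.5), 0.9), ((0.5, 0.5), (0.8, 0.2), 0.8)],
    )
    def test_assignment_probability(self, rng, row, e, p_first):
        n = 20_000
        values = np.tile(row, (n, 1))
        t, c = sample_assignments(np.array(e), values, rng)
        se = np.sqrt(p_first * (1 - p_first) / n)
        assert abs(c[0] / n - p_first) < 4 * se

    def test_counts_sum_to_n(self, rng):
        values = rng.random((50, 4)) + 0.01
        e = rng.dirichlet(np.ones(4))
        _, c = sample_assignments(e, values, rng)
        assert c.sum() == 50


class TestRunGibbs:
    def test_schedule_from_candidate_count(self):
        s = GibbsSchedule.for_candidates(100)
        assert s.burn_in == 7000 and s.samples == 70_000
        s1 = GibbsSchedule.for_candidates(1)
        assert s1.burn_in == 1060 and s1.samples == 10_600

    def test_single_candidate_degenerate(self):
        values = np.ones((4, 1))
        out = run_gibbs(values, SparsityPrior(pi=1.0, m=1), seed=0,
                        schedule=GibbsSchedule(burn_in=10, samples=50))
        assert out.confidence[0] == 1.0
        assert out.mean_e_expressed[0] == 1.0
        assert out.mean_count[0] == 4.0

    def test_seed_determinism(self):
        values = np.array([[1.0, 0.2], [0.3, 1.0], [0.5, 0.5]])
        prior = SparsityPrior(pi=0.5, m=2)
        sched = GibbsSchedule(burn_in=100, samples=500)
        a = run_gibbs(values, prior, schedule=sched, seed=42)
        b = run_gibbs(values, prior, schedule=sched, seed=42)
        np.testing.assert_array_equal(a.expressed_count, b.expressed_count)
        np.testing.assert_array_equal(a.e_sum, b.e_sum)
        np.testing.assert_array_equal(a.c_sum, b.c_sum)

    def test_pi_one_expresses_everything_every_iteration(self):
        values = np.array([[1.0, 0.2], [0.3, 1.0], [0.5, 0.5]])
        out = run_gibbs(values, SparsityPrior(pi=1.0, m=2), seed=1,
                        schedule=GibbsSchedule(burn_in=50, samples=300), keep_trace=True)
        assert np.all(out.z_trace == 1)

    def test_invariants_hold_each_iteration(self):
        values = np.array([[1.0, 0.2, 0.1], [0.3, 1.0, 0.2], [0.5, 0.5, 0.9]])
        run_gibbs(values, SparsityPrior(pi=0.4, m=3), seed=3,
                  schedule=GibbsSchedule(burn_in=50, samples=200), check_invariants=True)

    def test_conjugate_quantification_with_pi_one(self):
        # forced single-candidate assignment: collapsed Dirichlet-multinomial mean
        values = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        out = run_gibbs(values, SparsityPrior(pi=1.0, m=2), gamma=1.0, seed=5,
                        schedule=GibbsSchedule(burn_in=200, samples=20_000))
        # c fixed at (3, 1): E[e_1] = (3+1)/(4+2) = 2/3
        assert out.mean_e[0] == pytest.approx(2 / 3, abs=0.01)


class TestExactPosterior:
    def test_single_candidate_certain(self):
        out = exact_posterior(np.ones((3, 1)), SparsityPrior(pi=0.6, m=1))
        assert out["p_expressed"][0] == pytest.approx(1.0)
        assert out["mean_e"][0] == pytest.approx(1.0)

    def test_symmetric_instance_has_equal_marginals(self):
        values = np.tile([0.4, 0.4], (4, 1))
        out = exact_posterior(values, SparsityPrior(pi=0.5, m=2))
        assert out["p_expressed"][0] == pytest.approx(out["p_expressed"][1], abs=1e-12)
        assert out["mean_e"][0] == pytest.approx(out["mean_e"][1], abs=1e-12)

    def test_refuses_large_instances(self):
        with pytest.raises(ValueError):
            exact_posterior(np.ones((30, 4)), SparsityPrior(pi=0.5, m=4))

    def test_forced_candidate_is_certain(self):
        values = np.array([[1.0, 0.0], [0.5, 0.5]])
        out = exact_posterior(values, SparsityPrior(pi=0.5, m=2))
        assert out["p_expressed"][0] == pytest.approx(1.0)
        assert 0.0 < out["p_expressed"][1] < 1.0

    def test_gibbs_agrees_on_tiny_instance(self):
        values = np.array([[1.0, 0.3], [0.2, 1.0], [0.6, 0.6]])
        prior = SparsityPrior(pi=0.5, m=2)
        exact = exact_posterior(values, prior)
        out = run_gibbs(values, prior, seed=11,
                        schedule=GibbsSchedule(burn_in=500, samples=20_000))
        np.testing.assert_allclose(out.confidence, exact["p_expressed"], atol=0.02)
        np.testing.assert_allclose(out.mean_e, exact["mean_e"], atol=0.02)
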