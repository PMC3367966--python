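"""Transition-matrix construction: gamma rule, assembly, Monte Carlo."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coraldemog.matrices import (
    LifeTableSample,
    TransitionMatrix,
    build_transition_matrix,
    build_matrix_lambda_iterated,
    dominant_eigenvalue,
    gamma_from_survival,
    monte_carlo_mean_matrix,
)


def cohort_gamma_oracle(sigma, T, n_individuals=2_000_000, burn_in=60, measure=40, seed=0):
    """Stationary advancing fraction from a stochastic cohort simulation.

    A stage receives a constant inflow of recruits each step; every resident
    survives with probability sigma and is forced to advance after T
    survived steps.  At stationarity, the fraction of within-stage
    survivors that advance per step estimates gamma.
    """
    rng = np.random.default_rng(seed)
    inflow = n_individuals // (burn_in + measure)
    counts = np.zeros(T, dtype=np.int64)  # residents by within-stage age
    advanced = survived = 0
    for step in range(burn_in + measure):
        surv = rng.binomial(counts, sigma)
        if step >= burn_in:
            advanced += surv[-1]
            survived += surv.sum()
        counts[1:] = surv[:-1]
        counts[0] = inflow
    return advanced / survived


class TestGamma:
    def test_one_year_stage_always_advances(self):
        assert gamma_from_survival(0.9, 1) == 1.0

    def test_perfect_survival_limit_is_one_over_duration(self):
        assert gamma_from_survival(1.0, 4) == pytest.approx(0.25)

    @pytest.mark.parametrize("sigma,T", [(0.8, 3), (0.5, 2), (0.95, 7)])
    def test_matches_ratio_form(self, sigma, T):
        expected = (sigma**T - sigma ** (T - 1)) / (sigma**T - 1)
        assert gamma_from_survival(sigma, T) == pytest.approx(expected, rel=1e-12)

    def test_matches_cohort_microsimulation(self):
        gamma = gamma_from_survival(0.8, 3)
        simulated = cohort_gamma_oracle(0.8, 3)
        assert simulated == pytest.approx(gamma, abs=2e-3)

    @pytest.mark.parametrize("sigma,T", [(-0.1, 2), (1.1, 2), (0.5, 0), (0.5, 2.5)])
    def test_rejects_invalid_inputs(self, sigma, T):
        with pytest.raises(ValueError):
            gamma_from_survival(sigma, T)

    @given(
        sigma=st.floats(0.0, 1.0, allow_nan=False),
        T=st.integers(1, 12),
    )
    @settings(max_examples=200, deadline=None)
    def test_is_a_probability(self, sigma, T):
        g = gamma_from_survival(sigma, T)
        assert 0.0 <= g <= 1.0


class TestBuildMatrix:
    def test_growth_and_loop_products(self):
        # sigma=0.8 with T chosen so gamma=0.3 is not on the duration grid;
        # check the products directly at an exactly representable gamma
        lt = LifeTableSample(
            growth_form="massive",
            sigma=np.array([0.8] * 5),
            duration=np.array([2, 2, 2, 2, 1]),
        )
        tm = build_transition_matrix(lt)
        g = gamma_from_survival(0.8, 2)
        assert tm.G == pytest.approx([0.8 * g] * 4)
        assert tm.P[:4] == pytest.approx([0.8 * (1 - g)] * 4)

    def test_conservation_G_plus_P_equals_sigma(self, simple_life_table):
        tm = build_transition_matrix(simple_life_table)
        np.testing.assert_allclose(tm.sigma, simple_life_table.sigma, rtol=0, atol=0)

    def test_last_stage_absorbing(self, simple_life_table):
        tm = build_transition_matrix(simple_life_table)
        assert tm.P[4] == simple_life_table.sigma[4]
        assert tm.A[4, :4].sum() == tm.A[4, 3]  # only G4 feeds stage 5

    def test_zero_survival_gives_zero_matrix(self):
        lt = LifeTableSample(
            growth_form="arborescent",
            sigma=np.zeros(5),
            duration=np.ones(5, dtype=int),
        )
        tm = build_transition_matrix(lt)
        assert np.all(tm.A == 0)
        assert tm.lambda_ == 0.0

    def test_fertility_placement_and_default_scaling(self, simple_life_table):
        tm = build_transition_matrix(simple_life_table, fertility_4=5.0)
        assert tm.fertility == (5.0, 50.0)  # f5 defaults to 10*f4
        with pytest.raises(ValueError):
            build_transition_matrix(simple_life_table, fertility_4=10.0, fertility_5=5.0)

    def test_rejects_entries_outside_structure(self):
        A = np.zeros((5, 5))
        A[3, 0] = 0.5  # a two-class jump is not a valid transition
        with pytest.raises(ValueError):
            TransitionMatrix(A=A)

    def test_shrinkage_moves_survivors_down_one_class(self, simple_life_table):
        shr = [0.1, 0.1, 0.1, 0.1]
        tm = build_transition_matrix(simple_life_table, shrinkage=shr)
        sig = simple_life_table.sigma
        np.testing.assert_allclose(
            [tm.A[i - 1, i] for i in range(1, 5)], sig[1:] * 0.1
        )
        # survival is still conserved per stage (loop + growth + retrogression)
        col_surv = tm.A.sum(axis=0)
        np.testing.assert_allclose(col_surv, sig, rtol=1e-12)

    def test_lambda_iterated_variant_converges(self, simple_life_table):
        tm = build_matrix_lambda_iterated(simple_life_table)
        rebuilt = build_transition_matrix(
            simple_life_table, gamma_lambda=tm.lambda_
        )
        assert rebuilt.lambda_ == pytest.approx(tm.lambda_, abs=1e-8)

    @given(
        sig=st.lists(st.floats(0.01, 0.99), min_size=5, max_size=5),
        dur=st.lists(st.integers(1, 10), min_size=5, max_size=5),
    )
    @settings(max_examples=100, deadline=None)
    def test_zero_fertility_is_subcritical(self, sig, dur):
        lt = LifeTableSample(
            growth_form="massive", sigma=np.array(sig), duration=np.array(dur)
        )
        tm = build_transition_matrix(lt)
        assert tm.lambda_ < 1.0
        np.testing.assert_allclose(tm.sigma, sig, rtol=1e-12)


class TestDominantEigenvalue:
    def test_diagonal_matrix(self):
        assert dominant_eigenvalue(0.5 * np.eye(5)) == pytest.approx(0.5)

    def test_matches_power_iteration(self):
        rng = np.random.default_rng(42)
        A = rng.uniform(0, 1, size=(5, 5))
        lam = dominant_eigenvalue(A)
        x = np.ones(5)
        for _ in range(200):
            x = A @ x
            x /= np.linalg.norm(x)
        growth = np.linalg.norm(A @ x)
        assert growth == pytest.approx(lam, rel=1e-10)

    def test_rejects_negative_entries(self):
        with pytest.raises(ValueError):
            dominant_eigenvalue(-np.eye(5))


class TestMonteCarlo:
    def test_degenerate_pool_has_zero_spread(self, simple_life_table):
        mc = monte_carlo_mean_matrix([simple_life_table], n_trials=50, rng_seed=0)
        single = build_transition_matrix(simple_life_table)
        np.testing.assert_allclose(mc.mean_matrix.A, single.A, rtol=1e-14)
        assert np.ptp(mc.lambda_samples) == 0.0

    def test_two_table_pool_mean_matches_enumeration(
        self, simple_life_table, second_life_table
    ):
        """Each stage draws independently from two candidates, so the exact
        expected matrix is the equal-weight average of the two per-stage
        entry sets; the sampled mean must agree within Monte-Carlo error."""
        pool = [simple_life_table, second_life_table]
        expected = (
            build_transition_matrix(simple_life_table).A
            + build_transition_matrix(second_life_table).A
        ) / 2.0
        n = 10_000
        mc = monte_carlo_mean_matrix(pool, n_trials=n, rng_seed=7)
        # per-entry sd is bounded by half the entry gap; 5/sqrt(n) is ~5 se
        gap = np.abs(
            build_transition_matrix(simple_life_table).A
            - build_transition_matrix(second_life_table).A
        )
        tol = 5.0 * (gap / 2.0) / np.sqrt(n) + 1e-12
        assert np.all(np.abs(mc.mean_matrix.A - expected) <= tol)

    def test_zero_fertility_trials_all_subcritical(self, world):
        from coraldemog.synthdata import generate_life_table_pool

        pool = generate_life_table_pool("branching_encrusting", 20, rng_seed=5)
        mc = monte_carlo_mean_matrix(pool, n_trials=2000, rng_seed=5)
        assert np.all(mc.lambda_samples < 1.0)
        assert mc.mean_matrix.lambda_ < 1.0

    def test_seed_determinism(self, simple_life_table, second_life_table):
        pool = [simple_life_table, second_life_table]
        a = monte_carlo_mean_matrix(pool, n_trials=500, rng_seed=11)
        b = monte_carlo_mean_matrix(pool, n_trials=500, rng_seed=11)
        assert np.array_equal(a.mean_matrix.A, b.mean_matrix.A)
        assert np.array_equal(a.lambda_samples, b.lambda_samples)

    def test_rejects_empty_pool_and_bad_trials(self, simple_life_table):
        with pytest.raises(ValueError):
            monte_carlo_mean_matrix([], n_trials=10)
        with pytest.raises(ValueError):
            monte_carlo_mean_matrix([simple_life_table], n_trials=0)
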