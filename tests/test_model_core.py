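"""Unit and property tests for the model's containers and densities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import gammaln

import rxdeconv as rx
from rxdeconv.errors import (
    AlignmentError,
    BoundaryError,
    DegenerateSampleError,
    InvalidInputError,
    InvalidWeightsError,
)
from rxdeconv.model_core import _largest_remainder

from conftest import make_matrix


class TestNormalizeReference:
    def test_columns_become_stochastic(self):
        df = make_matrix([[2, 1], [2, 1], [4, 2]], ["a", "b", "c"], ["s1", "s2"])
        panel = rx.normalize_reference(df)
        np.testing.assert_allclose(panel.values[:, 0], [0.25, 0.25, 0.5])
        np.testing.assert_allclose(panel.values.sum(axis=0), 1.0, atol=1e-12)

    def test_already_stochastic_is_identity(self):
        vals = np.array([[0.2, 0.1], [0.3, 0.4], [0.5, 0.5]])
        df = make_matrix(vals, ["a", "b", "c"], ["s1", "s2"])
        panel = rx.normalize_reference(df)
        np.testing.assert_allclose(panel.values, vals, atol=1e-12)

    def test_zero_column_names_the_sample(self):
        df = make_matrix([[1, 0], [1, 0], [1, 0]], ["a", "b", "c"], ["s1", "bad"])
        with pytest.raises(DegenerateSampleError, match="bad"):
            rx.normalize_reference(df)

    def test_negative_entry_rejected(self):
        df = make_matrix([[1, 1], [-0.1, 1], [1, 1]], ["a", "b", "c"], ["s1", "s2"])
        with pytest.raises(InvalidInputError):
            rx.normalize_reference(df)


class TestDiscretizeCounts:
    def test_exact_proportions(self):
        df = make_matrix([[0.25], [0.75]], ["a", "b"], ["s1"])
        counts = rx.discretize_counts(df, target_total=100)
        np.testing.assert_array_equal(counts.values[:, 0], [25, 75])

    def test_largest_remainder_beats_plus_minus_one_adjustments(self):
        # brute force: no reassignment of one unit between two genes lowers
        # the total absolute rounding error of the largest-remainder solution
        rng = np.random.default_rng(0)
        col = rng.uniform(0.1, 5.0, size=50)
        T = 100_000
        sol = _largest_remainder(col, T)
        assert sol.sum() == T
        target = col * T / col.sum()
        err = np.abs(sol - target).sum()
        for i in range(50):
            for j in range(50):
                if i == j or sol[i] == 0:
                    continue
                alt = sol.copy()
                alt[i] -= 1
                alt[j] += 1
                assert np.abs(alt - target).sum() >= err - 1e-9

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=10_000), st.integers(min_value=0, max_value=2**31 - 1))
    def test_total_conserved_exactly(self, total, seed):
        rng = np.random.default_rng(seed)
        col = rng.uniform(0.0, 1.0, size=20) + 1e-9
        assert _largest_remainder(col, total).sum() == total

    def test_negative_entry_rejected(self):
        df = make_matrix([[1.0], [-1.0]], ["a", "b"], ["s1"])
        with pytest.raises(InvalidInputError):
            rx.discretize_counts(df, target_total=10)


class TestMixtureProfile:
    def test_pure_reference_returns_that_column(self, tiny_panel):
        r = rx.ResponseProfile(values=np.array([0.2, 0.3, 0.5]), gene_ids=tiny_panel.gene_ids)
        out = rx.mixture_profile(tiny_panel, r, np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(out, tiny_panel.values[:, 0])

    def test_two_component_arithmetic(self):
        panel = rx.ReferencePanel(
            values=np.array([[0.5], [0.5]]), gene_ids=["a", "b"], sample_ids=["s1"]
        )
        r = rx.ResponseProfile(values=np.array([0.2, 0.8]), gene_ids=["a", "b"])
        out = rx.mixture_profile(panel, r, np.array([0.5, 0.5]))
        np.testing.assert_allclose(out, [0.35, 0.65])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_output_on_simplex(self, seed):
        rng = np.random.default_rng(seed)
        panel = rx.ReferencePanel(
            values=np.array([[0.2, 0.1], [0.3, 0.4], [0.5, 0.5]]),
            gene_ids=["gA", "gB", "gC"],
            sample_ids=["s1", "s2"],
        )
        theta = rng.dirichlet(np.ones(3))
        r = rx.ResponseProfile(values=rng.dirichlet(np.ones(3)), gene_ids=panel.gene_ids)
        out = rx.mixture_profile(panel, r, theta)
        assert out.min() >= 0
        assert abs(out.sum() - 1.0) <= 1e-10

    def test_off_simplex_rejected(self, tiny_panel):
        r = rx.ResponseProfile(values=np.array([0.2, 0.3, 0.5]), gene_ids=tiny_panel.gene_ids)
        with pytest.raises(InvalidWeightsError):
            rx.mixture_profile(tiny_panel, r, np.array([0.5, 0.4, 0.2]))


class TestMultinomialLoglik:
    def test_symmetric_two_cell_case(self):
        assert rx.multinomial_loglik(np.array([1, 1]), np.array([0.5, 0.5])) == pytest.approx(
            np.log(0.5), abs=1e-12
        )

    def test_probability_one_event(self):
        assert rx.multinomial_loglik(np.array([3, 0]), np.array([1.0, 0.0])) == 0.0

    def test_impossible_count_gives_minus_inf(self):
        assert rx.multinomial_loglik(np.array([0, 3]), np.array([1.0, 0.0])) == -np.inf

    def test_matches_log_gamma_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            probs = rng.dirichlet(np.ones(5) * 2)
            counts = rng.multinomial(60, probs)
            # independent closed-form oracle: log n! - sum log x_i! + sum x_i log p_i
            oracle = (
                gammaln(counts.sum() + 1)
                - gammaln(counts + 1).sum()
                + (counts * np.log(probs)).sum()
            )
            assert rx.multinomial_loglik(counts, probs) == pytest.approx(oracle, abs=1e-9)

    def test_matches_scipy_multinomial(self):
        rng = np.random.default_rng(3)
        probs = rng.dirichlet(np.ones(4))
        counts = rng.multinomial(30, probs)
        expected = stats.multinomial.logpmf(counts, n=30, p=probs)
        assert rx.multinomial_loglik(counts, probs) == pytest.approx(expected, abs=1e-9)


class TestDirichletLogpdf:
    def test_uniform_density_is_zero(self):
        assert rx.dirichlet_logpdf(np.array([0.3, 0.7]), np.array([1.0, 1.0])) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_beta22_at_center(self):
        val = rx.dirichlet_logpdf(np.array([0.5, 0.5]), np.array([2.0, 2.0]))
        assert val == pytest.approx(np.log(1.5), abs=1e-12)

    def test_matches_scipy_dirichlet(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            k = rng.integers(2, 6)
            alpha = rng.uniform(0.5, 4.0, size=k)
            x = rng.dirichlet(np.ones(k))
            assert rx.dirichlet_logpdf(x, alpha) == pytest.approx(
                stats.dirichlet.logpdf(x, alpha), abs=1e-9
            )

    def test_density_integrates_to_one_on_grid(self):
        # numerical integration oracle over the 3-simplex
        alpha = np.array([2.0, 3.0, 4.0])
        h = 1e-3
        x1, x2 = np.meshgrid(np.arange(h, 1, h), np.arange(h, 1, h))
        mask = x1 + x2 < 1 - h / 2
        x1, x2 = x1[mask], x2[mask]
        x3 = 1 - x1 - x2
        logc = gammaln(alpha.sum()) - gammaln(alpha).sum()
        dens = np.exp(
            logc
            + (alpha[0] - 1) * np.log(x1)
            + (alpha[1] - 1) * np.log(x2)
            + (alpha[2] - 1) * np.log(x3)
        )
        assert dens.sum() * h * h == pytest.approx(1.0, abs=1e-3)

    def test_boundary_rejected(self):
        with pytest.raises(BoundaryError):
            rx.dirichlet_logpdf(np.array([0.0, 1.0]), np.array([2.0, 2.0]))


class TestCompleteLoglik:
    def _single_patient_state(self):
        panel = rx.ReferencePanel(
            values=np.array([[0.2], [0.3], [0.5]]), gene_ids=["a", "b", "c"], sample_ids=["s1"]
        )
        counts = rx.CountMatrix(
            values=np.array([[4], [3], [3]]), gene_ids=["a", "b", "c"], sample_ids=["p1"]
        )
        state = rx.init_state(panel, counts, seed=0)
        return state.with_(
            theta=rx.MixtureWeights(np.array([[0.6, 0.4]])),
            response=rx.ResponseProfile(values=np.array([0.5, 0.25, 0.25]), gene_ids=["a", "b", "c"]),
        )

    def test_single_patient_additive_decomposition(self):
        state = self._single_patient_state()
        alpha_r = state.hyper.kappa * state.prior_mean_profile
        phat = rx.mixture_profile(state.panel, state.response, state.theta.values[0])
        expected = (
            rx.dirichlet_logpdf(state.response.values, alpha_r)
            + rx.dirichlet_logpdf(state.theta.values[0], state.hyper.v)
            + rx.multinomial_loglik(state.counts.values[:, 0], phat)
        )
        assert rx.complete_loglik(state) == pytest.approx(expected, abs=1e-9)

    def test_term_by_term_on_random_state(self, small_cohort):
        state = rx.init_state(small_cohort.panel, small_cohort.counts, seed=9)
        alpha_r = state.hyper.kappa * state.prior_mean_profile
        expected = rx.dirichlet_logpdf(state.response.values, alpha_r)
        for n in range(state.counts.n_samples):
            phat = rx.mixture_profile(state.panel, state.response, state.theta.values[n])
            expected += rx.dirichlet_logpdf(state.theta.values[n], state.hyper.v)
            expected += rx.multinomial_loglik(state.counts.values[:, n], phat / phat.sum())
        assert rx.complete_loglik(state) == pytest.approx(expected, abs=1e-9)

    def test_invariant_to_patient_permutation(self, small_cohort):
        state = rx.init_state(small_cohort.panel, small_cohort.counts, seed=9)
        ll = rx.complete_loglik(state)
        perm = np.random.default_rng(0).permutation(state.counts.n_samples)
        shuffled = state.with_(
            counts=rx.CountMatrix(
                values=state.counts.values[:, perm],
                gene_ids=state.counts.gene_ids,
                sample_ids=[state.counts.sample_ids[i] for i in perm],
            ),
            theta=rx.MixtureWeights(state.theta.values[perm]),
        )
        assert rx.complete_loglik(shuffled) == pytest.approx(ll, rel=1e-12)

    def test_priors_independent_of_count_scale(self):
        state = self._single_patient_state()
        doubled = state.with_(
            counts=rx.CountMatrix(
                values=2 * state.counts.values,
                gene_ids=state.counts.gene_ids,
                sample_ids=state.counts.sample_ids,
            )
        )
        phat = rx.mixture_profile(state.panel, state.response, state.theta.values[0])
        mult_delta = rx.multinomial_loglik(
            doubled.counts.values[:, 0], phat
        ) - rx.multinomial_loglik(state.counts.values[:, 0], phat)
        assert rx.complete_loglik(doubled) - rx.complete_loglik(state) == pytest.approx(
            mult_delta, abs=1e-9
        )


class TestInitState:
    def test_theta_uniform_at_one_over_m_plus_one(self, tiny_panel, tiny_counts):
        state = rx.init_state(tiny_panel, tiny_counts, seed=0)
        np.testing.assert_allclose(state.theta.values, 1.0 / 3.0)

    def test_cohort_scale_initialization(self):
        # M=29 references: every theta entry starts at 1/30
        rng = np.random.default_rng(1)
        vals = rng.dirichlet(np.ones(40), size=29).T
        panel = rx.ReferencePanel(
            values=vals, gene_ids=[f"g{i}" for i in range(40)],
            sample_ids=[f"s{i}" for i in range(29)],
        )
        counts = rx.CountMatrix(
            values=rng.multinomial(1000, np.ones(40) / 40, size=3).T,
            gene_ids=panel.gene_ids,
            sample_ids=["p1", "p2", "p3"],
        )
        state = rx.init_state(panel, counts, seed=0)
        np.testing.assert_allclose(state.theta.values, 1.0 / 30.0)
        assert state.hyper.kappa == 10_000.0

    def test_v_ranges_and_determinism(self, tiny_panel, tiny_counts):
        a = rx.init_state(tiny_panel, tiny_counts, seed=5)
        b = rx.init_state(tiny_panel, tiny_counts, seed=5)
        np.testing.assert_array_equal(a.hyper.v, b.hyper.v)
        assert np.all(a.hyper.v[:-1] >= 1.0) and np.all(a.hyper.v[:-1] <= 2.0)
        assert 5.0 <= a.hyper.v[-1] <= 6.0
        c = rx.init_state(tiny_panel, tiny_counts, seed=6)
        assert not np.array_equal(a.hyper.v, c.hyper.v)

    def test_r_starts_at_prior_mean(self, tiny_panel, tiny_counts):
        state = rx.init_state(tiny_panel, tiny_counts, seed=0)
        np.testing.assert_allclose(
            state.response.values, tiny_panel.values @ state.hyper.omega, atol=1e-12
        )

    def test_gene_order_mismatch_is_alignment_error(self, tiny_panel):
        counts = rx.CountMatrix(
            values=np.array([[1], [1], [1]]), gene_ids=["gB", "gA", "gC"], sample_ids=["p1"]
        )
        with pytest.raises(AlignmentError):
            rx.init_state(tiny_panel, counts, seed=0)


class TestContainers:
    def test_mixture_rows_must_sum_to_one(self):
        with pytest.raises(InvalidInputError):
            rx.MixtureWeights(np.array([[0.5, 0.4]]))

    def test_response_must_be_positive(self):
        with pytest.raises(InvalidInputError):
            rx.ResponseProfile(values=np.array([0.0, 1.0]), gene_ids=["a", "b"])

    def test_count_matrix_totals(self, tiny_counts):
        np.testing.assert_array_equal(tiny_counts.totals, [10, 10])

    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(InvalidInputError):
            rx.CountMatrix(values=np.array([[1], [1]]), gene_ids=["a", "a"], sample_ids=["p"])
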