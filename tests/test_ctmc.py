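"""Unit and property tests for the CTMC machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from scipy.integrate import quad

import glycpath as gp
from glycpath.ctmc import NotEmbeddableError

from conftest import random_generator, simulate_panel_counts


def uniformization(q, t, terms=200):
    """Independent series oracle: P(t) = e^{-lt} sum (lt)^k/k! (I + Q/l)^k."""
    lam = max(-np.diag(q).min(), 1e-12)
    m = np.eye(q.shape[0]) + q / lam
    acc = np.zeros_like(q)
    mk = np.eye(q.shape[0])
    log_weight = -lam * t
    for k in range(terms):
        acc = acc + np.exp(log_weight) * mk
        mk = mk @ m
        log_weight += np.log(lam * t) - np.log(k + 1)
    return acc


class TestTransitionMatrix:
    def test_zero_generator_is_identity(self):
        q = np.zeros((3, 3))
        assert np.allclose(gp.transition_matrix(q, 5.0), np.eye(3))

    def test_two_state_closed_form(self, q_two_state):
        # exponential decay: P11(ln 2) = 1/2
        p = gp.transition_matrix(q_two_state, np.log(2))
        assert np.allclose(p, [[0.5, 0.5], [0.0, 1.0]], atol=1e-12)

    def test_matches_uniformization_series(self, random_q):
        p = gp.transition_matrix(random_q, 1.7)
        assert np.max(np.abs(p - uniformization(random_q, 1.7))) < 1e-9

    def test_p0_is_identity_and_negative_t_rejected(self, random_q):
        assert np.array_equal(gp.transition_matrix(random_q, 0.0), np.eye(3))
        with pytest.raises(ValueError):
            gp.transition_matrix(random_q, -0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_chapman_kolmogorov_and_row_sums(self, seed):
        rng = np.random.default_rng(seed)
        q = random_generator(rng)
        s, t = rng.uniform(0, 10, size=2)
        pst = gp.transition_matrix(q, s + t)
        prod = gp.transition_matrix(q, s) @ gp.transition_matrix(q, t)
        assert np.max(np.abs(pst - prod)) < 1e-9
        for tt in (s, t, s + t):
            p = gp.transition_matrix(q, tt)
            assert np.max(np.abs(p.sum(axis=1) - 1)) < 1e-10
            assert p.min() >= -1e-12


class TestValidateGenerator:
    def test_accepts_valid_and_rejects_invalid(self, random_q):
        gp.validate_generator(random_q, absorbing=[2])
        bad = random_q.copy()
        bad[0, 1] = -0.1
        with pytest.raises(ValueError, match="non-negative"):
            gp.validate_generator(bad)
        bad = random_q.copy()
        bad[0, 0] += 0.5
        with pytest.raises(ValueError, match="sum to zero"):
            gp.validate_generator(bad)

    def test_disallowed_mask(self, random_q):
        with pytest.raises(ValueError, match="disallowed"):
            gp.validate_generator(random_q, absorbing=[2], allowed=[(0, 1)])


class TestPanelLoglik:
    def test_single_cell_closed_form(self, q_two_state, two_state_structure):
        data = gp.IntervalCounts()
        data.add("A", "B", np.log(2))
        ll = gp.panel_loglik(q_two_state, data, two_state_structure)
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_aggregation_equals_per_pair_product(self, bi_structure, rng):
        # five subjects' visit pairs, aggregated vs summed one at a time
        q = random_generator(rng)
        pairs = [("N", "P", 2.0), ("P", "D", 2.0), ("N", "N", 2.0),
                 ("P", "N", 4.0), ("N", "P", 2.0), ("N", "D", 6.0),
                 ("P", "P", 2.0), ("N", "N", 2.0)]
        agg = gp.IntervalCounts()
        per_pair = 0.0
        for a, b, dt in pairs:
            agg.add(a, b, dt)
            single = gp.IntervalCounts()
            single.add(a, b, dt)
            per_pair += gp.panel_loglik(q, single, bi_structure)
        assert gp.panel_loglik(q, agg, bi_structure) == pytest.approx(per_pair, abs=1e-12)

    def test_linear_in_counts(self, bi_structure, random_q):
        data = gp.IntervalCounts()
        data.add("N", "P", 2.0, 3)
        data.add("P", "D", 2.0, 2)
        doubled = gp.IntervalCounts()
        for (a, b, dt), c in data.cells.items():
            doubled.add(a, b, dt, 2 * c)
        assert gp.panel_loglik(random_q, doubled, bi_structure) == pytest.approx(
            2 * gp.panel_loglik(random_q, data, bi_structure))

    def test_zero_probability_is_minus_inf(self, two_state_structure, q_two_state):
        data = gp.IntervalCounts()
        data.add("A", "B", 1.0)
        q_frozen = np.zeros((2, 2))
        assert gp.panel_loglik(q_frozen, data, two_state_structure) == -np.inf

    def test_unknown_state_rejected(self, two_state_structure, q_two_state):
        data = gp.IntervalCounts()
        data.add("A", "Z", 1.0)
        with pytest.raises(ValueError, match="outside the model"):
            gp.panel_loglik(q_two_state, data, two_state_structure)


class TestGeneratorFromAnnual:
    def test_identity_maps_to_zero(self):
        assert np.allclose(gp.generator_from_annual(np.eye(3)), 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        q = random_generator(rng, scale=0.4)
        p1 = gp.transition_matrix(q, 1.0)
        assert np.max(np.abs(gp.generator_from_annual(p1) - q)) < 1e-8

    def test_published_style_matrix_embeddable(self):
        p1 = np.array([[0.948, 0.042, 0.010], [0.252, 0.671, 0.077], [0, 0, 1.0]])
        q = gp.generator_from_annual(p1)
        gp.validate_generator(q, absorbing=[2])
        assert q[0, 1] > 0 and q[0, 2] > 0 and q[1, 0] > 0 and q[1, 2] > 0
        assert np.max(np.abs(gp.transition_matrix(q, 1.0) - p1)) < 1e-8

    def test_non_embeddable_rejected(self):
        flip = np.array([[0.0, 1.0], [1.0, 0.0]])  # period-2 chain: no generator
        with pytest.raises(NotEmbeddableError):
            gp.generator_from_annual(flip)
        with pytest.raises(NotEmbeddableError, match="sum to 1"):
            gp.generator_from_annual(np.array([[0.5, 0.4], [0.0, 1.0]]))


class TestSojournAndResidence:
    def test_sojourn_reciprocal_and_absorbing(self, random_q):
        soj = gp.mean_sojourn(random_q, absorbing=[2])
        assert soj[0] == pytest.approx(-1 / random_q[0, 0])
        assert np.isinf(soj[2])
        with pytest.raises(ValueError):
            gp.mean_sojourn(np.zeros((2, 2)), absorbing=[1])

    def test_sojourn_scaling(self, random_q):
        soj = gp.mean_sojourn(random_q, absorbing=[2])
        soj_scaled = gp.mean_sojourn(3.0 * random_q, absorbing=[2])
        assert np.allclose(soj_scaled[:2], soj[:2] / 3.0)

    def test_sojourn_matches_simulated_holding_times(self, random_q, rng):
        draws = rng.exponential(1.0 / -random_q[0, 0], size=20_000)
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - gp.mean_sojourn(random_q, [2])[0]) < 2 * se

    def test_two_state_residence_is_exponential_mean(self, q_two_state):
        res = gp.total_length_of_stay(q_two_state, 0, absorbing=[1])
        assert res[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_residence_matches_quadrature(self, seed):
        # residence_j = integral of P_{start,j}(t) dt, checked to 0.1%
        rng = np.random.default_rng(seed)
        q = random_generator(rng)
        res = gp.total_length_of_stay(q, 0, absorbing=[2])
        for j, value in res.items():
            integral, _ = quad(lambda t: gp.transition_matrix(q, t)[0, j],
                               0, 500, limit=200)
            assert value == pytest.approx(integral, rel=1e-3)

    def test_singular_transient_block_rejected(self):
        q = np.zeros((2, 2))  # absorption unreachable
        with pytest.raises(ValueError, match="singular|transient"):
            gp.total_length_of_stay(q, 0, absorbing=[1])


class TestFit:
    def test_saturated_model_matches_empirical_matrix(self, bi_structure):
        # uniform dt=2 with an embeddable empirical matrix: the MLE makes
        # P(2) reproduce the row-normalised count matrix exactly
        q_true = gp.generator_from_annual(
            np.array([[0.90, 0.08, 0.02], [0.20, 0.72, 0.08], [0, 0, 1.0]]))
        p2 = gp.transition_matrix(q_true, 2.0)
        data = gp.IntervalCounts()
        for i, a in enumerate(("N", "P")):
            for j, b in enumerate(("N", "P", "D")):
                data.add(a, b, 2.0, 10_000 * p2[i, j])
        fit = gp.fit_ctmc(bi_structure, data)
        assert fit.converged
        p2_hat = gp.transition_matrix(fit.q_hat, 2.0)
        norm = np.array([[p2[0]], [p2[1]]]).reshape(2, 3)
        assert np.max(np.abs(p2_hat[:2] - norm)) < 1e-6

    def test_parameter_recovery_within_ten_percent(self, bi_structure):
        rng = np.random.default_rng(7)
        q_true = gp.default_generator("igt")
        data = simulate_panel_counts(q_true, bi_structure, 8000, 20.0, 2.0, rng,
                                     initial_probs=[0.765, 0.235, 0.0])
        fit = gp.fit_ctmc(bi_structure, data)
        assert fit.converged
        for i, j in bi_structure.allowed:
            assert fit.q_hat[i, j] == pytest.approx(q_true[i, j], rel=0.10)

    def test_unidirectional_structure_without_regression_parameter(self):
        uni = gp.CtmcStructure(states=("N", "P", "D"), absorbing=frozenset({"D"}),
                               allowed=((0, 1), (0, 2), (1, 2)))
        q_true = np.array([[-0.15, 0.13, 0.02], [0.0, -0.08, 0.08], [0, 0, 0.0]])
        rng = np.random.default_rng(3)
        data = simulate_panel_counts(q_true, uni, 2000, 20.0, 2.0, rng)
        fit = gp.fit_ctmc(uni, data)
        assert fit.converged
        assert fit.q_hat[1, 0] == 0.0
        assert len(fit.theta) == 3

    def test_empty_data_rejected(self, bi_structure):
        with pytest.raises(ValueError, match="no interval data"):
            gp.fit_ctmc(bi_structure, gp.IntervalCounts())

    def test_unobserved_transition_hits_lower_bound_with_warning(self, bi_structure):
        # regression never observed: its intensity is driven to the bound
        data = gp.IntervalCounts()
        data.add("N", "N", 2.0, 500)
        data.add("N", "P", 2.0, 60)
        data.add("N", "D", 2.0, 10)
        data.add("P", "P", 2.0, 60)
        data.add("P", "D", 2.0, 10)
        with pytest.warns(UserWarning, match="lower bound"):
            fit = gp.fit_ctmc(bi_structure, data)
        assert any("lower bound" in m for m in fit.messages)


class TestAnnualTransitions:
    def _fit_two_state(self):
        structure = gp.CtmcStructure(states=("A", "B"), absorbing=frozenset({"B"}),
                                     allowed=((0, 1),))
        q = np.array([[-np.log(2), np.log(2)], [0.0, 0.0]])
        return gp.FitResult(structure=structure, theta=np.array([np.log(np.log(2))]),
                            q_hat=q, cov_theta=np.zeros((1, 1)), loglik=0.0,
                            converged=True, n_intervals=10)

    def test_half_life_intensity_gives_fifty_percent(self):
        atp = gp.annual_transitions(self._fit_two_state(), b=200, rng=0)
        row = atp[(atp["from"] == "A") & (atp["to"] == "B")].iloc[0]
        assert row["atp_pct"] == pytest.approx(50.0, abs=1e-9)

    def test_degenerate_covariance_collapses_ci(self):
        atp = gp.annual_transitions(self._fit_two_state(), b=200, rng=0)
        assert np.allclose(atp["ci_lo"], atp["atp_pct"])
        assert np.allclose(atp["ci_hi"], atp["atp_pct"])

    def test_rows_sum_to_hundred(self, bi_structure, rng):
        data = simulate_panel_counts(random_generator(rng), bi_structure,
                                     1500, 10.0, 2.0, rng,
                                     initial_probs=[0.7, 0.3, 0.0])
        fit = gp.fit_ctmc(bi_structure, data)
        atp = gp.annual_transitions(fit, b=200, rng=1)
        sums = atp.groupby("from")["atp_pct"].sum()
        assert np.allclose(sums, 100.0, atol=0.1)
        assert ((atp["atp_pct"] >= 0) & (atp["atp_pct"] <= 100)).all()

    def test_too_few_draws_warns(self):
        with pytest.warns(UserWarning, match="too few"):
            gp.annual_transitions(self._fit_two_state(), b=50, rng=0)


class TestCiCalibration:
    def test_intensity_ci_coverage_scaled_down(self, bi_structure):
        # 40 replicates at n=1,000: nominal-95% normal-simulation CIs for the
        # q_ij should cover truth in at least 85% of replicates
        q_true = gp.default_generator("igt")
        n_rep = 40
        covered = np.zeros(len(bi_structure.allowed))
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            data = simulate_panel_counts(q_true, bi_structure, 1000, 20.0, 2.0,
                                         rng, initial_probs=[0.765, 0.235, 0.0])
            fit = gp.fit_ctmc(bi_structure, data)
            draws = rng.multivariate_normal(fit.theta, fit.cov_theta, size=500)
            q_draws = np.exp(draws)
            lo = np.percentile(q_draws, 2.5, axis=0)
            hi = np.percentile(q_draws, 97.5, axis=0)
            truth = np.array([q_true[i, j] for i, j in bi_structure.allowed])
            covered += (lo <= truth) & (truth <= hi)
        assert (covered / n_rep >= 0.85).all()


@settings(max_examples=30, deadline=None, derandomize=True)
@given(hst.integers(min_value=0, max_value=10_000))
def test_build_generator_round_trips_theta(seed):
    """exp(theta) always reproduces the off-diagonals of the built generator."""
    rng = np.random.default_rng(seed)
    structure = gp.CtmcStructure(states=("N", "P", "D"), absorbing=frozenset({"D"}),
                                 allowed=((0, 1), (0, 2), (1, 0), (1, 2)))
    theta = rng.uniform(-6, 1, size=4)
    q = gp.build_generator(structure, theta)
    gp.validate_generator(q, absorbing=[2], allowed=structure.allowed)
    for k, (i, j) in enumerate(structure.allowed):
        assert q[i, j] == pytest.approx(np.exp(theta[k]))
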