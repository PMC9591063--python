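"""Stability statistics: divergence, fluctuation, success and failure rates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orderica import (
    StabilityReport,
    align_runs,
    analytic_failure_bound,
    divergence,
    failure_rates,
    fit_success_model,
    fluctuation_curve,
    make_dataset,
    mean_fluctuation,
    run_ordering_ica,
    success_rate,
)
from orderica.fastica import CandidateResult


def _cand(w, alpha=1.0, converged=True):
    w = np.asarray(w, dtype=float)
    return CandidateResult(
        w=w / np.linalg.norm(w), y=np.zeros(1), alpha=alpha,
        converged=converged, iterations=1,
    )


class TestDivergence:
    def test_same_and_opposite_directions_give_zero(self):
        w = np.array([0.3, -0.8, 0.1])
        assert divergence(w, w) == pytest.approx(0.0, abs=1e-15)
        assert divergence(w, -w) == pytest.approx(0.0, abs=1e-15)

    def test_orthogonal_gives_one(self):
        assert divergence([1.0, 0.0], [0.0, 5.0]) == pytest.approx(1.0)

    def test_hand_computed_45_degrees(self):
        assert divergence([1.0, 0.0], [1.0, 1.0]) == pytest.approx(
            1 - 1 / np.sqrt(2), abs=1e-12
        )

    def test_missing_operand_scores_maximum(self):
        assert divergence(None, [1.0, 0.0]) == 1.0
        assert divergence([1.0, 0.0], None) == 1.0

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            divergence([0.0, 0.0], [1.0, 0.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        seed=st.integers(0, 10**6),
        scale=st.floats(0.01, 100),
        sign=st.sampled_from([-1.0, 1.0]),
    )
    def test_symmetric_bounded_scale_invariant(self, seed, scale, sign):
        g = np.random.default_rng(seed)
        a, b = g.standard_normal(4), g.standard_normal(4)
        d = divergence(a, b)
        assert 0.0 <= d <= 1.0 + 1e-12
        assert d == pytest.approx(divergence(b, a), abs=1e-12)
        assert d == pytest.approx(divergence(sign * scale * a, b), abs=1e-9)


class TestFluctuation:
    def test_identical_runs_have_zero_fluctuation(self):
        runs = [[np.array([1.0, 0.0])] for _ in range(4)]
        assert mean_fluctuation(runs, 0) == pytest.approx(0.0, abs=1e-15)

    def test_two_runs_equal_single_pair_divergence(self):
        runs = [[np.array([1.0, 0.0])], [np.array([1.0, 1.0])]]
        assert mean_fluctuation(runs, 0) == pytest.approx(1 - 1 / np.sqrt(2))

    def test_three_runs_hand_average(self):
        # pairwise divergences (0, 0.3, 0.3) -> mean 0.2
        v = np.array([1.0, 0.0])
        u = np.array([0.7, np.sqrt(1 - 0.49)])  # |cos| with v = 0.7
        runs = [[v], [v], [u]]
        assert mean_fluctuation(runs, 0) == pytest.approx(0.2, abs=1e-12)

    def test_fewer_than_two_runs_rejected(self):
        with pytest.raises(ValueError):
            mean_fluctuation([[np.array([1.0, 0.0])]], 0)


class TestAlignRuns:
    def test_sorted_input_unchanged(self):
        w = np.eye(2)
        aligned = align_runs([(w, np.array([2.0, 1.0]))])
        np.testing.assert_array_equal(aligned[0][0], w[0])
        np.testing.assert_array_equal(aligned[0][1], w[1])

    def test_permutation_removed_by_upsilon_rank(self):
        w = np.eye(2)
        runs = [(w, np.array([2.0, 1.0])), (w[::-1], np.array([1.0, 2.0]))]
        curve = fluctuation_curve(runs)
        np.testing.assert_allclose(curve, 0.0, atol=1e-15)

    def test_missing_component_scores_one(self):
        runs = [
            (np.eye(2), np.array([2.0, 1.0])),
            (np.eye(2)[:1], np.array([2.0])),  # run with one fewer component
        ]
        curve = fluctuation_curve(runs)
        assert curve[0] == pytest.approx(0.0, abs=1e-15)
        assert curve[1] == 1.0


class TestSuccessRate:
    def test_all_candidates_equal_best(self):
        cands = [_cand([1.0, 0.0]) for _ in range(5)]
        assert success_rate(cands, 0) == 1.0

    def test_minimum_is_one_over_l_max(self):
        cands = [_cand([1.0, 0.0])] + [_cand([0.0, 1.0]) for _ in range(9)]
        assert success_rate(cands, 0) == pytest.approx(0.1)

    def test_direct_count(self):
        near = [_cand([1.0, 0.0]) for _ in range(3)]
        far = [_cand([0.0, 1.0]) for _ in range(7)]
        assert success_rate(near + far, 0) == pytest.approx(0.3)

    def test_diverged_candidates_never_counted(self):
        cands = [_cand([1.0, 0.0])] + [
            _cand([1.0, 0.0], converged=False) for _ in range(3)
        ]
        assert success_rate(cands, 0) == pytest.approx(0.25)

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ValueError):
            success_rate([], 0)


class TestFailureRates:
    def test_perfect_success_rate_never_fails(self):
        nu_each, nu_total = failure_rates([1.0, 1.0], 64)
        np.testing.assert_array_equal(nu_each, 0.0)
        np.testing.assert_array_equal(nu_total, 0.0)

    def test_printed_bound_at_l_128(self):
        nu_each, _ = failure_rates([10**-1.5], 128)
        assert nu_each[0] == pytest.approx(0.01633, abs=1e-4)
        assert nu_each[0] < 0.0164
        assert nu_each[0] == analytic_failure_bound(128)

    def test_constant_rate_closed_form(self):
        # constant nu_each = c gives nu_total_i = 1 - (1-c)^i
        mu = np.full(6, 0.2)
        nu_each, nu_total = failure_rates(mu, 3)
        c = 0.8**3
        np.testing.assert_allclose(
            nu_total, 1 - (1 - c) ** np.arange(1, 7), rtol=1e-12
        )

    def test_total_rate_matches_product_form_and_is_monotone(self, rng):
        mu = rng.uniform(0.05, 1.0, size=8)
        nu_each, nu_total = failure_rates(mu, 16)
        np.testing.assert_allclose(
            nu_total, 1 - np.cumprod(1 - nu_each), rtol=1e-12, atol=1e-15
        )
        assert np.all(np.diff(nu_total) >= 0)
        assert np.all((nu_total >= 0) & (nu_total <= 1))

    def test_nonpositive_mu_rejected(self):
        with pytest.raises(ValueError):
            failure_rates([0.5, 0.0], 8)


class TestSuccessModelFit:
    def test_exact_power_law_recovered(self):
        ups = np.array([0.5, 1.0, 2.0, 5.0, 20.0])
        b1, b2 = -0.9, 0.15
        mus = 10**b1 * ups**b2
        fit = fit_success_model(ups, mus)
        assert fit == pytest.approx((b1, b2), abs=1e-10)

    def test_two_points_interpolated_exactly(self):
        ups, mus = np.array([1.0, 10.0]), np.array([0.1, 0.4])
        b1, b2 = fit_success_model(ups, mus)
        np.testing.assert_allclose(
            10**b1 * ups**b2, mus, rtol=1e-10
        )

    def test_noisy_power_law_recovered_within_three_se(self, rng):
        n = 200
        ups = 10 ** rng.uniform(-1, 1.5, size=n)
        b1, b2, sigma = -0.7, 0.2, 0.1
        logmu = b1 + b2 * np.log10(ups) + rng.normal(0, sigma, size=n)
        b1_hat, b2_hat = fit_success_model(ups, 10**logmu)
        lx = np.log10(ups)
        se_slope = sigma / np.sqrt(np.sum((lx - lx.mean()) ** 2))
        se_inter = se_slope * np.sqrt(np.mean(lx**2))
        assert abs(b2_hat - b2) < 3 * se_slope
        assert abs(b1_hat - b1) < 3 * se_inter

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_success_model([1.0], [0.5])
        with pytest.raises(ValueError):
            fit_success_model([1.0, -1.0], [0.5, 0.5])


class TestAnalyticBound:
    def test_certain_failure_without_candidates(self):
        assert analytic_failure_bound(0) == 1.0

    def test_decay_coefficient_supports_conservative_form(self):
        # (1 - 10^-1.5)^L decays at least as fast as 10^(-0.0139 L)
        assert -np.log10(1 - 10**-1.5) >= 0.0139


class TestStabilityReport:
    def test_from_candidates_end_to_end(self):
        x, _ = make_dataset(["laplace", "uniform"], 10000, seed=17)
        res = run_ordering_ica(
            x, l_candidates=40, seed=17, whiten_input=True, keep_candidates=True
        )
        report = StabilityReport.from_candidates(res, l_candidates=64)
        mus = report.success_rates
        assert mus.shape == (2,)
        assert np.all((mus >= 1 / 40) & (mus <= 1.0))
        # the last component's direction is forced, so every converged
        # restart finds it
        assert mus[-1] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(report.failure_total) >= 0)

    def test_from_runs_on_stable_problem(self):
        x, _ = make_dataset(["laplace", "uniform"], 10000, seed=23)
        runs = [
            run_ordering_ica(x, l_candidates=16, seed=s, whiten_input=True)
            for s in range(3)
        ]
        report = StabilityReport.from_runs(runs)
        assert report.n_runs == 3
        assert np.all(report.per_component_fluctuation < 0.01)
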