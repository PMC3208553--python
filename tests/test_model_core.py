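"""Forward-model unit and property tests.

The independent oracle for the quadrant predictions is exact enumeration of
all (hit count, internalization outcome) pairs at small truncation, with
binomial internalization probabilities — no shared code with the model's
truncated-series implementation.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from phagofit import (
    ConfigError,
    NegativeControlStats,
    ParamPoint,
    QuadrantFractions,
    poisson_pmf,
    predicted_histogram,
    predicted_q1,
    predicted_q23,
    predicted_quadrants,
    prob_all_internalized,
    prob_any_hit,
    q23_closed_form,
)

params_st = st.builds(
    ParamPoint,
    m=st.floats(0.05, 6.4),
    p=st.floats(0.0, 1.0),
    alpha=st.floats(0.0, 4.5),
)


def enumerate_quadrants(m: float, p: float, alpha: float, n_max: int):
    """Exact enumeration oracle over (n hits, k internalized).

    P(n, k) = Pois(n; m) * C(n, k) p^k (1-p)^(n-k).  A cell is
    adsorption-positive iff k < n; an adsorption-negative cell (k = n) sits
    above the gate with probability Phi(n * alpha).
    """
    q23 = 0.0
    q1 = 0.0
    for n in range(n_max + 1):
        pois = math.exp(-m) * m**n / math.factorial(n)
        for k in range(n + 1):
            prob = pois * math.comb(n, k) * p**k * (1 - p) ** (n - k)
            if k < n:
                q23 += prob
            else:
                q1 += prob * stats.norm.cdf(n * alpha)
    return q1, q23


class TestElementaryProbabilities:
    @pytest.mark.parametrize(
        "n, m, expected",
        [
            (0, 2.17, math.exp(-2.17)),  # 0.11418
            (0, 1e-9, 1.0),
            (3, 1.5, math.exp(-1.5) * 1.5**3 / 6),
        ],
    )
    def test_poisson_pmf_values(self, n, m, expected):
        assert poisson_pmf(n, m) == pytest.approx(expected, rel=1e-9)

    def test_poisson_pmf_normalizes(self):
        assert sum(poisson_pmf(n, 2.17) for n in range(200)) == pytest.approx(1.0)

    def test_truncated_mass_at_m_bound(self):
        # at the m < 6.5 working bound, 12 hits capture over 98% of the mass
        assert sum(poisson_pmf(n, 6.5) for n in range(13)) >= 0.98

    @pytest.mark.parametrize("bad_n, bad_m", [(-1, 2.0), (2, 0.0), (2, -1.0)])
    def test_poisson_pmf_domain_errors(self, bad_n, bad_m):
        with pytest.raises(ValueError):
            poisson_pmf(bad_n, bad_m)

    def test_prob_any_hit(self):
        assert prob_any_hit(2.17) == pytest.approx(1 - math.exp(-2.17), rel=1e-12)
        assert prob_any_hit(1e-12) == pytest.approx(0.0, abs=1e-11)
        with pytest.raises(ValueError):
            prob_any_hit(0.0)

    def test_prob_any_hit_monotone_bounded(self):
        ms = np.linspace(0.01, 6.4, 50)
        vals = [prob_any_hit(m) for m in ms]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1.0

    @pytest.mark.parametrize(
        "n, p, expected",
        [(0, 0.3, 1.0), (3, 1.0, 1.0), (2, 0.739, 0.739**2), (5, 0.0, 0.0)],
    )
    def test_prob_all_internalized(self, n, p, expected):
        assert prob_all_internalized(n, p) == pytest.approx(expected, rel=1e-12)

    def test_prob_all_internalized_domain(self):
        with pytest.raises(ValueError):
            prob_all_internalized(2, 1.5)


class TestQuadrantPredictions:
    def test_q23_reference_value(self, fig_params):
        # truncated sum at the reference fit; closed form 1 - e^(-m(1-p))
        q23 = predicted_q23(fig_params, n_max=12)
        assert round(q23, 3) == 0.432
        assert abs(q23 - q23_closed_form(2.17, 0.739)) < 1e-5

    def test_q23_degenerate_p(self):
        assert predicted_q23(ParamPoint(m=2.0, p=1.0, alpha=1.0)) == 0.0
        # p = 0: nothing internalized, q23 = P(any hit) up to truncation
        q23 = predicted_q23(ParamPoint(m=2.17, p=0.0, alpha=1.0), n_max=12)
        assert q23 == pytest.approx(prob_any_hit(2.17), abs=1e-5)

    def test_q1_reference_values(self, fig_params):
        # p = 0: only the n = 0 term survives, Phi(0) = 1/2
        q1 = predicted_q1(ParamPoint(m=2.0, p=1e-300, alpha=1.0))
        assert q1 == pytest.approx(0.5 * math.exp(-2), rel=1e-9)
        # alpha -> infinity: every internalizing cell clears the gate
        q1_inf = predicted_q1(ParamPoint(m=2.17, p=0.739, alpha=40.0))
        expected = math.exp(-2.17 * (1 - 0.739)) - 0.5 * math.exp(-2.17)
        assert q1_inf == pytest.approx(expected, abs=1e-5)
        # reference parameters, term-by-term frozen value
        assert predicted_q1(fig_params) == pytest.approx(0.5094, abs=2e-4)

    def test_quadrants_bundles_components(self, fig_params):
        q = predicted_quadrants(fig_params)
        assert q.q1 == predicted_q1(fig_params)
        assert q.q23 == predicted_q23(fig_params)

    def test_quadrants_limits(self):
        q = predicted_quadrants(ParamPoint(m=1.7, p=1.0, alpha=40.0))
        assert q.q23 == 0.0
        assert q.q1 == pytest.approx(1 - 0.5 * math.exp(-1.7), abs=1e-4)
        q0 = predicted_quadrants(ParamPoint(m=1e-9, p=0.5, alpha=1.0))
        assert q0.q23 == pytest.approx(0.0, abs=1e-8)
        assert q0.q1 == pytest.approx(0.5, abs=1e-8)

    def test_n_max_config_error(self, fig_params):
        with pytest.raises(ConfigError):
            predicted_q23(fig_params, n_max=0)

    @pytest.mark.parametrize("m", [0.3, 1.1, 2.8])
    @pytest.mark.parametrize("p", [0.0, 0.25, 0.739])
    @pytest.mark.parametrize("alpha", [0.0, 1.3, 4.5])
    def test_enumeration_oracle_small_truncation(self, m, p, alpha):
        params = ParamPoint(m=m, p=max(p, 1e-300), alpha=alpha)
        for n_max in (1, 2, 4):
            q1_oracle, q23_oracle = enumerate_quadrants(m, p, alpha, n_max)
            assert predicted_q23(params, n_max) == pytest.approx(q23_oracle, abs=1e-12)
            assert predicted_q1(params, n_max) == pytest.approx(q1_oracle, abs=1e-12)


class TestModelProperties:
    @settings(max_examples=60, derandomize=True)
    @given(params=params_st)
    def test_fractions_valid_and_truncation_bound(self, params):
        q1 = predicted_q1(params)
        q23 = predicted_q23(params)
        assert 0 <= q1 and 0 <= q23
        assert q1 + q23 <= 1 + 1e-12
        assert -1e-12 <= q23_closed_form(params.m, params.p) - q23 < 0.02

    @settings(max_examples=40, derandomize=True)
    @given(
        m=st.floats(0.1, 6.0), p=st.floats(0.0, 0.95), dm=st.floats(0.05, 0.4)
    )
    def test_q23_monotone_in_m(self, m, p, dm):
        # n_max far beyond the truncation guard so the property reflects the
        # model, not the boundary truncation error
        lo = predicted_q23(ParamPoint(m=m, p=p, alpha=1.0), n_max=60)
        hi = predicted_q23(ParamPoint(m=min(m + dm, 6.4), p=p, alpha=1.0), n_max=60)
        assert hi > lo

    @settings(max_examples=40, derandomize=True)
    @given(m=st.floats(0.1, 6.0), p=st.floats(0.0, 0.9), dp=st.floats(0.02, 0.1))
    def test_q23_monotone_decreasing_in_p(self, m, p, dp):
        hi = predicted_q23(ParamPoint(m=m, p=p, alpha=1.0))
        lo = predicted_q23(ParamPoint(m=m, p=min(p + dp, 1.0), alpha=1.0))
        assert lo < hi

    @settings(max_examples=40, derandomize=True)
    @given(
        m=st.floats(0.1, 6.0),
        p=st.floats(0.01, 1.0),
        a=st.floats(0.0, 4.0),
        da=st.floats(0.0, 0.5),
    )
    def test_q1_nondecreasing_in_alpha(self, m, p, a, da):
        lo = predicted_q1(ParamPoint(m=m, p=p, alpha=a))
        hi = predicted_q1(ParamPoint(m=m, p=p, alpha=a + da))
        assert hi >= lo - 1e-12

    def test_truncation_converges_from_below(self, fig_params):
        exact = q23_closed_form(fig_params.m, fig_params.p)
        vals = [predicted_q23(fig_params, n_max) for n_max in range(1, 20)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert all(v <= exact + 1e-12 for v in vals)
        assert exact - vals[-1] < 1e-10


class TestPredictedHistogram:
    def test_component_means_and_total(self, fig_params, reference_neg):
        # widest component sits n_max * alpha ~ 30 SDs above the control mean
        grid = np.linspace(
            reference_neg.log_mean - 5 * reference_neg.log_sd,
            reference_neg.log_mean + 36 * reference_neg.log_sd,
            8001,
        )
        hist = predicted_histogram(fig_params, reference_neg, grid)
        assert hist.component_densities.shape == (13, grid.size)
        assert np.all(hist.component_densities >= 0)
        np.testing.assert_allclose(
            hist.total_density, hist.component_densities.sum(axis=0)
        )
        # mixture integrates to 1 over the adsorption-negative population
        assert np.trapezoid(hist.total_density, grid) == pytest.approx(1.0, abs=1e-3)
        # component n peaks at log_mean + n * alpha * log_sd
        n1_mode = grid[np.argmax(hist.component_densities[1])]
        expected = reference_neg.log_mean + fig_params.alpha * reference_neg.log_sd
        assert n1_mode == pytest.approx(expected, abs=grid[1] - grid[0])
        # in the display log10 convention that mean is 4.57 + 2.53 * 0.29
        assert expected / np.log(10) == pytest.approx(5.3037, abs=1e-3)

    def test_degenerate_single_component(self, reference_neg):
        grid = np.linspace(8, 14, 500)
        hist = predicted_histogram(
            ParamPoint(m=1e-9, p=0.5, alpha=2.0), reference_neg, grid
        )
        ref = stats.norm.pdf(grid, reference_neg.log_mean, reference_neg.log_sd)
        np.testing.assert_allclose(hist.total_density, ref, atol=1e-6)

    def test_grid_validation(self, fig_params, reference_neg):
        with pytest.raises(ConfigError):
            predicted_histogram(fig_params, reference_neg, np.array([]))
        with pytest.raises(ConfigError):
            predicted_histogram(fig_params, reference_neg, np.array([2.0, 1.0]))


class TestDomainTypes:
    def test_negative_control_stats_invariants(self):
        with pytest.raises(ValueError):
            NegativeControlStats(log_mean=1.0, log_sd=0.0)
        with pytest.raises(ValueError):
            NegativeControlStats(log_mean=np.inf, log_sd=0.1)

    def test_param_point_invariants(self):
        for bad in [dict(m=-1, p=0.5, alpha=1), dict(m=1, p=1.2, alpha=1),
                    dict(m=1, p=0.5, alpha=-0.1)]:
            with pytest.raises(ValueError):
                ParamPoint(**bad)

    def test_quadrant_fraction_invariants(self):
        with pytest.raises(ValueError):
            QuadrantFractions(q1=0.7, q23=0.5)
        with pytest.raises(ValueError):
            QuadrantFractions(q1=-0.1, q23=0.5)
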