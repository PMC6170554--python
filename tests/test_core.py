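"""Closed-form identities: worked examples, inversions and monotonicity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pubbias.core import (
    CorrelationPowerSpec,
    PowerLink,
    correlation_power,
    posterior,
    prob_positive_false,
    prob_positive_total,
    prob_positive_true,
    reproducibility,
    smallest_prior_for_positive_rate,
    solve_naive,
)

probs = st.floats(0.0, 1.0, allow_nan=False)


class TestPositiveRate:
    @pytest.mark.parametrize(
        "theta, power, alpha, expected",
        [
            (0.9, 1.0, 0.05, 0.905),   # 90% true prior at perfect power
            (1.0, 0.7, 0.05, 0.7),     # all-true prior reduces to power
            (0.0, 0.7, 0.05, 0.05),    # all-false prior reduces to alpha
        ],
    )
    def test_examples(self, theta, power, alpha, expected):
        assert prob_positive_total(theta, power, alpha) == pytest.approx(
            expected, abs=1e-12)

    @given(theta=probs, power=probs, alpha=probs)
    @settings(max_examples=200, derandomize=True)
    def test_true_plus_false_is_total(self, theta, power, alpha):
        total = prob_positive_true(theta, power) + prob_positive_false(theta, alpha)
        assert total == pytest.approx(prob_positive_total(theta, power, alpha),
                                      abs=1e-12)

    @given(theta=probs, power=probs, alpha=probs)
    @settings(max_examples=200, derandomize=True)
    def test_bounded_by_alpha_and_power(self, theta, power, alpha):
        rate = prob_positive_total(theta, power, alpha)
        assert min(alpha, power) - 1e-12 <= rate <= max(alpha, power) + 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            prob_positive_total(1.2, 0.5, 0.05)


class TestPosterior:
    @pytest.mark.parametrize(
        "theta, power, alpha, expected, tol",
        [
            (0.894737, 1.0, 0.05, 0.9942, 1e-4),   # smallest 90%-rate prior
            (0.3, 0.8, 0.0, 1.0, 1e-12),           # no false positives
            (0.5, 0.8, 0.05, 0.4 / 0.425, 1e-12),
        ],
    )
    def test_examples(self, theta, power, alpha, expected, tol):
        assert posterior(theta, power, alpha) == pytest.approx(expected, abs=tol)

    def test_degenerate_priors(self):
        assert posterior(1.0, 0.8, 0.05) == 1.0
        assert posterior(0.0, 0.8, 0.05) == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            posterior(0.0, 0.5, 0.0)

    def test_monotone_in_each_argument(self):
        """Posterior rises with prior and power, falls with alpha."""
        thetas = np.linspace(0.05, 0.95, 20)
        powers = np.linspace(0.05, 1.0, 20)
        alphas = np.linspace(0.01, 0.5, 20)
        grid = np.array([
            [posterior(t, p, a) for a in alphas]
            for t in thetas for p in powers
        ]).reshape(20, 20, 20)
        assert (np.diff(grid, axis=2) <= 1e-12).all()      # alpha down
        grid_tp = grid.reshape(20, 20, 20)
        assert (np.diff(grid_tp, axis=0) >= -1e-12).all()  # theta up
        assert (np.diff(grid_tp, axis=1) >= -1e-12).all()  # power up

    def test_updates_upward_iff_test_informative(self):
        """A positive result raises the prior exactly when power >= alpha."""
        rng = np.random.default_rng(7)
        for _ in range(300):
            theta = rng.uniform(0.01, 0.99)
            power = rng.uniform(0.01, 1.0)
            alpha = rng.uniform(0.01, 0.5)
            up = posterior(theta, power, alpha) >= theta - 1e-12
            assert up == (power >= alpha - 1e-12)


class TestReproducibility:
    def test_worked_example_perfect_power(self):
        post = posterior(0.894737, 1.0, 0.05)
        assert reproducibility(post, 1.0, 0.05) == pytest.approx(0.9944, abs=2e-4)

    def test_certain_truth_replicates_at_power(self):
        assert reproducibility(1.0, 0.36, 0.025) == pytest.approx(0.36)

    def test_headline_scenario_consistency(self):
        assert reproducibility(0.52, 0.67, 0.025) == pytest.approx(0.3604, abs=1e-6)

    @given(post=probs, pr=probs, ar=st.floats(0.0, 0.5))
    @settings(max_examples=200, derandomize=True)
    def test_floor_from_false_positives(self, post, pr, ar):
        assert reproducibility(post, pr, ar) >= ar * (1.0 - post) - 1e-12


class TestSmallestPrior:
    @pytest.mark.parametrize(
        "rate, power, alpha, expected",
        [
            (0.90, 1.0, 0.05, 0.894737),
            (0.05, 1.0, 0.05, 0.0),
            (0.50, 1.0, 0.05, 0.473684),
        ],
    )
    def test_examples(self, rate, power, alpha, expected):
        assert smallest_prior_for_positive_rate(rate, power, alpha) == pytest.approx(
            expected, abs=1e-6)

    def test_round_trip_to_rate(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            alpha = rng.uniform(0.01, 0.2)
            power = rng.uniform(alpha + 0.05, 1.0)
            rate = rng.uniform(alpha, power)
            theta = smallest_prior_for_positive_rate(rate, power, alpha)
            assert prob_positive_total(theta, power, alpha) == pytest.approx(
                rate, abs=1e-12)

    def test_degenerate_and_unreachable(self):
        with pytest.raises(ValueError):
            smallest_prior_for_positive_rate(0.5, 0.05, 0.05)
        with pytest.raises(ValueError):
            smallest_prior_for_positive_rate(0.9, 0.5, 0.05)


class TestSolveNaive:
    def test_perfect_replication_lower_bound(self):
        res = solve_naive(0.36, 0.05, link=PowerLink.perfect())
        assert res.feasible
        assert res.power_original == pytest.approx(0.497, abs=5e-4)
        assert res.power_replication == 1.0

    def test_certain_prior_identical_link(self):
        res = solve_naive(0.36, 1.0, link=PowerLink.identical())
        assert res.power_original == pytest.approx(0.36, abs=1e-9)

    def test_against_grid_scan_oracle(self):
        """Root agrees with a brute-force scan over a fine power grid."""
        R, theta, ao, ar = 0.36, 0.1, 0.05, 0.025
        p = np.linspace(1e-6, 1.0, 1_000_001)
        post = theta * p / (theta * p + ao * (1 - theta))
        rep = post * p + ar * (1 - post)
        best = p[np.argmin(np.abs(rep - R))]
        res = solve_naive(R, theta, ao, ar, PowerLink.identical())
        assert res.power_original == pytest.approx(best, abs=2e-6)

    def test_round_trip_recovers_power(self):
        """Forward map then solve returns the generating power to 1e-6."""
        rng = np.random.default_rng(3)
        links = [PowerLink.identical(), PowerLink.perfect(),
                 PowerLink.offset(0.06), PowerLink.offset(0.10)]
        n_checked = 0
        while n_checked < 100:
            theta = rng.uniform(0.02, 0.99)
            p = rng.uniform(0.05, 0.9)
            link = links[rng.integers(len(links))]
            p_r = link.replication_power(p)
            if p_r > 1.0:
                continue
            R = reproducibility(posterior(theta, p, 0.05), p_r, 0.025)
            res = solve_naive(R, theta, 0.05, 0.025, link)
            assert res.feasible
            assert res.power_original == pytest.approx(p, abs=1e-6)
            n_checked += 1

    def test_infeasible_is_flagged_not_raised(self):
        res = solve_naive(0.99, 0.05, link=PowerLink.identical())
        assert not res.feasible
        assert math.isnan(res.power_original)
        assert "replication power" in res.reason


class TestCorrelationPower:
    def test_null_effect_gives_alpha(self):
        assert correlation_power(CorrelationPowerSpec(0.0, 54)) == pytest.approx(
            0.05, abs=1e-10)

    def test_replication_power_increment(self):
        """A median replication (df 68 vs 54) adds ~10 points at r = 0.3."""
        inc = (correlation_power(CorrelationPowerSpec(0.3, 68))
               - correlation_power(CorrelationPowerSpec(0.3, 54)))
        assert inc == pytest.approx(0.10, abs=0.02)

    def test_against_simulation_oracle(self):
        """Fisher-z power matches simulated bivariate-normal rejections."""
        nsim, n, r = 100_000, 70, 0.3
        rng = np.random.default_rng(42)
        x = rng.standard_normal((nsim, n))
        y = r * x + math.sqrt(1 - r * r) * rng.standard_normal((nsim, n))
        xc = x - x.mean(1, keepdims=True)
        yc = y - y.mean(1, keepdims=True)
        rhat = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
        t = rhat * np.sqrt((n - 2) / (1 - rhat**2))
        from scipy.stats import t as tdist
        tcrit = tdist.ppf(0.975, n - 2)
        emp = (np.abs(t) > tcrit).mean()
        assert correlation_power(CorrelationPowerSpec(r, n - 2)) == pytest.approx(
            emp, abs=0.02)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            CorrelationPowerSpec(0.3, 2)


class TestPowerLink:
    @pytest.mark.parametrize("spec, power, expected", [
        ("identical", 0.6, 0.6),
        ("perfect", 0.6, 1.0),
        ("offset:0.08", 0.6, 0.68),
    ])
    def test_parse_and_apply(self, spec, power, expected):
        link = PowerLink.parse(spec)
        assert link.replication_power(power) == pytest.approx(expected)
        assert PowerLink.parse(str(link)) == link

    def test_bad_specs_rejected(self):
        with pytest.raises(ValueError):
            PowerLink.parse("nearly")
        with pytest.raises(ValueError):
            PowerLink("identical", delta=0.1)
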