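"""Unit tests of the beta-binomial core: posterior updates, two-posterior
comparison probability, predictive mass, and the two-sample PPP."""

import numpy as np
import pytest
from scipy import integrate, stats

from ppdesigns.bayes import (
    ArmData,
    BetaPrior,
    ImproperPosteriorError,
    PosteriorBeta,
    Thresholds,
    betabinom_pmf,
    prob_exceeds,
    two_sample_ppp,
    update_posterior,
)


class TestPosteriorUpdate:
    @pytest.mark.parametrize(
        "prior, x, n, expected",
        [
            (BetaPrior(0.5, 0.5), 3, 10, (3.5, 7.5)),
            (BetaPrior(1, 1), 0, 0, (1.0, 1.0)),  # no data leaves the prior
            (BetaPrior(2, 2), 5, 5, (7.0, 2.0)),
        ],
    )
    def test_conjugate_update(self, prior, x, n, expected):
        post = update_posterior(prior, ArmData(x=x, n=n, N=max(n, 1)))
        assert (post.a, post.b) == expected

    def test_improper_posterior_raises(self):
        with pytest.raises(ImproperPosteriorError):
            update_posterior(BetaPrior(0, 0), ArmData(x=0, n=10, N=10))

    def test_negative_prior_shape_rejected(self):
        with pytest.raises(ValueError):
            BetaPrior(-0.1, 0.5)

    def test_arm_data_invariants(self):
        with pytest.raises(ValueError):
            ArmData(x=5, n=3, N=10)
        with pytest.raises(ValueError):
            ArmData(x=0, n=11, N=10)
        assert ArmData(x=2, n=8, N=20).n_star == 12

    def test_thresholds_open_interval(self):
        with pytest.raises(ValueError):
            Thresholds(1.0, 0.1)
        with pytest.raises(ValueError):
            Thresholds(0.9, 0.0)


class TestProbExceeds:
    def test_identical_posteriors_half(self):
        p = PosteriorBeta(3, 7)
        assert prob_exceeds(p, p) == pytest.approx(0.5, abs=1e-8)

    def test_analytic_two_thirds(self):
        # Pr(p1 > p2) with p1 ~ Beta(2,1) (density 2p) and p2 ~ Uniform:
        # integral of 2p * p over (0,1) = 2/3
        assert prob_exceeds(PosteriorBeta(2, 1), PosteriorBeta(1, 1)) == pytest.approx(
            2 / 3, abs=1e-8
        )

    def test_complement_symmetry(self):
        a = PosteriorBeta(4.5, 12.5)
        b = PosteriorBeta(2.5, 20.5)
        assert prob_exceeds(a, b) + prob_exceeds(b, a) == pytest.approx(1.0, abs=1e-8)

    def test_monte_carlo_oracle_half_integer_shapes(self):
        a, b = PosteriorBeta(10.5, 40.5), PosteriorBeta(5.5, 45.5)
        rng = np.random.default_rng(7)
        n = 10_000_000
        draws = rng.beta(a.a, a.b, n) > rng.beta(b.a, b.b, n)
        est = draws.mean()
        se = np.sqrt(est * (1 - est) / n)
        assert prob_exceeds(a, b) == pytest.approx(est, abs=3 * se)

    def test_improper_raises_without_regularize(self):
        with pytest.raises(ImproperPosteriorError):
            prob_exceeds(PosteriorBeta(0.0, 5.0), PosteriorBeta(1.0, 1.0))

    def test_improper_regularized_is_finite(self):
        v = prob_exceeds(
            PosteriorBeta(0.0, 5.0), PosteriorBeta(1.0, 1.0), regularize=True
        )
        assert 0.0 <= v <= 1.0


class TestBetaBinomial:
    def test_empty_future_is_certain(self):
        assert betabinom_pmf(0, 0, PosteriorBeta(3.5, 7.5)) == 1.0

    def test_uniform_predictive_mean(self):
        assert betabinom_pmf(1, 1, PosteriorBeta(1, 1)) == pytest.approx(0.5)

    def test_support_sums_to_one(self):
        post = PosteriorBeta(3.5, 7.5)
        total = sum(betabinom_pmf(k, 12, post) for k in range(13))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_k(self):
        with pytest.raises(ValueError):
            betabinom_pmf(5, 3, PosteriorBeta(1, 1))
        with pytest.raises(ValueError):
            betabinom_pmf(-1, 3, PosteriorBeta(1, 1))

    def test_numerical_integration_oracle(self):
        # integrate the binomial pmf against the beta density directly
        a, b = 3.5, 7.5
        val, _ = integrate.quad(
            lambda p: stats.binom.pmf(2, 3, p) * stats.beta.pdf(p, a, b), 0, 1
        )
        assert betabinom_pmf(2, 3, PosteriorBeta(a, b)) == pytest.approx(val, abs=1e-10)


class TestTwoSamplePpp:
    prior = BetaPrior(0.5, 0.5)

    def test_no_future_collapses_to_decision(self):
        # fully enrolled arms: PPP is exactly the 0/1 posterior decision
        up = two_sample_ppp(
            ArmData(9, 10, 10), ArmData(1, 10, 10), self.prior, theta=0.9
        )
        down = two_sample_ppp(
            ArmData(0, 10, 10), ArmData(9, 10, 10), self.prior, theta=0.9
        )
        assert up == 1.0
        assert down == 0.0

    def test_small_case_enumeration_oracle(self):
        # one future patient per arm: four joint outcomes, summed explicitly
        trt = ArmData(1, 2, 3)
        ctrl = ArmData(1, 2, 3)
        theta = 0.5
        expected = 0.0
        for y_t in (0, 1):
            w_t = betabinom_pmf(y_t, 1, update_posterior(self.prior, trt))
            for y_c in (0, 1):
                w_c = betabinom_pmf(y_c, 1, update_posterior(self.prior, ctrl))
                post_t = update_posterior(self.prior, ArmData(1 + y_t, 3, 3))
                post_c = update_posterior(self.prior, ArmData(1 + y_c, 3, 3))
                if prob_exceeds(post_t, post_c) > theta:
                    expected += w_t * w_c
        got = two_sample_ppp(trt, ctrl, self.prior, theta)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_non_increasing_in_theta(self):
        trt, ctrl = ArmData(4, 10, 20), ArmData(2, 10, 20)
        values = [
            two_sample_ppp(trt, ctrl, self.prior, th)
            for th in (0.5, 0.7, 0.9, 0.95, 0.99)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))
        assert all(0 <= v <= 1 for v in values)

    def test_improper_prior_admitted(self):
        v = two_sample_ppp(
            ArmData(0, 5, 10), ArmData(1, 5, 10), BetaPrior(0, 0), theta=0.9
        )
        assert 0.0 <= v <= 1.0
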