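"""Conjugate beta-binomial machinery for two-arm response-rate comparisons.

This module is the probabilistic core of predictive-probability futility
monitoring for randomized phase II trials with a binary response endpoint.
Each arm's true response rate ``p`` carries an independent Beta(a0, b0)
prior; observing ``x`` responses in ``n`` patients gives the conjugate
posterior ``p | x ~ Beta(a0 + x, b0 + n - x)``.  Three quantities built on
that posterior drive trial conduct:

* :func:`prob_exceeds` -- the posterior probability that the experimental
  arm's response rate exceeds the control arm's, used for the end-of-trial
  efficacy decision ``Pr(p_trt > p_ctrl | data) > theta``;
* :func:`betabinom_pmf` -- the beta-binomial posterior predictive mass of
  future responses among the ``n* = N - n`` patients yet to enroll;
* :func:`two_sample_ppp` -- the posterior predictive probability (PPP) that
  the trial, if run to full enrollment in both arms, ends in a positive
  efficacy decision.  Enrollment stops for futility when PPP drops below a
  predictive threshold ``theta_star``.

The default Beta(1/2, 1/2) prior carries the effective information of a
single patient's observation.  The improper Beta(0, 0) prior is admitted for
sensitivity analysis: any zero posterior shape encountered during evaluation
is replaced by :data:`IMPROPER_SHAPE_EPS` and the substitution is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate
from scipy import stats
from scipy.special import betainc, betaln

__all__ = [
    "IMPROPER_SHAPE_EPS",
    "ImproperPosteriorError",
    "BetaPrior",
    "PosteriorBeta",
    "ArmData",
    "Thresholds",
    "update_posterior",
    "prob_exceeds",
    "betabinom_pmf",
    "predictive_weights",
    "two_sample_ppp",
]

logger = logging.getLogger(__name__)

#: Shape substituted for a zero beta shape parameter when the improper
#: Beta(0, 0) prior meets data with zero responses or zero non-responses.
IMPROPER_SHAPE_EPS = 1e-6

_improper_warned = False


class ImproperPosteriorError(ValueError):
    """An improper beta posterior (zero shape) was used where a proper one is required."""


@dataclass(frozen=True)
class BetaPrior:
    """Beta(a0, b0) prior on a response rate.

    Both shapes must be nonnegative.  A zero shape marks an improper prior
    (the Jeffreys-like Beta(0, 0) used in sensitivity analysis); it is
    admitted but flagged via :attr:`improper`, and downstream evaluation
    regularizes zero posterior shapes with :data:`IMPROPER_SHAPE_EPS`.
    """

    a0: float = 0.5
    b0: float = 0.5

    def __post_init__(self) -> None:
        if self.a0 < 0 or self.b0 < 0 or not (
            math.isfinite(self.a0) and math.isfinite(self.b0)
        ):
            raise ValueError(f"beta prior shapes must be finite and >= 0, got {self}")

    @property
    def improper(self) -> bool:
        return self.a0 == 0 or self.b0 == 0


@dataclass(frozen=True)
class PosteriorBeta:
    """Beta(a, b) posterior of a response rate."""

    a: float
    b: float

    @property
    def proper(self) -> bool:
        return self.a > 0 and self.b > 0

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)


@dataclass(frozen=True)
class ArmData:
    """Running response data for one arm or biomarker subgroup.

    Parameters
    ----------
    x : int
        Responses observed so far.
    n : int
        Patients observed so far.
    N : int
        Maximum planned patients for this arm; ``n_star = N - n`` remain.
    """

    x: int
    n: int
    N: int

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError(f"maximum sample size must be positive, got N={self.N}")
        if not 0 <= self.x <= self.n <= self.N:
            raise ValueError(f"need 0 <= x <= n <= N, got {self}")

    @property
    def n_star(self) -> int:
        """Future patients remaining to full enrollment."""
        return self.N - self.n


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds: posterior ``theta`` and predictive ``theta_star``.

    The trial is declared positive at full enrollment when
    ``Pr(p_trt > p_ctrl | data) > theta``; it stops early for futility when
    the two-sample PPP falls below ``theta_star``.
    """

    theta: float
    theta_star: float

    def __post_init__(self) -> None:
        if not (0 < self.theta < 1 and 0 < self.theta_star < 1):
            raise ValueError(f"thresholds must lie in (0, 1), got {self}")


def update_posterior(prior: BetaPrior, arm: ArmData) -> PosteriorBeta:
    """Conjugate update ``Beta(a0 + x, b0 + n - x)``.

    Raises
    ------
    ImproperPosteriorError
        If either posterior shape is zero (possible only under an improper
        prior with all-response or no-response data).
    """
    post = PosteriorBeta(prior.a0 + arm.x, prior.b0 + arm.n - arm.x)
    if not post.proper:
        raise ImproperPosteriorError(
            f"posterior Beta({post.a:g}, {post.b:g}) from prior {prior} with "
            f"x={arm.x}, n={arm.n} is improper"
        )
    return post


def _proper_shapes(a: float, b: float) -> tuple[float, float]:
    """Regularize zero shapes (improper-prior corner cases), logging once."""
    global _improper_warned
    if a <= 0 or b <= 0:
        if not _improper_warned:
            logger.warning(
                "improper beta shape (a=%g, b=%g); substituting %g for zero "
                "shapes here and in all later occurrences",
                a, b, IMPROPER_SHAPE_EPS,
            )
            _improper_warned = True
        else:
            logger.debug("improper beta shape (a=%g, b=%g) regularized", a, b)
        a = max(a, IMPROPER_SHAPE_EPS)
        b = max(b, IMPROPER_SHAPE_EPS)
    return float(a), float(b)


@lru_cache(maxsize=None)
def _prob_exceeds(a1: float, b1: float, a2: float, b2: float) -> float:
    # Pr(p1 > p2) = E_{p2}[ Pr(p1 > u) ] = int_0^1 f(u; a2, b2) S(u; a1, b1) du.
    # Adaptive quadrature; half-integer shapes from the Beta(1/2, 1/2) prior
    # rule out the integer-shape closed form.  Absolute accuracy ~1e-10.
    if (a1, b1) == (a2, b2):
        return 0.5
    ln_b2 = betaln(a2, b2)

    def integrand(u: float) -> float:
        if u <= 0.0 or u >= 1.0:
            return 0.0
        log_f2 = (a2 - 1.0) * math.log(u) + (b2 - 1.0) * math.log1p(-u) - ln_b2
        return math.exp(log_f2) * (1.0 - betainc(a1, b1, u))

    pts = sorted({a1 / (a1 + b1), a2 / (a2 + b2)})
    val, _ = integrate.quad(
        integrand, 0.0, 1.0, epsabs=1e-11, epsrel=1e-11, limit=300, points=pts
    )
    return float(min(1.0, max(0.0, val)))


def prob_exceeds(
    post_trt: PosteriorBeta, post_ctrl: PosteriorBeta, *, regularize: bool = False
) -> float:
    """``Pr(p_trt > p_ctrl)`` for independent beta posteriors.

    Computed by adaptive quadrature of the control density against the
    treatment survival function, to absolute tolerance better than 1e-8.
    Results are memoized on the four shape parameters; caching never alters
    a returned value.

    Parameters
    ----------
    regularize : bool
        If True, zero shapes are replaced by :data:`IMPROPER_SHAPE_EPS`
        (logged) instead of raising; used for improper-prior sensitivity runs.
    """
    if not regularize and not (post_trt.proper and post_ctrl.proper):
        raise ImproperPosteriorError(
            f"improper posterior in comparison: {post_trt} vs {post_ctrl}"
        )
    a1, b1 = _proper_shapes(post_trt.a, post_trt.b)
    a2, b2 = _proper_shapes(post_ctrl.a, post_ctrl.b)
    return _prob_exceeds(a1, b1, a2, b2)


def betabinom_pmf(k: int, n_star: int, post: PosteriorBeta) -> float:
    """Beta-binomial posterior predictive mass of ``k`` responses in ``n_star`` future patients."""
    if not 0 <= k <= n_star:
        raise ValueError(f"k={k} outside the support 0..{n_star}")
    if not post.proper:
        raise ImproperPosteriorError(f"improper posterior {post}")
    if n_star == 0:
        return 1.0
    return float(stats.betabinom.pmf(k, n_star, post.a, post.b))


def predictive_weights(n_star: int, a: float, b: float) -> np.ndarray:
    """Vector of beta-binomial predictive masses over ``k = 0..n_star``.

    Zero shapes are regularized (improper-prior corner cases).
    """
    if n_star == 0:
        return np.ones(1)
    a, b = _proper_shapes(a, b)
    return stats.betabinom.pmf(np.arange(n_star + 1), n_star, a, b)


def two_sample_ppp(
    trt: ArmData, ctrl: ArmData, prior: BetaPrior, theta: float
) -> float:
    """Two-sample posterior predictive probability of end-of-trial success.

    Sums, over all joint future outcomes ``(y_t, y_c)`` with
    ``y_t = 0..n*_trt`` and ``y_c = 0..n*_ctrl``, the product of the two
    arms' independent beta-binomial predictive masses times the indicator
    that the completed-data posterior satisfies
    ``Pr(p_trt > p_ctrl | X, y) > theta``.  The enumeration is exact: under
    the model the arms are independent, so the joint predictive factorizes.

    With ``n* = 0`` in both arms the sum collapses to the single indicator
    of the final posterior decision, returning exactly 0 or 1.
    """
    if not 0 < theta < 1:
        raise ValueError(f"theta must lie in (0, 1), got {theta}")
    w_t = predictive_weights(trt.n_star, prior.a0 + trt.x, prior.b0 + trt.n - trt.x)
    w_c = predictive_weights(ctrl.n_star, prior.a0 + ctrl.x, prior.b0 + ctrl.n - ctrl.x)
    total = 0.0
    for y_t, wt in enumerate(w_t):
        x_t = trt.x + y_t
        a1, b1 = _proper_shapes(prior.a0 + x_t, prior.b0 + trt.N - x_t)
        for y_c, wc in enumerate(w_c):
            x_c = ctrl.x + y_c
            a2, b2 = _proper_shapes(prior.a0 + x_c, prior.b0 + ctrl.N - x_c)
            if _prob_exceeds(a1, b1, a2, b2) > theta:
                total += wt * wc
    return float(min(1.0, max(0.0, total)))
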