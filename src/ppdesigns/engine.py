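"""Cached evaluation of two-sample PPP over a grid of posterior thresholds.

Threshold calibration re-evaluates the same interim states millions of
times: the same (x_trt, n_trt, x_ctrl, n_ctrl) tuples recur across
replicates, across threshold-grid cells, and between the null and
alternative scenarios.  :class:`PppTable` exploits two structural facts:

1. For fixed arm maxima and prior, the end-of-trial decision quantity
   ``Pr(p_trt > p_ctrl | completed data)`` depends only on the final
   response totals -- a single (N_trt+1) x (N_ctrl+1) matrix.
2. For a fixed interim state, PPP as a function of the posterior threshold
   ``theta`` is a right-continuous step function: sorting the joint-future
   decision quantities once yields PPP at every grid theta via one
   cumulative sum and a binary search.

Caching is purely an evaluation strategy; it never changes a returned
value (asserted against :func:`ppdesigns.bayes.two_sample_ppp` in tests).
"""

from __future__ import annotations

import numpy as np

from .bayes import BetaPrior, _prob_exceeds, _proper_shapes, predictive_weights

__all__ = ["PppTable", "get_table", "clear_table_cache"]


class PppTable:
    """Two-sample PPP evaluations for fixed prior, arm maxima and theta grid.

    Parameters
    ----------
    prior : BetaPrior
        Shared prior for both arms.
    n_max_trt, n_max_ctrl : int
        Maximum planned sample sizes of the treatment and control arms.
    thetas : array-like of float
        Grid of posterior thresholds; :meth:`ppp` and :meth:`decision`
        return one value per grid entry, in order.
    """

    def __init__(self, prior: BetaPrior, n_max_trt: int, n_max_ctrl: int, thetas) -> None:
        self.prior = prior
        self.n_max_trt = int(n_max_trt)
        self.n_max_ctrl = int(n_max_ctrl)
        self.thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
        if self.thetas.ndim != 1 or not ((self.thetas > 0) & (self.thetas < 1)).all():
            raise ValueError("thetas must be a 1-D grid inside (0, 1)")
        self._final: np.ndarray | None = None
        self._ppp_cache: dict[tuple[int, int, int, int], np.ndarray] = {}

    @property
    def final_matrix(self) -> np.ndarray:
        """Matrix ``M[x_t, x_c] = Pr(p_trt > p_ctrl)`` at full enrollment."""
        if self._final is None:
            a0, b0 = self.prior.a0, self.prior.b0
            m = np.empty((self.n_max_trt + 1, self.n_max_ctrl + 1))
            for x_t in range(self.n_max_trt + 1):
                a1, b1 = _proper_shapes(a0 + x_t, b0 + self.n_max_trt - x_t)
                for x_c in range(self.n_max_ctrl + 1):
                    a2, b2 = _proper_shapes(a0 + x_c, b0 + self.n_max_ctrl - x_c)
                    m[x_t, x_c] = _prob_exceeds(a1, b1, a2, b2)
            self._final = m
        return self._final

    def decision(self, x_trt: int, x_ctrl: int) -> np.ndarray:
        """Boolean final-efficacy decision at each grid theta (strict ``>``)."""
        return self.final_matrix[x_trt, x_ctrl] > self.thetas

    def ppp(self, x_trt: int, n_trt: int, x_ctrl: int, n_ctrl: int) -> np.ndarray:
        """Two-sample PPP of the state, evaluated at every grid theta.

        Returns the cached vector; callers must not mutate it.
        """
        key = (x_trt, n_trt, x_ctrl, n_ctrl)
        out = self._ppp_cache.get(key)
        if out is not None:
            return out
        ns_t = self.n_max_trt - n_trt
        ns_c = self.n_max_ctrl - n_ctrl
        if ns_t < 0 or ns_c < 0 or x_trt > n_trt or x_ctrl > n_ctrl:
            raise ValueError(f"invalid interim state {key}")
        a0, b0 = self.prior.a0, self.prior.b0
        w_t = predictive_weights(ns_t, a0 + x_trt, b0 + n_trt - x_trt)
        w_c = predictive_weights(ns_c, a0 + x_ctrl, b0 + n_ctrl - x_ctrl)
        weights = np.outer(w_t, w_c).ravel()
        final = self.final_matrix[
            x_trt : x_trt + ns_t + 1, x_ctrl : x_ctrl + ns_c + 1
        ].ravel()
        order = np.argsort(final, kind="stable")
        cum = np.concatenate(([0.0], np.cumsum(weights[order])))
        # mass on strictly-greater decision quantities, per theta
        idx = np.searchsorted(final[order], self.thetas, side="right")
        out = np.clip(cum[-1] - cum[idx], 0.0, 1.0)
        out.flags.writeable = False
        self._ppp_cache[key] = out
        return out


_TABLES: dict[tuple, PppTable] = {}


def get_table(prior: BetaPrior, n_max_trt: int, n_max_ctrl: int, thetas) -> PppTable:
    """Shared :class:`PppTable` instances, keyed on prior, maxima and theta grid."""
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    key = (prior.a0, prior.b0, int(n_max_trt), int(n_max_ctrl), tuple(thetas))
    table = _TABLES.get(key)
    if table is None:
        table = _TABLES[key] = PppTable(prior, n_max_trt, n_max_ctrl, thetas)
    return table


def clear_table_cache() -> None:
    _TABLES.clear()
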