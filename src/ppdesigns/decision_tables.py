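"""Pre-computed stopping boundaries for trial conduct.

Once a (theta, theta*) pair is fixed, every decision of the monitoring
rule is a function of the four observable counts
(x_trt, n_trt, x_ctrl, n_ctrl) alone.  Tabulating the continuation
boundary at each look therefore removes any need for mid-trial posterior
computation: site staff can read off the minimum number of treatment-arm
responses required to continue, given the control-arm responses observed.

Looks are indexed by the treatment-arm sample size (multiples of the look
interval).  Because the concurrent control sample size at a look varies
with accrual, a boundary is tabulated for a stated control size (by
default equal to the treatment size); :func:`build_decision_table` accepts
explicit per-look control sizes to cover the realized accrual, and the
boundary for any control size reproduces the simulator's action exactly,
since both evaluate the same cached PPP values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .designs import DesignConfig
from .engine import get_table

__all__ = ["DecisionRule", "build_decision_table", "decision_table_frame"]


@dataclass(frozen=True)
class DecisionRule:
    """Continuation boundary at one interim (or final) look.

    ``min_continue[x_ctrl]`` is the minimum number of treatment-arm
    responses needed to continue past this look (final look: to declare the
    comparison positive), or ``None`` when no response count suffices.  The
    boundary is non-decreasing in the control response count.
    """

    look: int
    n_trt: int
    n_ctrl: int
    final: bool
    min_continue: tuple[int | None, ...]


def _boundary(flags: list[bool]) -> int | None:
    # PPP is non-decreasing in the treatment responses, so the continue
    # region is an upper set; return its smallest element
    for x, ok in enumerate(flags):
        if ok:
            return x
    return None


def build_decision_table(
    config: DesignConfig, control_sizes: Sequence[int] | None = None
) -> list[DecisionRule]:
    """Stopping/continuation boundaries for one two-arm comparison.

    Covers the per-subgroup treatment-versus-control comparison (looks at
    treatment n = ``look_interval``, 2x, ..., ``arm_size``); the last entry
    is the final efficacy boundary.  ``control_sizes`` fixes the control
    sample size tabulated at each look (default: equal to the treatment
    size).
    """
    theta = config.thresholds.theta
    theta_star = config.thresholds.theta_star
    table = get_table(config.prior, config.arm_size, config.arm_size, (theta,))
    look = config.look_interval
    n_looks = config.n_looks
    if control_sizes is None:
        control_sizes = [k * look for k in range(1, n_looks + 1)]
    if len(control_sizes) != n_looks:
        raise ValueError(f"need {n_looks} control sizes, got {len(control_sizes)}")
    rules: list[DecisionRule] = []
    for k in range(1, n_looks + 1):
        n_t = k * look
        n_c = int(control_sizes[k - 1])
        final = k == n_looks
        boundary = []
        for x_c in range(n_c + 1):
            if final:
                flags = [
                    table.ppp(x_t, n_t, x_c, n_c)[0] > theta for x_t in range(n_t + 1)
                ]
            else:
                flags = [
                    table.ppp(x_t, n_t, x_c, n_c)[0] >= theta_star
                    for x_t in range(n_t + 1)
                ]
            boundary.append(_boundary(flags))
        rules.append(
            DecisionRule(
                look=k, n_trt=n_t, n_ctrl=n_c, final=final, min_continue=tuple(boundary)
            )
        )
    return rules


def decision_table_frame(rule: DecisionRule) -> pd.DataFrame:
    """One look's boundary as a two-column frame (CSV-friendly; -1 = never)."""
    return pd.DataFrame(
        {
            "control_responses": range(rule.n_ctrl + 1),
            "min_treatment_responses_to_continue": [
                -1 if v is None else v for v in rule.min_continue
            ],
        }
    )
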