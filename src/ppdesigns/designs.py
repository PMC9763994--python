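"""Simulation of biomarker-guided randomized phase II trial designs.

Three design topologies share the same Bayesian monitoring engine:

* **Pooled control arm** -- patients are randomized 3:1 to experimental
  treatment versus control; only treated patients are biomarker-typed, and
  the three biomarker-specific treatment arms (IC0, IC1, IC2/3; 50 patients
  each) are each compared against the single shared 50-patient control arm.
  Maximum enrollment 200.
* **Stratified control arm** -- all patients are biomarker-typed and then
  randomized 1:1 within subgroup, giving three independent 50 + 50
  comparisons.  Maximum enrollment 300.
* **Two-stage enrichment** -- stage 1 is the pooled design; at its end the
  subgroup with the highest posterior predictive probability, subject to a
  null-calibrated lower bound, advances to stage 2, where 100 further
  patients of that subgroup alone are randomized 1:1 and the stage-1
  treatment data are carried forward.  Maximum enrollment 300.

Accrual and monitoring
----------------------
Patients accrue individually in a uniformly random enrollment order of the
full planned pool, which realizes the randomization ratios and the equal
subgroup split exactly (block randomization over the whole trial).  A
subgroup is evaluated each time its treatment arm reaches a multiple of
``look_interval`` (default 10) patients, against the control data
accumulated at that moment.  Interim evaluations apply the futility rule
(stop the subgroup if its two-sample PPP drops below ``theta_star``); the
evaluation at full treatment-arm enrollment is the final analysis, declaring
the subgroup positive when its PPP exceeds ``theta``.  Because the control
arm finishes enrolling last, the final evaluation is a genuine predictive
probability over the control arm's few outstanding patients.  The pooled
control arm stops when every subgroup has stopped or completed.

A consequence of exchangeable accrual is that a subgroup's look states
(its responses, and the concurrent control data) do not depend on when
*other* subgroups stop; look states can therefore be precomputed once per
simulated trial and replayed under any threshold pair (common random
numbers across calibration grids).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bayes import BetaPrior, Thresholds
from .engine import PppTable, get_table

__all__ = [
    "SUBGROUPS",
    "Scenario",
    "null_scenario",
    "alternative_scenario",
    "homogeneous_scenario",
    "DesignConfig",
    "TrialResult",
    "simulate_pooled_trial",
    "simulate_stratified_trial",
    "calibrate_stage1_bound",
    "simulate_enrichment_trial",
    "simulate_trials",
    "results_to_frame",
]

#: Biomarker subgroups by PD-L1-expressing immune-cell percentage:
#: IC0 (<1%), IC1 (1-5%), IC2/3 (>=5%).
SUBGROUPS = ("IC0", "IC1", "IC2/3")

DECISION_POSITIVE = "positive"
DECISION_NEGATIVE = "negative"
DECISION_STOPPED = "stopped_futility"

_DESIGN_KINDS = ("pooled", "stratified", "enrichment")


def _per_subgroup(value, name: str) -> tuple[float, float, float]:
    if isinstance(value, Mapping):
        try:
            vals = tuple(float(value[g]) for g in SUBGROUPS)
        except KeyError as exc:
            raise ValueError(f"{name} mapping must have keys {SUBGROUPS}") from exc
    elif np.isscalar(value):
        vals = (float(value),) * 3
    else:
        vals = tuple(float(v) for v in value)
        if len(vals) != 3:
            raise ValueError(f"{name} needs one value per subgroup {SUBGROUPS}")
    if not all(0 <= v <= 1 for v in vals):
        raise ValueError(f"{name} must lie in [0, 1], got {vals}")
    return vals


@dataclass(frozen=True)
class Scenario:
    """True response probabilities per subgroup and arm.

    ``p_ctrl`` and ``p_trt`` may be given as a scalar, a sequence ordered as
    :data:`SUBGROUPS`, or a mapping keyed by subgroup label.  ``prevalence``
    gives the subgroup mix in the screened population and must sum to 1.
    """

    p_ctrl: tuple[float, float, float]
    p_trt: tuple[float, float, float]
    prevalence: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __init__(self, p_ctrl, p_trt, prevalence=(1 / 3, 1 / 3, 1 / 3)):
        object.__setattr__(self, "p_ctrl", _per_subgroup(p_ctrl, "p_ctrl"))
        object.__setattr__(self, "p_trt", _per_subgroup(p_trt, "p_trt"))
        prev = _per_subgroup(prevalence, "prevalence")
        if abs(sum(prev) - 1.0) > 1e-9:
            raise ValueError(f"prevalences must sum to 1, got {prev}")
        object.__setattr__(self, "prevalence", prev)

    @property
    def pooled_control_rate(self) -> float:
        """Control response rate of a biomarker-unselected (pooled) control arm."""
        return float(np.dot(self.prevalence, self.p_ctrl))


def null_scenario(rate: float = 0.1) -> Scenario:
    """Global null: every arm at the historical control rate (10%)."""
    return Scenario(rate, rate)


def alternative_scenario() -> Scenario:
    """Predictive-biomarker alternative: control 10%, treatment 10/20/30%."""
    return Scenario(0.1, (0.1, 0.2, 0.3))


def homogeneous_scenario(rate: float = 0.3) -> Scenario:
    """Homogeneous treatment effect: control 10%, treatment ``rate`` everywhere."""
    return Scenario(0.1, rate)


@dataclass(frozen=True)
class DesignConfig:
    """Full specification of one design.

    ``arm_size`` is the per-arm (per-subgroup) stage-1 maximum;
    ``stage2_per_arm`` applies to the enrichment design only, as do
    ``stage1_bound_percentile`` (quantile of the per-trial maximum subgroup
    PPP under the null used as the stage-1 advancement bound) and the
    carried-forward stage-1 treatment data.  ``n_sim`` is the default
    replicate count for calibration runs.
    """

    kind: str
    thresholds: Thresholds
    prior: BetaPrior = BetaPrior()
    arm_size: int = 50
    look_interval: int = 10
    stage2_per_arm: int = 50
    stage1_bound_percentile: float = 0.8
    n_sim: int = 1000

    def __post_init__(self) -> None:
        if self.kind not in _DESIGN_KINDS:
            raise ValueError(f"kind must be one of {_DESIGN_KINDS}, got {self.kind!r}")
        for name in ("arm_size", "stage2_per_arm"):
            size = getattr(self, name)
            if size <= 0 or size % self.look_interval:
                raise ValueError(
                    f"{name}={size} must be a positive multiple of "
                    f"look_interval={self.look_interval}"
                )
        if not 0 < self.stage1_bound_percentile < 1:
            raise ValueError("stage1_bound_percentile must lie in (0, 1)")
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")

    @property
    def n_looks(self) -> int:
        """Evaluations per subgroup in stage 1; the last is the final analysis."""
        return self.arm_size // self.look_interval

    @property
    def n_looks_stage2(self) -> int:
        return self.stage2_per_arm // self.look_interval

    @property
    def max_total(self) -> int:
        if self.kind == "pooled":
            return 4 * self.arm_size
        if self.kind == "stratified":
            return 6 * self.arm_size
        return 4 * self.arm_size + 2 * self.stage2_per_arm


@dataclass
class TrialResult:
    """Outcome of one simulated trial.

    ``decisions`` maps each subgroup to ``positive``, ``negative`` or
    ``stopped_futility`` (for the enrichment design, non-selected subgroups
    that completed stage 1 are ``negative``).  ``enrolled`` maps arm labels
    to patient counts; pooled/enrichment stage 1 use a single ``control``
    arm, the stratified design one ``control:<subgroup>`` per subgroup, and
    the enrichment design adds ``stage2:treatment`` / ``stage2:control``.
    """

    design: str
    decisions: dict[str, str]
    enrolled: dict[str, int]
    total_enrolled: int
    total_treatment: int
    total_biomarker_tested: float
    selected_subgroup: str | None = None
    stage_reached: int = 1
    final_ppp: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# data generation: per-replicate look states under patient-level accrual
# ---------------------------------------------------------------------------
# For each subgroup and look k (treatment n = (k+1)*look_interval) we store
# the treatment responses and the concurrent control sample size and
# responses.  These states are invariant to the stopping decisions of other
# subgroups, so one draw serves every threshold combination.


@dataclass
class ComparisonStates:
    """Look states of two-arm comparisons: arrays indexed (rep, subgroup, look)."""

    x_trt: np.ndarray  # treatment responses at the look
    n_ctrl: np.ndarray  # concurrent control sample size
    x_ctrl: np.ndarray  # concurrent control responses


@dataclass
class PooledData:
    states: ComparisonStates  # (n_sim, 3, K); shared control per replicate


@dataclass
class StratifiedData:
    states: ComparisonStates  # (n_sim, 3, K); per-subgroup control


@dataclass
class EnrichmentData:
    stage1: PooledData
    stage2: ComparisonStates  # (n_sim, 3, K2); fresh 1:1 pair per candidate subgroup


def _scan_pooled(rng: np.random.Generator, rates: np.ndarray, arm_size: int,
                 look: int, n_looks: int) -> np.ndarray:
    """One pooled trial's look states; returns (3, K, 3) of (x_t, n_c, x_c)."""
    labels = np.repeat(np.arange(4), arm_size)  # 0 = control, 1..3 = subgroups
    lab = labels[rng.permutation(labels.size)]
    resp = rng.random(labels.size) < rates[lab]
    out = np.zeros((3, n_looks, 3), dtype=np.int64)
    nn = [0, 0, 0, 0]
    xx = [0, 0, 0, 0]
    for a, y in zip(lab, resp):
        nn[a] += 1
        xx[a] += y
        if a > 0 and nn[a] % look == 0:
            out[a - 1, nn[a] // look - 1] = (xx[a], nn[0], xx[0])
    return out


def _scan_pair(rng: np.random.Generator, p_trt: float, p_ctrl: float,
               arm_size: int, look: int, n_looks: int) -> np.ndarray:
    """One 1:1 two-arm comparison's look states; returns (K, 3)."""
    labels = np.repeat(np.array([0, 1]), arm_size)  # 0 = control, 1 = treatment
    lab = labels[rng.permutation(labels.size)]
    resp = rng.random(labels.size) < np.where(lab == 1, p_trt, p_ctrl)
    out = np.zeros((n_looks, 3), dtype=np.int64)
    nn = [0, 0]
    xx = [0, 0]
    for a, y in zip(lab, resp):
        nn[a] += 1
        xx[a] += y
        if a == 1 and nn[1] % look == 0:
            out[nn[1] // look - 1] = (xx[1], nn[0], xx[0])
    return out


def draw_pooled_data(
    scenario: Scenario, n_sim: int, rng: np.random.Generator, config: DesignConfig
) -> PooledData:
    k, look = config.n_looks, config.look_interval
    rates = np.array([scenario.pooled_control_rate, *scenario.p_trt])
    st = np.zeros((n_sim, 3, k, 3), dtype=np.int64)
    for r in range(n_sim):
        st[r] = _scan_pooled(rng, rates, config.arm_size, look, k)
    return PooledData(ComparisonStates(st[..., 0], st[..., 1], st[..., 2]))


def draw_stratified_data(
    scenario: Scenario, n_sim: int, rng: np.random.Generator, config: DesignConfig
) -> StratifiedData:
    k, look = config.n_looks, config.look_interval
    st = np.zeros((n_sim, 3, k, 3), dtype=np.int64)
    for r in range(n_sim):
        for g in range(3):
            st[r, g] = _scan_pair(
                rng, scenario.p_trt[g], scenario.p_ctrl[g], config.arm_size, look, k
            )
    return StratifiedData(ComparisonStates(st[..., 0], st[..., 1], st[..., 2]))


def draw_enrichment_data(
    scenario: Scenario, n_sim: int, rng: np.random.Generator, config: DesignConfig
) -> EnrichmentData:
    stage1 = draw_pooled_data(scenario, n_sim, rng, config)
    k2, look = config.n_looks_stage2, config.look_interval
    st2 = np.zeros((n_sim, 3, k2, 3), dtype=np.int64)
    for r in range(n_sim):
        for g in range(3):
            st2[r, g] = _scan_pair(
                rng, scenario.p_trt[g], scenario.p_ctrl[g], config.stage2_per_arm, look, k2
            )
    return EnrichmentData(
        stage1, ComparisonStates(st2[..., 0], st2[..., 1], st2[..., 2])
    )


# ---------------------------------------------------------------------------
# trial replay for one (theta, theta_star) cell
# ---------------------------------------------------------------------------


def _compare_path(
    x_trt: np.ndarray,
    n_ctrl: np.ndarray,
    x_ctrl: np.ndarray,
    table: PppTable,
    ti: int,
    theta_star: float,
    look: int,
    n_looks: int,
    trt_offset: int = 0,
    x_offset: int = 0,
):
    """Run one comparison through its look schedule.

    Interim looks (all but the last) stop the comparison when PPP falls
    below ``theta_star``; the last look is the final analysis, positive when
    its PPP exceeds the posterior threshold indexed by ``ti``.  Returns
    ``(n_trt, n_ctrl, stopped, positive, terminal_ppp)``.  ``trt_offset`` /
    ``x_offset`` shift the treatment sample size and responses (carried
    stage-1 data in the enrichment design).
    """
    theta = table.thetas[ti]
    for k in range(n_looks - 1):
        v = table.ppp(
            x_offset + int(x_trt[k]),
            trt_offset + (k + 1) * look,
            int(x_ctrl[k]),
            int(n_ctrl[k]),
        )[ti]
        if v < theta_star:
            return trt_offset + (k + 1) * look, int(n_ctrl[k]), True, False, v
    k = n_looks - 1
    v = table.ppp(
        x_offset + int(x_trt[k]),
        trt_offset + (k + 1) * look,
        int(x_ctrl[k]),
        int(n_ctrl[k]),
    )[ti]
    return trt_offset + (k + 1) * look, int(n_ctrl[k]), False, bool(v > theta), v


@dataclass
class PooledCellResult:
    positive: np.ndarray  # (n_sim, 3) bool
    stopped: np.ndarray  # (n_sim, 3) bool
    enrolled: np.ndarray  # (n_sim, 3) treatment-arm patients
    ctrl_enrolled: np.ndarray  # (n_sim,) shared control patients
    terminal_ppp: np.ndarray  # (n_sim, 3) PPP at the stopping or final look
    x_final: np.ndarray  # (n_sim, 3) responses at full treatment enrollment

    @property
    def total_enrolled(self) -> np.ndarray:
        return self.ctrl_enrolled + self.enrolled.sum(axis=1)

    @property
    def total_treatment(self) -> np.ndarray:
        return self.enrolled.sum(axis=1)


def replay_pooled_cell(
    data: PooledData, table: PppTable, ti: int, theta_star: float, config: DesignConfig
) -> PooledCellResult:
    st = data.states
    n_sim = st.x_trt.shape[0]
    look, n_looks = config.look_interval, config.n_looks
    positive = np.zeros((n_sim, 3), dtype=bool)
    stopped = np.zeros((n_sim, 3), dtype=bool)
    enrolled = np.zeros((n_sim, 3), dtype=np.int64)
    term_nc = np.zeros((n_sim, 3), dtype=np.int64)
    terminal = np.full((n_sim, 3), np.nan)
    for r in range(n_sim):
        for g in range(3):
            e, nc, s, p, v = _compare_path(
                st.x_trt[r, g], st.n_ctrl[r, g], st.x_ctrl[r, g],
                table, ti, theta_star, look, n_looks,
            )
            enrolled[r, g] = e
            term_nc[r, g] = nc
            stopped[r, g] = s
            positive[r, g] = p
            terminal[r, g] = v
    # the shared control stops at the last subgroup's terminal look
    ctrl_enrolled = term_nc.max(axis=1)
    return PooledCellResult(
        positive, stopped, enrolled, ctrl_enrolled, terminal, st.x_trt[:, :, -1]
    )


@dataclass
class StratifiedCellResult:
    positive: np.ndarray
    stopped: np.ndarray
    enrolled: np.ndarray  # (n_sim, 3) treatment arms
    ctrl_enrolled: np.ndarray  # (n_sim, 3) control arms (stop with their subgroup)

    @property
    def total_enrolled(self) -> np.ndarray:
        return self.enrolled.sum(axis=1) + self.ctrl_enrolled.sum(axis=1)

    @property
    def total_treatment(self) -> np.ndarray:
        return self.enrolled.sum(axis=1)


def replay_stratified_cell(
    data: StratifiedData, table: PppTable, ti: int, theta_star: float, config: DesignConfig
) -> StratifiedCellResult:
    st = data.states
    n_sim = st.x_trt.shape[0]
    look, n_looks = config.look_interval, config.n_looks
    positive = np.zeros((n_sim, 3), dtype=bool)
    stopped = np.zeros((n_sim, 3), dtype=bool)
    enrolled = np.zeros((n_sim, 3), dtype=np.int64)
    ctrl_enr = np.zeros((n_sim, 3), dtype=np.int64)
    for r in range(n_sim):
        for g in range(3):
            e, nc, s, p, _ = _compare_path(
                st.x_trt[r, g], st.n_ctrl[r, g], st.x_ctrl[r, g],
                table, ti, theta_star, look, n_looks,
            )
            enrolled[r, g] = e
            ctrl_enr[r, g] = nc
            stopped[r, g] = s
            positive[r, g] = p
    return StratifiedCellResult(positive, stopped, enrolled, ctrl_enr)


# ---------------------------------------------------------------------------
# enrichment design
# ---------------------------------------------------------------------------


def stage1_bound_from_maxima(terminal_ppp: np.ndarray, percentile: float) -> float:
    """Quantile of the per-replicate maximum subgroup terminal PPP."""
    return float(np.quantile(terminal_ppp.max(axis=1), percentile))


def _select(vals_row: np.ndarray) -> int:
    # ties broken toward the highest-expression subgroup (IC2/3 over IC1
    # over IC0), mirroring the fixed-sequence testing order of the
    # motivating trial
    return int(vals_row.size - 1 - np.argmax(vals_row[::-1]))


@dataclass
class EnrichmentCellResult:
    stage1: PooledCellResult
    selected: np.ndarray  # (n_sim,) subgroup index with the maximum terminal PPP
    advanced: np.ndarray  # (n_sim,) bool
    positive: np.ndarray  # (n_sim,) bool, end-of-stage-2 decision
    stage2_trt: np.ndarray  # (n_sim,) stage-2 treatment patients
    stage2_ctrl: np.ndarray  # (n_sim,) stage-2 control patients
    bound: float

    @property
    def stage2_enrolled(self) -> np.ndarray:
        return self.stage2_trt + self.stage2_ctrl

    @property
    def total_enrolled(self) -> np.ndarray:
        return self.stage1.total_enrolled + self.stage2_enrolled

    @property
    def total_treatment(self) -> np.ndarray:
        return self.stage1.total_treatment + self.stage2_trt


def replay_enrichment_cell(
    data: EnrichmentData,
    table1: PppTable,
    table2: PppTable,
    ti: int,
    theta_star: float,
    config: DesignConfig,
    bound: float,
) -> EnrichmentCellResult:
    """Replay full two-stage trials given a precomputed stage-1 bound.

    The subgroup with the maximum terminal stage-1 PPP advances iff it did
    not stop for futility and its PPP is at least ``bound``.  Stage 2 then
    monitors the selected subgroup's fresh 1:1 comparison, with the stage-1
    treatment data carried forward into the treatment posterior (planned
    treatment maximum ``arm_size + stage2_per_arm``; the stage-1 pooled
    control, a biomarker-unselected mixture, is not reused).
    """
    if not 0 <= bound <= 1:
        raise ValueError(f"stage-1 bound must lie in [0, 1], got {bound}")
    pool = replay_pooled_cell(data.stage1, table1, ti, theta_star, config)
    n_sim = pool.positive.shape[0]
    look, k2 = config.look_interval, config.n_looks_stage2
    selected = np.zeros(n_sim, dtype=np.int64)
    advanced = np.zeros(n_sim, dtype=bool)
    positive = np.zeros(n_sim, dtype=bool)
    s2_trt = np.zeros(n_sim, dtype=np.int64)
    s2_ctrl = np.zeros(n_sim, dtype=np.int64)
    st2 = data.stage2
    for r in range(n_sim):
        g = _select(pool.terminal_ppp[r])
        selected[r] = g
        if pool.stopped[r, g] or pool.terminal_ppp[r, g] < bound:
            continue
        advanced[r] = True
        e, nc, s, p, _ = _compare_path(
            st2.x_trt[r, g], st2.n_ctrl[r, g], st2.x_ctrl[r, g],
            table2, ti, theta_star, look, k2,
            trt_offset=config.arm_size, x_offset=int(pool.x_final[r, g]),
        )
        s2_trt[r] = e - config.arm_size
        s2_ctrl[r] = nc
        positive[r] = p
    return EnrichmentCellResult(
        pool, selected, advanced, positive, s2_trt, s2_ctrl, bound
    )


# ---------------------------------------------------------------------------
# public single-trial / batch API
# ---------------------------------------------------------------------------


def _as_rng(rng_stream) -> np.random.Generator:
    return (
        rng_stream
        if isinstance(rng_stream, np.random.Generator)
        else np.random.default_rng(rng_stream)
    )


def _tables(config: DesignConfig) -> tuple[PppTable, PppTable | None]:
    thetas = (config.thresholds.theta,)
    t1 = get_table(config.prior, config.arm_size, config.arm_size, thetas)
    t2 = None
    if config.kind == "enrichment":
        t2 = get_table(
            config.prior,
            config.arm_size + config.stage2_per_arm,
            config.stage2_per_arm,
            thetas,
        )
    return t1, t2


def _decision_label(positive: bool, stopped: bool) -> str:
    if stopped:
        return DECISION_STOPPED
    return DECISION_POSITIVE if positive else DECISION_NEGATIVE


def simulate_pooled_trial(
    config: DesignConfig, scenario: Scenario, rng_stream
) -> TrialResult:
    """Simulate one pooled-control-arm trial."""
    if config.kind != "pooled":
        raise ValueError(f"expected a pooled config, got kind={config.kind!r}")
    rng = _as_rng(rng_stream)
    table, _ = _tables(config)
    data = draw_pooled_data(scenario, 1, rng, config)
    res = replay_pooled_cell(data, table, 0, config.thresholds.theta_star, config)
    enrolled = {"control": int(res.ctrl_enrolled[0])}
    enrolled.update({g: int(res.enrolled[0, i]) for i, g in enumerate(SUBGROUPS)})
    return TrialResult(
        design="pooled",
        decisions={
            g: _decision_label(res.positive[0, i], res.stopped[0, i])
            for i, g in enumerate(SUBGROUPS)
        },
        enrolled=enrolled,
        total_enrolled=int(res.total_enrolled[0]),
        total_treatment=int(res.total_treatment[0]),
        total_biomarker_tested=float(res.total_treatment[0]),
        final_ppp={g: float(res.terminal_ppp[0, i]) for i, g in enumerate(SUBGROUPS)},
    )


def simulate_stratified_trial(
    config: DesignConfig, scenario: Scenario, rng_stream
) -> TrialResult:
    """Simulate one stratified-control-arm trial."""
    if config.kind != "stratified":
        raise ValueError(f"expected a stratified config, got kind={config.kind!r}")
    rng = _as_rng(rng_stream)
    table, _ = _tables(config)
    data = draw_stratified_data(scenario, 1, rng, config)
    res = replay_stratified_cell(data, table, 0, config.thresholds.theta_star, config)
    enrolled: dict[str, int] = {}
    for i, g in enumerate(SUBGROUPS):
        enrolled[g] = int(res.enrolled[0, i])
        enrolled[f"control:{g}"] = int(res.ctrl_enrolled[0, i])
    return TrialResult(
        design="stratified",
        decisions={
            g: _decision_label(res.positive[0, i], res.stopped[0, i])
            for i, g in enumerate(SUBGROUPS)
        },
        enrolled=enrolled,
        total_enrolled=int(res.total_enrolled[0]),
        total_treatment=int(res.total_treatment[0]),
        total_biomarker_tested=float(res.total_enrolled[0]),
    )


def calibrate_stage1_bound(
    config: DesignConfig, null_scenario: Scenario, rng_stream
) -> float:
    """Null-calibrated stage-1 advancement bound for the enrichment design.

    Runs ``config.n_sim`` stage-1 (pooled) simulations under the global
    null and returns the ``stage1_bound_percentile`` quantile of the
    per-replicate maximum subgroup terminal PPP (stopped subgroups
    contribute the PPP at their stopping look).
    """
    if config.kind != "enrichment":
        raise ValueError(f"expected an enrichment config, got kind={config.kind!r}")
    rng = _as_rng(rng_stream)
    table1, _ = _tables(config)
    data = draw_pooled_data(null_scenario, config.n_sim, rng, config)
    pool = replay_pooled_cell(data, table1, 0, config.thresholds.theta_star, config)
    return stage1_bound_from_maxima(pool.terminal_ppp, config.stage1_bound_percentile)


def simulate_enrichment_trial(
    config: DesignConfig, scenario: Scenario, bound: float, rng_stream
) -> TrialResult:
    """Simulate one two-stage enrichment trial with a precomputed stage-1 bound."""
    if config.kind != "enrichment":
        raise ValueError(f"expected an enrichment config, got kind={config.kind!r}")
    rng = _as_rng(rng_stream)
    table1, table2 = _tables(config)
    data = draw_enrichment_data(scenario, 1, rng, config)
    res = replay_enrichment_cell(
        data, table1, table2, 0, config.thresholds.theta_star, config, bound
    )
    pool = res.stage1
    advanced = bool(res.advanced[0])
    sel = int(res.selected[0]) if advanced else None
    decisions = {}
    for i, g in enumerate(SUBGROUPS):
        if advanced and i == sel:
            s2_stopped = res.stage2_trt[0] < config.stage2_per_arm
            if s2_stopped:
                decisions[g] = DECISION_STOPPED
            else:
                decisions[g] = DECISION_POSITIVE if res.positive[0] else DECISION_NEGATIVE
        else:
            decisions[g] = _decision_label(False, pool.stopped[0, i])
    enrolled = {"control": int(pool.ctrl_enrolled[0])}
    enrolled.update({g: int(pool.enrolled[0, i]) for i, g in enumerate(SUBGROUPS)})
    if advanced:
        enrolled["stage2:treatment"] = int(res.stage2_trt[0])
        enrolled["stage2:control"] = int(res.stage2_ctrl[0])
    # stage 1 tests only treated patients; stage 2 screens all comers, of
    # whom a `prevalence` fraction belongs to the selected subgroup
    # (reported analytically rather than simulated patient by patient)
    tested = float(pool.total_treatment[0])
    if advanced:
        tested += float(res.stage2_enrolled[0]) / scenario.prevalence[sel]
    return TrialResult(
        design="enrichment",
        decisions=decisions,
        enrolled=enrolled,
        total_enrolled=int(res.total_enrolled[0]),
        total_treatment=int(res.total_treatment[0]),
        total_biomarker_tested=tested,
        selected_subgroup=SUBGROUPS[sel] if advanced else None,
        stage_reached=2 if advanced else 1,
        final_ppp={g: float(pool.terminal_ppp[0, i]) for i, g in enumerate(SUBGROUPS)},
    )


def simulate_trials(
    config: DesignConfig,
    scenario: Scenario,
    rng_stream,
    n_sim: int | None = None,
    bound: float | None = None,
) -> list[TrialResult]:
    """Simulate ``n_sim`` independent trials (default ``config.n_sim``).

    For the enrichment design the stage-1 bound is calibrated first, from
    the same generator, when not supplied.
    """
    rng = _as_rng(rng_stream)
    n = config.n_sim if n_sim is None else int(n_sim)
    sims: list[TrialResult] = []
    if config.kind == "enrichment" and bound is None:
        null = null_scenario(scenario.pooled_control_rate)
        bound = calibrate_stage1_bound(config, null, rng)
    for _ in range(n):
        if config.kind == "pooled":
            sims.append(simulate_pooled_trial(config, scenario, rng))
        elif config.kind == "stratified":
            sims.append(simulate_stratified_trial(config, scenario, rng))
        else:
            sims.append(simulate_enrichment_trial(config, scenario, bound, rng))
    return sims


def results_to_frame(
    results: Sequence[TrialResult], scenario_label: str = ""
) -> pd.DataFrame:
    """Tidy frame: one row per replicate per subgroup (stable column schema)."""
    rows = []
    for r, res in enumerate(results):
        for g in SUBGROUPS:
            rows.append(
                {
                    "design": res.design,
                    "scenario": scenario_label,
                    "replicate": r,
                    "subgroup": g,
                    "decision": res.decisions[g],
                    "enrolled_treatment": res.enrolled.get(g, 0),
                    "enrolled_control": res.enrolled.get(
                        f"control:{g}", res.enrolled.get("control", 0)
                    ),
                    "selected_subgroup": res.selected_subgroup or "",
                    "stage_reached": res.stage_reached,
                    "total_enrolled": res.total_enrolled,
                    "total_treatment": res.total_treatment,
                    "total_biomarker_tested": res.total_biomarker_tested,
                }
            )
    return pd.DataFrame(rows)
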