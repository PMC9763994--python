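"""Operating characteristics over the (theta, theta*) grid and design selection.

For each combination of posterior threshold ``theta`` and predictive
threshold ``theta_star``, :func:`estimate_oc` estimates by simulation the
per-subgroup type I error and power, and the average sample sizes under the
null and alternative scenarios.  The same simulated response streams are
reused across all grid cells (common random numbers): a replicate is a set
of cumulative block response counts, and the (theta, theta*)-specific trial
path is replayed from cached PPP evaluations, which leaves the estimates
distributionally identical to independent per-cell simulation while
reducing the computation by orders of magnitude.

Candidate designs are then filtered to a type I error between 0.05 and 0.1
and power of at least 0.8 (:func:`filter_acceptable`; type I error is
calibrated in the IC0 subgroup under the null, power in the IC2/3 subgroup
under the alternative, and for the enrichment design on the stage-2 results
among advancing replicates).  Among acceptable designs,
:func:`select_optimal_efficiency` picks the one closest to the corner of
minimal average sample size under the null and maximal average sample size
under the alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bayes import BetaPrior
from .designs import (
    SUBGROUPS,
    DesignConfig,
    Scenario,
    draw_enrichment_data,
    draw_pooled_data,
    draw_stratified_data,
    replay_enrichment_cell,
    replay_pooled_cell,
    replay_stratified_cell,
    stage1_bound_from_maxima,
)
from .engine import get_table

__all__ = [
    "ThresholdGrid",
    "OCRecord",
    "estimate_oc",
    "filter_acceptable",
    "select_optimal_efficiency",
    "annotate_distances",
    "oc_table",
]

logger = logging.getLogger(__name__)

#: The candidate posterior thresholds of the case study (14 values).
DEFAULT_POSTERIOR_THRESHOLDS = (
    0.7, 0.74, 0.78, 0.82, 0.86, 0.9, 0.92, 0.93, 0.94, 0.95, 0.96, 0.97, 0.98, 0.99,
)
#: The candidate predictive thresholds of the case study (4 values).
DEFAULT_PREDICTIVE_THRESHOLDS = (0.05, 0.1, 0.15, 0.2)


@dataclass(frozen=True)
class ThresholdGrid:
    """Grid of candidate posterior x predictive thresholds (default 14 x 4)."""

    posterior_thresholds: tuple[float, ...] = DEFAULT_POSTERIOR_THRESHOLDS
    predictive_thresholds: tuple[float, ...] = DEFAULT_PREDICTIVE_THRESHOLDS

    def __post_init__(self) -> None:
        for vals in (self.posterior_thresholds, self.predictive_thresholds):
            if not vals or not all(0 < v < 1 for v in vals):
                raise ValueError("thresholds must be non-empty and lie in (0, 1)")

    @property
    def n_cells(self) -> int:
        return len(self.posterior_thresholds) * len(self.predictive_thresholds)


@dataclass
class OCRecord:
    """Estimated operating characteristics of one (theta, theta*) design.

    ``type1`` and ``power`` are per-subgroup positive proportions for the
    pooled/stratified designs; for the enrichment design they are overall
    proportions split by stage, with the stage-2 entries computed among the
    replicates that advanced (``n_advance_null`` / ``n_advance_alt``
    record those denominators, and ``power["stage2_unconditional"]`` the
    positives out of all replicates).
    """

    design: str
    theta: float
    theta_star: float
    type1: dict[str, float]
    power: dict[str, float]
    avg_n_null: float
    avg_n_alt: float
    avg_n_trt_null: float
    avg_n_trt_alt: float
    arm_means_null: dict[str, float] = field(default_factory=dict)
    arm_means_alt: dict[str, float] = field(default_factory=dict)
    # enrichment bookkeeping
    bound: float | None = None
    advance_null: dict[str, float] | None = None
    advance_alt: dict[str, float] | None = None
    n_advance_null: int | None = None
    n_advance_alt: int | None = None
    distance: float | None = None
    optimal: bool = False

    @property
    def calibration_type1(self) -> float | None:
        """Type I error used for constraint filtering (IC0 null; enrichment: stage 2)."""
        if self.design == "enrichment":
            return self.type1.get("stage2")
        return self.type1["IC0"]

    @property
    def calibration_power(self) -> float | None:
        """Power used for constraint filtering (IC2/3 alternative; enrichment: stage 2)."""
        if self.design == "enrichment":
            return self.power.get("stage2")
        return self.power["IC2/3"]


def _pooled_like_records(
    design: str, config: DesignConfig, grid, data_null, data_alt, replay, table
) -> list[OCRecord]:
    records = []
    for ti, theta in enumerate(grid.posterior_thresholds):
        for ts in grid.predictive_thresholds:
            res_null = replay(data_null, table, ti, ts, config)
            res_alt = replay(data_alt, table, ti, ts, config)
            type1 = {g: float(res_null.positive[:, i].mean()) for i, g in enumerate(SUBGROUPS)}
            power = {g: float(res_alt.positive[:, i].mean()) for i, g in enumerate(SUBGROUPS)}
            arm_null = {g: float(res_null.enrolled[:, i].mean()) for i, g in enumerate(SUBGROUPS)}
            arm_alt = {g: float(res_alt.enrolled[:, i].mean()) for i, g in enumerate(SUBGROUPS)}
            if design == "pooled":
                arm_null["control"] = float(res_null.ctrl_enrolled.mean())
                arm_alt["control"] = float(res_alt.ctrl_enrolled.mean())
            else:
                arm_null["control"] = float(res_null.ctrl_enrolled.sum(axis=1).mean())
                arm_alt["control"] = float(res_alt.ctrl_enrolled.sum(axis=1).mean())
            records.append(
                OCRecord(
                    design=design,
                    theta=theta,
                    theta_star=ts,
                    type1=type1,
                    power=power,
                    avg_n_null=float(res_null.total_enrolled.mean()),
                    avg_n_alt=float(res_alt.total_enrolled.mean()),
                    avg_n_trt_null=float(res_null.total_treatment.mean()),
                    avg_n_trt_alt=float(res_alt.total_treatment.mean()),
                    arm_means_null=arm_null,
                    arm_means_alt=arm_alt,
                )
            )
    return records


def _enrichment_records(
    config: DesignConfig, grid, data_null, data_alt, table1, table2
) -> list[OCRecord]:
    records = []
    ic23 = len(SUBGROUPS) - 1
    for ti, theta in enumerate(grid.posterior_thresholds):
        for ts in grid.predictive_thresholds:
            # null-calibrated stage-1 advancement bound for this cell
            pool_null = replay_pooled_cell(data_null.stage1, table1, ti, ts, config)
            bound = stage1_bound_from_maxima(
                pool_null.terminal_ppp, config.stage1_bound_percentile
            )
            res_null = replay_enrichment_cell(data_null, table1, table2, ti, ts, config, bound)
            res_alt = replay_enrichment_cell(data_alt, table1, table2, ti, ts, config, bound)

            n_adv_null = int(res_null.advanced.sum())
            n_adv_alt = int(res_alt.advanced.sum())
            n_sim_null = res_null.advanced.size
            n_sim_alt = res_alt.advanced.size
            type1 = {"stage1": n_adv_null / n_sim_null}
            power = {
                # stage-1 power: IC2/3 selected and advanced
                "stage1": float(
                    (res_alt.advanced & (res_alt.selected == ic23)).mean()
                ),
                "stage1_any": n_adv_alt / n_sim_alt,
            }
            type1["stage2_unconditional"] = float(res_null.positive.mean())
            power["stage2_unconditional"] = float(res_alt.positive.mean())
            if n_adv_null:
                type1["stage2"] = float(res_null.positive.sum() / n_adv_null)
            if n_adv_alt:
                power["stage2"] = float(res_alt.positive.sum() / n_adv_alt)
            advance_null = {
                g: float((res_null.advanced & (res_null.selected == i)).mean())
                for i, g in enumerate(SUBGROUPS)
            }
            advance_alt = {
                g: float((res_alt.advanced & (res_alt.selected == i)).mean())
                for i, g in enumerate(SUBGROUPS)
            }
            arm_null = {
                "control": float(
                    (res_null.stage1.ctrl_enrolled + res_null.stage2_ctrl).mean()
                ),
                "stage2": float(res_null.stage2_enrolled.mean()),
            }
            arm_alt = {
                "control": float(
                    (res_alt.stage1.ctrl_enrolled + res_alt.stage2_ctrl).mean()
                ),
                "stage2": float(res_alt.stage2_enrolled.mean()),
            }
            records.append(
                OCRecord(
                    design="enrichment",
                    theta=theta,
                    theta_star=ts,
                    type1=type1,
                    power=power,
                    avg_n_null=float(res_null.total_enrolled.mean()),
                    avg_n_alt=float(res_alt.total_enrolled.mean()),
                    avg_n_trt_null=float(res_null.total_treatment.mean()),
                    avg_n_trt_alt=float(res_alt.total_treatment.mean()),
                    arm_means_null=arm_null,
                    arm_means_alt=arm_alt,
                    bound=bound,
                    advance_null=advance_null,
                    advance_alt=advance_alt,
                    n_advance_null=n_adv_null,
                    n_advance_alt=n_adv_alt,
                )
            )
    return records


def estimate_oc(
    design_kind: str,
    grid: ThresholdGrid,
    null_scenario: Scenario,
    alt_scenario: Scenario,
    n_sim: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    prior: BetaPrior = BetaPrior(),
    arm_size: int = 50,
    look_interval: int = 10,
    stage2_per_arm: int = 50,
    stage1_bound_percentile: float = 0.8,
) -> list[OCRecord]:
    """Estimate operating characteristics for every cell of the grid.

    ``n_sim`` replicates are drawn once per scenario from a seed-sequence
    spawned generator pair (null first, then alternative) and replayed
    across all grid cells.  Returns one :class:`OCRecord` per cell, in
    row-major (theta, theta_star) order.
    """
    from .bayes import Thresholds  # deferred to avoid cycle in docs builds

    config = DesignConfig(
        kind=design_kind,
        thresholds=Thresholds(grid.posterior_thresholds[0], grid.predictive_thresholds[0]),
        prior=prior,
        arm_size=arm_size,
        look_interval=look_interval,
        stage2_per_arm=stage2_per_arm,
        stage1_bound_percentile=stage1_bound_percentile,
        n_sim=n_sim,
    )
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_null, rng_alt = (np.random.default_rng(c) for c in ss.spawn(2))
    thetas = grid.posterior_thresholds
    table = get_table(prior, arm_size, arm_size, thetas)
    if design_kind == "pooled":
        data_null = draw_pooled_data(null_scenario, n_sim, rng_null, config)
        data_alt = draw_pooled_data(alt_scenario, n_sim, rng_alt, config)
        return _pooled_like_records(
            "pooled", config, grid, data_null, data_alt, replay_pooled_cell, table
        )
    if design_kind == "stratified":
        data_null = draw_stratified_data(null_scenario, n_sim, rng_null, config)
        data_alt = draw_stratified_data(alt_scenario, n_sim, rng_alt, config)
        return _pooled_like_records(
            "stratified", config, grid, data_null, data_alt, replay_stratified_cell, table
        )
    if design_kind == "enrichment":
        table2 = get_table(prior, arm_size + stage2_per_arm, stage2_per_arm, thetas)
        data_null = draw_enrichment_data(null_scenario, n_sim, rng_null, config)
        data_alt = draw_enrichment_data(alt_scenario, n_sim, rng_alt, config)
        return _enrichment_records(config, grid, data_null, data_alt, table, table2)
    raise ValueError(f"unknown design kind {design_kind!r}")


def filter_acceptable(
    records: list[OCRecord],
    type1_range: tuple[float, float] = (0.05, 0.1),
    min_power: float = 0.8,
) -> list[OCRecord]:
    """Designs with calibration type I error in ``type1_range`` and power >= ``min_power``.

    Enrichment cells that never advanced to stage 2 under a scenario have
    no stage-2 operating characteristics and are excluded.  An empty result
    is a reportable condition, not an error.
    """
    lo, hi = type1_range
    kept = []
    for rec in records:
        t1, pw = rec.calibration_type1, rec.calibration_power
        if t1 is None or pw is None:
            continue
        if lo <= t1 <= hi and pw >= min_power:
            kept.append(rec)
    if not kept:
        logger.info("no threshold combination satisfies the accuracy constraints")
    return kept


def annotate_distances(records: list[OCRecord]) -> list[OCRecord]:
    """Efficiency distance of each record to the ideal sample-size corner.

    The corner has the smallest average total sample size under the null
    and the largest under the alternative among ``records`` (computed over
    the constraint-satisfying set passed in):
    ``d = sqrt((n_null - min_null)^2 + (max_alt - n_alt)^2)``.
    """
    if not records:
        raise ValueError("no records to annotate")
    min_null = min(r.avg_n_null for r in records)
    max_alt = max(r.avg_n_alt for r in records)
    out = []
    for rec in records:
        d = float(np.hypot(rec.avg_n_null - min_null, max_alt - rec.avg_n_alt))
        out.append(replace(rec, distance=d))
    return out


def select_optimal_efficiency(records: list[OCRecord]) -> OCRecord:
    """Minimal-efficiency-distance record among constraint-satisfying designs.

    Ties are broken deterministically: higher power, then lower type I
    error, then lower posterior threshold, then lower predictive threshold.
    """
    if not records:
        raise ValueError("cannot select an optimal design from an empty set")
    annotated = annotate_distances(records)
    best = min(
        annotated,
        key=lambda r: (
            r.distance,
            -(r.calibration_power or 0.0),
            r.calibration_type1 or 1.0,
            r.theta,
            r.theta_star,
        ),
    )
    best.optimal = True
    return best


def oc_table(records: list[OCRecord], optimal: OCRecord | None = None) -> pd.DataFrame:
    """Flat one-row-per-cell table of operating characteristics."""
    rows = []
    for rec in records:
        row: dict = {
            "design": rec.design,
            "theta": rec.theta,
            "theta_star": rec.theta_star,
            "avg_n_null": rec.avg_n_null,
            "avg_n_alt": rec.avg_n_alt,
            "avg_n_trt_null": rec.avg_n_trt_null,
            "avg_n_trt_alt": rec.avg_n_trt_alt,
            "calibration_type1": rec.calibration_type1,
            "calibration_power": rec.calibration_power,
            "distance": rec.distance,
            "optimal": bool(
                optimal is not None
                and rec.theta == optimal.theta
                and rec.theta_star == optimal.theta_star
            )
            or rec.optimal,
        }
        for g, v in rec.type1.items():
            row[f"type1_{g}"] = v
        for g, v in rec.power.items():
            row[f"power_{g}"] = v
        if rec.bound is not None:
            row["stage1_bound"] = rec.bound
            row["n_advance_null"] = rec.n_advance_null
            row["n_advance_alt"] = rec.n_advance_alt
        rows.append(row)
    return pd.DataFrame(rows)
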