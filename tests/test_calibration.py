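"""Constraint filtering, efficiency distance, and optimal-design selection."""

import random

import numpy as np
import pytest

from ppdesigns.calibration import (
    OCRecord,
    ThresholdGrid,
    annotate_distances,
    estimate_oc,
    filter_acceptable,
    oc_table,
    select_optimal_efficiency,
)
from ppdesigns.designs import alternative_scenario, null_scenario


def record(theta=0.9, theta_star=0.1, t1=0.07, pw=0.82, n_null=100.0, n_alt=150.0):
    return OCRecord(
        design="pooled",
        theta=theta,
        theta_star=theta_star,
        type1={"IC0": t1, "IC1": t1, "IC2/3": t1},
        power={"IC0": 0.05, "IC1": 0.4, "IC2/3": pw},
        avg_n_null=n_null,
        avg_n_alt=n_alt,
        avg_n_trt_null=n_null * 0.7,
        avg_n_trt_alt=n_alt * 0.7,
    )


class TestFilter:
    @pytest.mark.parametrize(
        "t1, pw, kept",
        [
            (0.04, 0.85, False),  # below the type I band
            (0.07, 0.82, True),
            (0.06, 0.79, False),  # power floor
            (0.11, 0.9, False),  # above the band
            (0.05, 0.80, True),  # boundaries are inclusive
            (0.10, 0.80, True),
        ],
    )
    def test_accuracy_band(self, t1, pw, kept):
        out = filter_acceptable([record(t1=t1, pw=pw)])
        assert bool(out) is kept

    def test_empty_result_is_not_an_error(self):
        assert filter_acceptable([record(t1=0.5)]) == []

    def test_enrichment_cells_without_advancers_excluded(self):
        rec = record()
        rec.design = "enrichment"
        rec.type1 = {"stage1": 0.1}
        rec.power = {"stage1": 0.7}
        assert filter_acceptable([rec]) == []


class TestEfficiencyDistance:
    def test_hand_computed_three_records(self):
        a = record(theta=0.9, n_null=100, n_alt=150)
        b = record(theta=0.93, n_null=110, n_alt=160)
        c = record(theta=0.95, n_null=120, n_alt=170)
        annotated = annotate_distances([a, b, c])
        np.testing.assert_allclose(
            [r.distance for r in annotated], [20.0, np.sqrt(200.0), 20.0]
        )
        best = select_optimal_efficiency([a, b, c])
        assert (best.theta, best.theta_star) == (0.93, 0.1)

    def test_single_record_attains_both_corners(self):
        best = select_optimal_efficiency([record()])
        assert best.distance == 0.0

    def test_selection_invariant_to_order(self):
        recs = [
            record(theta=th, n_null=n0, n_alt=n1)
            for th, n0, n1 in [(0.9, 100, 150), (0.93, 110, 160), (0.95, 120, 170)]
        ]
        shuffled = recs[:]
        random.Random(4).shuffle(shuffled)
        assert select_optimal_efficiency(recs).theta == select_optimal_efficiency(
            shuffled
        ).theta

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            select_optimal_efficiency([])

    def test_tie_break_prefers_higher_power(self):
        a = record(theta=0.9, pw=0.85)
        b = record(theta=0.93, pw=0.9)
        # identical sample sizes: both attain the corner, distance 0
        best = select_optimal_efficiency([a, b])
        assert best.theta == 0.93


class TestEstimateOC:
    def test_common_random_numbers_reproducible(self):
        grid = ThresholdGrid((0.9, 0.95), (0.1,))
        kw = dict(
            null_scenario=null_scenario(),
            alt_scenario=alternative_scenario(),
            n_sim=50,
            seed=42,
        )
        a = estimate_oc("pooled", grid, **kw)
        b = estimate_oc("pooled", grid, **kw)
        for ra, rb in zip(a, b):
            assert ra.type1 == rb.type1
            assert ra.avg_n_null == rb.avg_n_null

    def test_oc_table_layout(self):
        grid = ThresholdGrid((0.9,), (0.1, 0.2))
        recs = estimate_oc(
            "stratified", grid, null_scenario(), alternative_scenario(), n_sim=20, seed=1
        )
        frame = oc_table(recs)
        assert len(frame) == 2
        assert {"theta", "theta_star", "avg_n_null", "optimal"} <= set(frame.columns)

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError):
            estimate_oc(
                "crossover",
                ThresholdGrid((0.9,), (0.1,)),
                null_scenario(),
                alternative_scenario(),
                n_sim=2,
                seed=0,
            )
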