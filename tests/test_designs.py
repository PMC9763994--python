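"""Behavioral tests of the three trial simulators."""

import numpy as np
import pytest

from ppdesigns.bayes import BetaPrior, Thresholds
from ppdesigns.calibration import ThresholdGrid, estimate_oc
from ppdesigns.designs import (
    SUBGROUPS,
    DesignConfig,
    Scenario,
    alternative_scenario,
    calibrate_stage1_bound,
    draw_pooled_data,
    homogeneous_scenario,
    null_scenario,
    replay_pooled_cell,
    simulate_enrichment_trial,
    simulate_pooled_trial,
    simulate_stratified_trial,
    simulate_trials,
)
from ppdesigns.engine import get_table


def config(kind, theta=0.9, theta_star=0.1, **kw):
    return DesignConfig(kind=kind, thresholds=Thresholds(theta, theta_star), **kw)


class TestScenario:
    def test_prevalence_must_sum_to_one(self):
        with pytest.raises(ValueError):
            Scenario(0.1, 0.2, prevalence=(0.5, 0.5, 0.5))

    def test_mapping_and_scalar_inputs(self):
        s = Scenario(0.1, {"IC0": 0.1, "IC1": 0.2, "IC2/3": 0.3})
        assert s.p_trt == (0.1, 0.2, 0.3)
        assert s.p_ctrl == (0.1, 0.1, 0.1)
        assert s.pooled_control_rate == pytest.approx(0.1)

    def test_case_study_constructors(self):
        assert alternative_scenario().p_trt == (0.1, 0.2, 0.3)
        assert null_scenario().p_trt == (0.1, 0.1, 0.1)
        assert homogeneous_scenario().p_trt == (0.3, 0.3, 0.3)

    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            Scenario(0.1, 1.2)


class TestConfigValidation:
    def test_bad_kind(self):
        with pytest.raises(ValueError):
            config("adaptive")

    def test_arm_size_look_interval_mismatch(self):
        with pytest.raises(ValueError):
            config("pooled", arm_size=55)

    def test_maxima(self):
        assert config("pooled").max_total == 200
        assert config("stratified").max_total == 300
        assert config("enrichment").max_total == 300


class TestStoppingBehavior:
    def test_tiny_theta_star_stops_only_hopeless_arms(self):
        # with theta* ~ 0 a subgroup can stop only when success is
        # literally impossible (PPP exactly zero)
        cfg = config("pooled", theta_star=1e-9)
        res = simulate_trials(cfg, null_scenario(), 5, n_sim=20)
        stopped = 0
        for r in res:
            for g in SUBGROUPS:
                if r.decisions[g] == "stopped_futility":
                    stopped += 1
                    assert r.final_ppp[g] <= 1e-9
                else:
                    assert r.enrolled[g] == 50
        assert stopped <= 3  # out of 60 subgroup comparisons

    def test_huge_theta_star_stops_at_first_look(self):
        cfg = config("pooled", theta_star=0.999)
        res = simulate_trials(cfg, null_scenario(), 5, n_sim=20)
        for r in res:
            assert all(r.decisions[g] == "stopped_futility" for g in SUBGROUPS)
            assert all(r.enrolled[g] == 10 for g in SUBGROUPS)
            assert r.total_enrolled < 80

    def test_maxima_respected(self):
        for kind in ("pooled", "stratified"):
            cfg = config(kind, theta_star=1e-9)
            for r in simulate_trials(cfg, alternative_scenario(), 11, n_sim=10):
                assert r.total_enrolled <= cfg.max_total
                assert r.total_treatment <= 150

    def test_determinism_same_seed(self):
        cfg = config("stratified", theta_star=0.2)
        a = simulate_stratified_trial(cfg, alternative_scenario(), 123)
        b = simulate_stratified_trial(cfg, alternative_scenario(), 123)
        assert a == b

    def test_raising_theta_never_creates_positives(self):
        """With fixed data streams, a stricter posterior threshold can only
        lose positives (monotone decision and stopping rules)."""
        cfg = config("pooled")
        data = draw_pooled_data(
            alternative_scenario(), 200, np.random.default_rng(5), cfg
        )
        table = get_table(BetaPrior(), 50, 50, (0.85, 0.95))
        low = replay_pooled_cell(data, table, 0, 0.1, cfg)
        high = replay_pooled_cell(data, table, 1, 0.1, cfg)
        assert not np.any(high.positive & ~low.positive)


class TestTrialResults:
    def test_pooled_biomarker_testing_only_treated(self):
        r = simulate_pooled_trial(config("pooled"), null_scenario(), 3)
        assert r.total_biomarker_tested == r.total_treatment <= 150
        assert r.enrolled["control"] <= 50

    def test_stratified_tests_everyone(self):
        r = simulate_stratified_trial(
            config("stratified", theta_star=0.2), null_scenario(), 3
        )
        assert r.total_biomarker_tested == r.total_enrolled <= 300
        # a subgroup's control arm stops with its treatment arm
        for g in SUBGROUPS:
            assert abs(r.enrolled[f"control:{g}"] - r.enrolled[g]) <= 15

    def test_wrong_kind_rejected(self):
        with pytest.raises(ValueError):
            simulate_pooled_trial(config("stratified"), null_scenario(), 1)


class TestEnrichment:
    cfg = config("enrichment", theta=0.96, theta_star=0.15, n_sim=200)

    def test_unattainable_bound_blocks_stage2(self):
        for r in simulate_trials(self.cfg, null_scenario(), 7, n_sim=30, bound=1.0):
            assert r.stage_reached == 1
            assert r.selected_subgroup is None

    def test_bound_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            simulate_enrichment_trial(self.cfg, null_scenario(), 1.5, 1)

    def test_calibrated_bound_in_unit_interval(self):
        bound = calibrate_stage1_bound(self.cfg, null_scenario(), 11)
        assert 0.0 < bound < 1.0

    def test_advancing_trial_accounting(self):
        bound = 0.0  # always advance unless all stopped
        rng = np.random.default_rng(13)
        seen_stage2 = False
        for _ in range(20):
            r = simulate_enrichment_trial(self.cfg, alternative_scenario(), bound, rng)
            assert r.total_enrolled <= 300
            assert r.total_treatment <= 200
            if r.stage_reached == 2:
                seen_stage2 = True
                g = r.selected_subgroup
                assert g in SUBGROUPS
                assert r.decisions[g] in ("positive", "negative", "stopped_futility")
                # stage-2 screening: all comers tested, one-third eligible
                expected = r.total_treatment - r.enrolled["stage2:treatment"] + 3 * (
                    r.enrolled["stage2:treatment"] + r.enrolled["stage2:control"]
                )
                assert r.total_biomarker_tested == pytest.approx(expected)
        assert seen_stage2

    def test_all_stopped_means_no_selection(self):
        cfg = config("enrichment", theta=0.96, theta_star=0.999)
        r = simulate_enrichment_trial(cfg, null_scenario(), 0.0, 3)
        assert r.stage_reached == 1
        assert all(r.decisions[g] == "stopped_futility" for g in SUBGROUPS)


class TestSingleReplicateOC:
    def test_one_replicate_proportions_are_binary(self):
        recs = estimate_oc(
            "pooled",
            ThresholdGrid((0.9,), (0.1,)),
            null_scenario(),
            alternative_scenario(),
            n_sim=1,
            seed=5,
        )
        rec = recs[0]
        assert set(rec.type1.values()) <= {0.0, 1.0}
        assert set(rec.power.values()) <= {0.0, 1.0}

    def test_perfect_separation_gives_full_power(self):
        sep = Scenario(0.0, 1.0)
        recs = estimate_oc(
            "pooled",
            ThresholdGrid((0.9,), (0.1,)),
            null_scenario(),
            sep,
            n_sim=20,
            seed=6,
        )
        assert all(v == 1.0 for v in recs[0].power.values())
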