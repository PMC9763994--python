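"""Calibrate thresholds on a small grid and pick the optimal-efficiency design.

Estimates type I error, power and expected sample sizes of the pooled
design over a 3 x 2 grid of (theta, theta*) with 200 simulated trials per
scenario (the case study uses the full 14 x 4 grid and 1000 replicates),
then filters to designs with IC0 type I error in [0.05, 0.1] and IC2/3
power >= 0.8 and reports the one closest to the ideal sample-size corner.
"""

from ppdesigns import (
    ThresholdGrid,
    alternative_scenario,
    estimate_oc,
    filter_acceptable,
    null_scenario,
    oc_table,
    select_optimal_efficiency,
)

grid = ThresholdGrid((0.86, 0.9, 0.95), (0.1, 0.2))
records = estimate_oc(
    "pooled", grid, null_scenario(), alternative_scenario(), n_sim=200, seed=7
)
print(oc_table(records)[
    ["theta", "theta_star", "calibration_type1", "calibration_power",
     "avg_n_null", "avg_n_alt"]
].to_string(index=False))

acceptable = filter_acceptable(records)
print(f"\n{len(acceptable)} of {len(records)} cells satisfy the accuracy constraints")
if acceptable:
    best = select_optimal_efficiency(acceptable)
    print(f"optimal efficiency: theta={best.theta}, theta*={best.theta_star} "
          f"(distance {best.distance:.1f})")
    print("\nThe optimum minimizes the distance to the corner of smallest")
    print("average trial under the null and largest under the alternative:")
    print("stop bad treatments early, study good ones fully.")
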