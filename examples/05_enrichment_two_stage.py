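"""The two-stage enrichment design: select a subgroup, then enrich.

Stage 1 runs the pooled design; the subgroup with the highest end-of-stage
predictive probability advances to a dedicated 1:1 randomized stage 2 --
provided its PPP clears a lower bound calibrated as the 80th percentile of
the best subgroup's PPP under the global null (targeting a 20% advancement
rate when no treatment works).
"""

import numpy as np

from ppdesigns import (
    DesignConfig,
    Thresholds,
    alternative_scenario,
    calibrate_stage1_bound,
    null_scenario,
    simulate_enrichment_trial,
)

config = DesignConfig(
    kind="enrichment", thresholds=Thresholds(theta=0.96, theta_star=0.15), n_sim=300
)

bound = calibrate_stage1_bound(config, null_scenario(), rng_stream=5)
print(f"null-calibrated stage-1 advancement bound: {bound:.3f}")

rng = np.random.default_rng(6)
advanced = positives = 0
n_trials = 50
for _ in range(n_trials):
    res = simulate_enrichment_trial(config, alternative_scenario(), bound, rng)
    if res.stage_reached == 2:
        advanced += 1
        positives += res.decisions[res.selected_subgroup] == "positive"

print(f"under the alternative: {advanced}/{n_trials} trials advanced to stage 2;")
print(f"{positives}/{advanced} advancing trials ended positive")
print()
print("Advancement concentrates on the truly responsive IC2/3 subgroup; the")
print("carried-forward stage-1 treatment data let stage 2 reach a decision")
print("with 100 additional patients from the selected subgroup alone.")
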