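# ppdesigns

Bayesian predictive probability futility monitoring and optimal-efficiency
design selection for **biomarker-guided randomized phase II oncology
trials**, with three design topologies: a pooled control arm, a stratified
control arm, and a two-stage enrichment design.

## The problem

Single-arm phase II trials judge a targeted therapy against a historical
control rate — a population average that may badly misrepresent the
biomarker subpopulation actually enrolled. The motivating case study is
atezolizumab in metastatic urothelial carcinoma: the phase II trial beat a
10% historical response rate, but the randomized phase III trial found
chemotherapy itself responded at ~22% in the PD-L1-high (IC2/3) subgroup,
and the accelerated approval was withdrawn. Randomizing earlier avoids
this failure mode, but phase II sample sizes must stay small. This package
implements designs that keep randomized phase II trials small through
Bayesian sequential futility monitoring, and calibrates their thresholds
by simulation.

For whom: biostatisticians designing early-phase randomized trials with a
binary endpoint and a small number of biomarker subgroups.

## The model

Each arm's response rate has an independent conjugate beta prior,
p ~ Beta(a₀, b₀) (default Beta(½, ½), roughly one patient's information).
After x responses in n patients, p | x ~ Beta(a₀ + x, b₀ + n − x). The
end-of-trial efficacy rule declares a treatment arm positive when

    Pr(p_trt > p_ctrl | data) > θ.

At an interim look with n\* future patients per arm, future responses
follow independent beta-binomial predictive distributions, and the
**two-sample posterior predictive probability** (PPP) is the exact sum
over all joint completions

    PPP = Σ_{y_t, y_c} BB(y_t) · BB(y_c) · 1{ Pr(p_trt > p_ctrl | completed data) > θ },

i.e. the probability the trial ends positive at full enrollment.
Enrollment of a subgroup stops for futility when PPP < θ\*.

Design calibration simulates 1000 trials per scenario for each (θ, θ\*)
in a 14 × 4 grid, keeps combinations with type I error in [0.05, 0.1] and
power ≥ 0.8, and selects the **optimal-efficiency** design: the one
closest (Euclidean distance) to the corner of smallest average sample
size under the null and largest under the alternative.

The three designs (per-arm maxima of 50, looks every 10 treated patients
per subgroup):

| design | screening | randomization | maximum N |
|---|---|---|---|
| pooled | treated patients only | 3:1 to treatment, one shared control | 200 |
| stratified | everyone | 1:1 within each subgroup | 300 |
| enrichment | stage 1 as pooled; stage 2 everyone | stage 2: 1:1, selected subgroup only | 300 |

In the enrichment design, the subgroup with the highest end-of-stage-1
PPP advances iff it did not stop for futility and its PPP clears a lower
bound, calibrated as the 80th percentile of the per-trial best-subgroup
PPP under the global null; stage-1 treatment data are carried forward.

## Worked example

```python
from ppdesigns import ArmData, BetaPrior, prob_exceeds, two_sample_ppp, update_posterior

prior = BetaPrior(0.5, 0.5)
trt, ctrl = ArmData(x=7, n=20, N=50), ArmData(x=2, n=18, N=50)
post_t, post_c = update_posterior(prior, trt), update_posterior(prior, ctrl)
print(prob_exceeds(post_t, post_c))      # 0.9605
print(two_sample_ppp(trt, ctrl, prior, theta=0.9))  # 0.8903
```

The posterior comparison says we are 96% sure the experimental arm is
better *right now*; the PPP of 0.89 says that, completing both arms to 50
patients, the trial would end positive (θ = 0.9) with probability 0.89 —
comfortably above any futility threshold, so enrollment continues.

Simulating one pooled-design trial under the case-study alternative
(control 10%; subgroup treatment rates 10/20/30%):

```
$ python examples/02_single_trial.py
decisions by subgroup:
  IC0    stopped_futility (treated n=10, last PPP=0.057)
  IC1    positive         (treated n=50, last PPP=1.000)
  IC2/3  positive         (treated n=50, last PPP=1.000)
control arm enrolled: 50
total enrolled:       160 (maximum 200)
```

The null-rate IC0 arm stopped at its first look, saving 40 patients,
while the responsive subgroups ran to completion and were declared
positive. The other `examples/` scripts cover threshold calibration and
optimal-design selection, stopping-boundary tables, and the two-stage
enrichment design.

A thin CLI wraps the same library calls:

```bash
ppdesigns report -c src/ppdesigns/configs/case_study_pooled.yaml -o out/
```

writes the grid's operating characteristics (`oc_table.csv`), the
selected optimum, per-look decision tables and accuracy/efficiency
figures.

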