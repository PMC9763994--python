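# Case study: atezolizumab in metastatic urothelial carcinoma.
# Three PD-L1 subgroups (IC0, IC1, IC2/3) of equal prevalence; historical
# control response rate 10%; predictive-biomarker alternative 10/20/30%.
# Thresholds below are the optimal-efficiency cell for this design.
schema: 1
design: stratified
prior: [0.5, 0.5]
thresholds: {theta: 0.9, theta_star: 0.2}
arm_size: 50
look_interval: 10
stage2_per_arm: 50
stage1_bound_percentile: 0.8
n_sim: 1000
seed: 20221206
scenarios:
  "null":
    p_ctrl: 0.1
    p_trt: 0.1
  alternative:
    p_ctrl: 0.1
    p_trt: {IC0: 0.1, IC1: 0.2, "IC2/3": 0.3}
  homogeneous:
    p_ctrl: 0.1
    p_trt: 0.3
grid:
  theta: [0.7, 0.74, 0.78, 0.82, 0.86, 0.9, 0.92, 0.93, 0.94, 0.95, 0.96, 0.97, 0.98, 0.99]
  theta_star: [0.05, 0.1, 0.15, 0.2]
sensitivity_priors:
  - [0.5, 0.5]
  - [1, 1]
  - [0, 0]
  - [2, 2]
  - [0.75, 0.25]
  - [0.25, 0.75]
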