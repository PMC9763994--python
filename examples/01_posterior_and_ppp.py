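"""Posterior updating and the two-sample posterior predictive probability.

A trial has observed 7/20 responses on the experimental arm and 2/18 on
control, out of 50 planned per arm.  We update the Beta(1/2, 1/2) priors,
compute the probability that the experimental response rate is higher, and
the predictive probability that the trial will end positive at a posterior
threshold of 0.9.
"""

from ppdesigns import ArmData, BetaPrior, prob_exceeds, two_sample_ppp, update_posterior

prior = BetaPrior(0.5, 0.5)
trt = ArmData(x=7, n=20, N=50)
ctrl = ArmData(x=2, n=18, N=50)

post_t = update_posterior(prior, trt)
post_c = update_posterior(prior, ctrl)
print(f"treatment posterior: Beta({post_t.a}, {post_t.b}), mean {post_t.mean:.3f}")
print(f"control   posterior: Beta({post_c.a}, {post_c.b}), mean {post_c.mean:.3f}")

p_better = prob_exceeds(post_t, post_c)
print(f"Pr(p_trt > p_ctrl | data) = {p_better:.4f}")

for theta in (0.8, 0.9, 0.95):
    ppp = two_sample_ppp(trt, ctrl, prior, theta)
    print(f"PPP of a positive trial at theta={theta}: {ppp:.4f}")

print()
print("The posterior probability says how sure we are right now that the")
print("experimental arm is better; the PPP says how likely the trial is to")
print("END positive if both arms enroll to 50.  Futility monitoring stops")
print("the trial when the PPP drops below a threshold theta*.")
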