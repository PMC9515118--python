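# riskpref

Hierarchical Bayesian estimation of risk preferences from binary
lottery-choice experiments with within-subject stimulation conditions
(sham / right / left).

## The problem

In a random-lottery-pair task a participant answers 96 binary questions,
each a choice between a *safe* and a *risky* two-outcome lottery sharing
the same best-outcome probability `p`, drawn from multiple price lists
that sweep `p` from 0 to 1 (half the questions in the gain domain, half
sign-mirrored losses). The analysis question is structural: did an
intervention change the participant's *utility curvature*, their
*probability weighting*, or their *choice consistency*?

The model is rank-dependent utility with CRRA value,

    U(x) = x^r (x ≥ 0),   −(−x)^r (x < 0)
    EU   = w(p) · U(x_best) + (1 − w(p)) · U(x_worst)

with a linear, Kahneman–Tversky (`w(p) = p^γ/(p^γ+(1−p)^γ)^{1/γ}`) or
one-parameter Prelec (`w(p) = e^{−(−ln p)^α}`) weighting function, and a
Luce choice rule with inverse temperature τ:

    P(A ≻ B) = logistic( τ · (1/r) · ln(EU_A / EU_B) ).

Each subject's `(r, γ, τ)` is a baseline plus an additive per-condition
shift (`Δr, Δγ, Δτ` for right and left stimulation); subjects share a
truncated-normal population distribution per parameter, and the group
means of the shifts are the quantities of scientific interest, summarized
with 89%/95% credible intervals and Savage–Dickey Bayes factors at zero.
Model variants are compared by WAIC and PSIS-LOO; fit quality is checked
by the proportion of choices the posterior predicts correctly.

The package is aimed at decision-neuroscience / behavioral-economics
analyses of this design: it ships the task builder, a generative
simulator, a seed-deterministic NUTS-based sampler with analytic
gradients, and the full comparison/testing pipeline.

## Worked example

```python
import numpy as np
from riskpref import (GroupHyperParams, MCMCConfig, ModelSpec,
                      simulate_dataset, fit, diagnostics)
from riskpref.effects import effect_table

# a 12-subject synthetic cohort: near risk-neutral utility, S-shaped
# weighting, consistent choices, and a +0.6 left-stimulation shift of
# the weighting parameter
hyper = GroupHyperParams(mu_r0=1.0, mu_gamma0=2.5, mu_tau0=6.7,
                         mu_dgamma_left=0.6)
table = simulate_dataset(hyper, 12, np.random.default_rng(10),
                         domains=("gain",))

cfg = MCMCConfig(chains=2, warmup=200, draws=400,
                 target_accept=0.9, max_treedepth=6)
draws = fit(table, ModelSpec("kahneman_tversky"), cfg, seed=7)

for name in ("mu_r0", "mu_gamma0", "mu_tau0", "mu_dgamma_left"):
    x = draws.get(name)
    lo, hi = np.percentile(x, [2.5, 97.5])
    print(f"{name:15s} mean {x.mean():5.2f}   95% CI [{lo:5.2f}, {hi:5.2f}]")
```

prints (exact numbers are seed-dependent; this is the output of the call
above):

```
mu_r0           mean  1.61   95% CI [ 0.13,  3.17]
mu_gamma0       mean  3.96   95% CI [ 2.62,  4.78]
mu_tau0         mean  5.53   95% CI [ 2.29,  9.14]
mu_dgamma_left  mean  0.52   95% CI [-1.10,  1.42]
```

Read this as: at 12 subjects and a reduced sampling budget the group
posteriors are wide — utility curvature and weighting curvature trade off
along a near-flat likelihood ridge in this task, so the baseline means
carry broad intervals, and the left-stimulation weighting shift (truth
0.6) is covered but not distinguishable from zero. The
`analysis/` scripts walk the full pipeline (design construction,
simulation, three-family fits, WAIC/LOO comparison, posterior predictive
accuracy, effect tables with Bayes factors, parameter recovery) at larger
scale; `docs/methods.md` documents the model, priors, sampler, and known
limitations.

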