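# Methods

`riskpref` implements a complete analysis chain for binary lottery-choice
experiments with within-subject stimulation conditions: task construction,
a generative simulator, hierarchical Bayesian estimation of risk-preference
parameters, model comparison, posterior predictive checking, Savage–Dickey
hypothesis tests, and parameter-recovery validation.

## The task

Each multiple price list (MPL) opposes a *safe* two-outcome lottery (narrow
outcome spread) and a *risky* one (wide spread) at 16 levels of the
best-outcome probability, `p ∈ {0, .01, .05, .10, .15, .20, .30, .40, .50,
.60, .70, .80, .85, .90, .95, 1}`. Both options of a question share `p`.
The shipped battery holds three gain-domain outcome sets in monetary units:
the published example list (safe 260/180 vs risky 350/50) plus two
companion lists (240/160 vs 400/40 and 300/220 vs 420/80) chosen in the
same 50–500 MU magnitude range with the risky option's expected-value range
spanning the safe option's, so every list has a unique risk-neutral
crossover. A session presents 96 questions — the three lists in the gain
domain and their sign-mirrored loss versions — in randomized order, with
the risky lottery on the left screen position in a random half of the
questions. A risk-neutral agent answers the published list with option A
(safe) on rows 1–9 and option B on rows 10–16.

We probed alternative companion lists by an expected-information analysis
(profile expected log-likelihood over an (r, γ) grid at the generating
parameters): the fraction of the parameter box within 2 nats of the
optimum varies only between 0.11 and 0.15 across batteries, so the weak
joint identification of utility curvature and probability weighting
(discussed below) is a property of this task form, not of the particular
outcome amounts.

## The choice model

Utility is CRRA, `U(x) = x^r` for gains and `−(−x)^r` for losses; `r < 1`
is risk aversion in gains. A two-outcome lottery's rank-dependent value
gives the best outcome the decision weight `w(p)` and the worst the
complement `1 − w(p)`. Three weighting families are implemented: linear
`w(p) = p`; Kahneman–Tversky `w(p) = p^γ / (p^γ + (1−p)^γ)^{1/γ}`; and
one-parameter Prelec `w(p) = exp(−(−ln p)^α)`. Endpoints `w(0) = 0` and
`w(1) = 1` are returned exactly (the Prelec endpoint as its limit), and
probabilities are clamped to `[1e−12, 1 − 1e−12]` inside logarithms.

Choice follows the strict-utility (Luce) rule with the value-function
rescaling that decorrelates curvature and noise:

    P(A ≻ B) = logistic( τ · (1/r) · ln(EU_A / EU_B) ),

where τ is the inverse temperature (consistency). In the loss domain both
rank-dependent values are negative; the sign of the log-ratio term is
flipped so the option with the larger (less negative) value is preferred in
the deterministic limit τ → ∞. The rule is undefined when the two values
differ in sign or either is zero; such inputs raise an error.

The worst outcome's weight is written `1 − w(p_best)` rather than the
sometimes-seen `1 − w(p_worst)`: with shared two-outcome probabilities the
complement form is the standard rank-dependent assignment ("the rest of the
weight goes to the worst outcome"), and the two coincide only for linear
weighting.

## Hierarchical model

Each subject i carries baseline parameters `(r⁰ᵢ, γ⁰ᵢ, τ⁰ᵢ)` and additive
per-condition shifts `(Δrᵢ, Δγᵢ, Δτᵢ)` for the right- and left-stimulation
sessions; sham sessions use the baseline. Admissible intervals are
`r⁰ ∈ (0,5)`, `γ⁰ ∈ (0,6)`, `τ⁰ ∈ (0,∞)`, `Δr ∈ (−2,2)`, `Δγ ∈ (−1.5,1.5)`,
`Δτ ∈ (−5,5)`. The linear family has no curvature parameter and drops the
γ blocks.

Subject-level parameters follow a normal hierarchy **on their natural
scale**, truncated to the admissible interval: `θᵢ ~ N(m, σ)` restricted to
the bounds, with the truncation mass `Z(m, σ)` included in the density.
Group-level means carry weakly informative priors on the same scale —
`m_{r⁰} ~ N(0,5)`, `m_{γ⁰} ~ N(1,3)`, `m_{τ⁰} ~ N(0,10)` — whose stated
standard deviations match each parameter's natural range. The six shift
means are uniform over their intervals, realized as a standard normal on
the sampling scale pushed through the matched scaled-Phi transform; this
gives the closed-form prior densities at zero (1/4 for Δr, 1/3 for Δγ,
1/10 for Δτ) used by the Savage–Dickey tests. All group standard
deviations have LogNormal(0, 3) priors (log-scale parameters).

An alternative reading places the group-mean priors and the hierarchy on
the unconstrained sampling scale. We implemented and rejected it: pushing
N(0,5) or N(1,3) through a scaled-Phi map concentrates roughly 45% of the
implied prior mass against each interval boundary (e.g. P(γ⁰-location >
5.5) = 0.449), and a normal hierarchy on the latent scale implies a
boundary-spiked subject distribution on the natural scale (density ∝ 1/T′).
Because the task's likelihood is nearly flat along an (r, γ) ridge, those
spikes dominate: long converged runs pinned the group posteriors to the
upper corners (γ⁰ → 6, r⁰ → 3+), which contradicts the intended
weakly-informative reading and makes parameter recovery impossible. The
natural-scale reading is also the one under which "normally distributed
with the mean and standard deviation equal to the group-level mean and
standard deviation" refers to the parameters themselves.

Sampling works on an unconstrained space — `exp` for positive-only
parameters, `a + (b−a)Φ(z)` for two-sided intervals — with all
change-of-variables Jacobians applied analytically. Composed per-condition
parameters must stay positive; proposals violating this receive −∞.

## Sampling

No gradient-based MCMC backend is assumed; the package ships its own:

* analytic gradients of the joint log density, verified against central
  finite differences in the test suite (relative error < 1e−7);
* a No-U-Turn Sampler (slice variant, recursive tree doubling) with
  dual-averaging step-size adaptation and either a diagonal or a dense
  kinetic-energy metric; a static-trajectory HMC is kept as a cross-check;
* the default `gibbs_nuts` algorithm: group standard deviations are
  updated by one-dimensional slice sampling from their conditionals, and
  NUTS explores the (group means, subject values) block under a dense
  metric seeded from the Hessian at a warm-start point and refreshed
  mid-warmup at the best state visited. The warm start is the conditional
  posterior mode (group SDs pinned at plausible values) found by
  backtracking gradient descent followed by L-BFGS. Metric eigenvalues are
  floored so near-flat ridge directions cannot propose arbitrarily long
  jumps into curved territory.

Everything is deterministic given the seed: chain RNGs derive from
`numpy.random.SeedSequence(seed)`. Divergent transitions and acceptance
rates are recorded in the posterior's metadata and surfaced as warnings,
never discarded. The full-scale configuration is 8 chains × (1000 warmup
+ 4000 kept) = 32 000 draws; the reduced test configuration is 2 × (200 +
400) with target acceptance 0.9 and maximum tree depth 6, so one fit of a
12-subject cohort takes well under a minute.

The likelihood hot path is a numba kernel that exploits the design's
structure: effective parameters are constant within a subject-condition
cell, utilities depend only on (cell, outcome value) and weights only on
(cell, probability level), so both are tabulated over the small unique
sets before a single cheap pass over trials. The kernel is asserted equal
(to 1e−15) to the plain vectorized numpy route.

## Model comparison and checking

WAIC is computed from its definition (`lppd − p_waic` on the deviance
scale, log-sum-exp stabilized, sample-variance penalty). PSIS-LOO uses the
standard generalized-Pareto smoothing of the largest importance weights
(via `arviz.psislw`), with trials flagged above the customary k = 0.7
threshold; an unsmoothed importance-sampling estimate serves as the
independent oracle in tests. Selection is by LOOIC with WAIC and then
model simplicity as tie-breaks. The posterior predictive check draws
random joint-posterior samples and scores the fraction of observed choices
matching the model's modal prediction (probability > ½); sampled rather
than modal predictions are available behind a flag.

## Hypothesis testing

Credible intervals are equal-tailed percentile intervals (linear
interpolation between order statistics), reported at 89% and 95%. The
Savage–Dickey Bayes factor for each shift mean is the prior/posterior
density ratio at zero: the prior density comes from the closed uniform
form (cross-checked by transform-sampling Monte Carlo), the posterior
density from a Gaussian KDE with Silverman bandwidth (configurable), with
a warning when almost no posterior mass lies near zero. An analytic
posterior-density path exists for calibration cases where the KDE's
tail bias would dominate — a KDE evaluated two posterior SDs into a tail
carries an irreducible ~1% bias at any practical sample size, so exact
closed-form checks use the analytic path and the KDE path is validated
against it at the ~10% level. Evidence labels follow the usual
Jeffreys-style bins (BF 1–3 anecdotal, 3–10 moderate, 10–30 strong, and
so on, with reciprocals for the null).

## Synthetic cohorts

The generator draws subjects from exactly the hierarchy the estimator
assumes. Default group locations are the study regime (r⁰ ≈ 1.03,
γ⁰ ≈ 2.5, τ⁰ ≈ 6.68, all shifts zero); between-subject spreads — not
stated anywhere — were fixed once at natural-scale values (0.5 for r⁰,
0.8 for γ⁰, 2.5 for τ⁰, 0.25–0.8 for the shifts) that give subject ranges
a practitioner would call typical for student samples in such tasks
(r⁰ roughly 0.25–2.4, γ⁰ 1.2–4.3, τ⁰ 3–15). Subjects whose composed
per-condition parameters would fall within 0.3 of zero are redrawn:
empirical posteriors in this paradigm sit well inside the admissible
intervals, and boundary-riding subjects would place genuine posterior mass
against the hard support wall, where any Hamiltonian sampler degenerates.
Conditions are counterbalanced by a Latin square over the six session
orders; every session is a freshly shuffled 96-question design.

What the simulator does *not* emulate: reaction times, fatigue or
session-order drift, discomfort effects, payment realization, and any
deviation from the rank-dependent choice model itself (real subjects may
use heuristics the model only approximates). Passing recovery tests
therefore show that the estimator works when the model is true, not that
the model is true of any particular dataset.

## Known limitations

* **Weak joint identification.** For this task form, ~48 trials per
  subject-condition leave the likelihood nearly flat along a curved
  (r, γ, τ) ridge (the profile surface spans r ∈ (0, 3), γ ∈ (1, 6)
  within two nats for a single subject). The ridge runs deep: a
  linear-weighting agent with adapted (r, τ) reproduces the choice
  probabilities of the default curved-weighting agent to about 0.12 nats
  per 48-trial session on the shipped battery (a frozen property test),
  so the linear and Kahneman–Tversky specifications are nearly
  observationally equivalent for well-specified synthetic data at these
  parameter values, and information-criterion selection between them at
  small scale is close to a coin flip. Twelve-subject group posteriors
  are honest but wide, and group shift means are identified mostly through
  pooling. With the heavy-tailed LogNormal(0,3) prior on group SDs, the
  posterior retains mass in the large-σ regime where the truncated-normal
  hierarchy degenerates to a uniform over the interval and the shift mean
  decouples from the data; detecting a +0.6 weighting shift at this scale
  is therefore unreliable, consistent with the modest evidence (BF ≈ 3)
  such designs yield even at larger sample sizes.
* **Sampler efficiency.** The reduced-scale sampler trades effective
  sample size for runtime; group-level R-hat values of 1.1–1.5 are common
  at 2 × (200 + 400) and some divergent transitions remain near the
  composed-parameter support walls. The full-scale configuration with
  more chains and warmup is the one to use for substantive conclusions.
* Two of the three MPL outcome sets are package choices (the source prints
  only one list); analyses depending on the exact printed battery beyond
  the first list are approximate.
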