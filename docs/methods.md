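# Methods

## The model

`reachadapt` analyses force-field reach adaptation in a spontaneous-recovery
paradigm with the two-state (dual-rate) trial-by-trial model.  Net adaptation
is the sum of a fast state `xf` (learns quickly, forgets quickly) and a slow
state `xs` (learns slowly, retains well):

    y(n)    = xf(n) + xs(n) + ε_output,      ε_output ~ N(0, σ_output)
    e(n)    = f(n) − y(n)                    (0 on error-clamp trials)
    xf(n+1) = Rf·xf(n) + Lf·e(n) + ε_f,      ε_f ~ N(0, σ_state)
    xs(n+1) = Rs·xs(n) + Ls·e(n) + ε_s,      ε_s ~ N(0, σ_state)

with retention rates 0 < Rf < Rs < 1 and learning rates 0 < Ls < Lf < 1.
The perturbation f(n) is coded in adaptation-index (AI) units: +1 for the
clockwise (CW) curl field, −1 for counter-clockwise (CCW), 0 on null trials.
On error-clamp (EC) trials the channel removes the movement error, so the
states purely decay while the lateral channel force still expresses the
adaptive state — EC trials are therefore the probes on which the AI is
measured.

A note on the error sign: written with the update `+L·e`, the error must be
`e = f − y` for the dynamics to converge toward compensation (with `e = y − f`
the recursion diverges for any realistic retention/learning rates).  Some
presentations of the model write the error with the opposite sign convention
and a `−L·e` update; the two are equivalent.  We use `e = f − y` throughout.

The initial state is (0, 0): participants start unadapted.

## Paradigm

The default schedule is 100 null trials, 240 CW field trials (b = +13 Ns/m),
30 CCW trials (−13 Ns/m), and a final block of 50 EC trials (420 total).
Probe EC trials replace every fifth trial inside the window [21, 370].  The
probe anchor is a genuinely open choice — "every fifth trial from trial 21"
can mean indices 21, 26, … or multiples of five starting at 25.  We default
to multiples of five (25, 30, …, 370; 70 probes, of which 16 fall in the
baseline phase), which yields the four-field-trials-then-one-probe rhythm
that produces the characteristic zigzag in model predictions; the
alternative anchor is selectable via `ScheduleConfig(probe_anchor=
"window_start")`.

## Adaptation-index extraction

For an EC trial, the AI is the OLS slope of the measured lateral channel
force on the force the field would have produced (`b` times the velocity
along the channel), over the reach window.  Choices where the procedure is
under-determined:

* the regression includes an intercept (absorbs constant force bias); the
  slope alone is the AI;
* the regression window is reach onset (first sample with speed > 5 cm/s)
  to reach offset (200 ms after coming within 3 cm of the target centre,
  with the early-exit and stall exceptions);
* trials with maximum displacement < 6 cm are excluded — strictly less
  than, so exactly 6 cm is kept;
* AI series are baseline-corrected by subtracting the mean AI over
  baseline-phase probes.

The synthetic EC force model generates `measured = AI_true × b·v_y + noise`
on a minimum-jerk reach to a target 12 cm straight ahead, sampled at 1 kHz.
The channel spring/damper constants (6,000 N/m, 7.5 Ns/m) are carried in
`ChannelSpec` for fidelity but do not enter the AI computation, which never
needs them.

## Hierarchical Bayesian estimation

Each participant's six parameters (Rf, Rs, Lf, Ls, σ_state, σ_output) have
group-level priors: truncated normals on [0, 1] for the rates, normals
truncated to > 0 for the noise SDs, each with group mean μ and SD σ.
Hyperpriors: rate group means are truncated normals on [0, 1] with
(mean, SD) = (0.85, 0.5) for Rf, (0.998, 0.01) for Rs, (0.1, 0.5) for Lf
and Ls — the retention-mean hyperpriors deliberately informative to aid
convergence (a less-informative variant is available via
`HierarchicalPriorConfig.less_informative()`); all group SDs have
half-Cauchy(0, 0.5) hyperpriors and the noise group means half-Cauchy(0, 1).
The two groups of a comparison are fitted independently with identical
priors.  A single σ_state is shared by the fast and slow state noise, the
ordering constraints are imposed as support restrictions on the joint
density (the ordering-region normalisation constant, which depends weakly
on the hypers, is omitted), and the likelihood is evaluated only at EC
probes — the only trials on which the AI exists.

### Exact marginal likelihood

The dynamics are linear-Gaussian, so instead of sampling per-trial latent
noise we integrate it out exactly with a Kalman filter.  Folding the error
feedback into the transition matrix, on field/null trials

    x(n+1) = A x(n) + L f(n) + w(n),   A = [[Rf−Lf, −Lf], [−Ls, Rs−Ls]],
    Cov w  = σ_state² I + σ_output² L Lᵀ,

(the output noise enters the state update through the error), while on EC
trials A = diag(Rf, Rs) and Cov w = σ_state² I.  Observations y = xf + xs +
ε_output occur at EC probes, where the output noise does not enter the
dynamics, so process and observation noise remain uncorrelated and the
standard filter applies.  The implementation is verified in the test suite
against a brute-force joint-Gaussian construction of the probe observations
(agreement ~1e-14).

### Sampler

No probabilistic-programming backend is used; the sampler is an adaptive
random-walk Metropolis-within-Gibbs scheme written for this model
(numba-compiled):

* one 6-dimensional block per participant, updated against the Kalman
  likelihood and its conditional priors, with Haario-style empirical-
  covariance proposals and Robbins–Monro scale tuning toward ~27%
  acceptance;
* one 2-dimensional block per (μ, σ) hyperparameter pair (cheap — no
  likelihood);
* two *group moves* per sweep: a joint translation of one parameter's μ and
  all its participant values, or a joint rescaling of its σ and the
  participant values about μ (with the s^(P+1) Jacobian).  These moves break
  the funnel-shaped coupling between group SDs and participant values that
  otherwise throttles mixing of the hyper-SDs.

All adaptation happens during warmup and is frozen afterwards, so the kept
draws come from a valid fixed-kernel Markov chain.  Chains are seeded
deterministically from the fit seed; identical configurations reproduce
identical draws.

Profiles: `full` = 4 chains × 25,000 kept iterations after 3,000 warmup,
no thinning (the published chain settings; ~30 s for 20 participants on one
CPU); `reduced` = 4 × 10,000 after 2,000 warmup, used in tests.  The
reduced profile keeps a longer warmup fraction than the full one because
adaptive random-walk chains need a few thousand iterations to tune proposal
covariances.  On recovery cohorts the full profile yields hyperparameter
R̂ ≤ ~1.02 and bulk ESS in the hundreds-to-thousands, in the same range as
the published diagnostics.  The sampler was additionally cross-checked
against an independent affine-invariant ensemble sampler (emcee) on the
identical joint log-density of a small cohort; both gave the same
posterior.

Diagnostics use the modern split-chain rank-normalised R̂ and bulk ESS
(via arviz); MCSE is posterior SD / √ESS.

## Synthetic cohorts and the recovery experiment

`GroupSpec` draws each participant's parameters from truncated normals
(rates on [0, 1], noise SDs on (0, ∞)), redrawing until the orderings hold;
observed data are the noisy outputs y at EC probes of a stochastic
simulation.  The default recovery experiment (`recovery_dataset`) draws 20
participants from a spec whose means and SDs are the pooled group-level
posterior estimates of the published fits, e.g. mean Rf = 0.843 with
across-participant SD 0.053, mean σ_output = 0.101 with SD 0.050.

What this generator emulates: per-participant AI time courses with the
study's schedule, realistic parameter heterogeneity and trial-level state
and output noise.  What it does not emulate: kinematic artefacts (trial
exclusions, partial reaches), non-Gaussian or serially dependent
measurement noise, session effects (fatigue, attention drift), and any
model misspecification — real participants adapt somewhat faster than the
dual-rate model implies.  Passing recovery tests therefore demonstrates the
estimation machinery, not the model's adequacy for real behaviour.

### What recovery accuracy to expect

With these generative ranges the per-participant data are only weakly
informative about Rf (posterior SD ≈ 0.05–0.08): the recovery MAE for Rf
lands at 0.03–0.09 depending on the cohort draw, which is the Bayes floor —
MAE ≈ 0.8 × posterior SD with ~90% central-interval coverage, exactly what
a calibrated posterior gives.  Tighter published recovery figures for the
fast process are attainable only if the artificial participants are drawn
with less dispersion or less output noise than the pooled group-level
ranges imply; the slow process (Rs, Ls), by contrast, recovers to ~1e-3
because 420 trials constrain it strongly.  The noise SDs recover to
~5e-3 (σ_state) and ~1e-2 (σ_output).

## Group comparison

Decisions about group differences use the posterior of the difference of
the group-mean hyperparameters (group A − group B), formed by pairing
equal numbers of pooled post-warmup draws from the two independent fits.
The ROPE half-width is 0.1·√((σ₁² + σ₂²)/2) where σ₁², σ₂² are the
variances of the two groups' posteriors of that hyperparameter.  The 95%
HDI of the difference inside the ROPE ⇒ "no difference"; disjoint from the
ROPE ⇒ "difference"; otherwise the decision is withheld.  Because the ROPE
is proportional to the posterior spread, tight posteriors make "no
difference" a demanding verdict — in practice most non-differing rates are
withheld rather than accepted as equivalent, matching the published
pattern.  Report tables use 90% HDIs; decisions use 95%.

Phase-wise AI comparisons use per-participant means over the last 15 EC
trials of the CW block, the last 3 of the CCW block, and the first 12 of
the final EC block.  Although the original description calls the
between-group comparisons paired t tests, the groups are independent and
the printed degrees of freedom (e.g. 39 for 20 + 21 participants) match
independent-samples tests; `two_sample_test` therefore implements the
independent test, pooled (Student) or Welch — Welch by default, since
fractional printed dfs elsewhere indicate it was used for unequal-variance
cases.

## Numerical choices and degenerate inputs

* HDI: shortest contiguous interval on sorted draws; rejects < 2 samples.
* Kalman filter guards against underflowing innovation variances (returns
  −inf rather than NaN); NaN Metropolis ratios are rejected, and a chain at
  an invalid state accepts the first valid proposal.
* `DualRateParams` enforces the orderings strictly; boundary dynamics
  (R = 1, L = 0) needed by oracle tests bypass validation explicitly via
  `DualRateParams.unchecked`.
* `fixed_point_oracle` solves (I − A)x* = L f and rejects spectral radius
  ≥ 1.
* Truncated-normal draws use scipy's `truncnorm`; ordering redraws are
  bounded (1,000 attempts) so degenerate specs fail loudly.
* Zero-variance degenerate cases (all-equal samples, zero-width HDIs,
  zero-noise simulations) are handled explicitly and tested.

## Known limitations

* The sampler is tuned for this model family; very small cohorts (n < 4)
  leave the hyper-SDs prior-dominated and slow to mix.
* The likelihood marginalises the latent states, so per-trial state
  trajectories are not part of the posterior; the posterior predictive
  regenerates them by simulation instead.
* Seed-reproducibility holds within a fixed numba/numpy version, not
  across versions.
* The deterministic two-parameter-set simulation and all synthetic
  validation operate in AI units; no claim is made about force units
  beyond the linear Eq.-level mapping used for AI extraction.
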