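# reachadapt

Dual-rate state-space modelling of force-field reach adaptation, with
hierarchical Bayesian inference and ROPE-based group comparison.

## The scientific problem

In a spontaneous-recovery paradigm, participants reach to a target while a
robot applies a velocity-dependent curl force field: a long clockwise (CW)
block, a brief counter-clockwise (CCW) block, then a block of error-clamp
(EC) trials in which the hand is constrained to a straight channel.  The
lateral force pressed into the channel wall, regressed against the force
the field would have produced, gives the **adaptation index (AI)** — the
fraction of ideal compensation.  After the CCW block drives the AI back
through zero, it rebounds toward the first-learned CW direction during the
EC block ("spontaneous recovery"), the signature of two adaptive processes
with different timescales.

The **dual-rate model** formalises this: net adaptation is the sum of a
fast state (learning rate `Lf`, retention `Rf`) and a slow state (`Ls`,
`Rs`),

```
y(n)    = xf(n) + xs(n) + ε_output
e(n)    = f(n) − y(n)               (0 on error-clamp trials)
xf(n+1) = Rf·xf(n) + Lf·e(n) + ε_f
xs(n+1) = Rs·xs(n) + Ls·e(n) + ε_s
```

with `0 < Rf < Rs < 1`, `0 < Ls < Lf < 1`, and `f ∈ {−1, 0, +1}` coding
the field direction in AI units.  Fitting this model hierarchically — each
participant's parameters drawn from group-level truncated normals, which
have their own hyperpriors — lets a clinical group (e.g. early-stage
Alzheimer's patients, whose fast, declarative-like process is hypothesised
to be affected) be compared with controls on the group-mean
hyperparameters via an HDI + ROPE decision rule.

This package is for researchers who want to run that whole analysis —
simulate the paradigm, extract AIs from trial-level force traces, fit the
hierarchical model, check convergence and posterior predictions, and make
group comparisons — on their own or on synthetic data, without any
probabilistic-programming toolchain: the likelihood is an exact
Kalman-filter marginal of the linear-Gaussian dynamics and the sampler is
a purpose-built adaptive blockwise Metropolis scheme (numba-compiled, a
full 4 × 25,000-iteration fit of 20 participants takes ~30 s on one CPU).

## Worked example

Deterministic simulation with the published two-parameter-set comparison
(`Ls=0.0169, Lf=0.0649, Rs=0.9967`; fast retention `Rf=0.9092` control-like
vs `0.7765` patient-like, all noise zero):

```python
import reachadapt as ra

sch = ra.build_schedule()           # 100 null + 240 CW + 30 CCW + 50 EC
for g in ["control", "patient"]:
    sim = ra.simulate(ra.DualRateParams.fig6(g), sch)
    print(g, "end-CW x=%.3f  end-CCW x=%.3f  final x=%.3f"
          % (sim.loc[339, "x"], sim.loc[369, "x"], sim.loc[419, "x"]))
```

```
control end-CW x=0.805  end-CCW x=-0.273  final x=0.179
patient end-CW x=0.800  end-CCW x=-0.059  final x=0.173
```

Both parameter sets plateau at the same CW level (~0.80) and converge to
the same spontaneous-recovery level (~0.17), but at the end of the CCW
block the control-like set is strongly negative (−0.27, it re-adapted to
the opposing field) while the patient-like set sits near zero (−0.06) —
the behavioural fingerprint of a lower fast-process retention rate.

Hierarchical fit of a synthetic 20-participant cohort and parameter
recovery:

```python
cohort = ra.recovery_dataset(20, seed=1)       # truth retained
model = ra.HierarchicalDualRate.from_cohort(cohort)
res = model.fit(profile="full", seed=1000001)  # 4 chains x 25,000
print(res.summary().head(4).round(4).to_string(index=False))
print(res.parameter_recovery(cohort).round(4).to_string())
```

```
parameter   mean  hdi_low  hdi_high
    Rf_mu 0.8614   0.7691    0.9846
    Rf_sd 0.1789   0.0727    0.2732
    Rs_mu 0.9977   0.9960    1.0000
    Rs_sd 0.0035   0.0012    0.0059
Rf              0.0605
Rs              0.0013
Lf              0.0143
Ls              0.0024
sigma_state     0.0070
sigma_output    0.0097
```

The summary rows are the group-level posterior means and 90% HDIs; the
second block is the mean absolute error between each participant's
posterior-mean parameters and the generative truth.  The slow process is
pinned to ~1e-3 by 420 trials of data; the fast retention rate is
intrinsically harder (per-participant posterior SD ≈ 0.05–0.08 under these
generative ranges), so its MAE sits at a few times 1e-2 — see
`docs/methods.md` for why that is the calibrated-Bayes floor.

Group comparison: `ra.compare_groups(res_a, res_b)` returns one ROPE
decision (`difference` / `no_difference` / `withheld`) per rate parameter,
using the 95% HDI of the difference of group-mean hyperparameters against
a ROPE of ±0.1·√((σ₁²+σ₂²)/2).

The same pipeline is scriptable from the shell:

```
reachadapt simulate --n 20 --seed 1 --out runs/sim
reachadapt fit --data runs/sim/observations.csv --profile full --seed 2 --out runs/fit
reachadapt diagnose --fit-dir runs/fit
reachadapt compare --fit-a runs/fitA/draws.csv --fit-b runs/fitB/draws.csv --out runs/cmp
```

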