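# saccrace

Why is the reaction time (RT) of a saccade to a lone, unambiguous target so
variable? `saccrace` implements a mechanistic answer: a two-accumulator
competition model of the frontal eye field (FEF) in which the stimulus-driven
motor plan races an incipient, internally driven plan toward a shared
threshold, together with the single-neuron spike-train analysis pipeline used
to test that model, and a synthetic-session generator that ties the two
together. It is aimed at computational/systems neuroscientists studying
rise-to-threshold dynamics, reward-biased saccade tasks, and single-trial
analyses of motor preparation.

## The model

Each trial of the one-direction-rewarded (1DR) task is a race between the
target-driven activity A_T(t) and the internally driven activity A_D(t)
toward the opposite location. Baselines are drawn per trial as
B = ⟨B⟩·[1 + σε]₊ (σ = 0.28, corr(ε_T, ε_D) = −0.5), with the higher mean
baseline at the rewarded location. The baselines then fix the trial's
threshold Θ = [1.185 + 1.2(B_T − B_D)]₀.₇₃ and build-up rates:

- G_D = 0.001·[1.4 + 1.7(B_D − B_T)]₊
- G_T = 0.001·(6.16 + 0.55η + 2.5B_T) when B_T ≥ B_D, and
  G_T = 0.001·(3.0 + 0.3η + 23.25B_T)/(1 + 1.3B_D) otherwise.

Plans rise after afferent delays (35/50 ms); an abrupt-onset inhibition
window ([40, 155] ms, 38% of G_D) transiently suppresses the internal plan;
two latched rules resolve the conflict (the leader either silences the
chaser or caps it); the first plan at Θ triggers the saccade and defines the
RT. Only ε_T, ε_D, η vary across trials — most RT variance is a
deterministic consequence of the baseline state. The target plan also
decomposes exactly into a baseline-coupled and a baseline-uncoupled
component, A_T = A_T^U + A_T^C, whose mixing offset α generates the
fast- vs. slow-preferring heterogeneity of single FEF cells.

The analysis layer provides spike density functions (unit-area Gaussian,
σ = 15 ms), per-trial response metrics (baseline/mean/presaccadic rates,
peak response and timing law Tp = β0 + β1·RT, onset and build-up rate),
RT-quantile trace families, activity maps, Spearman correlations,
permutation tests, RT distribution matching, and visuomotor classification.
See `docs/methods.md` for conventions and design choices.

## Worked example

```python
import numpy as np
from saccrace import ModelParams, BaselineDraw, simulate_trial, simulate_condition

params = ModelParams()

# one fully deterministic trial: congruent means, no noise
trace, outcome = simulate_trial(BaselineDraw(BT=0.34, BD=0.16,
                                             eps_T=0, eps_D=0, eta=0), params)
print(f"winner={outcome.winner} rt={outcome.rt_ms:.0f} ms "
      f"theta={trace.theta:.3f} rule1@{trace.rule1_time:.0f} ms")

# 20,000 incongruent trials
table, summary = simulate_condition(params, "incongruent", 20_000,
                                    np.random.default_rng(1))
c = summary["correct"]
print(f"errors={summary['error_pct']:.1f}%  "
      f"correct RT {c['mean']:.0f}+/-{c['sd']:.0f} ms  "
      f"incorrect median {summary['incorrect']['median']:.0f} ms")
```

prints

```
winner=T rt=148 ms theta=1.401 rule1@36 ms
errors=9.6%  correct RT 278+/-132 ms  incorrect median 235 ms
```

The deterministic congruent trial crosses its (high) threshold at 148 ms:
the target plan overtakes the internal plan one step after its afferent
delay, suppresses it, and rises at the winner rate. The incongruent
condition produces ~10% incorrect saccades, slower and wider correct RTs,
and error RTs whose median sits between the congruent and incongruent
correct medians — errors are neither the fastest nor the slowest responses.

Synthetic recording sessions and the analysis pipeline compose the same
way:

```python
from saccrace import SessionPlan, make_population, synthesize_session, pipeline

rng = np.random.default_rng(7)
session = synthesize_session(make_population(60, rng), SessionPlan(), params, rng)
metrics = pipeline.neuron_trial_metrics(session)        # Rb, Rp, RBU, ... per trial
corr = pipeline.neuron_correlations(metrics)            # Spearman rho per neuron
```

A command-line interface mirrors these stages:
`saccrace simulate|synth|analyze|report --seed S --out PATH ...`
(all outputs are tab-delimited tables with JSON sidecars recording seeds
and parameters).

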