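# Methods

## The competition model

A saccade in the one-direction-rewarded (1DR) task is modeled as a race
between two motor plans in frontal eye field (FEF): a target-driven plan
with activity `A_T(t)` toward the stimulus location T, and an internally
driven plan `A_D(t)` toward the diametrically opposite location D. All
activities are in normalized units (threshold crossings occur around 1);
time is in milliseconds with the go signal at t = 0.

Per trial, three random numbers determine everything. Correlated Gaussian
samples `eps_T, eps_D` (correlation −0.5) set the baselines

    B_x = <B_x> · max(1 + σ·eps_x, 0),        σ = 0.28,

with the higher mean (0.34 vs. 0.16) assigned to the rewarded location:
congruent trials give T the higher mean, incongruent trials give it to D.
A third sample `η` adds intrinsic noise to the target plan's build-up
rate. The baselines then fix the trial's threshold and gains:

    Θ   = max(1.185 + 1.2·(B_T − B_D), 0.73)
    G_D = 0.001 · max(1.4 + 1.7·(B_D − B_T), 0)
    G_T = 0.001 · (6.16 + 0.55·η + 2.5·B_T)                    if B_T ≥ B_D
    G_T = 0.001 · (3.0 + 0.3·η + 23.25·B_T) / (1 + 1.3·B_D)    otherwise

The two G_T regimes are chosen once per trial from the baselines. Plans
start at their baselines and rise after afferent delays (A_T from 35 ms,
A_D from 50 ms); A_D is additionally suppressed to 38% of G_D inside the
stimulus-driven inhibition window [40, 155] ms. Two latched rules resolve
the conflict: once A_T strictly exceeds A_D (after 35 ms), D is frozen and
T switches to the winner rate `V_Twin = −0.0088 + 2.6·G_T` (Rule 1); once
A_D strictly exceeds A_T outside the inhibition window (after 50 ms), A_T
is clamped to never exceed A_D (Rule 2). The first plan at Θ wins; both
plans then relax exponentially toward 0.2 with τ = 120 ms.

### Integration conventions

Forward Euler with Δt = 1 ms. At each grid time, in order: threshold check
on current values (crossing time = first sample ≥ Θ); rule evaluation with
strict inequalities (an exact tie triggers nothing); rate schedule; update.
Rule 2's clamp is an exact ceiling, `A_T ← min(A_T, A_D)`, applied after
the update. When both plans reach Θ on the same sample the latched rule
decides the winner (under Rule 2 the target may touch but never pass the
leader, so D wins such joint crossings; under Rule 1, T). Races are capped
at 1000 ms — double the task's 500 ms response deadline — and uncrossed
races are recorded as explicit omissions rather than retried, so their
frequency remains observable. These conventions make the trajectories
piecewise linear, and the test suite checks the stepper against an
independent event-driven closed-form integration on a bank of baseline
triples spanning both regimes, both rules, the threshold floor, and an
omission.

### Decomposition of the target plan

The target build-up rate splits as `G_T = f1 + φ + f2·B_T`, where `f1` is
the baseline-independent constant, `φ` the η term, and `f2·B_T` the
baseline-coupled term (in regime 2 the divisive factor applies to all
three). For any offset α,

    G_U = α·f1 + f1 + φ        (uncoupled component)
    G_C = −α·f1 + f2·B_T       (coupled component)

sum to G_T exactly. Both component trajectories start at B_T/2, share the
parent's delays and rule-change times, and sum to A_T(t) at every sample.
Two points were genuinely open and were resolved as follows:

- **Winner-phase allocation.** After Rule 1 the parent runs at V_Twin; each
  component is slowed by the parent's factor `V_Twin/G_T`. This keeps a
  positive-rate component rising until the crossing (its peak stays at the
  saccade) and sums exactly to V_Twin. If G_T is numerically zero the
  constant is split equally instead.
- **Clamp and postsaccadic relaxation.** Trajectory-level corrections that
  are not expressible as component rates (Rule 2's clamp, the decay toward
  0.2) are split equally between the components, mirroring the equal split
  of the baseline. After the race the U−C difference is therefore held
  fixed and both components inherit the parent's relaxation.

The sum identity holds to machine precision by construction for any α;
the acceptance suite verifies it on 1000 random trials at α ∈ {−2…2}.

## Spike-train analysis

The analysis layer implements the standard single-neuron procedures on
trial-structured spike data (times in ms relative to go):

- **Spike density function (SDF):** sum of unit-area Gaussians, σ = 15 ms,
  in spikes/s; no edge renormalization. Bulk traces use 1-ms binning plus
  Gaussian filtering, equivalent up to the binning discretization.
- **Per-trial metrics:** baseline rate Rb over [−250, 0); mean rate Rm over
  [0, RT); presaccadic rate Rsac over [RT−70, RT−50); peak response Rp =
  spike count in a 100 ms window centered on Tp = β0 + β1·RT divided by the
  window (truncated windows use the covered duration); onset (Ton, Ron)
  and build-up rate RBU = (Rp − Ron)/(Tp − Ton).
- **Onset detection:** the published per-trial latency method is external,
  so a stand-in is used: the earliest time in (0, Tp] at which the trial's
  SDF exceeds its baseline mean + 3 SD and stays above for ≥ 20 ms
  (both configurable). A silent baseline makes that rule degenerate; the
  detector then falls back to the half-rise point of the evoked excursion.
  Trials with no onset are excluded from RBU.
- **Timing fit:** Tmax (SDF argmax after go) regressed on RT by ordinary
  least squares over all saccade-into-RF trials, pooling bias conditions;
  the slope β1 is the visuomotor index (V < 0.46 ≤ VM ≤ 0.85 < M; cells
  with β1 < 0.1 are excluded from motor-pool analyses; only the V cutoff is
  empirically anchored, the M cutoff is a package default).
- **RT-quantile families:** 20 overlapping bins, each holding the 20% of
  trials whose RT ranks are nearest to centers spaced evenly from the 10th
  to the 90th percentile; ties broken by trial index.
- **Statistics:** Spearman rank correlations (mid-rank ties) via scipy;
  permutation tests for paired (sign flips) or unpaired (label shuffles)
  mean differences, enumerated exhaustively when the group is no larger
  than the permutation budget, otherwise Monte Carlo with the p value
  floored at 1/n_perm and reported as a bound.
- **RT matching:** every trial of condition A is probed once in random
  order; the nearest-RT remaining B trial is accepted if |ΔRT| < 15 ms and
  both are removed. Matched statistics are averaged over repetitions
  (slopes are averaged across repetitions before differencing — averaging
  |difference| would carry an upward noise bias).

## Synthetic sessions

The generator exists so that every analysis stage is testable without
recordings. Its defaults are the study conditions: 60 neurons, 2000 trials,
blocks of 40–100 trials alternating the rewarded location, target drawn
uniformly between the two locations, and the first 8 trials of each 1DR
block discarded downstream.

Per trial the race model supplies the outcome, RT, and both trajectories.
A neuron whose response field contains the target follows the target plan;
otherwise it follows the internally driven plan. Rates are the normalized
trajectories times a per-neuron maximum rate (40–100 spikes/s), held at the
drawn baseline before the go signal, and spikes are drawn by per-ms
Bernoulli thinning (an inhomogeneous Poisson process at these rates; a
configuration whose rate·Δt exceeds 1 raises an error instructing
rescaling).

Three constructions connect neuron heterogeneity to the model; all are
artifact plumbing, not claims about FEF:

- **RT preference (α).** Target-side neurons with α < 0 follow the coupled
  component (fast-preferring) and α > 0 the uncoupled one
  (slow-preferring), computed with offset |α| and doubled to restore the
  parent's scale. The correspondence between components and cell types
  holds when the target plan starts from behind (regime 2); in regime-1
  trials intrinsic noise dominates and every neuron follows the full plan.
  α is drawn Gaussian (mean −0.25, SD 0.35) clipped to [−0.9, 0.5]: the
  negative mean and asymmetric clip reproduce the mild fast-preferring
  dominance of FEF and the reported observation that slow-preferring
  modulation is mostly modest, and keep component rates non-negative on
  almost all trials.
- **Response timing (β0, β1).** A neuron's rate follows the plan's own
  rise, with its excursion above baseline amplified by a fixed per-neuron
  gain `1 + 2·(1 − β1)`, until the peak time Tp = β0 + β1·RT (plus 10 ms
  Gaussian per-trial jitter), then relaxes toward the resting level with
  τ = 120 ms. Truncation-with-gain, rather than a time warp, was chosen
  because compressing a slow trajectory into a fixed early peak steepens
  its rise artificially, inverting build-up-rate comparisons across
  conditions, whereas a stimulus-locked cell reading the plan out partially
  preserves slope ratios exactly. β1 is uniform on [0, 1.1] and β0 follows
  the printed archetypes (visual ≈ (80, 0); movement ≈ (−30, 1)) via a
  linear trend with 10 ms jitter.
- **Saturation.** Normalized activity is capped at 6 before rate scaling;
  decomposition components can exceed the parent's range for large |α| and
  long winner phases, and real firing rates saturate.

### What the generator does not emulate

No eye kinematics, four-location geometry, local field potentials,
refractoriness or bursting, sequential/block-transition effects, or any
non-Poisson count statistics. Passing pipeline tests on these sessions
shows that the analysis code recovers structure the model puts in; it does
not validate the model against biology, and effect sizes measured here
(e.g. correlation magnitudes) are attenuated relative to what noiseless
trajectories would give, because single-trial peak and onset estimation on
Poisson spikes is noisy.

## Problem sizes and numerical choices

Simulated error rates and RT-distribution properties use 20,000 trials per
condition. The pipeline-recovery checks run one 60-neuron × 2000-trial
session; the RT-matched build-up comparison uses the go-aligned population
slope over [50, 120] ms and 10 matching repetitions, which is where the
repetition average stabilizes at this session size. Parameter recovery
inverts the clipped-normal moment equations (Brent root-finding on the
relative variance) from 10,000 one-second baseline-epoch measurements,
after subtracting the Poisson counting variance. Random draws everywhere
go through `numpy.random.Generator` seeded explicitly; identical seeds
give bit-identical outputs.

## Known limitations

- The race stepper is O(RT) per trial in Python; 20,000 trials take a few
  seconds. This is deliberate — a single code path for traces and bulk
  outcomes — rather than a vectorized twin implementation that could drift.
- The onset stand-in is not the published latency estimator; RBU values are
  comparable within this package but not across implementations.
- With two locations only, adjacent-reward configurations of the task
  cannot be represented; incongruent means diametrically opposite.
- The ADR variant's reduced baseline variability and reduced maximal drive
  are unprinted values; the defaults (0.18, 5.8) are labeled package
  defaults in the configuration.
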