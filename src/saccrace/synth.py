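"""Synthetic FEF recording sessions driven by the competition model.

A session couples (a) trial outcomes and reaction times simulated by the
race model with (b) per-neuron spike trains generated as inhomogeneous
Poisson processes (per-ms Bernoulli thinning) whose underlying rates follow
the model trajectories, scaled per neuron. Neurons are heterogeneous in
response timing (beta0, beta1: peak time Tp = beta0 + beta1*RT) and in
RT preference (alpha: the mixing offset of the coupled/uncoupled
decomposition of the target plan). The geometry is two diametrically
opposite locations; each neuron's response field (RF) sits at one of them.

The spike-generation mapping (normalized activity x per-neuron max rate,
truncation of the trajectory at the neuron's peak time with a fixed
excursion gain for stimulus-locked cells) is a construction of this
package; only the trial outcomes, RTs, and rate trajectories come from the
model.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import decompose_target_plan, draw_baselines, simulate_trial
from .params import ModelParams

__all__ = [
    "NeuronSpec",
    "SessionPlan",
    "Session",
    "make_population",
    "synthesize_session",
    "trs_code",
    "recover_baseline_params",
]

FORMAT_VERSION = 1


@dataclass(frozen=True)
class NeuronSpec:
    """One synthetic neuron.

    ``rf_loc`` is the location index (0 or 1) of the response field.
    ``alpha`` sets the RT preference: negative values select the
    baseline-coupled (fast-preferring) component of the target plan,
    positive values the uncoupled (slow-preferring) component, with |alpha|
    controlling the modulation strength.
    """

    id: int
    rf_loc: int
    beta0: float
    beta1: float
    alpha: float
    max_rate: float
    baseline_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.max_rate <= 0:
            raise ValueError("max rate must be positive")
        if not 0.0 <= self.beta1 <= 1.2:
            raise ValueError("beta1 must lie in [0, 1.2]")


@dataclass(frozen=True)
class SessionPlan:
    """Block structure and scale of one synthetic recording session.

    Blocks alternate the rewarded location pseudorandomly; target location
    is drawn uniformly per trial, so roughly half the 1DR trials are
    congruent. ``adr_frac`` blocks (by count) use the equal-reward task.
    Block lengths are drawn uniformly from ``block_len_range`` (the task's
    blocks averaged ~70 trials).
    """

    n_trials: int = 2000
    block_len_range: tuple[int, int] = (40, 100)
    adr_frac: float = 0.0
    pre_go_ms: float = 300.0
    post_go_ms: float = 200.0
    beta0_jitter_ms: float = 10.0
    # saturation ceiling on normalized activity before rate scaling;
    # decomposition components can exceed the parent's range for large
    # |alpha|, and real firing rates saturate
    activity_ceiling: float = 6.0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.block_len_range[0] < 1:
            raise ValueError("block lengths must be >= 1")


def make_population(
    n_neurons: int,
    rng: np.random.Generator,
    beta1_range: tuple[float, float] = (0.0, 1.1),
    beta0_slope: float = -110.0,
    beta0_intercept: float = 80.0,
    beta0_sd: float = 10.0,
    alpha_mean: float = -0.25,
    alpha_sd: float = 0.35,
    alpha_clip: tuple[float, float] = (-0.9, 0.5),
    max_rate_range: tuple[float, float] = (40.0, 100.0),
    fixed: Optional[dict] = None,
) -> list[NeuronSpec]:
    """Draw a heterogeneous roster of synthetic neurons.

    beta1 (the visuomotor index) is uniform over ``beta1_range``; beta0 is
    anchored to the visual-like (beta1=0 -> ~80 ms) and movement-like
    (beta1=1 -> ~-30 ms) archetypes via a linear trend plus jitter. alpha
    is Gaussian with a negative mean and an asymmetric clip: fast-preferring
    (negative) modulation spans the full strength range while slow-preferring
    (positive) modulation stays modest, the asymmetry characteristic of FEF.
    ``fixed`` pins any NeuronSpec field to a constant
    (e.g. ``{"beta0": 80, "beta1": 0}``).
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    fixed = fixed or {}
    specs = []
    for i in range(n_neurons):
        b1 = float(rng.uniform(*beta1_range))
        b0 = beta0_intercept + beta0_slope * b1 + rng.normal(0.0, beta0_sd)
        spec = dict(
            id=i,
            rf_loc=i % 2,
            beta0=float(b0),
            beta1=b1,
            alpha=float(np.clip(rng.normal(alpha_mean, alpha_sd), *alpha_clip)),
            max_rate=float(rng.uniform(*max_rate_range)),
            baseline_scale=1.0,
        )
        spec.update(fixed)
        specs.append(NeuronSpec(**spec))
    return specs


@dataclass
class Session:
    """In-memory synthetic dataset: roster, trial table, spike trains."""

    neurons: pd.DataFrame
    trials: pd.DataFrame
    spikes: dict  # (neuron_id, trial) -> np.ndarray of spike times (ms)
    plan: SessionPlan
    params: ModelParams
    seed_info: dict = field(default_factory=dict)

    def spike_train(self, neuron_id: int, trial: int) -> np.ndarray:
        return self.spikes[(neuron_id, trial)]

    def to_dir(self, path) -> None:
        """Write the documented text layout: neurons.tsv, trials.tsv,
        spikes.tsv (long format), session.json."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.neurons.to_csv(path / "neurons.tsv", sep="\t", index=False)
        self.trials.to_csv(path / "trials.tsv", sep="\t", index=False)
        rows = []
        for (nid, tid), tr in self.spikes.items():
            for t in tr:
                rows.append((nid, tid, t))
        pd.DataFrame(rows, columns=["neuron_id", "trial", "time_ms"]).to_csv(
            path / "spikes.tsv", sep="\t", index=False
        )
        meta = {
            "format_version": FORMAT_VERSION,
            "plan": asdict(self.plan),
            "params": self.params.to_dict(),
            **self.seed_info,
        }
        with open(path / "session.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def from_dir(cls, path) -> "Session":
        path = Path(path)
        with open(path / "session.json") as fh:
            meta = json.load(fh)
        plan_d = meta["plan"]
        plan_d["block_len_range"] = tuple(plan_d["block_len_range"])
        neurons = pd.read_csv(path / "neurons.tsv", sep="\t")
        trials = pd.read_csv(path / "trials.tsv", sep="\t")
        long = pd.read_csv(path / "spikes.tsv", sep="\t")
        spikes = {
            (int(n), int(t)): g["time_ms"].to_numpy()
            for (n, t), g in long.groupby(["neuron_id", "trial"])
        }
        # trials without spikes still need entries
        for nid in neurons["id"]:
            for tid in trials["trial"]:
                spikes.setdefault((int(nid), int(tid)), np.empty(0))
        return cls(
            neurons=neurons,
            trials=trials,
            spikes=spikes,
            plan=SessionPlan(**plan_d),
            params=ModelParams.from_dict(meta["params"]),
            seed_info={k: meta[k] for k in meta if k == "seed"},
        )


def trs_code(rf_loc: int, target_loc: int, reward_loc: int, saccade_loc: int) -> str:
    """Target/Reward/Saccade in-vs-out-of-RF code, e.g. 'IOI'.

    ``reward_loc`` of -1 marks the equal-reward (ADR) task; its middle
    character is 'A'.
    """
    def io(loc):
        return "I" if loc == rf_loc else "O"

    mid = "A" if reward_loc == -1 else io(reward_loc)
    return io(target_loc) + mid + io(saccade_loc)


def _plan_blocks(plan: SessionPlan, rng: np.random.Generator):
    """Yield (block_idx, reward_loc, length) covering n_trials."""
    blocks = []
    total = 0
    loc = int(rng.integers(2))
    b = 0
    while total < plan.n_trials:
        length = int(rng.integers(plan.block_len_range[0], plan.block_len_range[1] + 1))
        length = min(length, plan.n_trials - total)
        is_adr = rng.random() < plan.adr_frac
        blocks.append((b, -1 if is_adr else loc, length))
        loc = 1 - loc  # rewarded location changes between 1DR blocks
        total += length
        b += 1
    return blocks


def _shape_rate(
    template: np.ndarray,
    rt_ms: float,
    tp_ms: float,
    gain: float = 1.0,
    decay_tau: float = 120.0,
    decay_level: float = 0.2,
) -> np.ndarray:
    """Give a plan trajectory a neuron-specific peak time.

    The neuron follows the plan's own rise, with its evoked excursion above
    baseline amplified by a fixed per-neuron ``gain``, until its peak time
    Tp; it then relaxes exponentially toward the postsaccadic resting
    level. An early Tp reads the plan out partially — the stimulus-locked
    transient of a visual cell — and the constant gain keeps such peaks
    salient without distorting slope ratios across trials or conditions.
    Tp is clamped to the rise interval.
    """
    n = len(template)
    i_rt = min(int(round(rt_ms)), n - 1)
    tp_i = int(np.clip(round(tp_ms), 20, i_rt))
    base = template[0]
    out = base + gain * (template - base)
    tail = np.arange(n - tp_i, dtype=float)
    out[tp_i:] = decay_level + (out[tp_i] - decay_level) * np.exp(-tail / decay_tau)
    return out


def synthesize_session(
    population: Sequence[NeuronSpec],
    plan: SessionPlan,
    params: ModelParams,
    rng: np.random.Generator,
) -> Session:
    """Generate a full synthetic session.

    Per trial: run the race model; record outcome and RT; give each neuron
    the target-plan trajectory (or its alpha-weighted component, doubled to
    restore the parent's scale) when the target is in its RF, and the
    internally driven trajectory otherwise; hold the pre-go rate at the
    drawn baseline; truncate the trajectory at the neuron's peak time
    beta0 + beta1*RT (plus per-trial jitter) and relax it thereafter;
    convert to spikes/s via the neuron's max rate and
    thin a per-ms Bernoulli process. Trials where no plan reaches threshold
    are flagged ``omitted`` and carry no spikes.
    """
    dt = params.dt
    if dt != 1.0:
        raise ValueError("spike synthesis assumes a 1 ms integration step")
    pre = int(round(plan.pre_go_ms))
    post = int(round(plan.post_go_ms))
    trial_rows = []
    spikes: dict = {}
    for b, reward_loc, length in _plan_blocks(plan, rng):
        for j in range(length):
            trial_rows.append([b, j, reward_loc])
    neurons_df = pd.DataFrame([asdict(s) for s in population])

    out_rows = []
    for tid, (b, j, reward_loc) in enumerate(trial_rows):
        target_loc = int(rng.integers(2))
        if reward_loc == -1:
            condition = "adr"
        elif target_loc == reward_loc:
            condition = "congruent"
        else:
            condition = "incongruent"
        eff = params.effective(condition)
        draw = draw_baselines(params, condition, rng)
        trace, out = simulate_trial(draw, eff, record=True, post_ms=post)
        omitted = out.winner == "none"
        if omitted:
            rt = math.nan
            saccade_loc = -9
        else:
            rt = out.rt_ms
            saccade_loc = target_loc if out.winner == "T" else 1 - target_loc
        out_rows.append(
            [
                tid, b, j, condition, target_loc, reward_loc, saccade_loc,
                out.winner, out.correct, rt, draw.BT, draw.BD, draw.eta,
                omitted,
            ]
        )
        if omitted:
            for spec in population:
                spikes[(spec.id, tid)] = np.empty(0)
            continue

        n_grid = len(trace.time)
        components: dict[float, np.ndarray] = {}
        for spec in population:
            if spec.rf_loc == target_loc:
                # negative alpha -> coupled component (fast-preferring),
                # positive -> uncoupled (slow-preferring); |alpha| sets the
                # strength by shifting constant drive out of / into the
                # component. Doubling restores the parent's scale after the
                # half/half baseline split. The component<->preference
                # correspondence holds when the target plan starts from
                # behind (regime 2); in regime-1 trials intrinsic noise
                # dominates and every neuron follows the full target plan.
                a = round(spec.alpha, 12)
                if trace.regime == 2 and a != 0.0:
                    if a not in components:
                        u, c = decompose_target_plan(trace, abs(spec.alpha))
                        components[a] = 2.0 * (c if spec.alpha < 0 else u)
                    template = components[a]
                else:
                    template = trace.a_t
                base_level = draw.BT
            else:
                template = trace.a_d
                base_level = draw.BD
            tp = spec.beta0 + spec.beta1 * rt + rng.normal(0.0, plan.beta0_jitter_ms)
            # stimulus-locked (low beta1) cells peak before the plan does;
            # a fixed excursion gain keeps those partial read-outs salient
            gain = 1.0 + 2.0 * max(1.0 - spec.beta1, 0.0)
            shaped = _shape_rate(
                template, rt, tp, gain, params.decay_tau, params.decay_level
            )
            rate = np.concatenate([np.full(pre, base_level), shaped])
            rate = (
                np.clip(rate, 0.0, plan.activity_ceiling)
                * spec.max_rate
                * spec.baseline_scale
            )
            p = rate * 1e-3  # spikes/s * 1 ms
            if np.any(p > 1.0):
                raise ValueError(
                    f"rate*dt exceeds 1 for neuron {spec.id}; rescale max_rate"
                )
            hits = rng.random(len(p)) < p
            times = (np.flatnonzero(hits) - pre) + rng.random(int(hits.sum()))
            spikes[(spec.id, tid)] = times

    trials = pd.DataFrame(
        out_rows,
        columns=[
            "trial", "block", "trial_in_block", "condition", "target_loc",
            "reward_loc", "saccade_loc", "winner", "correct", "rt_ms",
            "BT", "BD", "eta", "omitted",
        ],
    )
    return Session(
        neurons=neurons_df, trials=trials, spikes=spikes, plan=plan, params=params
    )


def baseline_epoch_rates(
    params: ModelParams,
    condition: str,
    side: str,
    n_trials: int,
    rng: np.random.Generator,
    max_rate: float = 100.0,
    window_ms: float = 1000.0,
) -> np.ndarray:
    """Synthetic baseline-epoch firing-rate measurements (spikes/s).

    Per trial, the fixation-epoch rate is the drawn baseline of ``side``
    ('T' or 'D') scaled by ``max_rate``; spikes follow the same per-ms
    Bernoulli thinning as full sessions, counted over ``window_ms``.
    """
    if side not in ("T", "D"):
        raise ValueError("side must be 'T' or 'D'")
    w = int(round(window_ms))
    rates = np.empty(n_trials)
    for i in range(n_trials):
        d = draw_baselines(params, condition, rng)
        b = d.BT if side == "T" else d.BD
        p = min(b * max_rate * 1e-3, 1.0)
        rates[i] = 1000.0 * rng.binomial(w, p) / w
    return rates


# ---------------------------------------------------------------------------
# Parameter recovery for the clipped-normal baseline model
# ---------------------------------------------------------------------------


def _clipped_moments(sigma: float) -> tuple[float, float]:
    """First two moments of max(1 + sigma*Z, 0), Z standard normal."""
    if sigma == 0:
        return 1.0, 1.0
    z = 1.0 / sigma
    cdf = stats.norm.cdf(z)
    pdf = stats.norm.pdf(z)
    m1 = cdf + sigma * pdf
    m2 = (1.0 + sigma**2) * cdf + sigma * pdf
    return m1, m2


def recover_baseline_params(
    rates: np.ndarray,
    max_rate: float,
    window_s: float,
) -> tuple[float, float]:
    """Recover (<B>, sigma) of the baseline law B = <B>*max(1+sigma*eps, 0)
    from measured baseline-epoch firing rates.

    Moment matching on the clipped-normal model: the Poisson counting
    contribution ``E[rate]/(window * max_rate^2)`` is subtracted from the
    variance of the normalized rates, and the remaining mean/variance pair
    is inverted for (<B>, sigma).
    """
    b = np.asarray(rates, dtype=float) / max_rate
    m = float(np.mean(b))
    v = float(np.var(b, ddof=1)) - m / (window_s * max_rate)
    if m <= 0 or v <= 0:
        raise ValueError("moments leave no room for baseline variability")
    target = v / (m * m)  # relative clipped variance, depends on sigma only

    def f(s: float) -> float:
        m1, m2 = _clipped_moments(s)
        return (m2 - m1 * m1) / (m1 * m1) - target

    sigma = float(optimize.brentq(f, 1e-6, 5.0))
    mean_b = m / _clipped_moments(sigma)[0]
    return mean_b, sigma
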