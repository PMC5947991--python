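"""Two-accumulator race model of saccadic reaction times.

Each trial is a race between a target-driven motor plan (activity A_T,
toward the stimulus location T) and an internally driven plan (A_D, toward
the diametrically opposite location D). Both start at baseline levels drawn
at fixation, rise toward a shared threshold after their afferent delays, and
interact through two latched conflict-resolution rules; the first plan to
reach threshold determines the saccade direction and the reaction time.

The target plan additionally admits an exact decomposition into a
baseline-coupled and a baseline-uncoupled component whose sum reproduces
A_T(t) at every sample; the mixing offset ``alpha`` tunes the components'
opposite reaction-time preferences without changing the race.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .params import ModelParams, _check_condition

__all__ = [
    "BaselineDraw",
    "TrialTrace",
    "TrialOutcome",
    "draw_baselines",
    "compute_threshold",
    "buildup_rate_distractor",
    "buildup_rate_target",
    "simulate_trial",
    "simulate_condition",
    "summarize_outcomes",
    "decompose_target_plan",
]


@dataclass(frozen=True)
class BaselineDraw:
    """Per-trial stochastic state: baselines and their generating samples."""

    BT: float
    BD: float
    eps_T: float
    eps_D: float
    eta: float

    def __post_init__(self) -> None:
        if self.BT < 0 or self.BD < 0:
            raise ValueError("baselines must be non-negative")


@dataclass
class TrialOutcome:
    winner: str  # 'T', 'D', or 'none'
    correct: bool
    rt_ms: float  # NaN when winner == 'none'


@dataclass
class TrialTrace:
    """Full record of one simulated race on the integration grid."""

    time: np.ndarray
    a_t: np.ndarray
    a_d: np.ndarray
    regime: int
    g_t: float
    g_d: float
    v_twin: float
    theta: float
    rule1_time: Optional[float]
    rule2_time: Optional[float]
    rt_index: Optional[int]  # grid index of the threshold crossing
    draw: BaselineDraw
    params: ModelParams


def draw_baselines(
    params: ModelParams, condition: str, rng: np.random.Generator
) -> BaselineDraw:
    """Draw the fixation-epoch state for one trial.

    (eps_T, eps_D) come from a bivariate standard normal with correlation
    ``params.baseline_corr``, realized through the fixed transform
    ``eps_D = c*z1 + sqrt(1-c^2)*z2`` of two independent draws so that seeds
    are portable. Baselines are B = <B> * max(1 + sigma*eps, 0); the build-up
    noise ``eta`` is an independent standard normal.
    """
    condition = _check_condition(condition)
    eff = params.effective(condition)
    mean_t, mean_d = params.condition_means(condition)
    c = eff.baseline_corr
    z1, z2 = rng.standard_normal(2)
    eps_t = z1
    eps_d = c * z1 + math.sqrt(1.0 - c * c) * z2
    sigma = eff.baseline_cv
    bt = mean_t * max(1.0 + sigma * eps_t, 0.0)
    bd = mean_d * max(1.0 + sigma * eps_d, 0.0)
    eta = float(rng.standard_normal())
    return BaselineDraw(BT=bt, BD=bd, eps_T=eps_t, eps_D=eps_d, eta=eta)


def compute_threshold(bt: float, bd: float, params: ModelParams) -> float:
    """Saccade threshold; grows with BT - BD but never below the floor."""
    raw = params.theta_intercept + params.theta_slope * (bt - bd)
    return max(raw, params.theta_floor)


def buildup_rate_distractor(bt: float, bd: float, params: ModelParams) -> float:
    """Nominal build-up rate of the internally driven plan (per ms)."""
    raw = params.gd_intercept + params.gd_slope * (bd - bt)
    return params.gd_scale * max(raw, 0.0)


def buildup_rate_target(
    bt: float, bd: float, eta: float, params: ModelParams
) -> tuple[float, int]:
    """Initial build-up rate of the target plan and the regime it is in.

    Regime 1 (BT >= BD): steep rise, weak dependence on BT, no opposition
    from the D plan. Regime 2 (BT < BD): rate depends strongly on BT and is
    divisively suppressed by BD. The regime is fixed once per trial from the
    baselines, before integration starts.
    """
    if bt >= bd:
        g = params.gt1_scale * (
            params.gt1_intercept + params.gt1_noise * eta + params.gt1_slope * bt
        )
        return g, 1
    num = params.gt2_intercept + params.gt2_noise * eta + params.gt2_slope * bt
    g = params.gt1_scale * num / (1.0 + params.gt2_div * bd)
    return g, 2


def simulate_trial(
    draw: BaselineDraw,
    params: ModelParams,
    record: bool = True,
    post_ms: float = 300.0,
) -> tuple[Optional[TrialTrace], TrialOutcome]:
    """Run one race by forward-Euler integration on the dt grid.

    Step order at each grid time t, operating on the current values:
    (1) threshold check (crossing time = first sample >= Theta);
    (2) rule evaluation — Rule 1 latches when t > afferent_T and A_T > A_D,
        fully suppressing D and switching T to the winner rate V_Twin;
        Rule 2 latches when t > afferent_D, t is outside the inhibition
        window, and A_D > A_T, after which A_T is clamped to never exceed
        A_D (a minimal, exact ceiling);
    (3) rate schedule — V_T = G_T once t >= afferent_T; V_D = inhib_gain*G_D
        while t >= afferent_D inside [inhib_on, inhib_off], G_D after;
    (4) Euler update. Both rules stay latched for the rest of the race.

    After the crossing both traces relax exponentially toward
    ``decay_level`` (recorded for ``post_ms`` when ``record``); a race that
    reaches ``trial_cap`` without a crossing is an omission
    (winner='none', rt NaN).
    """
    bt, bd = draw.BT, draw.BD
    theta = compute_threshold(bt, bd, params)
    g_d = buildup_rate_distractor(bt, bd, params)
    g_t, regime = buildup_rate_target(bt, bd, draw.eta, params)
    v_twin = params.win_intercept + params.win_slope * g_t

    dt = params.dt
    at, ad = params.afferent_T, params.afferent_D
    ion, ioff = params.inhib_on, params.inhib_off
    n_cap = int(round(params.trial_cap / dt))

    a_t, a_d = bt, bd
    rule1_time: Optional[float] = None
    rule2_time: Optional[float] = None
    winner = "none"
    rt_ms = math.nan
    rt_index: Optional[int] = None

    ts_t: list[float] = []
    ts_d: list[float] = []

    for i in range(n_cap + 1):
        t = i * dt
        if record:
            ts_t.append(a_t)
            ts_d.append(a_d)
        # (1) threshold
        hit_t = a_t >= theta
        hit_d = a_d >= theta
        if hit_t or hit_d:
            if hit_t and hit_d:
                # Joint crossings happen when one plan rides the other's
                # ceiling; the latched rule decides the winner (under Rule 2
                # A_T may touch but never pass A_D, so D wins the race).
                if rule2_time is not None:
                    winner = "D"
                elif rule1_time is not None:
                    winner = "T"
                else:
                    winner = "T" if a_t >= a_d else "D"
            else:
                winner = "T" if hit_t else "D"
            rt_ms = t
            rt_index = i
            break
        # (2) rules (strict inequalities; latched once triggered)
        if rule1_time is None and t > at and a_t > a_d:
            rule1_time = t
        if rule2_time is None and t > ad and not (ion <= t <= ioff) and a_d > a_t:
            rule2_time = t
        # (3) rate schedule
        if t < at:
            v_t = 0.0
        elif rule1_time is not None:
            v_t = v_twin
        else:
            v_t = g_t
        if rule1_time is not None or t < ad:
            v_d = 0.0
        elif ion <= t <= ioff:
            v_d = params.inhib_gain * g_d
        elif t > ioff:
            v_d = g_d
        else:
            v_d = 0.0
        # (4) update
        a_t += dt * v_t
        a_d += dt * v_d
        if rule2_time is not None and a_t > a_d:
            a_t = a_d

    if record and rt_index is not None:
        # postsaccadic relaxation, for reporting only; the race is over
        n_post = int(round(post_ms / dt))
        lam = dt / params.decay_tau
        for _ in range(n_post):
            a_t += lam * (params.decay_level - a_t)
            a_d += lam * (params.decay_level - a_d)
            ts_t.append(a_t)
            ts_d.append(a_d)

    outcome = TrialOutcome(winner=winner, correct=winner == "T", rt_ms=rt_ms)
    if not record:
        return None, outcome
    trace = TrialTrace(
        time=np.arange(len(ts_t), dtype=float) * dt,
        a_t=np.asarray(ts_t),
        a_d=np.asarray(ts_d),
        regime=regime,
        g_t=g_t,
        g_d=g_d,
        v_twin=v_twin,
        theta=theta,
        rule1_time=rule1_time,
        rule2_time=rule2_time,
        rt_index=rt_index,
        draw=draw,
        params=params,
    )
    return trace, outcome


def simulate_condition(
    params: ModelParams,
    condition: str,
    n_trials: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Simulate n independent trials of one bias condition.

    Returns a per-trial table (draws, winner, correct, rt_ms) and a summary
    with the error percentage and mean/median/SD/skewness of the correct and
    incorrect RT distributions. Fully reproducible from the generator state.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    condition = _check_condition(condition)
    eff = params.effective(condition)
    rows = []
    for i in range(n_trials):
        draw = draw_baselines(params, condition, rng)
        _, out = simulate_trial(draw, eff, record=False)
        rows.append(
            (
                i,
                draw.BT,
                draw.BD,
                draw.eps_T,
                draw.eps_D,
                draw.eta,
                out.winner,
                out.correct,
                out.rt_ms,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "trial",
            "BT",
            "BD",
            "eps_T",
            "eps_D",
            "eta",
            "winner",
            "correct",
            "rt_ms",
        ],
    )
    table.insert(1, "condition", condition)
    return table, summarize_outcomes(table)


def summarize_outcomes(table: pd.DataFrame) -> dict:
    """Error rate and RT moments of a trial table, by outcome."""
    n = len(table)
    n_err = int((table["winner"] == "D").sum())
    n_omit = int((table["winner"] == "none").sum())
    out = {
        "n_trials": n,
        "n_omitted": n_omit,
        "error_pct": 100.0 * n_err / n,
    }
    for label, mask in (
        ("correct", table["winner"] == "T"),
        ("incorrect", table["winner"] == "D"),
    ):
        rts = table.loc[mask, "rt_ms"].to_numpy()
        if len(rts) == 0:
            out[label] = {"n": 0, "mean": math.nan, "median": math.nan,
                          "sd": math.nan, "skewness": math.nan}
            continue
        out[label] = {
            "n": int(len(rts)),
            "mean": float(np.mean(rts)),
            "median": float(np.median(rts)),
            "sd": float(np.std(rts, ddof=1)) if len(rts) > 1 else math.nan,
            "skewness": float(stats.skew(rts)) if len(rts) > 2 else math.nan,
        }
    return out


# ---------------------------------------------------------------------------
# Decomposition of the target plan into coupled/uncoupled components
# ---------------------------------------------------------------------------


def _gain_terms(trace: TrialTrace) -> tuple[float, float, float]:
    """(f1, phi, f2*BT) of the regime-appropriate G_T expression.

    f1 is the baseline-independent drive, phi the eta noise term, and f2*BT
    the baseline-coupled term; in regime 2 the divisive suppression factor
    applies to all three, so that f1 + phi + f2*BT == G_T in both regimes.
    """
    p = trace.params
    bt, bd, eta = trace.draw.BT, trace.draw.BD, trace.draw.eta
    if trace.regime == 1:
        denom = 1.0
        intercept, noise, slope = p.gt1_intercept, p.gt1_noise, p.gt1_slope
    else:
        denom = 1.0 + p.gt2_div * bd
        intercept, noise, slope = p.gt2_intercept, p.gt2_noise, p.gt2_slope
    f1 = p.gt1_scale * intercept / denom
    phi = p.gt1_scale * noise * eta / denom
    f2bt = p.gt1_scale * slope * bt / denom
    return f1, phi, f2bt


def _decompose_basis(trace: TrialTrace) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """(u0, c0, w, f1): alpha-free parts of the decomposition.

    The components at any alpha are ``u = u0 + alpha*f1*w`` and
    ``c = c0 - alpha*f1*w``; their sum is alpha-independent and equals
    A_T(t) exactly at every sample.
    """
    p = trace.params
    f1, phi, f2bt = _gain_terms(trace)
    g_u0 = f1 + phi  # uncoupled component rate at alpha = 0
    g_c0 = f2bt  # coupled component rate at alpha = 0
    dt = p.dt
    n = len(trace.time)
    t = trace.time

    # Per-step structural velocity multipliers: the U/C rates apply from the
    # afferent delay to the Rule-1 latch; after the latch the parent runs at
    # V_Twin = win_intercept + win_slope*G_T, and each component slows by the
    # parent's factor V_Twin/G_T, which keeps a positive-rate component
    # rising to its peak at the crossing and sums to V_Twin exactly; zero
    # after the crossing.
    end = trace.rt_index if trace.rt_index is not None else n - 1
    r1 = trace.rule1_time if trace.rule1_time is not None else math.inf
    if abs(trace.g_t) > 1e-12:
        win_factor = trace.v_twin / trace.g_t
    else:  # degenerate drive: fall back to an equal split of the constant
        win_factor = 0.0

    steps_t = t[:-1]  # velocity applied on the step leaving each sample
    race = np.arange(n - 1) < end
    ramp = race & (steps_t >= p.afferent_T) & (steps_t < r1)
    winphase = race & (steps_t >= r1)

    v_u0 = np.where(ramp, g_u0, 0.0) + np.where(winphase, win_factor * g_u0, 0.0)
    v_c0 = np.where(ramp, g_c0, 0.0) + np.where(winphase, win_factor * g_c0, 0.0)
    if abs(trace.g_t) <= 1e-12:
        v_u0 = v_u0 + np.where(winphase, 0.5 * trace.v_twin, 0.0)
        v_c0 = v_c0 + np.where(winphase, 0.5 * trace.v_twin, 0.0)
    # d(velocity)/d(alpha) in units of f1: +1 on the ramp, +win_factor after
    # the latch, for U (and the negative for C).
    dv = np.where(ramp, 1.0, 0.0) + np.where(winphase, win_factor, 0.0)

    u0 = np.empty(n)
    c0 = np.empty(n)
    w = np.empty(n)
    u0[0] = c0[0] = 0.5 * trace.draw.BT
    w[0] = 0.0
    u0[1:] = u0[0] + np.cumsum(v_u0) * dt
    c0[1:] = c0[0] + np.cumsum(v_c0) * dt
    w[1:] = np.cumsum(dv) * dt

    # Equal-split correction ties the components to the parent trajectory:
    # it is zero except where Rule 2 clamped A_T and during the postsaccadic
    # relaxation, which the components inherit from the parent.
    corr = 0.5 * (trace.a_t - (u0 + c0))
    u0 = u0 + corr
    c0 = c0 + corr
    return u0, c0, w, f1


def decompose_target_plan(
    trace: TrialTrace, alpha: float, params: ModelParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Split A_T(t) into uncoupled (U) and coupled (C) component trajectories.

    The component build-up rates are ``G_U = alpha*f1 + f1 + phi`` and
    ``G_C = -alpha*f1 + f2*BT``; they sum to G_T for any alpha, and the two
    trajectories — integrated with the parent's delays, rule events, and
    rate-change times, starting from BT/2 each — sum to A_T(t) at every
    sample. The C component is coupled to the baseline (fast-preferring),
    the U component carries the baseline-independent drive and the intrinsic
    noise (slow-preferring); alpha shifts weight between them without
    altering the race.
    """
    if not math.isfinite(alpha):
        raise ValueError("alpha must be finite")
    u0, c0, w, f1 = _decompose_basis(trace)
    shift = alpha * f1 * w
    return u0 + shift, c0 - shift
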