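"""Summary artifacts: RT distribution tables and condition-averaged panels.

Every report is a plain table (DataFrame) carrying all the numbers needed
to redraw the corresponding panel; nothing lives only in an image.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from . import pipeline
from .model import simulate_trial, draw_baselines
from .params import ModelParams
from .synth import Session

__all__ = [
    "report_rt_distributions",
    "model_condition_panels",
    "report_condition_panels",
]


def report_rt_distributions(
    trials: pd.DataFrame, bin_ms: float = 10.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RT summary and normalized histograms per (condition, outcome).

    Returns (stats, hist). ``stats`` has one row per condition x outcome
    with n, error %, and the mean/median/SD/skewness of the RTs; rows with
    n=0 are emitted with undefined statistics. Histograms are normalized to
    a maximum of 1.
    """
    stats_rows, hist_rows = [], []
    for cond, g in trials.groupby("condition"):
        decided = g.loc[g["winner"].isin(["T", "D"])]
        err_pct = 100.0 * (g["winner"] == "D").mean()
        for outcome, mask in (
            ("correct", decided["winner"] == "T"),
            ("incorrect", decided["winner"] == "D"),
        ):
            rts = decided.loc[mask, "rt_ms"].to_numpy()
            row = {
                "condition": cond,
                "outcome": outcome,
                "n": len(rts),
                "error_pct": err_pct,
                "mean": float(np.mean(rts)) if len(rts) else math.nan,
                "median": float(np.median(rts)) if len(rts) else math.nan,
                "sd": float(np.std(rts, ddof=1)) if len(rts) > 1 else math.nan,
                # skewness of a point mass is undefined; report 0 for display
                "skewness": float(stats.skew(rts))
                if len(rts) > 2 and np.ptp(rts) > 0
                else (0.0 if len(rts) > 2 else math.nan),
            }
            stats_rows.append(row)
            if len(rts):
                lo = bin_ms * math.floor(rts.min() / bin_ms)
                hi = bin_ms * math.ceil(rts.max() / bin_ms) + bin_ms / 2
                edges = np.arange(lo, hi + bin_ms, bin_ms)
                counts, edges = np.histogram(rts, bins=edges)
                peak = counts.max() if counts.max() > 0 else 1
                for c, e in zip(counts, edges[:-1]):
                    hist_rows.append(
                        {
                            "condition": cond,
                            "outcome": outcome,
                            "bin_left_ms": float(e),
                            "density": c / peak,
                        }
                    )
    return pd.DataFrame(stats_rows), pd.DataFrame(hist_rows)


def model_condition_panels(
    params: ModelParams,
    n_trials: int,
    rng: np.random.Generator,
    conditions: tuple[str, ...] = ("congruent", "incongruent"),
    t_max_ms: float = 600.0,
) -> pd.DataFrame:
    """Mean simulated activity traces A_T/A_D per (condition, outcome).

    Trials are simulated with full traces, grouped by condition and
    outcome, and averaged go-aligned (NaN-padded beyond each trial's
    recorded extent). Long format: condition, outcome, plan (T/D), time_ms,
    mean_activity, n_trials.
    """
    n_grid = int(t_max_ms) + 1
    groups: dict = {}
    for cond in conditions:
        eff = params.effective(cond)
        for _ in range(n_trials):
            draw = draw_baselines(params, cond, rng)
            trace, out = simulate_trial(draw, eff)
            if out.winner == "none":
                continue
            key = (cond, "correct" if out.correct else "incorrect")
            at = np.full(n_grid, np.nan)
            ad = np.full(n_grid, np.nan)
            k = min(len(trace.a_t), n_grid)
            at[:k] = trace.a_t[:k]
            ad[:k] = trace.a_d[:k]
            groups.setdefault(key, []).append((at, ad))
    rows = []
    for (cond, outcome), pairs in sorted(groups.items()):
        at = np.nanmean(np.stack([p[0] for p in pairs]), axis=0)
        ad = np.nanmean(np.stack([p[1] for p in pairs]), axis=0)
        for plan, tr in (("T", at), ("D", ad)):
            for t, v in enumerate(tr):
                rows.append((cond, outcome, plan, float(t), v, len(pairs)))
    return pd.DataFrame(
        rows,
        columns=["condition", "outcome", "plan", "time_ms", "mean_activity", "n_trials"],
    )


def report_condition_panels(
    session: Session, metrics: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Population traces and baseline/peak summaries per TRS condition.

    Returns (traces, summary): go-aligned normalized population traces with
    SE per TRS code, and per-code mean baseline (Rb) and mean peak (Rp)
    responses across neurons (from ``metrics`` when given; recomputed
    otherwise).
    """
    trials = pipeline.trial_table(session)
    max_rates = pipeline.neuron_max_rates(session)
    codes = set()
    for spec in session.neurons.itertuples(index=False):
        codes.update(pipeline._trial_codes(trials, spec.rf_loc).unique())
    trace_rows = []
    for code in sorted(codes):
        try:
            grid, mean, se = pipeline.population_trace(
                session, code, max_rates=max_rates
            )
        except ValueError:
            continue
        for t, m, s in zip(grid, mean, se):
            trace_rows.append((code, float(t), m, s))
    traces = pd.DataFrame(trace_rows, columns=["trs", "time_ms", "mean", "se"])

    if metrics is None:
        metrics = pipeline.neuron_trial_metrics(session)
    per_neuron = metrics.groupby(["trs", "neuron_id"])[["Rb", "Rp"]].mean()
    summary = (
        per_neuron.groupby("trs")
        .agg(
            mean_Rb=("Rb", "mean"),
            se_Rb=("Rb", "sem"),
            mean_Rp=("Rp", "mean"),
            se_Rp=("Rp", "sem"),
            n_neurons=("Rb", "count"),
        )
        .reset_index()
    )
    return traces, summary
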