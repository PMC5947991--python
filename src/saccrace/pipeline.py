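"""Session-level analysis: per-trial metrics, correlations, population traces.

Glue between the synthetic-session container and the single-trial
procedures in :mod:`saccrace.spikes`: computes per-neuron/per-trial metric
tables (Rb, Rm, Rsac, Rp/Tp, Ron/Ton, RBU), per-neuron Spearman correlation
tables, normalized population traces per target/reward/saccade (TRS)
configuration, and the RT-matched comparison of population build-up rates.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import spikes as sp
from .synth import Session, trs_code

__all__ = [
    "trial_table",
    "neuron_trial_metrics",
    "neuron_correlations",
    "neuron_max_rates",
    "population_trace",
    "buildup_slope",
    "matched_buildup_gap",
]

GO_GRID = np.arange(-300.0, 401.0)  # common go-aligned analysis grid (ms)


def trial_table(session: Session, drop_block_start: int = 8) -> pd.DataFrame:
    """Usable trials: omissions dropped, first-k-of-block 1DR trials
    discarded (stable-expectation selection)."""
    t = session.trials
    t = t.loc[~t["omitted"]]
    return sp.discard_block_start(t, k=drop_block_start)


def _neuron_rows(session: Session) -> list[tuple]:
    return list(session.neurons.itertuples(index=False))


def _trial_codes(trials: pd.DataFrame, rf_loc: int) -> pd.Series:
    return trials.apply(
        lambda r: trs_code(rf_loc, r["target_loc"], r["reward_loc"], r["saccade_loc"]),
        axis=1,
    )


def neuron_trial_metrics(
    session: Session,
    neuron_ids: Optional[Sequence[int]] = None,
    peak_window_ms: float = 100.0,
    drop_block_start: int = 8,
) -> pd.DataFrame:
    """Per-neuron, per-trial response metrics.

    For each neuron the timing law Tp = beta0 + beta1*RT is fitted from all
    saccade-into-RF trials pooled over bias conditions; the metrics are then
    evaluated for every usable trial of the neuron (saccades away from the
    RF included, flagged by ``saccade_in_rf``). Returns one row per
    (neuron, trial) with the TRS code, RT, fitted beta0/beta1, and
    Rb, Rm, Rsac, Tp, Rp, Ton, Ron, RBU (NaN where undefined).
    """
    trials = trial_table(session, drop_block_start)
    pre = session.plan.pre_go_ms
    post = session.plan.post_go_ms
    rows = []
    for spec in _neuron_rows(session):
        if neuron_ids is not None and spec.id not in neuron_ids:
            continue
        codes = _trial_codes(trials, spec.rf_loc)
        into_rf = trials["saccade_loc"] == spec.rf_loc
        sub = trials.loc[into_rf]
        if len(sub) < 5:
            continue
        rts = sub["rt_ms"].to_numpy()
        grid = np.arange(-pre, float(np.max(rts)) + post)
        trains = [session.spike_train(spec.id, t) for t in sub["trial"]]
        sdfs = sp.sdf_matrix(trains, grid)
        b0, b1 = sp.fit_peak_timing(sdfs, rts, grid)
        for (_, tr), code, in_rf in zip(
            trials.iterrows(), codes, into_rf
        ):
            train = session.spike_train(spec.id, int(tr["trial"]))
            rt = tr["rt_ms"]
            rb, rm, rsac = sp.window_rates(train, rt)
            rp, tp = sp.peak_response(
                train, rt, b0, b1, peak_window_ms, trial_window=(-pre, rt + post)
            )
            ton, ron = sp.response_onset(train, tp)
            rbu = sp.buildup_rate(rp, ron, tp, ton)
            rows.append(
                (
                    spec.id, int(tr["trial"]), code, bool(in_rf), rt, b0, b1,
                    rb, rm, rsac, tp, rp, ton, ron, rbu,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "neuron_id", "trial", "trs", "saccade_in_rf", "rt_ms",
            "beta0", "beta1",
            "Rb", "Rm", "Rsac", "Tp", "Rp", "Ton", "Ron", "RBU",
        ],
    )


_CORR_PAIRS = [
    ("Rb", "Rp"),
    ("Rb", "rt_ms"),
    ("Rp", "rt_ms"),
    ("Rsac", "rt_ms"),
    ("RBU", "rt_ms"),
]


def neuron_correlations(
    metrics: pd.DataFrame, min_trials: int = 10
) -> pd.DataFrame:
    """Spearman correlations between metric pairs, per neuron and TRS code.

    One row per (neuron, trs) with rho and p columns for each standard pair
    (e.g. ``rho_Rb_rt``); computed only when at least ``min_trials`` trials
    with finite values are available.
    """
    rows = []
    for (nid, code), g in metrics.groupby(["neuron_id", "trs"]):
        row: dict = {"neuron_id": nid, "trs": code, "n_trials": len(g)}
        for x, y in _CORR_PAIRS:
            name = f"{x}_{y}".replace("_ms", "").replace("rt", "RT")
            vals = g[[x, y]].dropna()
            if len(vals) < min_trials:
                row[f"rho_{name}"] = math.nan
                row[f"p_{name}"] = math.nan
                continue
            rho, p = sp.spearman_correlations(
                vals[x].to_numpy(), vals[y].to_numpy()
            )
            row[f"rho_{name}"] = rho
            row[f"p_{name}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def neuron_max_rates(session: Session, grid: np.ndarray = GO_GRID) -> dict:
    """Per-neuron overall maximum firing rate: the max over time and TRS
    conditions of the trial-averaged go-aligned SDF."""
    trials = trial_table(session)
    out = {}
    for spec in _neuron_rows(session):
        codes = _trial_codes(trials, spec.rf_loc)
        best = 0.0
        for code in codes.unique():
            ids = trials.loc[codes == code, "trial"]
            sdfs = sp.sdf_matrix([session.spike_train(spec.id, t) for t in ids], grid)
            best = max(best, float(sdfs.mean(axis=0).max()))
        out[spec.id] = best if best > 0 else 1.0
    return out


def population_trace(
    session: Session,
    trs: str,
    align: str = "go",
    grid: np.ndarray = GO_GRID,
    max_rates: Optional[dict] = None,
    trial_subset: Optional[dict] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized population firing-rate trace for one TRS configuration.

    Per neuron: average SDF over its trials with that code, normalized by
    the neuron's overall max rate; then unweighted mean and SE across
    neurons. ``trial_subset`` (neuron_id -> trial ids) restricts each
    neuron's trials (used by RT matching). Returns (grid, mean, se).
    """
    trials = trial_table(session)
    if max_rates is None:
        max_rates = neuron_max_rates(session, grid)
    traces, rates = [], []
    out_grid = grid
    for spec in _neuron_rows(session):
        codes = _trial_codes(trials, spec.rf_loc)
        sub = trials.loc[codes == trs]
        if trial_subset is not None:
            if spec.id not in trial_subset:
                continue
            sub = sub.loc[sub["trial"].isin(trial_subset[spec.id])]
        if len(sub) == 0:
            continue
        sdfs = sp.sdf_matrix(
            [session.spike_train(spec.id, t) for t in sub["trial"]], grid
        )
        if align == "saccade":
            fam = sp.rt_quantile_traces(
                sdfs, sub["rt_ms"].to_numpy(), grid, n_bins=1, bin_frac=1.0,
                align="saccade",
            )
            traces.append(fam.traces[0])
            out_grid = fam.grid
        else:
            traces.append(sdfs.mean(axis=0))
        rates.append(max_rates[spec.id])
    mean, se = sp.normalize_and_average(traces, rates)
    return out_grid, mean, se


def buildup_slope(
    grid: np.ndarray, trace: np.ndarray, window: tuple[float, float] = (50.0, 120.0)
) -> float:
    """Slope (per ms) of a go-aligned trace over the early rise window."""
    m = (grid >= window[0]) & (grid <= window[1])
    return float(np.polyfit(grid[m], trace[m], 1)[0])


def matched_buildup_gap(
    session: Session,
    rng: np.random.Generator,
    cond_a: str = "III",
    cond_b: str = "IOI",
    tol_ms: float = 15.0,
    reps: int = 50,
    window: tuple[float, float] = (50.0, 120.0),
    grid: np.ndarray = GO_GRID,
    neuron_ids: Optional[Sequence[int]] = None,
) -> dict:
    """Population build-up-rate gap between two TRS conditions, before and
    after per-neuron RT matching.

    The gap is |slope_a - slope_b| of the go-aligned normalized population
    traces over ``window``. Matching pairs each neuron's condition-a trials
    with nearest-RT condition-b trials (tolerance ``tol_ms``); matched
    slopes are averaged over ``reps`` random repetitions before the gap is
    taken. ``neuron_ids`` restricts the pool (build-up rate is a motor-plan
    quantity, so the comparison is usually run on cells that carry the
    motor signal).
    """
    trials = trial_table(session)
    max_rates = neuron_max_rates(session, grid)

    # cache per-neuron SDF matrices and RTs for both conditions
    cache: dict = {}
    for spec in _neuron_rows(session):
        if neuron_ids is not None and spec.id not in neuron_ids:
            continue
        codes = _trial_codes(trials, spec.rf_loc)
        per = {}
        for code in (cond_a, cond_b):
            sub = trials.loc[codes == code]
            sdfs = sp.sdf_matrix(
                [session.spike_train(spec.id, t) for t in sub["trial"]], grid
            )
            per[code] = (sdfs, sub["rt_ms"].to_numpy())
        cache[spec.id] = per

    def slopes(selections: Optional[dict]) -> dict:
        out = {}
        for code in (cond_a, cond_b):
            traces, rates = [], []
            for nid, per in cache.items():
                sdfs, rts = per[code]
                idx = None if selections is None else selections[nid][code]
                if idx is not None:
                    if len(idx) < 5:
                        continue
                    sdfs = sdfs[idx]
                if len(sdfs) == 0:
                    continue
                traces.append(sdfs.mean(axis=0))
                rates.append(max_rates[nid])
            mean, _ = sp.normalize_and_average(traces, rates)
            out[code] = buildup_slope(grid, mean, window)
        return out

    s0 = slopes(None)
    unmatched = abs(s0[cond_a] - s0[cond_b])
    # slopes averaged across matching repetitions first, then differenced:
    # |mean| rather than mean |.| avoids the upward noise bias
    sa, sb = [], []
    for _ in range(reps):
        selections = {}
        for nid, per in cache.items():
            ia, ib = sp.rt_match(per[cond_a][1], per[cond_b][1], tol_ms, rng)
            selections[nid] = {cond_a: ia, cond_b: ib}
        sm = slopes(selections)
        sa.append(sm[cond_a])
        sb.append(sm[cond_b])
    matched = abs(float(np.mean(sa)) - float(np.mean(sb)))
    return {
        "unmatched_gap": unmatched,
        "matched_gap": matched,
        "shrinkage": 1.0 - matched / unmatched if unmatched > 0 else math.nan,
    }
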