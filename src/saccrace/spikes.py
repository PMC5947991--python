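"""Single-neuron spike-train analysis for trial-structured saccade data.

Spike times are in milliseconds relative to the go signal (t = 0); reaction
time (RT) is the go-to-saccade-onset interval. Firing rates are in spikes/s.
The procedures here — spike density functions, RT-quantile trace families,
per-trial response metrics (Rb, Rm, Rsac, Rp, Tp, Ron, Ton, RBU), rank
correlations, permutation tests, RT matching, and visuomotor classification —
operate on plain arrays plus the trial tables produced by
:mod:`saccrace.synth`.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "SDF_SIGMA_MS",
    "spike_density",
    "sdf_matrix",
    "normalize_and_average",
    "rt_quantile_traces",
    "QuantileTraceFamily",
    "activity_map",
    "ActivityMap",
    "fit_peak_timing",
    "peak_response",
    "response_onset",
    "buildup_rate",
    "window_rates",
    "spearman_correlations",
    "permutation_test",
    "PermutationResult",
    "rt_match",
    "classify_neuron",
    "discard_block_start",
]

SDF_SIGMA_MS = 15.0


# ---------------------------------------------------------------------------
# Continuous firing activity
# ---------------------------------------------------------------------------


def spike_density(
    spikes: np.ndarray, grid: np.ndarray, sigma_ms: float = SDF_SIGMA_MS
) -> np.ndarray:
    """Spike density function: sum of unit-area Gaussians, in spikes/s.

    Each spike contributes a Gaussian of width ``sigma_ms`` and unit area
    (one spike); no edge reflection or renormalization is applied, so mass
    is lost for spikes within a few sigma of the grid ends.
    """
    spikes = np.asarray(spikes, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if grid.size > 1 and np.max(np.diff(grid)) > 1.0 + 1e-9:
        raise ValueError("grid step must be <= 1 ms")
    if spikes.size == 0:
        return np.zeros_like(grid)
    z = (grid[None, :] - spikes[:, None]) / sigma_ms
    dens = np.exp(-0.5 * z * z).sum(axis=0) / (sigma_ms * math.sqrt(2 * math.pi))
    return 1000.0 * dens  # spikes/ms -> spikes/s


def sdf_matrix(
    spike_lists: Sequence[np.ndarray],
    grid: np.ndarray,
    sigma_ms: float = SDF_SIGMA_MS,
) -> np.ndarray:
    """SDFs for many trials at once via 1-ms binning + Gaussian filtering.

    Equivalent to :func:`spike_density` up to the 1-ms discretization of
    spike times; used for bulk pipeline work where thousands of traces are
    needed.
    """
    grid = np.asarray(grid, dtype=float)
    step = grid[1] - grid[0]
    edges = np.concatenate([grid - step / 2, [grid[-1] + step / 2]])
    counts = np.stack(
        [np.histogram(np.asarray(s, dtype=float), bins=edges)[0] for s in spike_lists]
    ).astype(float)
    sm = gaussian_filter1d(
        counts, sigma=sigma_ms / step, axis=1, mode="constant", truncate=6.0
    )
    return 1000.0 * sm / step


def normalize_and_average(
    traces: Sequence[np.ndarray], max_rates: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Population trace: per-neuron traces normalized by each neuron's
    overall maximum firing rate, then averaged (unweighted) across neurons.

    Returns (mean, standard error across cells).
    """
    if len(traces) == 0:
        raise ValueError("need at least one neuron")
    arr = np.stack(
        [np.asarray(t, dtype=float) / r for t, r in zip(traces, max_rates)]
    )
    mean = arr.mean(axis=0)
    se = (
        arr.std(axis=0, ddof=1) / math.sqrt(arr.shape[0])
        if arr.shape[0] > 1
        else np.zeros_like(mean)
    )
    return mean, se


@dataclass
class QuantileTraceFamily:
    """RT-quantile-conditioned family of averaged firing-rate traces."""

    grid: np.ndarray
    centers: np.ndarray  # quantile of each bin, in [0, 1]
    traces: np.ndarray  # (n_bins, len(grid))
    counts: np.ndarray  # member trials per bin
    align: str  # 'go' or 'saccade'


def quantile_bin_members(
    rts: np.ndarray, n_bins: int = 20, bin_frac: float = 0.20
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Overlapping RT-rank bins: centers linearly spaced from the 10th to the
    90th percentile, each holding the ``bin_frac`` fraction of trials whose
    RT ranks are nearest the center. Ties in RT and in rank distance are
    broken deterministically by trial index."""
    rts = np.asarray(rts, dtype=float)
    n = len(rts)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} trials, got {n}")
    order = np.lexsort((np.arange(n), rts))  # rank by RT, ties by index
    m = max(1, int(round(bin_frac * n)))
    centers = np.linspace(0.10, 0.90, n_bins)
    members = []
    for q in centers:
        c = q * (n - 1)
        dist = np.abs(np.arange(n) - c)
        pick_ranks = np.lexsort((np.arange(n), dist))[:m]
        members.append(np.sort(order[pick_ranks]))
    return centers, members


def rt_quantile_traces(
    sdfs: np.ndarray,
    rts: np.ndarray,
    grid: np.ndarray,
    n_bins: int = 20,
    bin_frac: float = 0.20,
    align: str = "go",
    align_window: tuple[float, float] = (-300.0, 100.0),
) -> QuantileTraceFamily:
    """Average SDF traces within overlapping RT-quantile bins.

    ``sdfs`` is a (n_trials, len(grid)) matrix of go-aligned traces. With
    ``align='saccade'`` each trial is re-aligned on its saccade onset (the
    RT) before averaging, on the grid ``align_window`` around it.
    """
    sdfs = np.asarray(sdfs, dtype=float)
    rts = np.asarray(rts, dtype=float)
    centers, members = quantile_bin_members(rts, n_bins, bin_frac)
    if align == "go":
        out_grid = np.asarray(grid, dtype=float)
        aligned = sdfs
    elif align == "saccade":
        step = grid[1] - grid[0]
        out_grid = np.arange(align_window[0], align_window[1] + step / 2, step)
        aligned = np.full((len(rts), len(out_grid)), np.nan)
        for i, rt in enumerate(rts):
            src = np.round((rt + out_grid - grid[0]) / step).astype(int)
            ok = (src >= 0) & (src < sdfs.shape[1])
            aligned[i, ok] = sdfs[i, src[ok]]
    else:
        raise ValueError("align must be 'go' or 'saccade'")
    traces = np.stack([np.nanmean(aligned[idx], axis=0) for idx in members])
    counts = np.array([len(idx) for idx in members])
    return QuantileTraceFamily(
        grid=out_grid, centers=centers, traces=traces, counts=counts, align=align
    )


@dataclass
class ActivityMap:
    """Trial-by-time rate matrix, rows sorted by RT (fastest first)."""

    grid: np.ndarray
    rates: np.ndarray  # analysis copy: trials independent
    smoothed: np.ndarray  # display copy: Gaussian-smoothed across rows
    rts: np.ndarray  # per-row saccade-onset markers
    peak_times: np.ndarray  # per-row time of maximum rate


def activity_map(
    sdfs: np.ndarray, rts: np.ndarray, grid: np.ndarray, row_sigma: float = 2.0
) -> ActivityMap:
    """Assemble an RT-sorted activity map with a display-smoothed copy."""
    sdfs = np.asarray(sdfs, dtype=float)
    rts = np.asarray(rts, dtype=float)
    if len(rts) < 3:
        raise ValueError("need at least 3 trials")
    order = np.lexsort((np.arange(len(rts)), rts))
    rates = sdfs[order]
    smoothed = gaussian_filter1d(rates, sigma=row_sigma, axis=0, mode="nearest")
    peak_times = np.asarray(grid)[np.argmax(rates, axis=1)]
    return ActivityMap(
        grid=np.asarray(grid, dtype=float),
        rates=rates,
        smoothed=smoothed,
        rts=rts[order],
        peak_times=peak_times,
    )


# ---------------------------------------------------------------------------
# Per-trial response metrics
# ---------------------------------------------------------------------------


def fit_peak_timing(
    sdfs: np.ndarray, rts: np.ndarray, grid: np.ndarray
) -> tuple[float, float]:
    """Fit the peak-activity time law Tp = beta0 + beta1 * RT.

    Per trial, Tmax is the time of the SDF maximum after the go signal;
    Tmax is then regressed on RT by ordinary least squares over all trials
    with a saccade into the neuron's response field (pool all bias
    conditions before calling). Returns (beta0, beta1).
    """
    rts = np.asarray(rts, dtype=float)
    if len(rts) < 5:
        raise ValueError("need at least 5 trials for the timing fit")
    if np.ptp(rts) == 0:
        raise ValueError("degenerate RT variance: timing fit undefined")
    grid = np.asarray(grid, dtype=float)
    post = grid > 0
    tmax = grid[post][np.argmax(np.asarray(sdfs, dtype=float)[:, post], axis=1)]
    res = stats.linregress(rts, tmax)
    return float(res.intercept), float(res.slope)


def peak_response(
    spikes: np.ndarray,
    rt_ms: float,
    beta0: float,
    beta1: float,
    window_ms: float = 100.0,
    trial_window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Peak response Rp (spikes/s) and its time Tp = beta0 + beta1*RT.

    Rp is the spike count in a ``window_ms`` window centered on Tp divided
    by the window length; when the window sticks out of the recorded trial
    it is truncated and the covered duration is used as denominator.
    """
    tp = beta0 + beta1 * rt_ms
    lo, hi = tp - window_ms / 2, tp + window_ms / 2
    if trial_window is not None:
        lo2, hi2 = max(lo, trial_window[0]), min(hi, trial_window[1])
        if (lo2, hi2) != (lo, hi):
            warnings.warn(
                f"peak window [{lo:.0f}, {hi:.0f}] truncated to recorded "
                f"trial [{lo2:.0f}, {hi2:.0f}]",
                stacklevel=2,
            )
        lo, hi = lo2, hi2
    covered = hi - lo
    if covered <= 0:
        return math.nan, tp
    spikes = np.asarray(spikes, dtype=float)
    count = int(np.count_nonzero((spikes >= lo) & (spikes < hi)))
    return 1000.0 * count / covered, tp


def response_onset(
    spikes: np.ndarray,
    tp_ms: float,
    sigma_ms: float = SDF_SIGMA_MS,
    k_sd: float = 3.0,
    persist_ms: float = 20.0,
    baseline_window: tuple[float, float] = (-250.0, 0.0),
) -> tuple[float, float]:
    """Response onset time Ton and onset rate Ron for one trial.

    Ton is the earliest time in (0, Tp] at which the trial's SDF exceeds
    its own baseline mean + ``k_sd`` standard deviations and stays above for
    at least ``persist_ms``; a sustained-crossing detector standing in for
    per-trial latency estimation. Ron is the spike count in a 50 ms window
    centered on Ton divided by 50 ms. Returns (nan, nan) when no qualifying
    crossing exists (the trial is then excluded from build-up-rate use).
    """
    if not math.isfinite(tp_ms) or tp_ms <= 0:
        return math.nan, math.nan
    grid = np.arange(baseline_window[0], tp_ms + persist_ms + 1.0)
    sdf = spike_density(spikes, grid, sigma_ms)
    base = sdf[(grid >= baseline_window[0]) & (grid < baseline_window[1])]
    b_mean, b_sd = base.mean(), base.std(ddof=0)
    if b_sd > 1e-6:  # spikes/s; guards against floating dust on silence
        thresh = b_mean + k_sd * b_sd
    else:
        # silent baseline leaves the k*SD rule degenerate; fall back to the
        # half-rise point of the evoked excursion
        peak = sdf[(grid > 0) & (grid <= tp_ms)].max(initial=0.0)
        if peak <= 0:
            return math.nan, math.nan
        thresh = b_mean + 0.5 * (peak - b_mean)
    above = (sdf > thresh) & (grid > 0) & (grid <= tp_ms)
    need = int(round(persist_ms))
    idx = np.flatnonzero(above)
    for i in idx:
        seg = sdf[i : i + need]
        if len(seg) == need and np.all(seg > thresh):
            ton = float(grid[i])
            spikes = np.asarray(spikes, dtype=float)
            count = np.count_nonzero((spikes >= ton - 25.0) & (spikes < ton + 25.0))
            return ton, 1000.0 * count / 50.0
    return math.nan, math.nan


def buildup_rate(rp: float, ron: float, tp: float, ton: float) -> float:
    """RBU = (Rp - Ron) / (Tp - Ton), in spikes/s per ms; NaN if undefined."""
    if not (math.isfinite(ton) and math.isfinite(tp)) or tp <= ton:
        return math.nan
    return (rp - ron) / (tp - ton)


def window_rates(spikes: np.ndarray, rt_ms: float) -> tuple[float, float, float]:
    """(Rb, Rm, Rsac): baseline, mean, and presaccadic firing rates.

    Rb over [-250, 0) before the go signal; Rm over the full RT interval
    [0, rt); Rsac over the 20 ms window [rt-70, rt-50) preceding saccade
    onset.
    """
    spikes = np.asarray(spikes, dtype=float)

    def rate(lo: float, hi: float) -> float:
        if hi <= lo:
            return math.nan
        c = np.count_nonzero((spikes >= lo) & (spikes < hi))
        return 1000.0 * c / (hi - lo)

    return rate(-250.0, 0.0), rate(0.0, rt_ms), rate(rt_ms - 70.0, rt_ms - 50.0)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def spearman_correlations(
    metric: np.ndarray, rt: np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation (mid-rank ties) with two-sided p.

    A constant metric leaves the correlation undefined: returns (nan, nan).
    """
    metric = np.asarray(metric, dtype=float)
    rt = np.asarray(rt, dtype=float)
    ok = np.isfinite(metric) & np.isfinite(rt)
    metric, rt = metric[ok], rt[ok]
    if len(metric) < 5:
        raise ValueError("need at least 5 paired values")
    if np.ptp(metric) == 0 or np.ptp(rt) == 0:
        return math.nan, math.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(metric, rt)
    return float(rho), float(p)


@dataclass(frozen=True)
class PermutationResult:
    p: float
    at_floor: bool
    n_perm: int
    observed: float

    def __str__(self) -> str:  # reported as a bound when at the floor
        return f"p<{1.0 / self.n_perm:g}" if self.at_floor else f"p={self.p:g}"


def permutation_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    paired: bool = False,
    n_perm: int = 100_000,
    rng: Optional[np.random.Generator] = None,
) -> PermutationResult:
    """Two-sided permutation test for a difference of means.

    Unpaired: labels are permuted across the pooled sample. Paired: signs of
    the per-pair differences are flipped. When the full permutation group is
    no larger than ``n_perm`` it is enumerated exhaustively; otherwise
    ``n_perm`` random permutations are drawn and the p value is floored at
    1/n_perm (reported as a bound, e.g. ``p<1e-05``).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("group sizes must be >= 2")
    if rng is None:
        rng = np.random.default_rng()

    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal-sized groups")
        d = a - b
        obs = abs(d.mean())
        n = len(d)
        if 2**n <= n_perm:
            signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
            perm = np.abs((signs * d).mean(axis=1))
            p = float(np.mean(perm >= obs - 1e-12))
            return PermutationResult(p, False, n_perm, float(d.mean()))
        flips = rng.choice((1.0, -1.0), size=(n_perm, n))
        perm = np.abs((flips * d).mean(axis=1))
        count = int(np.sum(perm >= obs - 1e-12))
        p = max(count / n_perm, 1.0 / n_perm)
        return PermutationResult(p, count == 0, n_perm, float(d.mean()))

    pooled = np.concatenate([a, b])
    na = len(a)
    obs = abs(a.mean() - b.mean())
    n_comb = math.comb(len(pooled), na)
    if n_comb <= n_perm:
        count = 0
        idx_all = frozenset(range(len(pooled)))
        for pick in itertools.combinations(range(len(pooled)), na):
            sa = pooled[list(pick)]
            sb = pooled[list(idx_all - set(pick))]
            if abs(sa.mean() - sb.mean()) >= obs - 1e-12:
                count += 1
        p = count / n_comb
        return PermutationResult(p, False, n_perm, float(a.mean() - b.mean()))
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:na].mean() - perm[na:].mean()) >= obs - 1e-12:
            count += 1
    p = max(count / n_perm, 1.0 / n_perm)
    return PermutationResult(p, count == 0, n_perm, float(a.mean() - b.mean()))


def rt_match(
    rt_a: np.ndarray,
    rt_b: np.ndarray,
    tol_ms: float = 15.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy sub-sampling that equalizes two RT distributions.

    Every A trial is probed once, in random order; the nearest-RT remaining
    B trial is paired with it iff their RT difference is below ``tol_ms``,
    and accepted pairs are removed from both pools. Returns index arrays
    (into A and B) of equal length; an empty match is a valid result.
    Downstream statistics are typically averaged over repeated runs.
    """
    rt_a = np.asarray(rt_a, dtype=float)
    rt_b = np.asarray(rt_b, dtype=float)
    if rng is None:
        rng = np.random.default_rng()
    remaining = list(range(len(rt_b)))
    out_a, out_b = [], []
    for ia in rng.permutation(len(rt_a)):
        if not remaining:
            break
        diffs = np.abs(rt_b[remaining] - rt_a[ia])
        j = int(np.argmin(diffs))
        if diffs[j] < tol_ms:
            out_a.append(int(ia))
            out_b.append(remaining.pop(j))
    order = np.argsort(out_a)
    return np.asarray(out_a, dtype=int)[order], np.asarray(out_b, dtype=int)[order]


# ---------------------------------------------------------------------------
# Classification and trial selection
# ---------------------------------------------------------------------------


def classify_neuron(
    beta1: float,
    v_cut: float = 0.46,
    m_cut: float = 0.85,
    motor_pool_min: float = 0.1,
) -> str:
    """Visuomotor category from the timing slope beta1.

    beta1 below ``motor_pool_min`` marks cells that carry essentially no
    motor signal and are excluded from motor-pool analyses; otherwise cells
    are visual (V) below ``v_cut``, motor (M) above ``m_cut``, and
    visuomotor (VM) in between. Only ``v_cut`` is an empirically anchored
    boundary; the M cutoff is a package default.
    """
    if not math.isfinite(beta1):
        raise ValueError("beta1 must be finite")
    if beta1 < motor_pool_min:
        return "excluded"
    if beta1 < v_cut:
        return "V"
    if beta1 > m_cut:
        return "M"
    return "VM"


def discard_block_start(trials, k: int = 8):
    """Drop the first ``k`` trials of each 1DR block (reward-discovery
    period); ADR trials pass through untouched. ``trials`` is a DataFrame
    with ``condition`` and ``trial_in_block`` columns."""
    keep = (trials["condition"].str.lower() == "adr") | (
        trials["trial_in_block"] >= k
    )
    return trials.loc[keep].copy()
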