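"""Independent oracles used by the test suite.

These deliberately avoid the package's integration loop: the race oracle
does closed-form piecewise-linear algebra over continuous time, processing
events (afferent delays, inhibition window edges, rule latches, threshold
crossings) analytically instead of stepping a grid.
"""

from __future__ import annotations

import math

from saccrace.params import ModelParams


def race_oracle(bt: float, bd: float, eta: float, p: ModelParams):
    """Closed-form event-driven solution of one race.

    Returns (winner, rt_ms) with rt on the continuous time axis; the
    stepped simulation must agree within about one integration step. The
    stepped scheme applies velocities chosen at integer times over the
    following step, so the inhibition window effectively extends to
    Ioff + dt; the oracle mirrors that convention (it is part of the
    schedule, not of the integrator).
    """
    theta = max(p.theta_intercept + p.theta_slope * (bt - bd), p.theta_floor)
    g_d = p.gd_scale * max(p.gd_intercept + p.gd_slope * (bd - bt), 0.0)
    if bt >= bd:
        g_t = p.gt1_scale * (p.gt1_intercept + p.gt1_noise * eta + p.gt1_slope * bt)
    else:
        g_t = (
            p.gt1_scale
            * (p.gt2_intercept + p.gt2_noise * eta + p.gt2_slope * bt)
            / (1.0 + p.gt2_div * bd)
        )
    v_twin = p.win_intercept + p.win_slope * g_t
    ioff = p.inhib_off + p.dt  # step convention, see docstring

    a_t, a_d = bt, bd
    t = 0.0
    rule1 = False
    rule2 = False

    def vt(now: float) -> float:
        if now < p.afferent_T:
            return 0.0
        return v_twin if rule1 else g_t

    def vd(now: float) -> float:
        if rule1 or now < p.afferent_D:
            return 0.0
        if p.inhib_on <= now < ioff:
            return p.inhib_gain * g_d
        return g_d

    # fixed schedule breakpoints; dynamic events are found inside segments
    breaks = sorted({p.afferent_T, p.afferent_D, p.inhib_on, ioff, p.trial_cap})
    breaks = [b for b in breaks if b > 0]

    for b in breaks + [p.trial_cap]:
        while t < b - 1e-12:
            seg_end = b
            cvt, cvd = vt(t), vd(t)
            # candidate event times within (t, seg_end]
            events = []
            if cvt > 0 and a_t < theta:
                events.append(("cross_T", t + (theta - a_t) / cvt))
            if a_t >= theta:
                events.append(("cross_T", t))
            if cvd > 0 and a_d < theta:
                events.append(("cross_D", t + (theta - a_d) / cvd))
            if a_d >= theta:
                events.append(("cross_D", t))
            if not rule1 and not rule2 and cvt > cvd and a_t <= a_d:
                # T catches D -> Rule 1 at the first instant A_T > A_D
                events.append(("rule1", t + (a_d - a_t) / (cvt - cvd)))
            if not rule1 and not rule2 and a_t > a_d and t >= p.afferent_T:
                events.append(("rule1", t))
            if (
                not rule2
                and not rule1
                and t >= ioff
                and t >= p.afferent_D
                and a_d > a_t
            ):
                events.append(("rule2", t))
            events = [e for e in events if e[1] <= seg_end + 1e-12]
            if not events:
                a_t += cvt * (seg_end - t)
                a_d += cvd * (seg_end - t)
                t = seg_end
                continue
            kind, te = min(events, key=lambda e: e[1])
            te = max(te, t)
            a_t += cvt * (te - t)
            a_d += cvd * (te - t)
            t = te
            if kind == "cross_T":
                return "T", t
            if kind == "cross_D":
                return "D", t
            if kind == "rule1":
                if t < p.afferent_T:  # cannot latch before the delay
                    t = p.afferent_T
                    continue
                rule1 = True
            elif kind == "rule2":
                rule2 = True
                # D leads and T can never pass: D wins at its own crossing
                if vd(t) > 0:
                    return "D", t + (theta - a_d) / vd(t)
                return "none", math.nan
    return "none", math.nan


def spearman_oracle(x, y) -> float:
    """Brute-force Spearman rho via explicit mid-ranks and the Pearson
    formula on ranks."""

    def midranks(v):
        n = len(v)
        ranks = [0.0] * n
        order = sorted(range(n), key=lambda i: v[i])
        i = 0
        while i < n:
            j = i
            while j + 1 < n and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def unpaired_permutation_oracle(a, b) -> float:
    """Exhaustive two-sided permutation p for a difference of means."""
    import itertools

    pooled = list(a) + list(b)
    na = len(a)
    obs = abs(sum(a) / na - sum(b) / len(b))
    count = 0
    total = 0
    for pick in itertools.combinations(range(len(pooled)), na):
        sa = [pooled[i] for i in pick]
        sb = [pooled[i] for i in range(len(pooled)) if i not in pick]
        if abs(sum(sa) / len(sa) - sum(sb) / len(sb)) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total
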