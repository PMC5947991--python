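"""Model configuration for the saccadic competition race.

All firing quantities are in normalized activity units (threshold crossings
occur around 1), times are in milliseconds, and build-up rates are in
normalized activity per millisecond.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Literal

ConditionLabel = Literal["congruent", "incongruent", "adr"]

CONDITIONS: tuple[str, ...] = ("congruent", "incongruent", "adr")


class ConfigurationError(ValueError):
    """Raised when model parameters violate their declared invariants."""


@dataclass(frozen=True)
class ModelParams:
    """Constants of the two-accumulator saccadic competition model.

    The defaults are the hand-tuned values for the one-direction-rewarded
    (1DR) task. The two mean baselines are stored as high/low levels; which
    accumulator (target T vs. opposite D) receives the higher mean is decided
    by the bias condition, since the higher baseline always sits at the
    rewarded location.
    """

    # Baseline draw: B = <B> * max(1 + sigma*eps, 0)
    mean_baseline_hi: float = 0.34
    mean_baseline_lo: float = 0.16
    baseline_cv: float = 0.28
    baseline_corr: float = -0.5

    # Threshold: Theta = max(theta_intercept + theta_slope*(BT-BD), theta_floor)
    theta_intercept: float = 1.185
    theta_slope: float = 1.2
    theta_floor: float = 0.73

    # Build-up rate of the internally driven plan:
    # G_D = gd_scale * max(gd_intercept + gd_slope*(BD-BT), 0)
    gd_scale: float = 0.001
    gd_intercept: float = 1.4
    gd_slope: float = 1.7

    # Target plan, regime 1 (BT >= BD):
    # G_T = gt1_scale * (gt1_intercept + gt1_noise*eta + gt1_slope*BT)
    gt1_scale: float = 0.001
    gt1_intercept: float = 6.16
    gt1_noise: float = 0.55
    gt1_slope: float = 2.5

    # Target plan, regime 2 (BT < BD):
    # G_T = gt1_scale * (gt2_intercept + gt2_noise*eta + gt2_slope*BT)
    #       / (1 + gt2_div*BD)
    gt2_intercept: float = 3.0
    gt2_noise: float = 0.3
    gt2_slope: float = 23.25
    gt2_div: float = 1.3

    # Afferent delays and transient stimulus-driven suppression of D
    afferent_T: float = 35.0
    afferent_D: float = 50.0
    inhib_on: float = 40.0
    inhib_off: float = 155.0
    inhib_gain: float = 0.38

    # Rule 1 winner rate: V_Twin = win_intercept + win_slope * G_T
    win_intercept: float = -0.0088
    win_slope: float = 2.6

    # Postsaccadic exponential decay
    decay_level: float = 0.2
    decay_tau: float = 120.0

    # Integration
    dt: float = 1.0
    trial_cap: float = 1000.0

    # ADR variant: equal mean baselines at the measured level, with reduced
    # baseline variability and a slightly lower maximal stimulus-driven
    # build-up. The last two values are not printed anywhere and are
    # package defaults.
    adr_baseline: float = 0.2
    adr_baseline_cv: float = 0.18
    adr_gt1_intercept: float = 5.8

    def __post_init__(self) -> None:
        if self.baseline_cv < 0 or self.adr_baseline_cv < 0:
            raise ConfigurationError("baseline variability must be >= 0")
        if not -1.0 < self.baseline_corr < 1.0:
            raise ConfigurationError(
                f"baseline_corr must lie in (-1, 1), got {self.baseline_corr}"
            )
        if self.theta_floor <= 0:
            raise ConfigurationError("theta_floor must be positive")
        if self.inhib_on >= self.inhib_off:
            raise ConfigurationError("inhib_on must precede inhib_off")
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.afferent_T < 0 or self.afferent_D < 0:
            raise ConfigurationError("afferent delays must be >= 0")
        if self.trial_cap <= 0:
            raise ConfigurationError("trial_cap must be positive")

    def condition_means(self, condition: str) -> tuple[float, float]:
        """Mean baselines (<BT>, <BD>) for a bias condition.

        congruent: the target sits at the rewarded location, so T takes the
        higher mean; incongruent: reversed; adr: both equal.
        """
        condition = _check_condition(condition)
        hi = max(self.mean_baseline_hi, self.mean_baseline_lo)
        lo = min(self.mean_baseline_hi, self.mean_baseline_lo)
        if condition == "congruent":
            return hi, lo
        if condition == "incongruent":
            return lo, hi
        return self.adr_baseline, self.adr_baseline

    def effective(self, condition: str) -> "ModelParams":
        """Parameters actually used when simulating `condition`.

        The ADR task uses equal means, reduced baseline variability, and a
        slightly reduced maximal target drive; the 1DR conditions use the
        instance as-is.
        """
        condition = _check_condition(condition)
        if condition != "adr":
            return self
        return replace(
            self,
            baseline_cv=self.adr_baseline_cv,
            gt1_intercept=self.adr_gt1_intercept,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise ConfigurationError(f"unknown parameter(s): {sorted(bad)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _check_condition(condition: str) -> str:
    c = condition.lower()
    if c not in CONDITIONS:
        raise ConfigurationError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )
    return c
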