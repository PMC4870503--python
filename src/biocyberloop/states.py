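"""Baseline calibration and quadrant classification of player state.

Each 5-s epoch's frontal theta (Fz) and parietal upper alpha (P4) band powers
are expressed as ratios to a per-user resting baseline and mapped onto the
four Motivational-Intensity quadrants:

==================  ===========  ===========
state               theta         upper alpha
==================  ===========  ===========
boredom             down          up
overload            down          down
engagement          not down      up
zone                otherwise (no trigger)
==================  ===========  ===========

A percent trigger T is read ratio-symmetrically on linear power: "up" means
ratio >= 1 + T/100 and "down" means ratio <= 1/(1 + T/100).  (A literal
"decrease by 200%" is impossible for non-negative power; the symmetric-ratio
reading preserves the printed magnitudes and makes up/down mirror images.)
The controller raises demand on boredom, lowers it on overload, and holds
otherwise; artifact-invalid epochs are indeterminate and always hold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import BandPowerSeries

__all__ = [
    "BaselineProfile",
    "DeviationPair",
    "ThresholdProfile",
    "CONSERVATIVE",
    "MODERATE",
    "LIBERAL",
    "PROFILES",
    "PlayerState",
    "Action",
    "compute_baseline",
    "deviation",
    "classify",
    "controller_action",
]

PlayerState = str  # {"boredom", "engagement", "zone", "overload", "indeterminate"}
Action = str       # {"increase", "decrease", "hold"}

MIN_BASELINE_S = 30.0


@dataclass(frozen=True)
class BaselineProfile:
    """Per-user resting band powers (µV², linear) from the relaxation baseline."""

    theta_baseline: float
    alpha_baseline: float
    source_duration: float = 0.0

    def __post_init__(self) -> None:
        if self.theta_baseline <= 0 or self.alpha_baseline <= 0:
            raise ValueError("baseline band powers must be > 0")


@dataclass(frozen=True)
class DeviationPair:
    theta_ratio: float
    alpha_ratio: float
    valid: bool = True


@dataclass(frozen=True)
class ThresholdProfile:
    """Reactivity profile: the percent deviation that triggers adaptation."""

    name: str
    trigger_percent: float

    def __post_init__(self) -> None:
        if self.trigger_percent <= 0:
            raise ValueError("trigger_percent must be > 0")
        fixed = {"conservative": 200.0, "moderate": 150.0, "liberal": 100.0}
        if self.name in fixed and self.trigger_percent != fixed[self.name]:
            raise ValueError(
                f"preset {self.name!r} is fixed at {fixed[self.name]:g}%"
            )

    @property
    def up_ratio(self) -> float:
        return 1.0 + self.trigger_percent / 100.0

    @property
    def down_ratio(self) -> float:
        return 1.0 / self.up_ratio


CONSERVATIVE = ThresholdProfile("conservative", 200.0)
MODERATE = ThresholdProfile("moderate", 150.0)
LIBERAL = ThresholdProfile("liberal", 100.0)
PROFILES = {p.name: p for p in (CONSERVATIVE, MODERATE, LIBERAL)}


def compute_baseline(series_theta: BandPowerSeries,
                     series_alpha: BandPowerSeries) -> BaselineProfile:
    """Mean linear band power over unflagged frames of the rest recording.

    Requires at least 30 s of clean (unflagged) frames per channel, counted as
    unflagged frames × frame hop.
    """
    clean_durations = []
    means = []
    for series in (series_theta, series_alpha):
        clean = ~series.artifact_flags
        dur = float(np.sum(clean) * series.frame_hop)
        clean_durations.append(dur)
        if dur < MIN_BASELINE_S:
            raise ValueError(
                f"insufficient clean baseline data on {series.channel}: "
                f"{dur:.1f} s found, {MIN_BASELINE_S:.0f} s required"
            )
        means.append(float(np.mean(series.power[clean])))
    return BaselineProfile(theta_baseline=means[0], alpha_baseline=means[1],
                           source_duration=min(clean_durations))


def deviation(epoch_theta: float, epoch_alpha: float,
              baseline: BaselineProfile, valid: bool = True) -> DeviationPair:
    """Epoch-to-baseline power ratios; ``valid=False`` marks artifact epochs."""
    if epoch_theta < 0 or epoch_alpha < 0:
        raise ValueError("epoch powers must be >= 0")
    return DeviationPair(
        theta_ratio=epoch_theta / baseline.theta_baseline,
        alpha_ratio=epoch_alpha / baseline.alpha_baseline,
        valid=valid,
    )


def classify(dev: DeviationPair, profile: ThresholdProfile) -> PlayerState:
    """Map a deviation pair to exactly one player state.

    theta-down ∧ alpha-up → boredom; theta-down ∧ alpha-down → overload;
    otherwise alpha-up → engagement, else zone.  Invalid → indeterminate.
    """
    if not dev.valid:
        return "indeterminate"
    theta_down = dev.theta_ratio <= profile.down_ratio
    alpha_up = dev.alpha_ratio >= profile.up_ratio
    alpha_down = dev.alpha_ratio <= profile.down_ratio
    if theta_down and alpha_up:
        return "boredom"
    if theta_down and alpha_down:
        return "overload"
    return "engagement" if alpha_up else "zone"


def controller_action(state: PlayerState) -> Action:
    """boredom → increase; overload → decrease; everything else holds."""
    if state == "boredom":
        return "increase"
    if state == "overload":
        return "decrease"
    if state in ("engagement", "zone", "indeterminate"):
        return "hold"
    raise ValueError(f"unknown player state {state!r}")
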