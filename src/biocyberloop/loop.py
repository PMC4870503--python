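"""Closed-loop session runner and manual-control benchmark.

Every 5 s the loop aggregates frontal-theta (Fz) and upper-alpha (P4) band
power over the past epoch, expresses both as ratios to the resting baseline,
classifies the player state, and covertly nudges the adaptive game's demand
level by one step (clamped to 1–10).  The game is simulated continuously
between decisions by the bot player; game death resets the board and the
level.  The EEG stream is open-loop by default: the synthetic player state
script does not react to demand, which keeps sessions deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import spectral, states, tetris
from .spectral import BandDef, FilterSpec, THETA_LOOP, UPPER_ALPHA
from .states import BaselineProfile, ThresholdProfile
from .synth import EEGRecording
from .tetris import BotPlayer, GameConfig, GameState

__all__ = ["LoopConfig", "EpochRecord", "AdaptationLog",
           "run_closed_loop", "run_manual_session", "handle_artifact_epoch"]


@dataclass(frozen=True)
class LoopConfig:
    baseline: BaselineProfile
    profile: ThresholdProfile = states.LIBERAL
    epoch_length: float = 5.0
    session_duration: float = 300.0
    step_size: int = 1
    theta_band: BandDef = THETA_LOOP
    alpha_band: BandDef = UPPER_ALPHA
    filter_spec: FilterSpec = FilterSpec()
    artifact_threshold: float = 100.0
    skill: float = 0.8
    tick: float = 1.0 / 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be > 0")
        n = self.session_duration / self.epoch_length
        if abs(n - round(n)) > 1e-9 or n < 1:
            raise ValueError("session_duration must be a multiple of epoch_length")
        if self.step_size < 1:
            raise ValueError("step_size must be >= 1")

    @property
    def n_epochs(self) -> int:
        return int(round(self.session_duration / self.epoch_length))


@dataclass
class EpochRecord:
    index: int
    start: float
    theta_ratio: float
    alpha_ratio: float
    state: str
    action: str
    demand_before: int
    demand_after: int
    reset_occurred: bool = False


@dataclass
class AdaptationLog:
    config: LoopConfig
    epochs: list[EpochRecord]
    game_events: list[tuple[float, str, str]]
    level_trace: list[tuple[float, int]]  # (time, level) at every change, t=0 first
    commands: list[tuple[float, str]] | None = None  # manual sessions only

    @property
    def final_level(self) -> int:
        return self.level_trace[-1][1]

    @property
    def initial_level(self) -> int:
        return self.level_trace[0][1]

    def to_rows(self) -> list[dict]:
        return [vars(e).copy() for e in self.epochs]


def handle_artifact_epoch(record: EpochRecord) -> EpochRecord:
    """Fail-safe for artifact-invalid epochs: indeterminate state, hold, no change."""
    return replace(record, state="indeterminate", action="hold",
                   demand_after=record.demand_before)


def epoch_ratio_stream(config: LoopConfig, recording: EEGRecording):
    """Run the real-time signal chain and yield per-epoch deviation pairs."""
    if recording.duration + 1e-9 < config.session_duration:
        raise ValueError(
            f"EEG ({recording.duration:.1f} s) shorter than the "
            f"{config.session_duration:.0f}-s session"
        )
    filtered = spectral.apply_bandpass(recording, config.filter_spec)
    flags = spectral.exclude_artifacts(recording, threshold=config.artifact_threshold)
    theta = spectral.band_power_series(
        spectral.short_time_spectra(filtered, "Fz"), config.theta_band, flags)
    alpha = spectral.band_power_series(
        spectral.short_time_spectra(filtered, "P4"), config.alpha_band, flags)
    ep_theta = spectral.epoch_band_power(theta, config.epoch_length)
    ep_alpha = spectral.epoch_band_power(alpha, config.epoch_length)
    pairs = []
    for k in range(config.n_epochs):
        valid = bool(ep_theta.valid[k] and ep_alpha.valid[k])
        if valid:
            dev = states.deviation(float(ep_theta.power[k]), float(ep_alpha.power[k]),
                                   config.baseline, valid=True)
        else:
            dev = states.DeviationPair(1.0, 1.0, valid=False)
        pairs.append(dev)
    return pairs


def _simulate_epoch(game: GameState, bot: BotPlayer, config: LoopConfig,
                    level_trace: list[tuple[float, int]]) -> bool:
    """Advance the game for one epoch; returns True if any reset occurred."""
    resets_before = game.resets
    n_ticks = int(round(config.epoch_length / config.tick))
    for _ in range(n_ticks):
        level_before = game.demand_level
        tetris.step(game, config.tick, bot.action(game))
        if game.demand_level != level_before:  # death reset inside the engine
            level_trace.append((game.elapsed, game.demand_level))
    return game.resets > resets_before


def run_closed_loop(config: LoopConfig, recording: EEGRecording,
                    game: GameState | None = None) -> AdaptationLog:
    """Run a full biocybernetic session against an EEG recording.

    Each epoch is played at the current demand level; at the epoch's end its
    band powers are classified and the level is adjusted by ±step_size
    (clamped to 1–10) for the next epoch.  Deterministic for fixed inputs.
    """
    if game is None:
        game = tetris.new_game(GameConfig(mode="adaptive", seed=config.seed))
    if game.config.mode != "adaptive":
        raise ValueError("closed loop requires an adaptive-mode game")
    if game.demand_level != 1:
        raise ValueError("every game begins on the slowest speed setting")
    pairs = epoch_ratio_stream(config, recording)
    bot = BotPlayer(config.skill, config.seed)
    level_trace = [(0.0, game.demand_level)]
    records: list[EpochRecord] = []
    for k, dev in enumerate(pairs):
        start = k * config.epoch_length
        demand_before = game.demand_level
        reset = _simulate_epoch(game, bot, config, level_trace)
        state = states.classify(dev, config.profile)
        action = states.controller_action(state)
        level = game.demand_level  # may differ from demand_before after a reset
        if action == "increase":
            level = min(level + config.step_size, 10)
        elif action == "decrease":
            level = max(level - config.step_size, 1)
        if level != game.demand_level:
            game.demand_level = level
            game.log("level_change", str(level))
            level_trace.append((game.elapsed, level))
        rec = EpochRecord(k, start, dev.theta_ratio, dev.alpha_ratio,
                          state, action, demand_before, level, reset)
        if not dev.valid:
            rec = handle_artifact_epoch(rec)
            rec = replace(rec, demand_after=game.demand_level)
        records.append(rec)
    return AdaptationLog(config, records, list(game.events), level_trace)


def run_manual_session(config: LoopConfig,
                       command_schedule: list[tuple[float, str]],
                       game: GameState | None = None) -> AdaptationLog:
    """Benchmark mode: spoken "higher"/"lower" commands adjust demand by ±1.

    No EEG is consulted; epochs are logged with action='manual'.
    """
    for i, (t, word) in enumerate(command_schedule):
        if word not in ("higher", "lower"):
            raise ValueError(f"command {i} has unknown word {word!r}")
        if not 0 <= t < config.session_duration:
            raise ValueError(f"command {i} at {t} s lies outside the session")
    if game is None:
        game = tetris.new_game(GameConfig(mode="adaptive", seed=config.seed))
    if game.demand_level != 1:
        raise ValueError("every game begins on the slowest speed setting")
    schedule = sorted(command_schedule, key=lambda c: c[0])
    bot = BotPlayer(config.skill, config.seed)
    level_trace = [(0.0, game.demand_level)]
    records: list[EpochRecord] = []
    cmd_i = 0
    for k in range(config.n_epochs):
        start = k * config.epoch_length
        demand_before = game.demand_level
        resets_before = game.resets
        n_ticks = int(round(config.epoch_length / config.tick))
        for _ in range(n_ticks):
            while cmd_i < len(schedule) and schedule[cmd_i][0] <= game.elapsed + 1e-9:
                word = schedule[cmd_i][1]
                delta = 1 if word == "higher" else -1
                new_level = int(np.clip(game.demand_level + delta, 1, 10))
                if new_level != game.demand_level:
                    game.demand_level = new_level
                    game.log("level_change", f"manual:{new_level}")
                    level_trace.append((game.elapsed, new_level))
                cmd_i += 1
            level_before = game.demand_level
            tetris.step(game, config.tick, bot.action(game))
            if game.demand_level != level_before:
                level_trace.append((game.elapsed, game.demand_level))
        records.append(EpochRecord(
            k, start, float("nan"), float("nan"), "manual", "manual",
            demand_before, game.demand_level, game.resets > resets_before))
    return AdaptationLog(config, records, list(game.events), level_trace,
                         commands=schedule)
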