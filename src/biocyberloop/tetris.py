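"""Headless adapted-Tetris engine with a parameterised bot player.

Two game modes mirror the two experimental uses of the game:

* ``fixed_demand`` — a fixed drop-speed preset (low / high / excessive), the
  board capped at its centre (bottom rows are silently discarded whenever the
  stack would rise above half height, so the game never dies), and an optional
  coin incentive accrued every 10 s against the maximum possible row clearance.
* ``adaptive`` — demand level 1–10 maps to drop speed; blocks reaching the top
  cause "game death" and a restart on an empty board at the slowest speed.

Coordinates: board is ``height × width`` booleans, row 0 at the top, columns
0-based.  A piece descends by ``speed × dt`` squares per step with fractional
progress accumulated.  All randomness flows through a seeded generator, so an
entire game trajectory reproduces bit-identically for a fixed (config, policy,
seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SHAPES",
    "DEMAND_PRESETS",
    "GameConfig",
    "Piece",
    "CoinLedger",
    "GameState",
    "demand_to_speed",
    "new_game",
    "step",
    "enforce_center_cap",
    "reset_on_death",
    "accrue_coins",
    "run_coin_schedule",
    "BotPlayer",
    "run_fixed_game",
]

# Cell offsets (row, col) inside a 4×4 box for each rotation of the 7 tetrominoes.
SHAPES: dict[str, list[list[tuple[int, int]]]] = {
    "I": [[(1, 0), (1, 1), (1, 2), (1, 3)], [(0, 2), (1, 2), (2, 2), (3, 2)]] * 2,
    "O": [[(0, 1), (0, 2), (1, 1), (1, 2)]] * 4,
    "T": [
        [(0, 1), (1, 0), (1, 1), (1, 2)],
        [(0, 1), (1, 1), (1, 2), (2, 1)],
        [(1, 0), (1, 1), (1, 2), (2, 1)],
        [(0, 1), (1, 0), (1, 1), (2, 1)],
    ],
    "S": [[(0, 1), (0, 2), (1, 0), (1, 1)], [(0, 1), (1, 1), (1, 2), (2, 2)]] * 2,
    "Z": [[(0, 0), (0, 1), (1, 1), (1, 2)], [(0, 2), (1, 1), (1, 2), (2, 1)]] * 2,
    "J": [
        [(0, 0), (1, 0), (1, 1), (1, 2)],
        [(0, 1), (0, 2), (1, 1), (2, 1)],
        [(1, 0), (1, 1), (1, 2), (2, 2)],
        [(0, 1), (1, 1), (2, 0), (2, 1)],
    ],
    "L": [
        [(0, 2), (1, 0), (1, 1), (1, 2)],
        [(0, 1), (1, 1), (2, 1), (2, 2)],
        [(1, 0), (1, 1), (1, 2), (2, 0)],
        [(0, 0), (0, 1), (1, 1), (2, 1)],
    ],
}
SHAPE_NAMES = tuple(sorted(SHAPES))

# Drop speeds in board squares per second for the fixed-demand presets.
DEMAND_PRESETS = {"low": 2.5, "high": 6.7, "excessive": 20.0}

#: Coin incentive constants: ledger cap, per-accrual cap, accrual period.
MAX_COINS = 70
MAX_COINS_PER_ACCRUAL = 7
ACCRUAL_PERIOD_S = 10.0


def demand_to_speed(level: int) -> float:
    """Drop speed for a demand level 1–10 (squares/s).

    Geometric interpolation anchored at level 1 → 2.5 and level 10 → 20
    squares/s, i.e. a constant per-level speed ratio of (20/2.5)**(1/9).
    """
    if not 1 <= level <= 10:
        raise ValueError(f"demand level {level} outside [1, 10]")
    return 2.5 * (20.0 / 2.5) ** ((level - 1) / 9.0)


@dataclass(frozen=True)
class GameConfig:
    board_width: int = 10
    board_height: int = 20
    mode: str = "adaptive"  # or "fixed_demand"
    demand_preset: str | None = None  # fixed_demand: low/high/excessive
    demand_level: int | None = None   # adaptive: 1–10
    incentive_enabled: bool = False
    game_duration: float = 180.0
    death_enabled: bool = True  # adaptive only; False trims the stack instead
    seed: int = 0

    def __post_init__(self) -> None:
        if self.board_width < 4 or self.board_height < 8:
            raise ValueError("board must be at least 4 wide and 8 tall")
        if self.mode == "fixed_demand":
            if self.demand_preset not in DEMAND_PRESETS or self.demand_level is not None:
                raise ValueError("fixed_demand mode takes demand_preset only")
        elif self.mode == "adaptive":
            level = 1 if self.demand_level is None else self.demand_level
            if self.demand_preset is not None or not 1 <= level <= 10:
                raise ValueError("adaptive mode takes demand_level in [1, 10] only")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class Piece:
    shape: str
    rotation: int
    row: int
    col: int

    def cells(self) -> list[tuple[int, int]]:
        return [(self.row + r, self.col + c)
                for r, c in SHAPES[self.shape][self.rotation % 4]]


@dataclass
class CoinLedger:
    total: int = 0
    accruals: list[tuple[float, int]] = field(default_factory=list)

    def award(self, now: float, coins: int) -> None:
        if not 0 <= coins <= MAX_COINS_PER_ACCRUAL:
            raise ValueError("award outside [0, 7]")
        if self.total + coins > MAX_COINS:
            raise ValueError("ledger over the 70-coin cap")
        self.total += coins
        self.accruals.append((now, coins))


@dataclass
class GameState:
    config: GameConfig
    grid: np.ndarray
    active: Piece
    demand_level: int
    cleared_rows: int = 0
    pieces_spawned: int = 0
    resets: int = 0
    elapsed: float = 0.0
    drop_progress: float = 0.0
    coins: CoinLedger = field(default_factory=CoinLedger)
    events: list[tuple[float, str, str]] = field(default_factory=list)
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    @property
    def speed(self) -> float:
        if self.config.mode == "fixed_demand":
            return DEMAND_PRESETS[self.config.demand_preset]
        return demand_to_speed(self.demand_level)

    @property
    def max_possible_rows(self) -> float:
        """Rows achievable from the squares delivered so far (pieces × 4 / width)."""
        return self.pieces_spawned * 4.0 / self.config.board_width

    def log(self, event: str, detail: str = "") -> None:
        self.events.append((self.elapsed, event, detail))

    def stack_height(self) -> int:
        occupied = np.flatnonzero(self.grid.any(axis=1))
        if occupied.size == 0:
            return 0
        return self.config.board_height - int(occupied[0])


def _fits(grid: np.ndarray, piece: Piece) -> bool:
    h, w = grid.shape
    for r, c in piece.cells():
        if not (0 <= r < h and 0 <= c < w) or grid[r, c]:
            return False
    return True


def _spawn(state: GameState) -> bool:
    """Spawn the next random piece; returns False when it cannot be placed."""
    shape = SHAPE_NAMES[int(state.rng.integers(len(SHAPE_NAMES)))]
    piece = Piece(shape, 0, 0, (state.config.board_width - 4) // 2)
    state.active = piece
    state.pieces_spawned += 1
    state.drop_progress = 0.0
    state.log("spawn", shape)
    return _fits(state.grid, piece)


def new_game(config: GameConfig) -> GameState:
    level = config.demand_level if config.mode == "adaptive" and config.demand_level else 1
    grid = np.zeros((config.board_height, config.board_width), dtype=bool)
    state = GameState(config=config, grid=grid,
                      active=Piece("O", 0, 0, 0), demand_level=level,
                      rng=np.random.default_rng(config.seed))
    _spawn(state)
    return state


def _clear_rows(state: GameState) -> int:
    full = np.flatnonzero(state.grid.all(axis=1))
    n = len(full)
    if n:
        keep = np.delete(state.grid, full, axis=0)
        state.grid = np.vstack(
            [np.zeros((n, state.config.board_width), dtype=bool), keep]
        )
        state.cleared_rows += n
        state.log("clear", str(n))
    return n


def enforce_center_cap(state: GameState) -> GameState:
    """Keep the stack at or below board centre by discarding bottom rows.

    Discarded rows never count as cleared; the game cannot die in this mode.
    """
    cap = state.config.board_height // 2
    excess = state.stack_height() - cap
    if excess > 0:
        w = state.config.board_width
        cells = int(state.grid[-excess:].sum())
        state.grid = np.vstack(
            [np.zeros((excess, w), dtype=bool), state.grid[:-excess]]
        )
        state.log("cap_discard", f"rows={excess} cells={cells}")
    return state


def reset_on_death(state: GameState) -> GameState:
    """Game death: empty board, slowest speed, reset counter incremented."""
    state.log("death", f"level={state.demand_level}")
    state.grid[:] = False
    state.demand_level = 1
    state.resets += 1
    state.log("reset", "level=1")
    _spawn(state)
    return state


def _lock(state: GameState) -> None:
    for r, c in state.active.cells():
        state.grid[r, c] = True
    state.log("lock", state.active.shape)
    _clear_rows(state)
    if state.config.mode == "fixed_demand":
        enforce_center_cap(state)
        _spawn(state)
        return
    # Adaptive: blocks reaching the top of the board (or a blocked spawn) = death.
    died = state.grid[:2].any() or not _spawn(state)
    if died:
        if state.config.death_enabled:
            reset_on_death(state)
        else:
            enforce_center_cap(state)
            if not _fits(state.grid, state.active):
                state.grid[:] = False


def _try_move(state: GameState, drow: int, dcol: int, drot: int) -> bool:
    p = state.active
    cand = Piece(p.shape, (p.rotation + drot) % 4, p.row + drow, p.col + dcol)
    if _fits(state.grid, cand):
        state.active = cand
        return True
    return False


def step(state: GameState, dt: float, action: str = "none") -> GameState:
    """Advance the game by ``dt`` seconds, applying one player action.

    Illegal moves are no-ops.  The piece descends by ``speed × dt`` squares;
    on landing it locks, full rows clear, and a new random piece spawns.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if action == "left":
        _try_move(state, 0, -1, 0)
    elif action == "right":
        _try_move(state, 0, 1, 0)
    elif action == "rotate":
        _try_move(state, 0, 0, 1)
    elif action != "none":
        raise ValueError(f"unknown action {action!r}")
    state.drop_progress += state.speed * dt
    while state.drop_progress >= 1.0:
        state.drop_progress -= 1.0
        if not _try_move(state, 1, 0, 0):
            _lock(state)
            break
    state.elapsed += dt
    return state


def accrue_coins(state: GameState, now: float) -> CoinLedger:
    """Award coins at a 10-s boundary, proportional to relative row clearance.

    The cumulative target is ``floor(70 × cleared_rows / max_possible_rows)``;
    the award is the shortfall against the target, clamped to [0, 7].
    """
    if not state.config.incentive_enabled:
        raise ValueError("incentive not enabled for this game")
    if abs(now / ACCRUAL_PERIOD_S - round(now / ACCRUAL_PERIOD_S)) > 1e-9:
        raise ValueError(f"accrual time {now} s is not a 10-s boundary")
    if state.max_possible_rows == 0:
        raise ValueError("no pieces delivered yet: max_possible_rows is 0")
    target = math.floor(MAX_COINS * state.cleared_rows / state.max_possible_rows)
    award = min(max(target - state.coins.total, 0), MAX_COINS_PER_ACCRUAL)
    state.coins.award(now, award)
    state.log("coin", str(award))
    return state.coins


def run_coin_schedule(game_duration: float = 180.0,
                      clearance_fraction: float = 1.0) -> CoinLedger:
    """Simulate the coin-accrual schedule for uniform-in-time clearance.

    A synthetic trajectory in which ``clearance_fraction`` of the possible
    rows are cleared, with progress uniform in time (one possible row per
    accrual period); used to study the incentive schedule in isolation from
    piece-level play.
    """
    if not 0.0 <= clearance_fraction <= 1.0:
        raise ValueError("clearance_fraction must lie in [0, 1]")
    config = GameConfig(board_width=8, mode="fixed_demand", demand_preset="low",
                        incentive_enabled=True, game_duration=game_duration)
    state = new_game(config)
    n_accruals = int(round(game_duration / ACCRUAL_PERIOD_S))
    for k in range(1, n_accruals + 1):
        now = k * ACCRUAL_PERIOD_S
        state.pieces_spawned = 2 * k  # 8 squares = one possible row per period
        state.cleared_rows = int(math.floor(clearance_fraction * k))
        accrue_coins(state, now)
    return state.coins


class BotPlayer:
    """Greedy one-piece-lookahead bot with a simple human motor model.

    On each spawn the bot scores every (rotation, column) landing by cleared
    lines, holes, aggregate height and bumpiness, then queues the rotations and
    lateral moves to reach the best placement.  ``skill`` ∈ [0, 1] controls the
    per-piece decision latency (0.15 + 0.6·(1 − skill) s) and the action rate
    (1 + 5·skill per second); skill 0 issues no actions at all.  Deterministic
    for a fixed seed.
    """

    def __init__(self, skill: float, seed: int = 0):
        if not 0.0 <= skill <= 1.0:
            raise ValueError("skill must lie in [0, 1]")
        self.skill = skill
        self.rng = np.random.default_rng(seed)
        self.queue: list[str] = []
        self.piece_id = -1
        self.ready_at = 0.0
        self.next_action_at = 0.0
        self.latency = 0.15 + 0.6 * (1.0 - skill)
        self.rate = 1.0 + 5.0 * skill

    def _plan(self, state: GameState) -> list[str]:
        grid = state.grid
        h, w = grid.shape
        best = None
        piece = state.active
        n_rots = len({tuple(map(tuple, r)) for r in SHAPES[piece.shape]})
        for drot in range(n_rots):
            rot = (piece.rotation + drot) % 4
            offs = SHAPES[piece.shape][rot]
            min_c = min(c for _, c in offs)
            max_c = max(c for _, c in offs)
            for col in range(-min_c, w - max_c):
                cand = Piece(piece.shape, rot, piece.row, col)
                if not _fits(grid, cand):
                    continue
                # Hard-drop: push down until blocked.
                while _fits(grid, Piece(piece.shape, rot, cand.row + 1, col)):
                    cand = Piece(piece.shape, rot, cand.row + 1, col)
                score = self._score(grid, cand)
                key = (score, -abs(col - piece.col), -drot)
                if best is None or key > best[0]:
                    best = (key, drot, col)
        if best is None:
            return []
        _, drot, col = best
        moves = ["rotate"] * drot
        delta = col - piece.col
        moves += (["right"] * delta) if delta > 0 else (["left"] * (-delta))
        return moves

    @staticmethod
    def _score(grid: np.ndarray, landed: Piece) -> float:
        h, w = grid.shape
        g = grid.copy()
        for r, c in landed.cells():
            g[r, c] = True
        full = g.all(axis=1)
        lines = int(full.sum())
        g = g[~full]
        heights = np.where(
            g.any(axis=0), h - np.argmax(g, axis=0) - (h - g.shape[0]), 0
        )
        filled_below = np.cumsum(g, axis=0)
        holes = int(np.sum((~g) & (filled_below > 0)))
        bump = int(np.sum(np.abs(np.diff(heights))))
        return 10.0 * lines - 4.0 * holes - 0.7 * float(heights.sum()) - 0.3 * bump

    def action(self, state: GameState) -> str:
        """Next action for the current tick (``'none'`` when idle)."""
        if self.skill == 0.0:
            return "none"
        if state.pieces_spawned != self.piece_id:
            self.piece_id = state.pieces_spawned
            self.queue = self._plan(state)
            self.ready_at = state.elapsed + self.latency
            self.next_action_at = self.ready_at
        if not self.queue or state.elapsed < self.next_action_at:
            return "none"
        self.next_action_at = state.elapsed + 1.0 / self.rate
        return self.queue.pop(0)


def run_fixed_game(config: GameConfig, skill: float = 1.0, seed: int = 0,
                   tick: float = 1.0 / 30.0) -> GameState:
    """Run a complete fixed-demand (or fixed-level adaptive) game with the bot.

    Coins are accrued at every 10-s boundary when the incentive is enabled.
    Returns the final state; performance = cleared_rows / max_possible_rows.
    """
    state = new_game(config)
    bot = BotPlayer(skill, seed)
    n_ticks = int(round(config.game_duration / tick))
    next_accrual = ACCRUAL_PERIOD_S
    for _ in range(n_ticks):
        step(state, tick, bot.action(state))
        if config.incentive_enabled and state.elapsed >= next_accrual - 1e-9:
            accrue_coins(state, next_accrual)
            next_accrual += ACCRUAL_PERIOD_S
    return state
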