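"""Board geometry and goal configurations for the Tacit Communication Game.

The game is played on a small rectangular grid. A trial is defined by a goal
configuration: the sender's start cell ``A``, the sender's goal ``Gs`` and the
receiver's hidden goal ``Gr``. Movement is 4-connected (north/east/south/west),
coordinates are 0-based ``(row, col)`` and there is no wraparound.

Trials are *direct* when ``Gr`` lies on some shortest path from ``A`` to
``Gs`` (the sender can pass it at no extra cost) and *indirect* otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

__all__ = [
    "Cell",
    "BoardSpec",
    "GoalConfiguration",
    "DIRECTIONS",
    "manhattan",
    "neighbors",
    "trial_type",
    "generate_configurations",
    "score",
    "configurations_to_json",
    "configurations_from_json",
]


class Cell(NamedTuple):
    """A grid position, 0-based (row, col)."""

    row: int
    col: int


#: Absolute moves in deterministic (lexicographic) order: N < E < S < W.
DIRECTIONS: tuple[tuple[str, int, int], ...] = (
    ("N", -1, 0),
    ("E", 0, 1),
    ("S", 1, 0),
    ("W", 0, -1),
)


@dataclass(frozen=True)
class BoardSpec:
    """Rectangular board dimensions.

    The default 3x3 board is the smallest on which every message shape used
    by the agents (pass-by, enter-exit, wiggly) is expressible.
    """

    n_rows: int = 3
    n_cols: int = 3

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("board must be at least 2x2")

    def contains(self, c: Cell) -> bool:
        return 0 <= c.row < self.n_rows and 0 <= c.col < self.n_cols

    def cells(self) -> Iterable[Cell]:
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                yield Cell(r, c)


def manhattan(c1: Cell, c2: Cell) -> int:
    """City-block distance |r1-r2| + |c1-c2|."""
    return abs(c1.row - c2.row) + abs(c1.col - c2.col)


def neighbors(c: Cell, board: BoardSpec) -> set[Cell]:
    """The 2-4 orthogonally adjacent on-board cells of ``c`` (never ``c``)."""
    if not board.contains(c):
        raise ValueError(f"cell {c} is off the {board.n_rows}x{board.n_cols} board")
    out = set()
    for _, dr, dc in DIRECTIONS:
        n = Cell(c.row + dr, c.col + dc)
        if board.contains(n):
            out.add(n)
    return out


@dataclass(frozen=True)
class GoalConfiguration:
    """One trial: start ``A``, sender goal ``Gs``, receiver goal ``Gr``."""

    A: Cell
    Gs: Cell
    Gr: Cell
    board: BoardSpec = field(default_factory=BoardSpec)

    def __post_init__(self) -> None:
        cells = (self.A, self.Gs, self.Gr)
        for c in cells:
            if not self.board.contains(c):
                raise ValueError(f"cell {c} is off the board")
        if len(set(cells)) != 3:
            raise ValueError("A, Gs and Gr must be pairwise distinct")

    @property
    def trial_type(self) -> str:
        return trial_type(self)


def trial_type(cfg: GoalConfiguration) -> str:
    """``"direct"`` iff Gr lies on some shortest A->Gs path, else ``"indirect"``.

    On an unobstructed grid a cell lies on a shortest path exactly when the
    triangle equality holds for the Manhattan metric.
    """
    on_path = manhattan(cfg.A, cfg.Gr) + manhattan(cfg.Gr, cfg.Gs) == manhattan(
        cfg.A, cfg.Gs
    )
    return "direct" if on_path else "indirect"


def generate_configurations(
    board: BoardSpec,
    n_direct: int,
    n_indirect: int,
    seed: int,
) -> list[GoalConfiguration]:
    """Sample distinct goal configurations without replacement, reproducibly.

    The session design of the simulation study uses 20 direct and 10 indirect
    trials; this generator produces any requested split. Raises ``ValueError``
    when the board cannot supply the requested counts.
    """
    if n_direct < 0 or n_indirect < 0:
        raise ValueError("counts must be nonnegative")
    direct: list[GoalConfiguration] = []
    indirect: list[GoalConfiguration] = []
    cells = list(board.cells())
    for a in cells:
        for gs in cells:
            for gr in cells:
                if len({a, gs, gr}) != 3:
                    continue
                cfg = GoalConfiguration(A=a, Gs=gs, Gr=gr, board=board)
                (direct if cfg.trial_type == "direct" else indirect).append(cfg)
    if n_direct > len(direct) or n_indirect > len(indirect):
        raise ValueError(
            f"board supplies {len(direct)} direct / {len(indirect)} indirect "
            f"configurations; requested {n_direct}/{n_indirect}"
        )
    rng = np.random.default_rng(seed)
    picked_d = [direct[i] for i in rng.choice(len(direct), n_direct, replace=False)] if n_direct else []
    picked_i = [indirect[i] for i in rng.choice(len(indirect), n_indirect, replace=False)] if n_indirect else []
    out = picked_d + picked_i
    rng.shuffle(out)  # interleave trial types
    return out


def score(m, endowment: int = 10) -> int:
    """Trial score: the endowment minus one point per movement step.

    A message with L states has L-1 steps, so score = endowment - (L - 1).
    Accepts a Message or anything with a length.
    """
    length = len(m)
    return endowment - (length - 1)


# ---------------------------------------------------------------------------
# JSON (de)serialization of configuration sets


def configurations_to_json(configs: list[GoalConfiguration]) -> str:
    if not configs:
        return json.dumps({"board": {"rows": 3, "cols": 3}, "trials": []})
    board = configs[0].board
    payload = {
        "board": {"rows": board.n_rows, "cols": board.n_cols},
        "trials": [
            {"A": list(c.A), "Gs": list(c.Gs), "Gr": list(c.Gr)} for c in configs
        ],
    }
    return json.dumps(payload, indent=1)


def configurations_from_json(text: str) -> list[GoalConfiguration]:
    """Parse a configuration file, validating invariants and trial types."""
    data = json.loads(text)
    board = BoardSpec(int(data["board"]["rows"]), int(data["board"]["cols"]))
    out = []
    for t in data["trials"]:
        out.append(
            GoalConfiguration(
                A=Cell(*t["A"]), Gs=Cell(*t["Gs"]), Gr=Cell(*t["Gr"]), board=board
            )
        )
    return out
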