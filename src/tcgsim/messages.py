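"""Messages: grid walks that communicate the receiver's goal.

A message ``m = [s1, ..., sn]`` is an ordered sequence of 4-connected cells
that starts at the trial's start cell ``A``, ends at the sender's goal ``Gs``
and passes through the receiver's goal ``Gr``. Two quantities drive all agent
reasoning:

* ``L(m)`` — the number of *states* in the sequence (revisits counted), and
* ``U(m)`` — the set of *unique* states, ``|U(m)| <= L(m)``.

Note the off-by-one between conventions: a message of L states takes L-1
movement steps and therefore costs L-1 points.

The full message space is infinite (walks may revisit cells indefinitely), so
enumeration is capped at a maximum sequence length; the default cap allows
four states beyond the minimal valid length, enough to contain every message
shape the agents produce on small boards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

from .gridworld import DIRECTIONS, BoardSpec, Cell, GoalConfiguration, manhattan

__all__ = [
    "Message",
    "validate_message",
    "validate_message_strict",
    "enumerate_messages",
    "enumerate_walks",
    "shortest_path_states",
    "min_via_states",
    "default_cap",
    "classify",
    "MESSAGE_CLASSES",
]

MESSAGE_CLASSES = ("pass_by", "enter_exit", "wiggly", "other")


@dataclass(frozen=True)
class Message:
    """An ordered cell sequence; immutable and hashable."""

    states: tuple[Cell, ...]

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValueError("a message needs at least 2 states")
        object.__setattr__(
            self, "states", tuple(Cell(*s) for s in self.states)
        )

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    @property
    def L(self) -> int:
        """Sequence length: number of states, revisits counted."""
        return len(self.states)

    @property
    def unique(self) -> frozenset[Cell]:
        """U(m): the set of unique states."""
        return frozenset(self.states)

    @property
    def n_unique(self) -> int:
        return len(self.unique)

    @property
    def is_simple(self) -> bool:
        return self.n_unique == self.L


def _adjacent(a: Cell, b: Cell) -> bool:
    return manhattan(a, b) == 1


def validate_message(m: Message, cfg: GoalConfiguration) -> bool:
    """True iff m starts at A, ends at Gs, visits Gr, and every step is legal."""
    try:
        validate_message_strict(m, cfg)
    except ValueError:
        return False
    return True


def validate_message_strict(m: Message, cfg: GoalConfiguration) -> None:
    """Raise ``ValueError`` naming the violated clause; pass silently if valid."""
    if m.states[0] != cfg.A:
        raise ValueError(f"message starts at {m.states[0]}, not at A={cfg.A}")
    if m.states[-1] != cfg.Gs:
        raise ValueError(f"message ends at {m.states[-1]}, not at Gs={cfg.Gs}")
    for s in m.states:
        if not cfg.board.contains(s):
            raise ValueError(f"state {s} is off the board")
    for a, b in zip(m.states, m.states[1:]):
        if not _adjacent(a, b):
            raise ValueError(f"step {a}->{b} is not an orthogonal move")
    if cfg.Gr not in m.unique:
        raise ValueError(f"message never visits Gr={cfg.Gr}")


def min_via_states(s: Cell, cfg: GoalConfiguration) -> int:
    """Minimal L over A->Gs messages passing through ``s`` (closed form).

    Any walk through ``s`` needs at least d(A,s) + d(s,Gs) steps, and a
    concatenation of shortest legs achieves the bound, so the minimum
    sequence length is d(A,s) + d(s,Gs) + 1.
    """
    if not cfg.board.contains(s):
        raise ValueError(f"cell {s} is off the board")
    return manhattan(cfg.A, s) + manhattan(s, cfg.Gs) + 1


def default_cap(cfg: GoalConfiguration, extra: int = 4) -> int:
    """Default enumeration cap: minimal valid message length plus ``extra``."""
    return min_via_states(cfg.Gr, cfg) + extra


@lru_cache(maxsize=4096)
def _walks_cached(
    board: BoardSpec,
    start: Cell,
    end: Cell,
    max_states: int,
    forbidden: frozenset[Cell],
    via: Cell | None,
) -> tuple[tuple[Cell, ...], ...]:
    """Depth-first enumeration of walks, lexicographic in N<E<S<W moves.

    Prunes branches that cannot reach ``end`` (through ``via`` if required)
    within the state budget; the cached result is shared by senders,
    receivers and tests that sweep many configurations.
    """
    n_rows, n_cols = board.n_rows, board.n_cols
    results: list[tuple[Cell, ...]] = []
    if start in forbidden or end in forbidden:
        return ()

    def dist(a: Cell, b: Cell) -> int:
        return abs(a.row - b.row) + abs(a.col - b.col)

    def rec(path: list[Cell], via_done: bool) -> None:
        cur = path[-1]
        if len(path) >= 2 and cur == end and via_done:
            results.append(tuple(path))
        remaining = max_states - len(path)
        if remaining <= 0:
            return
        for _, dr, dc in DIRECTIONS:
            nxt = Cell(cur.row + dr, cur.col + dc)
            if not (0 <= nxt.row < n_rows and 0 <= nxt.col < n_cols):
                continue
            if nxt in forbidden:
                continue
            nd = via_done or (via is not None and nxt == via)
            need = dist(nxt, end) if (nd or via is None) else dist(nxt, via) + dist(via, end)
            if need > remaining - 1:
                continue
            path.append(nxt)
            rec(path, nd)
            path.pop()

    rec([start], via is None or start == via)
    return tuple(results)


def enumerate_walks(
    board: BoardSpec,
    start: Cell,
    end: Cell,
    max_states: int,
    forbidden: frozenset[Cell] | set[Cell] = frozenset(),
    via: Cell | None = None,
) -> tuple[tuple[Cell, ...], ...]:
    """All walks start->end with at most ``max_states`` states, in a
    deterministic order (lexicographic on move sequences, N<E<S<W).

    ``forbidden`` cells are never entered; ``via`` (if given) must appear in
    the walk. Walks of length 1 (start == end with no move) are not emitted.
    """
    return _walks_cached(board, start, end, max_states, frozenset(forbidden), via)


def enumerate_messages(
    cfg: GoalConfiguration, max_states: int | None = None
) -> tuple[Message, ...]:
    """Every valid message with L(m) <= ``max_states``, deterministically ordered.

    Returns an empty tuple (with a warning) when the cap is below the minimal
    valid length.
    """
    if max_states is None:
        max_states = default_cap(cfg)
    if max_states < min_via_states(cfg.Gr, cfg):
        warnings.warn(
            f"cap {max_states} is below the minimal valid message length "
            f"{min_via_states(cfg.Gr, cfg)}; no messages exist",
            stacklevel=2,
        )
        return ()
    walks = enumerate_walks(
        cfg.board, cfg.A, cfg.Gs, max_states, via=cfg.Gr
    )
    return tuple(Message(w) for w in walks)


def shortest_path_states(
    board: BoardSpec, start: Cell, end: Cell, forbidden: frozenset[Cell] | set[Cell] = frozenset()
) -> int:
    """Number of states on a shortest start->end path avoiding ``forbidden``.

    Plain breadth-first search; raises ``ValueError`` when no path exists
    (e.g. the forbidden set disconnects the board).
    """
    if start in forbidden or end in forbidden:
        raise ValueError("endpoint is forbidden")
    frontier = [start]
    seen = {start}
    depth = 0
    while frontier:
        if end in frontier:
            return depth + 1
        nxt = []
        for c in frontier:
            for _, dr, dc in DIRECTIONS:
                n = Cell(c.row + dr, c.col + dc)
                if board.contains(n) and n not in seen and n not in forbidden:
                    seen.add(n)
                    nxt.append(n)
        frontier = nxt
        depth += 1
    raise ValueError(f"no path from {start} to {end} avoiding {set(forbidden)}")


def classify(m: Message, cfg: GoalConfiguration, strict: bool = True) -> str:
    """Assign one of the message classes by revisit structure.

    * ``wiggly``     — Gr occurs at least twice in the sequence (the sender
      shuttles in and out of the receiver's goal);
    * ``enter_exit`` — some state is revisited, but not Gr (a side-trip into
      Gr with a backtrack elsewhere on the path);
    * ``pass_by``    — a simple path, Gr passed once en route.

    Exactly one label applies; ``other`` is unreachable under this rule set
    and retained only for classifier variants.
    """
    if strict:
        validate_message_strict(m, cfg)
    gr_visits = sum(1 for s in m.states if s == cfg.Gr)
    if gr_visits >= 2:
        return "wiggly"
    if m.n_unique < m.L:
        return "enter_exit"
    return "pass_by"
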