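"""Recursive Theory-of-Mind senders: level-specific message sets.

Each ToM level selects uniformly at random from a message set built from the
capped enumeration of the full message space M:

* ToM-0 minimizes sequence length:      M0 = {m in M : L(m) minimal};
* ToM-1 minimizes unique states:        M1 = {m in M : |U(m)| minimal};
* ToM-2 deliberately spends one extra unique state so the receiver's
  elimination strategy singles out Gr: with M2_direct the shortest Gr-avoiding
  A->Gs walks, M2_pass = {m in M : |U(m)| = min|U| over M2_direct + 1}.

ToM-0 does not reason about the partner; ToM-1 models a ToM-0 receiver
(fewer unique states = fewer candidate goals); ToM-2 models a ToM-1 receiver
(the one-extra-state detour survives the receiver's shorter-path elimination
and marks the goal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gridworld import GoalConfiguration
from .messages import (
    Message,
    default_cap,
    enumerate_messages,
    enumerate_walks,
    min_via_states,
    shortest_path_states,
)

__all__ = [
    "MessageSet",
    "build_M0",
    "build_M1",
    "build_M2",
    "build_for_level",
    "select_message",
    "UnsupportedConfigurationError",
]


class UnsupportedConfigurationError(ValueError):
    """Raised when a configuration admits no message of the required kind."""


@dataclass(frozen=True)
class MessageSet:
    """An enumerated candidate set for one sender level."""

    kind: str  # "M0" | "M1" | "M2_direct" | "M2_pass"
    messages: tuple[Message, ...]
    cap_used: int

    def __post_init__(self) -> None:
        if self.kind not in ("M0", "M1", "M2_direct", "M2_pass"):
            raise ValueError(f"unknown message-set kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.messages)


def build_M0(cfg: GoalConfiguration) -> MessageSet:
    """All valid messages of minimal sequence length.

    The minimum is the closed-form via-length of Gr, so enumeration can be
    capped there exactly.
    """
    cap = min_via_states(cfg.Gr, cfg)
    msgs = tuple(m for m in enumerate_messages(cfg, cap) if m.L == cap)
    return MessageSet("M0", msgs, cap)


def build_M1(cfg: GoalConfiguration, cap: int | None = None) -> MessageSet:
    """All valid messages (L <= cap) achieving the minimal unique-state count.

    No additional length tie-break is applied: equal-|U| messages of
    different lengths and shapes are all retained, which is what produces
    the mixed pass-by/enter-exit/wiggly output distribution of this level.
    """
    if cap is None:
        cap = default_cap(cfg)
    if cap < min_via_states(cfg.Gr, cfg):
        raise ValueError(f"cap {cap} below minimal valid message length")
    msgs = enumerate_messages(cfg, cap)
    min_u = min(m.n_unique for m in msgs)
    return MessageSet("M1", tuple(m for m in msgs if m.n_unique == min_u), cap)


def build_M2(
    cfg: GoalConfiguration, cap: int | None = None
) -> tuple[MessageSet, MessageSet]:
    """The (M2_direct, M2_pass) pair; the sender draws from M2_pass.

    M2_direct holds the shortest A->Gs walks that avoid Gr entirely (these
    are simple paths, so their unique count equals their length). M2_pass
    holds the valid messages spending exactly one unique state more — the
    minimal detour that still survives a ToM-1 receiver's elimination.

    When Gr lies far off a short A->Gs route, one extra unique state cannot
    reach it; the target then rises to the minimal unique count any valid
    message achieves, which collapses this level onto the ToM-1 choice (on
    such trials the two levels genuinely coincide: the cheapest goal-visiting
    message is already the maximally informative one).
    """
    if cap is None:
        cap = default_cap(cfg)
    try:
        min_avoid = shortest_path_states(cfg.board, cfg.A, cfg.Gs, frozenset({cfg.Gr}))
    except ValueError as e:
        raise UnsupportedConfigurationError(
            f"no Gr-avoiding path from A to Gs: {e}"
        ) from e
    direct_walks = enumerate_walks(
        cfg.board, cfg.A, cfg.Gs, min_avoid, forbidden=frozenset({cfg.Gr})
    )
    m2_direct = MessageSet(
        "M2_direct", tuple(Message(w) for w in direct_walks), min_avoid
    )
    min_u_direct = min(m.n_unique for m in m2_direct.messages)
    candidates = enumerate_messages(cfg, cap)
    min_u_valid = min(m.n_unique for m in candidates)
    target = max(min_u_direct + 1, min_u_valid)
    m2_pass = MessageSet(
        "M2_pass",
        tuple(m for m in candidates if m.n_unique == target),
        cap,
    )
    if not m2_pass.messages:
        raise UnsupportedConfigurationError(
            f"no valid message with {target} unique states under cap {cap}"
        )
    return m2_direct, m2_pass


def build_for_level(
    cfg: GoalConfiguration, level: int, cap: int | None = None
) -> MessageSet:
    """The message set a level-``level`` sender draws from."""
    if level == 0:
        return build_M0(cfg)
    if level == 1:
        return build_M1(cfg, cap)
    if level == 2:
        return build_M2(cfg, cap)[1]
    raise ValueError(f"unsupported ToM level {level}")


def select_message(
    ms: MessageSet, seed: int | np.random.Generator | None = None
) -> Message:
    """Uniform draw from the set, reproducible under a fixed seed."""
    if not ms.messages:
        raise ValueError(f"cannot select from empty message set {ms.kind}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return ms.messages[int(rng.integers(len(ms.messages)))]
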