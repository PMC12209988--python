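"""Theory-of-Mind receivers: candidate-goal construction and elimination.

A receiver observes the sender's message ``m*`` and must guess the hidden
goal ``Gr`` among the visited cells. The levels differ in how aggressively
they eliminate candidates by simulating the messages a lower-level sender
*would* have used:

* ToM-0 keeps every visited cell except the start ``A`` and the sender goal
  ``Gs`` and guesses uniformly.
* ToM-1 knows a ToM-0 sender uses shortest messages, so it discards any
  visited cell that also lies on some strictly shorter A->Gs walk: such a
  cell could have been communicated more cheaply, hence is unlikely to be
  the goal.
* ToM-2 knows a ToM-1 sender minimizes *unique* states and eliminates more:
  any visited cell reachable by a walk using fewer unique states than
  ``|U(m*)|``.

Both elimination rules have an equivalent closed form via the minimal
via-length ``min_via_states``: a cell lies on some A->Gs walk with fewer than
``k`` states iff its via-length is < k (back-and-forth padding fixes parity).
The explicit simulation ("union") mode and the closed form are both provided
and are proven equal on small boards by exhaustive tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gridworld import Cell, GoalConfiguration
from .messages import Message, enumerate_walks, min_via_states, validate_message_strict

__all__ = [
    "CandidateSet",
    "tom0_candidates",
    "tom1_candidates",
    "tom2_candidates",
    "candidates_for_level",
    "select_goal",
    "p_correct",
]


@dataclass(frozen=True)
class CandidateSet:
    """Candidate goal cells a receiver considers, with provenance.

    ``fallback_from`` records degraded elimination: a ToM-2 receiver whose
    rule eliminates every cell falls back to the ToM-1 rule, then ToM-0
    (the flag keeps such trials auditable rather than silently weaker).
    """

    candidates: frozenset[Cell]
    observed: Message
    level: int
    fallback_from: int | None = field(default=None)

    def __len__(self) -> int:
        return len(self.candidates)


def _base_exclusions(m: Message, cfg: GoalConfiguration) -> frozenset[Cell]:
    # A and Gs are excluded as cells (all occurrences): sequence positions
    # are ill-defined once the walk revisits them.
    return frozenset({cfg.A, cfg.Gs})


def tom0_candidates(m_star: Message, cfg: GoalConfiguration) -> CandidateSet:
    """Every visited cell except A and Gs."""
    validate_message_strict(m_star, cfg)
    cands = m_star.unique - _base_exclusions(m_star, cfg)
    return CandidateSet(frozenset(cands), m_star, 0)


def _eliminate(
    m_star: Message,
    cfg: GoalConfiguration,
    shorter_than: int,
    mode: str,
) -> frozenset[Cell]:
    """Visited cells not on any A->Gs walk with fewer than ``shorter_than`` states."""
    base = m_star.unique - _base_exclusions(m_star, cfg)
    if mode == "closed_form":
        return frozenset(
            s for s in base if min_via_states(s, cfg) >= shorter_than
        )
    if mode == "union":
        covered: set[Cell] = set()
        for walk in enumerate_walks(cfg.board, cfg.A, cfg.Gs, shorter_than - 1):
            covered.update(walk)
        return frozenset(s for s in base if s not in covered)
    raise ValueError(f"unknown mode {mode!r}")


def tom1_candidates(
    m_star: Message, cfg: GoalConfiguration, mode: str = "closed_form"
) -> CandidateSet:
    """Eliminate cells communicable by a message shorter than L(m*).

    Falls back to the ToM-0 rule (flagged) if elimination empties the set,
    which happens when the observed message is longer than every visited
    cell's minimal via-length.
    """
    validate_message_strict(m_star, cfg)
    cands = _eliminate(m_star, cfg, m_star.L, mode)
    if cands:
        return CandidateSet(cands, m_star, 1)
    fallback = tom0_candidates(m_star, cfg)
    return CandidateSet(fallback.candidates, m_star, 1, fallback_from=1)


def tom2_candidates(
    m_star: Message, cfg: GoalConfiguration, mode: str = "closed_form"
) -> CandidateSet:
    """Eliminate cells communicable with fewer unique states than |U(m*)|.

    Simulated walks are those with at most |U(m*)| - 1 states — each such
    walk necessarily visits fewer than |U(m*)| unique cells. On direct
    trials this rule can eliminate Gr itself (Gr lies on a shortest path);
    an emptied set degrades to the ToM-1 rule, then ToM-0, flagged.
    """
    validate_message_strict(m_star, cfg)
    cands = _eliminate(m_star, cfg, m_star.n_unique, mode)
    if cands:
        return CandidateSet(cands, m_star, 2)
    lower = tom1_candidates(m_star, cfg, mode)
    return CandidateSet(
        lower.candidates, m_star, 2, fallback_from=2 if lower.fallback_from is None else lower.fallback_from
    )


def candidates_for_level(
    m_star: Message, cfg: GoalConfiguration, level: int, mode: str = "closed_form"
) -> CandidateSet:
    if level == 0:
        return tom0_candidates(m_star, cfg)
    if level == 1:
        return tom1_candidates(m_star, cfg, mode)
    if level == 2:
        return tom2_candidates(m_star, cfg, mode)
    raise ValueError(f"unsupported receiver level {level}")


def select_goal(
    cs: CandidateSet, seed: int | np.random.Generator | None = None
) -> Cell:
    """Uniform seeded draw from the candidate set."""
    if not cs.candidates:
        raise ValueError("cannot select from an empty candidate set")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ordered = sorted(cs.candidates)
    return ordered[int(rng.integers(len(ordered)))]


def p_correct(cs: CandidateSet, cfg: GoalConfiguration) -> float:
    """Analytic probability a uniform guess from the set hits Gr."""
    if cfg.Gr not in cs.candidates:
        return 0.0
    return 1.0 / len(cs.candidates)
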