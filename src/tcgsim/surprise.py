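"""The Surprise sender: communicating by violating movement expectations.

Instead of selecting a message from an enumerated set, this agent *constructs*
its trajectory step by step. Two priors define what an observer expects:

* a **movement prior** over relative moves — a token is expected to keep
  going forward (objects in motion stay in motion), turns are less likely,
  reversals least:  p(f) > p(l) = p(r) > p(b), parameterized by
  lambda = p(b) and gamma = p(f) / (p(l) + p(r));
* a **state prior** over cells decaying geometrically with Manhattan
  distance d from the sender's goal:  p(s) proportional to alpha**(-d).

The two multiply into an action posterior p(a|s) (normalized over on-board
moves), whose Shannon surprise h(a|s) = -log2 p(a|s) is the signaling
currency: the planner *seeks* surprising moves near the receiver's goal so
they stand out, weighting each candidate move by its surprise times the
discounted points still attainable. Planning is a depth-H policy tree with
per-depth discount; once the trajectory has entered and left the receiver's
goal the agent switches to a homing phase that follows the state prior (and
hence a shortest path) to its own goal.

Ablations reproduce the model's component analysis: movement-prior-only
planning reverses direction incessantly and fails to terminate; state-prior
-only planning walks a minimal direct path and signals nothing; the full
model with reward produces enter-exit / wiggly messages with the surprise
spike at the receiver's goal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .gridworld import DIRECTIONS, Cell, GoalConfiguration, manhattan
from .messages import Message

__all__ = [
    "SurpriseParams",
    "movement_prior",
    "state_prior",
    "action_posterior",
    "surprise",
    "reward",
    "expected_values",
    "action_probabilities",
    "generate_message",
    "GeneratedMessage",
]

_OPPOSITE = {"N": "S", "S": "N", "E": "W", "W": "E"}
_LEFT = {"N": "W", "W": "S", "S": "E", "E": "N"}
_DELTA = {name: (dr, dc) for name, dr, dc in DIRECTIONS}


@dataclass(frozen=True)
class SurpriseParams:
    """Planner parameters.

    lambda_back : probability of a backward move (small; guidance band
        0.001-0.3, 0 allowed for analytic examples).
    gamma_ratio : forward-to-turn probability ratio p(f)/(p(l)+p(r));
        guidance band 2-10.
    alpha_decay : geometric decay of the state prior with goal distance
        (> 0; 1 flattens it).
    tau_softmax : softmax inverse temperature for stochastic action choice
        (0 = uniform).
    epsilon_discount : per-depth discount in the policy tree, in (0, 1].
    horizon : planning depth H >= 1.
    endowment : starting points; also the hard step budget for generation.
    """

    lambda_back: float = 0.05
    gamma_ratio: float = 3.0
    alpha_decay: float = 2.0
    tau_softmax: float = 5.0
    epsilon_discount: float = 0.9
    horizon: int = 2
    endowment: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_back < 1.0:
            raise ValueError("lambda_back must be in [0, 1)")
        if self.gamma_ratio <= 0:
            raise ValueError("gamma_ratio must be positive")
        if self.alpha_decay <= 0:
            raise ValueError("alpha_decay must be positive")
        if self.tau_softmax < 0:
            raise ValueError("tau_softmax must be nonnegative")
        if not 0.0 < self.epsilon_discount <= 1.0:
            raise ValueError("epsilon_discount must be in (0, 1]")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.lambda_back != 0.0 and not 0.001 <= self.lambda_back <= 0.3:
            warnings.warn("lambda_back outside the usual 0.001-0.3 band", stacklevel=2)
        if not 2.0 <= self.gamma_ratio <= 10.0:
            warnings.warn("gamma_ratio outside the usual 2-10 band", stacklevel=2)


def movement_prior(params: SurpriseParams, heading: str | None = None) -> dict[str, float]:
    """Relative-move probabilities {forward, left, right, back}, summing to 1.

    With gamma = p(f)/(p(l)+p(r)) and lambda = p(b):
    p(f) = (gamma/(gamma+1)) (1-lambda),  p(l) = p(r) = half the rest.
    ``heading`` is accepted for symmetry with the posterior API; the relative
    distribution itself does not depend on it.
    """
    lam, gam = params.lambda_back, params.gamma_ratio
    pf = gam / (gam + 1.0) * (1.0 - lam)
    pl = 0.5 * (1.0 - gam / (gam + 1.0)) * (1.0 - lam)
    return {"forward": pf, "left": pl, "right": pl, "back": lam}


def state_prior(s: Cell, Gs: Cell, alpha: float) -> float:
    """Unnormalized goal-orientation weight alpha**(-d(s, Gs))."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return float(alpha) ** (-manhattan(s, Gs))


def _relative(heading: str, move: str) -> str:
    if move == heading:
        return "forward"
    if move == _OPPOSITE[heading]:
        return "back"
    if move == _LEFT[heading]:
        return "left"
    return "right"


def _available_moves(s: Cell, cfg: GoalConfiguration) -> list[tuple[str, Cell]]:
    out = []
    for name, dr, dc in DIRECTIONS:
        nxt = Cell(s.row + dr, s.col + dc)
        if cfg.board.contains(nxt):
            out.append((name, nxt))
    return out


def action_posterior(
    s: Cell,
    heading: str | None,
    params: SurpriseParams,
    cfg: GoalConfiguration,
    component_mode: str = "full",
) -> dict[str, float]:
    """Normalized next-move distribution p(a|s) over on-board moves.

    The numerator is movement prior x landing-cell state prior (``full``),
    the movement prior alone (``movement_only``) or the state prior alone
    (``state_only``). Before the first move there is no heading and the
    movement component is uniform — only the state prior differentiates.
    Off-board moves get zero weight and are dropped from the normalization.
    """
    if component_mode not in ("full", "movement_only", "state_only"):
        raise ValueError(f"unknown component_mode {component_mode!r}")
    moves = _available_moves(s, cfg)
    if not moves:
        raise ValueError(f"no available moves from {s}")
    rel = movement_prior(params) if heading is not None else None
    weights: dict[str, float] = {}
    for name, nxt in moves:
        w = 1.0
        if component_mode in ("full", "movement_only"):
            w *= rel[_relative(heading, name)] if rel is not None else 1.0
        if component_mode in ("full", "state_only"):
            w *= state_prior(nxt, cfg.Gs, params.alpha_decay)
        weights[name] = w
    total = sum(weights.values())
    if total <= 0:
        # all-zero numerators (e.g. lambda=0 leaving only a backward move):
        # fall back to uniform over available moves
        return {name: 1.0 / len(moves) for name, _ in moves}
    return {name: w / total for name, w in weights.items()}


def surprise(p: float) -> float:
    """Shannon surprise -log2(p), in bits; p must be in (0, 1]."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"probability must be in (0, 1], got {p}")
    return -math.log2(p)


def reward(
    s_next: Cell,
    steps_elapsed: int,
    cfg: GoalConfiguration,
    params: SurpriseParams | None = None,
    gr_reached: bool = True,
) -> float:
    """Points still attainable after moving to ``s_next``, floored at 0.

    The agent has spent ``steps_elapsed + 1`` steps after this move; the
    best case completes the trial along a shortest remaining route. Before
    the receiver's goal has been visited that route still has to pass
    through it (d(s', Gr) + d(Gr, Gs)); afterwards it runs straight to the
    sender's goal (d(s', Gs)).
    """
    params = params or SurpriseParams()
    if steps_elapsed < 0:
        raise ValueError("steps_elapsed must be nonnegative")
    if gr_reached or s_next == cfg.Gr:
        remaining = manhattan(s_next, cfg.Gs)
    else:
        remaining = manhattan(s_next, cfg.Gr) + manhattan(cfg.Gr, cfg.Gs)
    return max(0.0, params.endowment - (steps_elapsed + 1) - remaining)


def _node_ev(
    s: Cell,
    move: str,
    s_next: Cell,
    heading: str | None,
    steps_elapsed: int,
    depth: int,
    gr_before: bool,
    homing: bool,
    params: SurpriseParams,
    cfg: GoalConfiguration,
    component_mode: str,
    reward_on: bool,
) -> float:
    """Discounted per-node expected value ev(a|s) at tree depth ``depth``."""
    gr_after = gr_before or s_next == cfg.Gr
    r = (
        reward(s_next, steps_elapsed, cfg, params, gr_reached=gr_after)
        if reward_on
        else 1.0
    )
    disc = params.epsilon_discount ** (depth - 1)
    if homing or component_mode == "state_only":
        # goal-seeking value: landing-state probability x reward
        p = action_posterior(s, heading, params, cfg, "state_only")[move]
        return p * disc * r
    p = action_posterior(s, heading, params, cfg, component_mode)[move]
    return surprise(p) * disc * r


def expected_values(
    s: Cell,
    heading: str | None,
    steps_elapsed: int,
    phase: str,
    params: SurpriseParams,
    cfg: GoalConfiguration,
    component_mode: str = "full",
    reward_on: bool = True,
    aggregate: str = "bellman",
    gr_reached: bool = False,
    gr_exits: int = 0,
    switch_visits: int = 1,
    node_budget: int = 200_000,
) -> dict[str, float]:
    """Depth-H policy-tree value EV(a|s) for each immediately available move.

    Per-node values are surprise x discounted reward in the signal phase and
    state-prior probability x discounted reward in the homing phase. A branch
    switches to homing values once it has occupied the receiver's goal and
    then left it ``switch_visits`` times (the same criterion the executed
    trajectory uses): entering and exiting the goal are surprise-valued acts,
    only the continuation afterwards is plain goal seeking.
    ``aggregate="bellman"`` sums values along the best continuation of each
    immediate move (finite-horizon backup); ``"sum_all_paths"`` sums over the
    whole subtree instead.
    """
    if phase not in ("signal", "homing"):
        raise ValueError(f"unknown phase {phase!r}")
    if aggregate not in ("bellman", "sum_all_paths"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    count = [0]

    def rec(
        cur: Cell, hd: str | None, steps: int, depth: int, gr: bool, exits: int
    ) -> dict[str, float]:
        out: dict[str, float] = {}
        homing = phase == "homing" or exits >= switch_visits
        for move, nxt in _available_moves(cur, cfg):
            count[0] += 1
            if count[0] > node_budget:
                raise RuntimeError(
                    f"policy tree exceeded node budget {node_budget}"
                )
            ev = _node_ev(
                cur, move, nxt, hd, steps, depth, gr, homing,
                params, cfg, component_mode, reward_on,
            )
            gr2 = gr or nxt == cfg.Gr
            exits2 = exits + (1 if cur == cfg.Gr and nxt != cfg.Gr else 0)
            if depth < params.horizon:
                child = rec(nxt, move, steps + 1, depth + 1, gr2, exits2)
                cont = (
                    max(child.values())
                    if aggregate == "bellman"
                    else sum(child.values())
                )
                ev += cont
            out[move] = ev
        return out

    return rec(s, heading, steps_elapsed, 1, gr_reached, gr_exits)


def action_probabilities(EVs: dict[str, float], tau: float) -> dict[str, float]:
    """Softmax policy Pr(a|s) with inverse temperature tau (max-shifted)."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    names = list(EVs)
    if tau == 0.0:
        return {n: 1.0 / len(names) for n in names}
    shift = max(EVs.values())
    exps = {n: math.exp(tau * (EVs[n] - shift)) for n in names}
    total = sum(exps.values())
    return {n: e / total for n, e in exps.items()}


@dataclass(frozen=True)
class GeneratedMessage:
    """A constructed trajectory with its planning trace.

    ``truncated`` flags trajectories that hit the step budget before
    completing (they are excluded from scoring); ``step_surprise`` holds the
    full-posterior surprise of each executed step; ``switch_step`` is the
    1-based step index at which the homing phase began (None if never).
    """

    states: tuple[Cell, ...]
    truncated: bool
    step_surprise: tuple[float, ...]
    switch_step: int | None
    phases: tuple[str, ...] = field(default=())

    @property
    def message(self) -> Message:
        return Message(self.states)

    def __len__(self) -> int:
        return len(self.states)


def _homing_step(s: Cell, cfg: GoalConfiguration) -> tuple[str, Cell]:
    """Deterministic shortest-path step toward Gs, N<E<S<W tie-break."""
    best = None
    for name, nxt in _available_moves(s, cfg):
        d = manhattan(nxt, cfg.Gs)
        if best is None or d < best[2]:
            best = (name, nxt, d)
    return best[0], best[1]


def generate_message(
    cfg: GoalConfiguration,
    params: SurpriseParams | None = None,
    seed: int | np.random.Generator | None = None,
    policy_mode: str = "argmax",
    component_mode: str = "full",
    reward_mode: str = "on",
    switch_visits: int = 1,
    aggregate: str = "bellman",
) -> GeneratedMessage:
    """Construct a trajectory by two-phase surprise planning.

    Phase 1 (signal) picks moves by policy-tree expected value until the
    token has occupied the receiver's goal and then exited it
    ``switch_visits`` times; phase 2 (homing) follows the state prior — a
    shortest path — to the sender's goal. The state-prior-only ablation has
    nothing to signal with and homes from the start. Generation stops after
    ``endowment`` steps regardless; an incomplete trajectory is returned
    with ``truncated=True``.
    """
    params = params or SurpriseParams()
    if policy_mode not in ("argmax", "sample"):
        raise ValueError(f"unknown policy_mode {policy_mode!r}")
    if reward_mode not in ("on", "off"):
        raise ValueError(f"unknown reward_mode {reward_mode!r}")
    reward_on = reward_mode == "on"
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    phase = "homing" if component_mode == "state_only" else "signal"
    state = cfg.A
    heading: str | None = None
    gr_reached = state == cfg.Gr
    gr_exits = 0
    states = [state]
    surprises: list[float] = []
    phases: list[str] = []
    switch_step: int | None = 0 if phase == "homing" else None
    budget = params.endowment

    for step in range(1, budget + 1):
        if phase == "homing" and state == cfg.Gs:
            break
        if phase == "homing":
            move, nxt = _homing_step(state, cfg)
        else:
            EVs = expected_values(
                state, heading, step - 1, phase, params, cfg,
                component_mode=component_mode, reward_on=reward_on,
                aggregate=aggregate, gr_reached=gr_reached,
                gr_exits=gr_exits, switch_visits=switch_visits,
            )
            if policy_mode == "argmax":
                # deterministic tie-break: first max in N<E<S<W order
                move = max(EVs, key=lambda k: (EVs[k], -"NESW".index(k)))
            else:
                probs = action_probabilities(EVs, params.tau_softmax)
                names = list(probs)
                move = names[int(rng.choice(len(names), p=[probs[n] for n in names]))]
            dr, dc = _DELTA[move]
            nxt = Cell(state.row + dr, state.col + dc)
        # trace surprise under the active posterior (uniform-movement start)
        post = action_posterior(state, heading, params, cfg, component_mode)
        surprises.append(surprise(post[move]))
        phases.append(phase)
        prev = state
        state, heading = nxt, move
        states.append(state)
        if state == cfg.Gr:
            gr_reached = True
        if prev == cfg.Gr and state != cfg.Gr:
            gr_exits += 1
            if phase == "signal" and gr_exits >= switch_visits:
                phase = "homing"
                switch_step = step
        if phase == "homing" and state == cfg.Gs:
            break

    complete = state == cfg.Gs and phase == "homing"
    return GeneratedMessage(
        states=tuple(states),
        truncated=not complete,
        step_surprise=tuple(surprises),
        switch_step=switch_step,
        phases=tuple(phases),
    )
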