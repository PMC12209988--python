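import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tcgsim.gridworld import Cell, GoalConfiguration, manhattan
from tcgsim.messages import Message, classify, validate_message
from tcgsim.surprise import (
    SurpriseParams,
    action_posterior,
    action_probabilities,
    expected_values,
    generate_message,
    movement_prior,
    reward,
    state_prior,
    surprise,
)


@pytest.fixture
def cfg(board):
    return GoalConfiguration(A=Cell(0, 0), Gr=Cell(1, 1), Gs=Cell(2, 0), board=board)


@pytest.fixture
def params():
    return SurpriseParams(
        gamma_ratio=3, lambda_back=0.05, alpha_decay=2, horizon=2, epsilon_discount=0.9
    )


# -- priors ----------------------------------------------------------------


@pytest.mark.parametrize(
    "gam,lam,expect",
    [
        (2.0, 0.0, (2 / 3, 1 / 6, 1 / 6, 0.0)),
        (1.0, 0.0, (0.5, 0.25, 0.25, 0.0)),
        (2.0, 0.1, (0.6, 0.15, 0.15, 0.1)),
    ],
)
def test_movement_prior_values(gam, lam, expect):
    with pytest.warns(UserWarning) if gam < 2 else _nullcontext():
        p = movement_prior(SurpriseParams(gamma_ratio=gam, lambda_back=lam))
    f, l, r, b = expect
    assert p["forward"] == pytest.approx(f, abs=1e-12)
    assert p["left"] == pytest.approx(l, abs=1e-12)
    assert p["right"] == pytest.approx(r, abs=1e-12)
    assert p["back"] == pytest.approx(b, abs=1e-12)


class _nullcontext:
    def __enter__(self):
        return None

    def __exit__(self, *a):
        return False


@given(
    lam=st.floats(0.001, 0.3),
    gam=st.floats(2.0, 10.0),
)
def test_movement_prior_sums_and_ordering(lam, gam):
    p = movement_prior(SurpriseParams(lambda_back=lam, gamma_ratio=gam))
    assert sum(p.values()) == pytest.approx(1.0, abs=1e-12)
    if lam < p["left"]:
        assert p["forward"] > p["left"] == p["right"] > p["back"]


@pytest.mark.parametrize("alpha,d,expect", [(2.0, 0, 1.0), (2.0, 2, 0.25), (1.0, 3, 1.0)])
def test_state_prior(alpha, d, expect):
    gs = Cell(0, 0)
    s = Cell(0, d)
    assert state_prior(s, gs, alpha) == pytest.approx(expect)


def test_state_prior_rejects_nonpositive_alpha():
    with pytest.raises(ValueError):
        state_prior(Cell(0, 0), Cell(0, 1), 0.0)


# -- posterior and surprise ------------------------------------------------


@pytest.mark.parametrize("mode", ["full", "movement_only", "state_only"])
def test_action_posterior_normalizes(cfg, params, mode):
    for s in cfg.board.cells():
        for heading in (None, "N", "E", "S", "W"):
            post = action_posterior(s, heading, params, cfg, mode)
            assert sum(post.values()) == pytest.approx(1.0, abs=1e-12)
            assert all(p > 0 for p in post.values())


def test_flat_state_prior_reduces_full_to_movement_only(cfg):
    p = SurpriseParams(alpha_decay=1.0)
    for heading in ("N", "E", "S", "W"):
        full = action_posterior(Cell(1, 1), heading, p, cfg, "full")
        mov = action_posterior(Cell(1, 1), heading, p, cfg, "movement_only")
        for k in full:
            assert full[k] == pytest.approx(mov[k], abs=1e-12)


def test_no_heading_movement_only_is_uniform(cfg, params):
    post = action_posterior(Cell(1, 1), None, params, cfg, "movement_only")
    assert all(v == pytest.approx(0.25) for v in post.values())


@pytest.mark.parametrize("p,bits", [(1.0, 0.0), (0.5, 1.0), (0.25, 2.0)])
def test_surprise_values(p, bits):
    assert surprise(p) == pytest.approx(bits)


def test_surprise_rejects_zero():
    with pytest.raises(ValueError):
        surprise(0.0)


# -- reward ----------------------------------------------------------------


def test_reward_examples(cfg, params):
    # at the sender goal after 9 steps: everything spent
    assert reward(cfg.Gs, 9, cfg, params) == 0.0
    # generic remaining-points case: 10 - 4 - 2
    s = Cell(0, 1)  # manhattan to Gs=(2,0) is 3... pick (2,2): d=2
    assert reward(Cell(2, 2), 3, cfg, params) == 4.0
    # monotone in elapsed steps
    vals = [reward(Cell(2, 2), t, cfg, params) for t in range(10)]
    assert all(a >= b for a, b in zip(vals, vals[1:]))


def test_reward_routes_through_gr_before_it_is_reached(cfg, params):
    # before Gr: completion must still detour through it
    r_pre = reward(Cell(2, 0), 1, cfg, params, gr_reached=False)
    r_post = reward(Cell(2, 0), 1, cfg, params, gr_reached=True)
    assert r_post - r_pre == manhattan(Cell(2, 0), cfg.Gr) + manhattan(cfg.Gr, cfg.Gs)


# -- expected values -------------------------------------------------------


def oracle_tree_ev(s, heading, steps, phase, params, cfg, gr, exits, depth):
    """Independent brute-force recursion over the policy tree."""
    out = {}
    homing = phase == "homing" or exits >= 1
    for name, dr, dc in (("N", -1, 0), ("E", 0, 1), ("S", 1, 0), ("W", 0, -1)):
        nxt = Cell(s.row + dr, s.col + dc)
        if not cfg.board.contains(nxt):
            continue
        gr2 = gr or nxt == cfg.Gr
        rem = (
            manhattan(nxt, cfg.Gs)
            if gr2
            else manhattan(nxt, cfg.Gr) + manhattan(cfg.Gr, cfg.Gs)
        )
        r = max(0.0, params.endowment - (steps + 1) - rem)
        if homing:
            p = action_posterior(s, heading, params, cfg, "state_only")[name]
            ev = p * params.epsilon_discount ** (depth - 1) * r
        else:
            p = action_posterior(s, heading, params, cfg, "full")[name]
            ev = -math.log2(p) * params.epsilon_discount ** (depth - 1) * r
        if depth < params.horizon:
            child = oracle_tree_ev(
                nxt, name, steps + 1, phase, params, cfg, gr2,
                exits + (1 if s == cfg.Gr and nxt != cfg.Gr else 0), depth + 1,
            )
            ev += max(child.values())
        out[name] = ev
    return out


def test_tree_matches_bruteforce_oracle(cfg, params):
    for H in (1, 2, 3):
        p = SurpriseParams(
            gamma_ratio=3, lambda_back=0.05, alpha_decay=2, horizon=H,
            epsilon_discount=0.9,
        )
        for s in cfg.board.cells():
            for heading in (None, "S", "E"):
                got = expected_values(s, heading, 1, "signal", p, cfg)
                want = oracle_tree_ev(s, heading, 1, "signal", p, cfg, False, 0, 1)
                assert set(got) == set(want)
                for k in got:
                    assert got[k] == pytest.approx(want[k], rel=1e-12)


def test_h1_reduces_to_single_step_ev(cfg):
    p = SurpriseParams(horizon=1)
    got = expected_values(Cell(1, 0), "S", 1, "signal", p, cfg)
    for name, nxt in (("N", Cell(0, 0)), ("E", Cell(1, 1)), ("S", Cell(2, 0))):
        post = action_posterior(Cell(1, 0), "S", p, cfg, "full")[name]
        gr2 = nxt == cfg.Gr
        rem = (
            manhattan(nxt, cfg.Gs)
            if gr2
            else manhattan(nxt, cfg.Gr) + manhattan(cfg.Gr, cfg.Gs)
        )
        r = max(0.0, 10 - 2 - rem)
        assert got[name] == pytest.approx(surprise(post) * r)


def test_discount_one_makes_depth_weightless(cfg):
    # with eps=1 every per-node weight is undiscounted
    p1 = SurpriseParams(epsilon_discount=1.0, horizon=2)
    got = expected_values(Cell(0, 0), None, 0, "signal", p1, cfg)
    want = oracle_tree_ev(Cell(0, 0), None, 0, "signal", p1, cfg, False, 0, 1)
    for k in got:
        assert got[k] == pytest.approx(want[k])


def test_argmax_turns_into_goal_at_its_neighbor(cfg, params):
    """Next to the receiver's goal, the surprising turn into it outvalues
    the prior-favored straight move."""
    evs = expected_values(Cell(1, 0), "S", 1, "signal", params, cfg)
    assert max(evs, key=evs.get) == "E"  # E leads from (1,0) into Gr=(1,1)


# -- softmax ---------------------------------------------------------------


def test_softmax_properties():
    assert action_probabilities({"a": 3.0, "b": -1.0}, 0.0) == {"a": 0.5, "b": 0.5}
    p = action_probabilities({"a": 1.0, "b": 1.0}, 5.0)
    assert p["a"] == pytest.approx(0.5)
    p = action_probabilities({"a": 1.0, "b": 0.0}, 1.0)
    e = math.e
    assert p["a"] == pytest.approx(e / (1 + e), abs=1e-12)
    assert p["b"] == pytest.approx(1 / (1 + e), abs=1e-12)
    # numerically stable under large values
    p = action_probabilities({"a": 1e6, "b": 1e6 - 1}, 10.0)
    assert sum(p.values()) == pytest.approx(1.0)


@given(
    evs=st.lists(st.floats(-50, 50), min_size=2, max_size=4),
    tau=st.floats(0, 20),
)
def test_softmax_sums_to_one(evs, tau):
    p = action_probabilities({str(i): v for i, v in enumerate(evs)}, tau)
    assert sum(p.values()) == pytest.approx(1.0, abs=1e-9)


# -- generation ------------------------------------------------------------


def test_full_generation_is_valid_and_signals(cfg, params):
    gen = generate_message(cfg, params)
    assert not gen.truncated
    m = Message(gen.states)
    assert validate_message(m, cfg)
    assert classify(m, cfg) in ("enter_exit", "wiggly")


def test_homing_suffix_is_shortest_path(cfg, params):
    gen = generate_message(cfg, params)
    assert gen.switch_step is not None
    switch_state = gen.states[gen.switch_step]
    suffix_steps = len(gen.states) - 1 - gen.switch_step
    assert suffix_steps == manhattan(switch_state, cfg.Gs)


def test_state_only_walks_minimal_direct_path(cfg, params):
    gen = generate_message(cfg, params, component_mode="state_only")
    assert not gen.truncated
    assert len(gen.states) == manhattan(cfg.A, cfg.Gs) + 1
    assert len(set(gen.states)) == len(gen.states)


def test_movement_only_without_reward_zigzags(board, params):
    # goal off the oscillation locus: the walk reverses forever and times out
    cfg = GoalConfiguration(A=Cell(0, 0), Gr=Cell(2, 2), Gs=Cell(2, 0), board=board)
    gen = generate_message(
        cfg, params, component_mode="movement_only", reward_mode="off"
    )
    assert gen.truncated  # never terminates efficiently
    reversals = sum(
        1
        for i in range(2, len(gen.states))
        if gen.states[i] == gen.states[i - 2]
    )
    assert reversals >= 3


def test_generation_determinism(cfg, params):
    g1 = generate_message(cfg, params, seed=4, policy_mode="sample")
    g2 = generate_message(cfg, params, seed=4, policy_mode="sample")
    assert g1.states == g2.states
    assert generate_message(cfg, params).states == generate_message(cfg, params).states


def test_step_budget_is_endowment(cfg):
    p = SurpriseParams(endowment=4)  # too few points to signal and return
    gen = generate_message(cfg, p, component_mode="movement_only", reward_mode="off")
    assert len(gen.states) <= p.endowment + 1


def test_param_validation():
    with pytest.raises(ValueError):
        SurpriseParams(lambda_back=1.5)
    with pytest.raises(ValueError):
        SurpriseParams(epsilon_discount=0.0)
    with pytest.raises(ValueError):
        SurpriseParams(horizon=0)
    with pytest.warns(UserWarning):
        SurpriseParams(gamma_ratio=20.0)
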