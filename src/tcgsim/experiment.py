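"""Session harness: run sender models over configuration sets and summarize.

A session mirrors the simulation-study design: one sender model is run over a
set of goal configurations (canonically 20 direct + 10 indirect trials), each
generated message is classified by shape, decoded by a model receiver of a
chosen ToM level, and the per-trial records are aggregated into message-class
frequencies and decoding accuracies. Model receivers stand in for the human
receivers of the original study and are labeled as such in the outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .gridworld import Cell, GoalConfiguration, score
from .messages import Message, classify, validate_message
from .surprise import SurpriseParams, generate_message
from .tom_receivers import candidates_for_level, p_correct, select_goal
from .tom_senders import UnsupportedConfigurationError, build_for_level, select_message

__all__ = ["TrialRecord", "SessionSummary", "run_session", "summarize", "records_to_frame"]

SENDER_MODELS = ("tom0", "tom1", "tom2", "surprise")


@dataclass(frozen=True)
class TrialRecord:
    trial_id: int
    model: str
    A: Cell
    Gs: Cell
    Gr: Cell
    trial_type: str
    message: tuple[Cell, ...] | None
    message_class: str | None
    L: int | None
    n_unique: int | None
    score: int | None
    receiver_level: int | None
    decoded_goal: Cell | None
    correct: bool | None
    p_correct_analytic: float | None
    receiver_fallback: int | None
    sender_ok: bool
    seed: int


def _send(model: str, cfg: GoalConfiguration, rng: np.random.Generator,
          cap: int | None, params: SurpriseParams | None, policy_mode: str):
    """Produce (states, ok) for one trial; failures are reported, not raised."""
    if model == "surprise":
        gen = generate_message(
            cfg, params=params, seed=rng, policy_mode=policy_mode
        )
        ok = not gen.truncated and validate_message(Message(gen.states), cfg)
        return gen.states, ok
    level = int(model[-1])
    try:
        ms = build_for_level(cfg, level, cap)
    except UnsupportedConfigurationError:
        return None, False
    return select_message(ms, rng).states, True


def run_session(
    model: str,
    configs: list[GoalConfiguration],
    receiver_level: int = 0,
    n_reps: int = 1,
    seed: int = 0,
    cap: int | None = None,
    params: SurpriseParams | None = None,
    policy_mode: str = "argmax",
    receiver_mode: str = "closed_form",
) -> list[TrialRecord]:
    """Run ``n_reps`` replications of a session for one sender model.

    Trial order is shuffled per replication; every trial draws from its own
    RNG substream spawned from the master seed, so sessions replay exactly
    and single trials can be reproduced in isolation.
    """
    if model not in SENDER_MODELS:
        raise ValueError(f"unknown sender model {model!r}; choose from {SENDER_MODELS}")
    if not configs:
        raise ValueError("configuration list is empty")
    records: list[TrialRecord] = []
    trial_id = 0
    for rep in range(n_reps):
        # deterministic substreams: one child per replication slot, then per trial
        rep_children = np.random.SeedSequence([seed, rep]).spawn(len(configs) + 1)
        order_rng = np.random.default_rng(rep_children[0])
        order = order_rng.permutation(len(configs))
        for slot, idx in enumerate(order):
            cfg = configs[int(idx)]
            child = rep_children[slot + 1]
            trial_seed = int(child.generate_state(1)[0] % (2**31))
            rng = np.random.default_rng(child)
            states, ok = _send(model, cfg, rng, cap, params, policy_mode)
            if states is None or not ok:
                records.append(
                    TrialRecord(
                        trial_id, model, cfg.A, cfg.Gs, cfg.Gr, cfg.trial_type,
                        states, None, None if states is None else len(states),
                        None, None, receiver_level, None, None, None, None,
                        sender_ok=False, seed=trial_seed,
                    )
                )
                trial_id += 1
                continue
            msg = Message(states)
            cs = candidates_for_level(msg, cfg, receiver_level, receiver_mode)
            decoded = select_goal(cs, rng)
            records.append(
                TrialRecord(
                    trial_id, model, cfg.A, cfg.Gs, cfg.Gr, cfg.trial_type,
                    msg.states, classify(msg, cfg), msg.L, msg.n_unique,
                    score(msg), receiver_level, decoded,
                    decoded == cfg.Gr, p_correct(cs, cfg), cs.fallback_from,
                    sender_ok=True, seed=trial_seed,
                )
            )
            trial_id += 1
    return records


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Flatten records to a DataFrame; the message is a JSON string column."""
    rows = []
    for r in records:
        d = asdict(r)
        d["message"] = (
            json.dumps([list(s) for s in r.message]) if r.message else None
        )
        for k in ("A", "Gs", "Gr", "decoded_goal"):
            d[k] = json.dumps(list(d[k])) if d[k] is not None else None
        rows.append(d)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SessionSummary:
    """Per-model class frequencies and receiver accuracies."""

    frequencies: pd.DataFrame  # index model, columns message classes, fractions
    class_accuracy: pd.DataFrame  # mean correct per model x class
    overall_accuracy: pd.Series  # mean correct per model
    analytic_accuracy: pd.Series  # mean analytic p_correct per model
    n_trials: pd.Series
    n_failed: pd.Series


def summarize(records: list[TrialRecord] | pd.DataFrame) -> SessionSummary:
    """Aggregate trial records; deterministic given the records."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise ValueError("no records to summarize")
    ok = df[df["sender_ok"]]
    freq = (
        ok.groupby("model")["message_class"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    class_acc = (
        ok.groupby(["model", "message_class"])["correct"].mean().unstack()
    )
    return SessionSummary(
        frequencies=freq,
        class_accuracy=class_acc,
        overall_accuracy=ok.groupby("model")["correct"].mean(),
        analytic_accuracy=ok.groupby("model")["p_correct_analytic"].mean(),
        n_trials=df.groupby("model").size(),
        n_failed=df.groupby("model")["sender_ok"].apply(lambda s: int((~s).sum())),
    )
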