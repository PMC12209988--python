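# tcgsim

Agents for the **Tacit Communication Game** (TCG): a two-player cooperative
grid game in which a *Sender* must convey a hidden goal location to a
*Receiver* using nothing but her movement trajectory. The package is for
computational cognitive scientists who want to simulate, compare and extend
generative models of nonverbal signaling — recursive Theory-of-Mind (ToM)
reasoning versus information-theoretic expectancy violation — without human
subjects in the loop.

## The game

A trial is a goal configuration `(A, Gs, Gr)` on a small grid (default 3×3):
the Sender starts at `A`, must end at her own goal `Gs`, and must pass
through the Receiver's hidden goal `Gr` in a way the Receiver can decode.
Each movement step costs one point out of an endowment of 10, so a message
`m = [s1, …, sn]` (a 4-connected walk with `s1 = A`, `sn = Gs`, `Gr ∈ m`)
scores `10 − (L(m) − 1)`, where `L(m)` is the number of states and
`U(m) = {si}` the set of *unique* states. Trials are *direct* when `Gr` lies
on a shortest `A → Gs` path and *indirect* otherwise. Messages are classed
by shape: **pass-by** (simple path), **enter-exit** (a revisit somewhere off
the goal), **wiggly** (`Gr` itself revisited).

## The models

**ToM senders** select uniformly from level-specific message sets:

- ToM-0: `M0 = {m ∈ M : L(m) = min L}` — cheapest messages, no partner model;
- ToM-1: `M1 = {m ∈ M : |U(m)| = min |U|}` — fewest unique states, because a
  ToM-0 receiver guesses uniformly among visited cells;
- ToM-2: one unique state *more* than the cheapest `Gr`-avoiding route
  (`M2,direct`), so that a ToM-1 receiver's elimination isolates the goal.

**ToM receivers** invert these strategies. Level 0 keeps every visited cell
except `A` and `Gs`; level 1 eliminates any cell lying on a strictly shorter
`A → Gs` walk than the observed one; level 2 eliminates any cell reachable
with a smaller unique-state footprint. Both eliminations admit a closed form
via the minimal via-length `d(A,s) + d(s,Gs) + 1`, provably identical to
explicit walk simulation (tested exhaustively).

**The Surprise sender** constructs its trajectory step by step instead of
selecting one. A movement prior `p(f) > p(l) = p(r) > p(b)` (parameters
`λ = p(b)`, `γ = p(f)/(p(l)+p(r))`) and a state prior `p(s) ∝ α^(−d(s,Gs))`
multiply into an action posterior `p(a|s)`; the Shannon surprise
`h(a|s) = −log2 p(a|s)` of each candidate move, weighted by the discounted
points still attainable, is summed over a depth-`H` policy tree and passed
through a softmax `Pr(a|s) ∝ exp(τ·EV(a|s))`. The planner seeks *surprising*
moves to mark the goal, then homes to `Gs` along the state prior once the
goal has been entered and exited.

## Worked example

```python
from tcgsim import (GoalConfiguration, Cell, SurpriseParams, score, classify,
                    build_M0, build_M2, select_message, generate_message,
                    tom2_candidates, p_correct)
from tcgsim.messages import Message

cfg = GoalConfiguration(A=Cell(0, 0), Gr=Cell(1, 1), Gs=Cell(2, 0))
print(cfg.trial_type)                      # indirect

m0 = select_message(build_M0(cfg), seed=0)
print(m0.states, classify(m0, cfg), score(m0))
# ((0,0),(1,0),(1,1),(1,0),(2,0)) enter_exit 6

gen = generate_message(cfg, SurpriseParams())
print(gen.states, [round(h, 2) for h in gen.step_surprise])
# ((0,0),(1,0),(1,1),(1,0),(2,0)) [0.32, 4.67, 2.91, 0.44]

m2 = select_message(build_M2(cfg)[1], seed=0)
cs = tom2_candidates(m2, cfg)
print(sorted(cs.candidates), p_correct(cs, cfg))
# [Cell(row=1, col=1)] 1.0
```

The ToM-0 draw happens to be one of the four minimal 5-state messages (score
6 = 10 − 4 steps). The Surprise planner builds the same shape from first
principles: its per-step surprise trace spikes at 4.67 bits on the turn
*into* the goal cell and 2.91 bits on the backtrack out — those two
unexpected moves are the signal. The ToM-2 receiver, eliminating every cell
communicable with a smaller footprint, is left with exactly the true goal
(`p_correct = 1.0`).

Sessions mirror the original 30-trial design (20 direct + 10 indirect):

```bash
tcgsim gen-configs --n-direct 20 --n-indirect 10 --seed 0 --out configs.json
tcgsim session --models tom0,tom1,tom2,surprise --configs configs.json \
       --receiver-level 0 --seed 0 --out-prefix session
```

which writes per-model trial CSVs plus frequency and accuracy tables.

## Layout

- `tcgsim.gridworld` — board, configurations, trial typing, scoring;
- `tcgsim.messages` — message representation, capped enumeration, classifier;
- `tcgsim.tom_senders` / `tcgsim.tom_receivers` — the recursive ToM levels;
- `tcgsim.surprise` — priors, surprise, policy-tree planner, ablations;
- `tcgsim.experiment` — session harness and summaries;
- `tcgsim.cli` — `tcgsim` command-line entry point.

See `docs/methods.md` for model details, parameter guidance and known
limitations.
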