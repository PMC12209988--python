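# Methods

This note records how the models are defined, which choices were genuinely
open, and what the simulations do and do not establish.

## Game conventions

Boards are rectangular grids, coordinates 0-based `(row, col)`, movement
4-connected with no wraparound. A message is the full state sequence
`m = [s1, …, sn]`; `L(m)` counts **states** while the score counts **steps**
(`score = endowment − (L − 1)`, endowment 10 by default). Both quantities
are exposed to avoid off-by-one drift. Trials are typed by the Manhattan
triangle equality: *direct* iff `d(A,Gr) + d(Gr,Gs) = d(A,Gs)` — "passes
by" is read as "on some shortest path", not merely adjacent.

The message space `M` is infinite (walks may revisit cells), so all
enumeration is capped at a maximum sequence length. The default cap is the
minimal valid length plus 4 extra states, enough to contain every shape the
agents use on small boards while keeping the search finite. Enumeration
order is deterministic (lexicographic on move sequences, N<E<S<W), so
uniform draws are reproducible under a seed. The depth-first enumeration
prunes branches that cannot reach the remaining targets within the state
budget; this is exact, not heuristic.

### Message classes

The classifier operationalizes the three shapes by revisit structure,
checked in order: **wiggly** if `Gr` occurs at least twice in the sequence;
otherwise **enter-exit** if any state is revisited; otherwise **pass-by**
(the path is simple). This precedence is one defensible reading of the
pictorial definitions; it is centralized in `classify` so variants can be
swapped in for sensitivity analysis.

## ToM message sets

`m′` in each set definition is read as "a minimizer of the stated quantity
within the stated set" — the only reading under which the definitions are
well-formed — and is computed as an explicit minimum over the capped
enumeration.

- **M0**: all valid messages of minimal `L`. Note that M0 is *not* always a
  set of simple paths: on "overshoot" layouts (the shortest `A→Gr` and
  `Gr→Gs` legs share a cell, e.g. `A=(0,0)`, `Gr=(1,1)`, `Gs=(2,0)` sharing
  `(1,0)`), minimal messages revisit that cell and classify as enter-exit.
  This is why a zero-order sender emits mostly — but not only — pass-by
  messages on mixed trial sweeps.
- **M1**: all valid messages (within the cap) achieving minimal `|U|`. No
  secondary length minimization is applied: equal-footprint messages of
  different lengths (pass-by, enter-exit and wiggly shapes alike) are all
  retained, which is what produces this level's mixed output distribution.
  The cap shapes that distribution and is surfaced as a parameter.
- **M2**: `M2,direct` holds the shortest `Gr`-avoiding `A→Gs` walks
  (simple paths, so `|U| = L`); the sender draws from `M2,pass`, the valid
  messages with unique count `min|U|(M2,direct) + 1`. When `Gr` lies far
  off a short route (e.g. `A` adjacent to `Gs`), one extra unique state
  cannot reach it and no such message exists; the target then rises to the
  minimal unique count any valid message achieves, collapsing the level
  onto the ToM-1 choice. On exactly those layouts the cheapest goal-visiting
  message is already the maximally informative one, so the collapse is the
  model's own logic, not a fallback hack.

## ToM receivers

Candidate sets always exclude `A` and `Gs` as *cells* (all occurrences);
sequence positions are ill-defined once a walk revisits them.

The level-1 rule eliminates any observed cell that lies on some `A→Gs` walk
with fewer than `L(m*)` states; the level-2 rule, fewer than `|U(m*)|`
states. Both have a closed form through the minimal via-length
`v(s) = d(A,s) + d(s,Gs) + 1`:

> a cell `s` lies on some `A→Gs` walk of fewer than `k` states **iff**
> `v(s) < k`.

Forward direction: concatenating shortest legs through `s` realizes `v(s)`,
and two-step back-and-forth padding reaches any longer length of the same
parity — and every `A→Gs` walk length shares that parity on a bipartite
grid. Converse: any walk through `s` needs at least `d(A,s) + d(s,Gs)`
steps. For the level-2 rule the simulated walks are those with at most
`|U(m*)| − 1` *states*: each such walk automatically has a smaller unique
footprint, and any cell on a low-footprint-but-long walk (length
`≥ |U(m*)|`) is not eliminated. (Without the length restriction the
unique-count criterion would eliminate strictly more — e.g. a cell of
via-length 5 sits on an enter-exit walk with only 4 unique states — and
the closed form would no longer agree; the restricted reading keeps the
elimination principled and testable.) The explicit-simulation ("union") and
closed-form modes are verified identical over every valid message of at
most 7 states on every 3×3 configuration.

Elimination can empty the candidate set — notably the level-2 rule applied
to messages in *direct* trials, where `Gr` itself lies on a shortest path
and hence on low-footprint walks. An empty set degrades to the next lower
rule (level 2 → level 1 → level 0) with a `fallback_from` flag on the
result, keeping such trials auditable. This is why matched second-order
chains decode indirect trials almost perfectly but lose accuracy on direct
ones; the session harness reports both.

## The Surprise planner

Movement prior (relative to the current heading):
`p(b) = λ`, `p(f) = (γ/(γ+1))(1−λ)`, `p(l) = p(r) = ½(1 − γ/(γ+1))(1−λ)`,
with `γ = p(f)/(p(l)+p(r))` — the ratio reading is fixed by the worked
example `γ=2 → p(f)=2/3`. Guidance bands: `λ ∈ [0.001, 0.3]`,
`γ ∈ [2, 10]` (values outside warn but are allowed; `λ=0` is admitted for
analytic examples). Before the first move there is no heading and the
movement component is uniform — only the state prior differentiates; an
alternative initial heading is a deliberate non-feature, since "forward" is
undefined before movement. Off-board moves get zero weight and are dropped
from the normalization: the board has walls, and the surprise of an
impossible action is undefined.

State prior: `α^(−d(s,Gs))`, `α > 0`; `α = 1` flattens it, making the full
posterior reduce exactly to the movement-only ablation.

Reward: the points still attainable after the move, assuming optimal
completion of the *task* — before the goal has been visited the remaining
route must still pass through it (`d(s′,Gr) + d(Gr,Gs)`), afterwards it
runs straight home (`d(s′,Gs)`); floored at 0. The via-goal term is what
draws the planner toward `Gr` at all; with a plain distance-to-`Gs` reward
the signal phase has no attractor and the model degenerates to wandering.

Planning: a depth-`H` policy tree. Per-node value is
`h(a|s) · ε^(i−1) · r` in the signal phase and `p_state(a|s) · ε^(i−1) · r`
in the homing phase, with `ε^(i−1)` the per-depth discount (the immediate
step undiscounted — conventional, as no form is prescribed). A branch
switches to homing values once it has occupied the goal and then exited it
(`switch_visits` times, default 1) — the same criterion the executed
trajectory uses. Switching on *reaching* the goal instead would devalue the
exit move's surprise and collapse the output to plain pass-bys. Default
aggregation is a finite-horizon backup (per-node value plus the best
continuation); a literal sum over all subtree paths is available as
`aggregate="sum_all_paths"`. Action choice is argmax with a deterministic
N<E<S<W tie-break (the default for reproducibility) or softmax sampling
with inverse temperature `τ` (`τ = 0` gives a uniform policy; the softmax
is max-shifted for numerical stability).

Generation runs phase 1 (signal) until the switch fires, then phase 2
(homing) follows the state prior — a shortest path — to `Gs`. The
state-prior-only ablation has nothing to signal with and homes from the
start, reproducing the minimal-direct-path regime; the movement-only
ablation without reward reverses direction indefinitely and hits the step
budget. The hard budget is `endowment` steps; an incomplete trajectory is
returned with `truncated=True` and excluded from scoring.

Defaults `γ=3, λ=0.05, α=2, τ=5, ε=0.9, H=2` are package defaults chosen
inside the guidance bands; they are not fitted values, and message-type
frequencies are sensitive to them (see Limitations).

## Session harness

A session runs one sender model over a configuration set (canonically 20
direct + 10 indirect trials sampled without replacement from the board's
distinct triples), classifies each message, decodes it with a model
receiver of a chosen level, and aggregates class frequencies, empirical
accuracy and the analytic accuracy `1/|candidates|` (0 if the goal was
eliminated). Trial order is shuffled per replication and every trial draws
from its own RNG substream spawned from the master seed, so the entire
artifact set is byte-identical across runs. Sender failures (truncation,
unreachable set) are recorded per trial, never fatal. Model receivers stand
in for the human receivers of the original experimental design and are
labeled as such; human accuracy and reaction-time panels are out of scope.

## Problem sizes

The exhaustive verifications sweep all 504 distinct-triple configurations
of the 3×3 board: elimination-mode equivalence over every valid message of
at most 7 states (≈14k messages), and message-set minima against
independent search oracles at the default caps. Normalization identities
are checked over 10⁴ random parameter draws plus a symbolic proof of the
movement-prior identity. These sizes keep the full suite under a minute
apart from the sweeps, which take a few seconds each.

## What the synthetic conditions do and do not show

The configuration generator reproduces the *design* of the original
sessions (board-scale trials, 20/10 direct/indirect split, seeded
sampling), not the original stimulus set, which is unpublished. Message
frequencies depend on that set and on fitted parameters, so published
percentages are treated as qualitative anchors only (e.g. second-order
senders concentrate on enter-exit; zero-order senders are mostly pass-by).
Decoding accuracies here come from *model* receivers, not humans; they
bound and order the strategies but do not estimate human performance.

## Known limitations

- The surprise spike of a full-model trajectory does not reliably land on
  the goal entry/exit step: across the parameter guidance bands, 35–65% of
  indirect 3×3 trials place their maximum per-step surprise there, the
  remainder on reversal moves made while the budget is slack (reversals
  are the most improbable — hence most surprising — acts wherever they
  occur). The corresponding check reports per-trial violations rather than
  hiding them.
- ToM levels above 2, noisy/probabilistic ToM variants, parameter fitting
  to behavioral trajectories, diagonal or weighted movement, obstacles,
  and a surprise-based receiver are out of scope.
- Enumeration caps make `M1`/`M2,pass` distributions cap-dependent; the
  session logs record the set sizes so cap sensitivity is visible.
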