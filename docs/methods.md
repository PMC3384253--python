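# Methods

This note documents the model implemented by `eventsearn`, the numerical and
design choices that were genuinely open, what the synthetic data does and
does not emulate, and the problem sizes used by the shipped tests.

## Task and decomposition

A sentence with pre-annotated protein mentions is predicted through an
ordered sequence of multiclass actions.  Trigger recognition runs left to
right over candidate tokens (coarse PoS prefixes N/V/J), a 10-way decision
per token (nine event types plus `No_trigger`).  Theme assignment works off
an agenda: initially every predicted trigger crossed with every protein;
whenever a trigger receives its first Theme, pairs between every
Regulation-class trigger and that trigger as argument are appended, which is
what makes nested events reachable.  Pairs are processed in order of
increasing shortest-dependency-path length (ties by agenda insertion order,
so protein-argument pairs precede event-argument pairs), and pairs that
would close a directed cycle over the union of Theme and Cause edges are
filtered out.  Cause assignment repeats the scheme for Regulation triggers
holding at least one Theme, with proteins and all Themed triggers as
candidate arguments.  Event construction is rule-based and deterministic;
the only learned-data component is a dictionary of lemmas that carry a dual
Simple+Regulation annotation (e.g. "overexpression"), built from training
data as the majority Regulation type per lemma, ties broken
lexicographically.

Trigger spans are reduced to their syntactic heads on load: the head of a
multi-token span is the token whose dependency head lies outside the span,
the rightmost such token if several, falling back to the rightmost token.
Evaluation consequently matches triggers by head token (approximate trigger
matching); an event is correct only if its type, trigger head, full Theme
set (recursively for event arguments) and Cause all agree.

## Dependency paths

Shortest paths are computed over the undirected view of the collapsed
dependency graph, each step tagged `up` or `down`.  Among equal-length paths
the lexicographically smallest label-direction string wins; this tie-break
is part of the feature contract (path features must be reproducible across
runs and machines), which is why the Dijkstra is implemented directly
rather than through a graph library that does not expose the tie-break.
Disconnected pairs stay on the agenda (ordered last) and fall back to the
textual-string feature: the concatenated lemmas strictly between trigger and
argument head, collapsing to a length bucket beyond 10 tokens to bound
feature-space growth.

## Learning

The base learner is a K-class linear classifier with one sparse weight
vector per label, trained with cost-sensitive passive-aggressive updates
(PA-II, prediction-based).  For an example x with cost vector c, if the
predicted label ŷ has positive cost the update corrects toward the cheapest
label y = argmin c (ties to the lowest index) with margin √c(ŷ) and learning
rate τ = ℓ/(‖x‖² + 1/(2C)); the aggressiveness C damps updates on noisy
data.  Training performs R rounds over a seeded shuffle and averages all
T×R post-example weight snapshots (computed with the lazy-delta trick);
prediction uses the averaged weights.  Examples whose cost vector is
entirely zero carry no signal and are dropped.  Defaults: C = 1, R = 10,
tunable per run.

SEARN wraps one such classifier per stage.  Per iteration i the prediction
policy uses the optimal policy with probability (1−β)^(i−1), otherwise a
stochastically sampled hypothesis from the learned ensemble (mixture weight
of hypothesis j of n proportional to β(1−β)^(n−j)).  Costing an action
forces each candidate label, rolls out the remaining actions with that same
interpolated policy, constructs events and measures the weighted FP/FN
loss; the vector is shifted so its minimum is zero and averaged over
`samples_per_action` rollouts (default 1 — more samples reduce variance at
proportional cost).  With *focused costing* (default on) the loss counts
only events whose trigger belongs to the connected component (weak
connectivity over the union of gold and predicted argument graphs) touching
the action site, which keeps estimates clean in sentences with several
disconnected event clusters.  The new hypothesis is trained on the current
iteration's examples only.  At test time the ensemble combines per-label
scores as the mixture-weighted sum (deterministic, the default) or samples
one hypothesis per action (the training-time behavior) when requested —
the deterministic mode exists so predictions and serialized outputs are
reproducible.  Defaults β = 0.3, 12 iterations, at which point the optimal
policy probability has decayed to (1−0.3)¹² ≈ 0.01.

The optimal policy labels triggers with their gold types and asserts a
Theme only when the acting trigger's predicted type is correct, the edge is
gold, and an event-valued argument has been recognized correctly (type and
Theme set); Causes additionally require one correct Theme already in place.
A mistyped trigger therefore receives no arguments, which is exactly what
makes first-iteration costs of wrong trigger labels zero and later-iteration
costs (under learned rollouts) positive.

Setting β = 1, `structural=False` and `zero_one_costs=True` reduces the
whole machinery to the independently trained pipeline: one iteration, pure
optimal-policy states, cost 0 iff the label follows from the gold standard.
`train_independent` is exactly this configuration, so the equivalence holds
by construction and is asserted event-for-event in the tests.

The precision/recall trade-off is controlled through the loss weights: the
cost of an action is w_FP·FP + w_FN·FN, so raising w_FN makes rollouts that
drop gold events expensive and shifts the learned classifiers toward
recall; no development-set threshold search is involved.  Score offsets on
the negative classes (`No_trigger`/`No_Theme`/`No_Cause`) provide the
complementary test-time mechanism and drive the `sweep` command.

Domain adaptation uses feature augmentation: each feature gets one
domain-conjoined copy, so exactly two of the three conceptual versions
(shared, abstract, full-paper) are active per instance and the learner can
allocate shared versus domain-specific weight.

## Synthetic data

The generator emits documents from hand-authored templates whose dependency
parses are constructed jointly with the gold annotation, covering: Simple
events in prepositional and compound-noun frames; single- and multi-Theme
Binding, including the two-group frame ("interactions of A and B with C"),
the same-token and "bind"-lemma exceptions; Regulation over proteins and
over events with verb-chain nesting to depth three; optional protein Causes
realized as `by`-phrases or subjects; the dual-annotation dictionary
pattern; and a bare/modified "regulation" ambiguity that is only resolvable
from context features.  Protein mentions are `PROT<k>` tokens annotated in
`.a1`.  Causer slots hold an annotated protein exactly when the Cause edge
exists (otherwise an unannotated noun), so the gold standard is a
deterministic function of the observable sentence — synthetic annotation
must be supervised-learnable, otherwise held-out comparisons measure noise.

Defaults, chosen once for the package: 10 documents × 5 sentences,
p_nested = 0.4 (share of sentences drawn from the Regulation-bearing
templates, roughly echoing the prominence of Regulation events in the
shared-task data), p_cause = 0.3, p_binding_multi = 0.5, domain_mix = 0.25
full-paper documents, domain-specific vocabulary off, parse noise off.  The
`parse_noise` knob relabels a fraction of edges to generic labels,
corrupting path features and exercising the textual-string fallback.

What the generator does **not** emulate: real lexical variety (the trigger
lexicon is three lemmas per type), parser attachment errors beyond label
noise, multi-token triggers, event-valued Causes, intersentential structure
and anaphora, and realistic GENIA-like type frequencies.  Tests passing on
this data show the machinery is correct and that joint learning behaves as
designed; they do not predict absolute accuracy on real corpora.

## Problem sizes and numerical choices in the shipped tests

The end-to-end suites use, as the package's documented small-corpus
profile: 400 training / 100 held-out sentences with p_nested = 0.5 for the
joint-vs-independent comparison (β = 0.3, 6 iterations, PA C = 1, R = 5);
200 sentences for the β = 1 degeneration equivalence; and 150 training /
100 held-out sentences with parse_noise = 0.2, β = 0.3, 3 iterations,
R = 3 for the loss-weight scans over w ∈ {1, 2, 4, 8, 16, 32, 64} — the
noise keeps base performance off the ceiling so the trade-off has room to
move, and the monotonicity assertion tolerates one decreasing transition
per scan, reflecting the stochastic character of cost estimation.

Degenerate inputs behave as follows: an empty corpus, a zero-example
training set and test-time prediction without hypotheses raise errors;
sentences without proteins produce empty agendas and no events; triggers
without Themes produce no events; disconnected pairs are classified on
string features alone.  All randomness (shuffles, policy interpolation,
rollout sampling) derives from a single seed keyed by iteration, sentence,
action, label and sample index, so training, prediction and serialized
models are bitwise reproducible.

## Known limitations

Binding event construction remains heuristic (grouping by first path
label), so Binding structures whose grouping is not recoverable from the
parse are out of reach.  One event type per token is assumed; dual
annotations are recovered only through the lemma dictionary and only for
the Simple-under-Regulation pattern without a Cause.  Regulation triggers
with several predicted Causes emit one event per Theme×Cause combination,
a convention the task's data rarely exercises.  Cost estimation with one
sample per action is noisy; the `samples_per_action` knob trades time for
variance.
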