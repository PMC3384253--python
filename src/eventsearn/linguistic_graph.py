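"""Dependency-graph utilities and candidate-pair agendas.

Covers trigger head reduction, shortest unlexicalized dependency paths
(Dijkstra over the undirected view of the directed parse, every step tagged
``up`` or ``down``), Theme/Cause candidate agendas with their dynamic
extension for nested events, the action ordering by increasing path length,
and directed-cycle checks over the growing event graph.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Sequence

from .standoff_io import (
    NO_TRIGGER,
    GoldTrigger,
    IntegrityError,
    Sentence,
    is_regulation,
)

if TYPE_CHECKING:  # pragma: no cover
    from .state import ArgRef, SentenceState

UP = "up"
DOWN = "down"

#: PoS prefixes of tokens considered as trigger candidates: nouns, verbs and
#: adjectives cover the vast majority of triggers.
CANDIDATE_POS = ("N", "V", "J")


@dataclass(frozen=True)
class DependencyPath:
    """An unlexicalized dependency path plus its endpoint lemmas.

    ``edges`` is an ordered tuple of ``(label, direction)`` steps where the
    direction records whether the step follows a dependency edge from
    dependent to head (``up``) or head to dependent (``down``).
    """

    edges: tuple[tuple[str, str], ...]
    first_lemma: str
    last_lemma: str

    @property
    def length(self) -> int:
        return len(self.edges)

    def unlexicalized(self) -> str:
        return "/".join(f"{d}:{l}" for l, d in self.edges)


@dataclass(frozen=True)
class CandidatePair:
    """One trigger-argument candidate: a single classification action.

    The argument is ``("prot", ann_id)`` for a protein mention or
    ``("trig", token_index)`` for a predicted trigger used as a nested-event
    argument.  ``insertion_rank`` records agenda insertion order and breaks
    ties among equal path lengths.
    """

    trigger: int
    argument: "ArgRef"
    stage: str  # "theme" | "cause"
    path: DependencyPath | None
    insertion_rank: int

    @property
    def key(self) -> tuple[int, "ArgRef"]:
        return (self.trigger, self.argument)


# ---------------------------------------------------------------------------
# Graph primitives
# ---------------------------------------------------------------------------


def _adjacency(sentence: Sentence) -> dict[int, list[tuple[int, str, str]]]:
    adj = sentence._cache.get("adjacency")
    if adj is None:
        adj = {t.index: [] for t in sentence.tokens}
        for e in sentence.edges:
            adj[e.head].append((e.dependent, e.label, DOWN))
            adj[e.dependent].append((e.head, e.label, UP))
        sentence._cache["adjacency"] = adj
    return adj


def dep_neighbors(sentence: Sentence, token: int) -> list[int]:
    """Token indices sharing a dependency edge with ``token``, sorted."""
    return sorted({other for other, _, _ in _adjacency(sentence)[token]})


def shortest_path(sentence: Sentence, a: int, b: int) -> DependencyPath | None:
    """Minimal-edge-count dependency path from ``a`` to ``b``, or None.

    Directed edges may be followed in either direction; among equal-length
    paths the one with the lexicographically smallest label-direction string
    is returned, so path features are deterministic.
    """
    n = len(sentence.tokens)
    if not (0 <= a < n and 0 <= b < n):
        raise ValueError(f"token index out of range: {a}, {b}")
    if a == b:
        raise ValueError("shortest_path requires distinct endpoints")
    adj = _adjacency(sentence)
    # Dijkstra keyed on (length, step-string tuple): the first time b is
    # settled we hold the shortest, lexicographically smallest path.
    heap: list[tuple[int, tuple[str, ...], int]] = [(0, (), a)]
    settled: set[int] = set()
    while heap:
        dist, steps, u = heapq.heappop(heap)
        if u in settled:
            continue
        settled.add(u)
        if u == b:
            edges = tuple(
                (s.partition(":")[2], s.partition(":")[0]) for s in steps
            )
            return DependencyPath(
                edges=edges,
                first_lemma=sentence.tokens[a].lemma,
                last_lemma=sentence.tokens[b].lemma,
            )
        for v, label, direction in adj[u]:
            if v not in settled:
                heapq.heappush(heap, (dist + 1, steps + (f"{direction}:{label}",), v))
    return None


def path_between(sentence: Sentence, a: int, b: int) -> DependencyPath | None:
    """Memoized :func:`shortest_path` (per-sentence cache)."""
    cache = sentence._cache.setdefault("paths", {})
    if (a, b) not in cache:
        cache[(a, b)] = shortest_path(sentence, a, b)
    return cache[(a, b)]


# ---------------------------------------------------------------------------
# Head reduction
# ---------------------------------------------------------------------------


def head_token_for_span(sentence: Sentence, char_start: int, char_end: int) -> int:
    """Syntactic head token of a character span.

    The head is the token inside the span whose dependency head (if any) lies
    outside the span; with several such tokens the rightmost wins, and spans
    whose internal structure offers no candidate fall back to the rightmost
    token.  Raises ``IntegrityError`` if the span overlaps no token.
    """
    inside = sentence.overlapping_tokens(char_start, char_end)
    if not inside:
        raise IntegrityError(
            f"span [{char_start},{char_end}) overlaps no token in sentence "
            f"{sentence.index}"
        )
    if len(inside) == 1:
        return inside[0]
    inside_set = set(inside)
    heads: dict[int, list[int]] = {}
    for e in sentence.edges:
        heads.setdefault(e.dependent, []).append(e.head)
    external = [
        t for t in inside
        if all(h not in inside_set for h in heads.get(t, []))
    ]
    return max(external) if external else max(inside)


def reduce_trigger_to_head(trigger: GoldTrigger, sentence: Sentence) -> GoldTrigger:
    """Reduce a (possibly multi-token) trigger span to its head token's span.

    Idempotent on single-token triggers.
    """
    head = head_token_for_span(sentence, trigger.char_start, trigger.char_end)
    tok = sentence.tokens[head]
    return replace(
        trigger, char_start=tok.char_start, char_end=tok.char_end, head_token=head
    )


def trigger_candidates(sentence: Sentence) -> list[int]:
    """Tokens eligible as triggers: nouns, verbs, adjectives (coarse PoS)."""
    cands = sentence._cache.get("candidates")
    if cands is None:
        cands = [
            t.index for t in sentence.tokens if t.pos[:1] in CANDIDATE_POS
        ]
        sentence._cache["candidates"] = cands
    return cands


# ---------------------------------------------------------------------------
# Cycle checks and agendas
# ---------------------------------------------------------------------------


def _reachable(edges: Sequence[tuple[int, "ArgRef"]], src: int, dst: int) -> bool:
    # Directed reachability over trigger->trigger argument edges only;
    # protein arguments cannot continue a directed path.
    adj: dict[int, list[int]] = {}
    for t, arg in edges:
        if arg[0] == "trig":
            adj.setdefault(t, []).append(arg[1])
    stack, seen = [src], set()
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        if u in seen:
            continue
        seen.add(u)
        stack.extend(adj.get(u, ()))
    return False


def creates_directed_cycle(state: "SentenceState", edge: tuple[int, "ArgRef"]) -> bool:
    """Would adding ``trigger -> argument`` close a directed cycle?

    Checked over the union of current Theme and Cause edges (the task forbids
    directed cycles in the event graph).
    """
    trigger, arg = edge
    if arg[0] != "trig":
        return False
    if arg[1] == trigger:
        return True
    existing = list(state.theme_edges) + list(state.cause_edges)
    return _reachable(existing, arg[1], trigger)


def _arg_head(sentence: Sentence, arg: "ArgRef") -> int | None:
    if arg[0] == "prot":
        return sentence.protein_by_id(arg[1]).head_token
    return arg[1]


def _make_pair(sentence: Sentence, trigger: int, arg: "ArgRef", stage: str,
               rank: int) -> CandidatePair:
    head = _arg_head(sentence, arg)
    path = None
    if head is not None and head != trigger:
        path = path_between(sentence, trigger, head)
    return CandidatePair(trigger, arg, stage, path, rank)


def build_theme_agenda(sentence: Sentence, state: "SentenceState") -> list[CandidatePair]:
    """Theme-stage candidate pairs consistent with the current state.

    The initial agenda crosses every predicted trigger with every protein in
    the sentence; whenever a trigger has been assigned a Theme, pairs between
    every Regulation-class trigger and that trigger as the argument are
    appended (enabling nested events).  Pairs that would close a directed
    cycle are excluded.
    """
    labels = state.trigger_labels
    trigs = [
        t for t in trigger_candidates(sentence)
        if labels.get(t, NO_TRIGGER) != NO_TRIGGER
    ]
    pairs: list[CandidatePair] = []
    rank = 0
    for t in trigs:
        for p in sentence.proteins:
            pairs.append(_make_pair(sentence, t, ("prot", p.ann_id), "theme", rank))
            rank += 1
    for a in state.themed_order:
        for t in trigs:
            if t != a and is_regulation(labels[t]):
                pairs.append(_make_pair(sentence, t, ("trig", a), "theme", rank))
                rank += 1
    return [p for p in pairs if not creates_directed_cycle(state, p.key)]


def build_cause_agenda(sentence: Sentence, state: "SentenceState") -> list[CandidatePair]:
    """Cause-stage candidate pairs.

    Only Regulation-class triggers holding at least one Theme act; candidate
    arguments are every protein plus every other trigger holding a Theme.
    """
    labels = state.trigger_labels
    regs = [
        t for t in trigger_candidates(sentence)
        if is_regulation(labels.get(t, NO_TRIGGER)) and state.themes_of(t)
    ]
    pairs: list[CandidatePair] = []
    rank = 0
    for t in regs:
        for p in sentence.proteins:
            pairs.append(_make_pair(sentence, t, ("prot", p.ann_id), "cause", rank))
            rank += 1
        for a in state.themed_order:
            if a != t:
                pairs.append(_make_pair(sentence, t, ("trig", a), "cause", rank))
                rank += 1
    return [p for p in pairs if not creates_directed_cycle(state, p.key)]


_INF = float("inf")


def order_actions(pairs: Sequence[CandidatePair]) -> list[CandidatePair]:
    """Stable sort by (dependency path length, agenda insertion order).

    Pairs without a connecting path sort after all finite paths.
    """
    return sorted(
        pairs,
        key=lambda p: (p.path.length if p.path is not None else _INF,
                       p.insertion_rank),
    )
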