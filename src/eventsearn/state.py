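"""Sentence-level prediction state and the gold-standard decomposition.

A :class:`SentenceState` is the partial or complete action sequence for one
sentence: trigger labels assigned left to right, then Theme edges, then Cause
edges.  :func:`decompose` converts a sentence's gold events into the same
representation, which drives the optimal policy and the zero-loss oracle.

Event identity is structural: a signature ``(head token, type, theme
signatures, cause signature)`` with nested events compared recursively, which
is the task's "all elements identified correctly" criterion with approximate
trigger matching realized as head-token equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

from .standoff_io import (
    Event,
    IntegrityError,
    ProteinMention,
    Sentence,
    is_regulation,
)

#: ("prot", ann_id) for a protein mention, ("trig", token index) for an event
#: trigger used as argument.
ArgRef = tuple[str, Union[str, int]]

Signature = tuple  # (token, event_type, frozenset of arg sigs, cause sig|None)


def arg_signature(arg) -> tuple:
    if isinstance(arg, ProteinMention):
        return ("P", arg.ann_id)
    return ("E", event_signature(arg))


def event_signature(event: Event) -> Signature:
    themes = frozenset(arg_signature(a) for a in event.themes)
    cause = arg_signature(event.cause) if event.cause is not None else None
    return (event.trigger.head_token, event.trigger.event_type, themes, cause)


def sentence_gold_signatures(sentence: Sentence) -> frozenset[Signature]:
    return frozenset(event_signature(e) for e in sentence.events)


@dataclass
class SentenceState:
    """Partial/complete action sequence for one sentence.

    ``trigger_labels`` holds one entry per already-classified candidate token
    (value may be ``No_trigger``); edges point from trigger token to argument.
    ``action_log`` records every decision as
    ``(stage, site, label, policy_used)``.
    """

    trigger_labels: dict[int, str] = field(default_factory=dict)
    theme_edges: list[tuple[int, ArgRef]] = field(default_factory=list)
    cause_edges: list[tuple[int, ArgRef]] = field(default_factory=list)
    decided_theme: set[tuple[int, ArgRef]] = field(default_factory=set)
    decided_cause: set[tuple[int, ArgRef]] = field(default_factory=set)
    next_trigger_pos: int = 0
    themed_order: list[int] = field(default_factory=list)
    action_log: list[tuple] = field(default_factory=list)

    def copy(self) -> "SentenceState":
        return SentenceState(
            trigger_labels=dict(self.trigger_labels),
            theme_edges=list(self.theme_edges),
            cause_edges=list(self.cause_edges),
            decided_theme=set(self.decided_theme),
            decided_cause=set(self.decided_cause),
            next_trigger_pos=self.next_trigger_pos,
            themed_order=list(self.themed_order),
            action_log=list(self.action_log),
        )

    def themes_of(self, trigger: int) -> list[ArgRef]:
        return [a for t, a in self.theme_edges if t == trigger]

    def causes_of(self, trigger: int) -> list[ArgRef]:
        return [a for t, a in self.cause_edges if t == trigger]

    def add_theme(self, trigger: int, arg: ArgRef) -> None:
        self.theme_edges.append((trigger, arg))
        if trigger not in self.themed_order:
            self.themed_order.append(trigger)

    def add_cause(self, trigger: int, arg: ArgRef) -> None:
        self.cause_edges.append((trigger, arg))


@dataclass(frozen=True)
class GoldDecomposition:
    """The gold standard rewritten as decomposition actions.

    ``trigger_labels`` maps head tokens to event types (absent tokens are
    non-triggers); edges mirror ``SentenceState``.  Regulation events that
    share their trigger token with their own Theme event (the
    "overexpress"-style dual annotation) are excluded from the edges — the
    event-construction dictionary regenerates them — but their signatures
    remain part of ``event_signatures``.
    """

    trigger_labels: dict[int, str]
    theme_edges: frozenset[tuple[int, ArgRef]]
    cause_edges: frozenset[tuple[int, ArgRef]]
    themes_by_trigger: dict[int, frozenset[ArgRef]]
    event_signatures: frozenset[Signature]


def _event_arg_ref(arg) -> ArgRef:
    if isinstance(arg, ProteinMention):
        return ("prot", arg.ann_id)
    return ("trig", arg.trigger.head_token)


def is_dictionary_pattern(event: Event) -> bool:
    """Regulation event whose single Theme is an event on the same token."""
    return (
        is_regulation(event.trigger.event_type)
        and len(event.themes) == 1
        and isinstance(event.themes[0], Event)
        and event.themes[0].trigger.head_token == event.trigger.head_token
    )


def decompose(sentence: Sentence) -> GoldDecomposition:
    """Rewrite a sentence's gold events as trigger labels and argument edges.

    Raises ``IntegrityError`` when two non-dictionary events assign different
    types to the same head token (the annotation is then not reachable by the
    one-type-per-token decomposition).
    """
    labels: dict[int, str] = {}
    theme_edges: set[tuple[int, ArgRef]] = set()
    cause_edges: set[tuple[int, ArgRef]] = set()

    def visit(event: Event) -> None:
        if is_dictionary_pattern(event):
            visit(event.themes[0])
            return
        tok = event.trigger.head_token
        etype = event.trigger.event_type
        if labels.get(tok, etype) != etype:
            raise IntegrityError(
                f"token {tok} in sentence {sentence.index} carries conflicting "
                f"event types {labels[tok]} / {etype}"
            )
        labels[tok] = etype
        for a in event.themes:
            theme_edges.add((tok, _event_arg_ref(a)))
            if isinstance(a, Event):
                visit(a)
        if event.cause is not None:
            cause_edges.add((tok, _event_arg_ref(event.cause)))
            if isinstance(event.cause, Event):
                visit(event.cause)

    for e in sentence.events:
        visit(e)

    themes_by: dict[int, set[ArgRef]] = {}
    for t, a in theme_edges:
        themes_by.setdefault(t, set()).add(a)
    return GoldDecomposition(
        trigger_labels=labels,
        theme_edges=frozenset(theme_edges),
        cause_edges=frozenset(cause_edges),
        themes_by_trigger={t: frozenset(v) for t, v in themes_by.items()},
        event_signatures=sentence_gold_signatures(sentence),
    )
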