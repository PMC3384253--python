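"""Rule-based event construction and the end-to-end prediction pipeline.

The classification stages leave a sentence state (trigger labels, Theme and
Cause edges); this module turns it into events.  Simple triggers emit one
event per Theme.  Nominal Binding triggers group their Themes by the first
label of the trigger-argument dependency path and emit the cross-product of
the groups (so "interactions of A and B with C" yields two two-Theme
events), except that Themes sharing a token with each other or with the
trigger, or a trigger lemma "bind", collapse everything into a single
multi-Theme event; verbal Binding triggers emit one event per Theme.
Regulation triggers emit one event per Theme with the Cause (if any)
attached to each, nested arguments resolved bottom-up.  Tokens that in
training data carry both a Simple and a Regulation annotation (e.g.
"overexpress") get the extra Regulation event from a dictionary, since the
decomposition predicts a single type per token.
"""

from __future__ import annotations

import itertools
from collections import Counter
from typing import Iterable, Sequence

from .csc_pa_learner import PAConfig
from .linguistic_graph import path_between
from .standoff_io import (
    BINDING_TYPE,
    NO_TRIGGER,
    Document,
    Event,
    GoldTrigger,
    IntegrityError,
    ProteinMention,
    Sentence,
    is_simple,
    write_a2,
)
from .state import SentenceState, Signature, is_dictionary_pattern

RegulationDictionary = dict[str, str]


def build_regulation_dictionary(corpus: Iterable[Document]) -> RegulationDictionary:
    """Collect lemmas that carry a Simple event plus a Regulation event over it.

    The value is the majority Regulation type for the lemma (ties broken
    lexicographically).  Built from training data only.
    """
    counts: dict[str, Counter] = {}
    for doc in corpus:
        for sentence in doc.sentences:
            for event in sentence.events:
                if is_dictionary_pattern(event):
                    lemma = sentence.tokens[event.trigger.head_token].lemma
                    counts.setdefault(lemma, Counter())[
                        event.trigger.event_type
                    ] += 1
    out: RegulationDictionary = {}
    for lemma, counter in counts.items():
        top = max(counter.values())
        out[lemma] = min(t for t, c in counter.items() if c == top)
    return out


# ---------------------------------------------------------------------------
# Event construction
# ---------------------------------------------------------------------------


def _topological_triggers(themed: Sequence[int], state: SentenceState) -> list[int]:
    # Arguments before the triggers that consume them (the edge graph is
    # acyclic by construction).
    children: dict[int, list[int]] = {}
    for t, a in list(state.theme_edges) + list(state.cause_edges):
        if a[0] == "trig":
            children.setdefault(t, []).append(a[1])
    order: list[int] = []
    seen: set[int] = set()

    def visit(t: int) -> None:
        if t in seen:
            return
        seen.add(t)
        for c in children.get(t, ()):
            visit(c)
        order.append(t)

    for t in themed:
        visit(t)
    return order


def _binding_signatures(
    sentence: Sentence,
    state: SentenceState,
    tok: int,
    themes: Sequence,
) -> list[Signature]:
    lemma = sentence.tokens[tok].lemma
    prots = [a for a in themes if a[0] == "prot"]
    heads = [sentence.protein_by_id(pid).head_token for _, pid in prots]
    same_token = len(set(heads)) < len(heads) or tok in heads
    if lemma == "bind" or same_token:
        return [(tok, BINDING_TYPE, frozenset(("P", pid) for _, pid in prots), None)]
    if not sentence.tokens[tok].pos.startswith("N"):
        return [(tok, BINDING_TYPE, frozenset({("P", pid)}), None)
                for _, pid in prots]
    groups: dict[str, list[str]] = {}
    for i, (_, pid) in enumerate(prots):
        head = sentence.protein_by_id(pid).head_token
        path = path_between(sentence, tok, head) if head != tok else None
        key = (f"{path.edges[0][1]}:{path.edges[0][0]}"
               if path is not None and path.edges else f"nopath#{i}")
        groups.setdefault(key, []).append(pid)
    out = []
    for combo in itertools.product(*groups.values()):
        out.append((tok, BINDING_TYPE, frozenset(("P", pid) for pid in combo), None))
    return out


def construct_event_signatures(
    sentence: Sentence,
    state: SentenceState,
    regdict: RegulationDictionary | None = None,
) -> set[Signature]:
    """Build the event set implied by a completed sentence state.

    Returns structural signatures (head token, type, Theme signatures,
    Cause signature); triggers with no Theme produce no event.
    """
    regdict = regdict or {}
    themes_by: dict[int, list] = {}
    for t, a in state.theme_edges:
        themes_by.setdefault(t, []).append(a)
    causes_by: dict[int, list] = {}
    for t, a in state.cause_edges:
        causes_by.setdefault(t, []).append(a)

    built: dict[int, list[Signature]] = {}

    def resolve(arg) -> list:
        if arg[0] == "prot":
            return [("P", arg[1])]
        return [("E", s) for s in built.get(arg[1], [])]

    for tok in _topological_triggers(list(themes_by), state):
        label = state.trigger_labels.get(tok, NO_TRIGGER)
        themes = themes_by.get(tok)
        if label == NO_TRIGGER or not themes:
            continue
        sigs: list[Signature] = []
        if label == BINDING_TYPE:
            sigs = _binding_signatures(sentence, state, tok, themes)
        elif is_simple(label):
            for a in themes:
                for r in resolve(a):
                    sigs.append((tok, label, frozenset({r}), None))
        else:  # Regulation class
            causes = [c for a in causes_by.get(tok, ()) for c in resolve(a)]
            for a in themes:
                for r in resolve(a):
                    if causes:
                        sigs.extend(
                            (tok, label, frozenset({r}), c) for c in causes
                        )
                    else:
                        sigs.append((tok, label, frozenset({r}), None))
        # de-duplicate preserving construction order
        seen: set[Signature] = set()
        sigs = [s for s in sigs if not (s in seen or seen.add(s))]
        if is_simple(label):
            lemma = sentence.tokens[tok].lemma
            if lemma in regdict:
                sigs = sigs + [
                    (tok, regdict[lemma], frozenset({("E", s)}), None)
                    for s in sigs
                ]
        built[tok] = sigs
    return {s for sigs in built.values() for s in sigs}


def construct_events(
    sentence: Sentence,
    state: SentenceState,
    regdict: RegulationDictionary | None = None,
) -> list[Event]:
    """Like :func:`construct_event_signatures` but materialized as
    :class:`Event` objects with (unassigned-id) trigger annotations."""
    sigs = construct_event_signatures(sentence, state, regdict)
    trig_memo: dict[tuple[int, str], GoldTrigger] = {}
    ev_memo: dict[Signature, Event] = {}

    def trigger_for(tok: int, etype: str) -> GoldTrigger:
        if (tok, etype) not in trig_memo:
            t = sentence.tokens[tok]
            trig_memo[(tok, etype)] = GoldTrigger(
                "", etype, t.char_start, t.char_end, head_token=tok
            )
        return trig_memo[(tok, etype)]

    def to_event(sig: Signature) -> Event:
        if sig in ev_memo:
            return ev_memo[sig]
        tok, etype, theme_sigs, cause_sig = sig

        def arg_of(a):
            if a[0] == "P":
                return sentence.protein_by_id(a[1])
            if a[1] not in sigs and a[1] not in ev_memo:
                raise IntegrityError(f"unresolvable nested reference {a[1]!r}")
            return to_event(a[1])

        themes = tuple(arg_of(a) for a in sorted(theme_sigs, key=repr))
        cause = arg_of(cause_sig) if cause_sig is not None else None
        ev = Event("", trigger_for(tok, etype), themes, cause)
        ev_memo[sig] = ev
        return ev

    # Deterministic output order: by trigger token, then signature repr.
    return [to_event(s) for s in sorted(sigs, key=lambda s: (s[0], repr(s)))]


# ---------------------------------------------------------------------------
# Document-level prediction
# ---------------------------------------------------------------------------


def predict_signatures(
    doc: Document,
    policy,
    regdict: RegulationDictionary | None = None,
    offsets: dict[str, float] | None = None,
) -> list[set[Signature]]:
    """Per-sentence predicted event signatures for one document."""
    from .searn_engine import TrainedPolicy, run_policy

    if regdict is None and isinstance(policy, TrainedPolicy):
        regdict = policy.regdict
    out = []
    for sentence in doc.sentences:
        state = run_policy(sentence, policy, mode="test", offsets=offsets) \
            if isinstance(policy, TrainedPolicy) else \
            run_policy(sentence, policy, mode="test")
        out.append(construct_event_signatures(sentence, state, regdict))
    return out


def predict_document(
    doc: Document,
    policy,
    regdict: RegulationDictionary | None = None,
    offsets: dict[str, float] | None = None,
) -> str:
    """Predict a document and serialize the result as .a2 text.

    Annotation ids are assigned in sentence order then construction order, T
    ids continuing after the document's protein ids, so output is
    deterministic byte for byte.
    """
    from .searn_engine import TrainedPolicy, run_policy

    if regdict is None and isinstance(policy, TrainedPolicy):
        regdict = policy.regdict
    all_triggers: list[GoldTrigger] = []
    all_events: list[Event] = []
    t_counter = len(doc.proteins)
    e_counter = 0
    for sentence in doc.sentences:
        state = run_policy(sentence, policy, mode="test", offsets=offsets)
        events = construct_events(sentence, state, regdict)
        # assign ids: first triggers (unique per event list), then events
        id_map: dict[int, GoldTrigger] = {}
        renamed: dict[int, Event] = {}

        def rename(ev: Event) -> Event:
            nonlocal t_counter, e_counter
            if id(ev) in renamed:
                return renamed[id(ev)]
            trig = ev.trigger
            if id(trig) not in id_map:
                t_counter += 1
                id_map[id(trig)] = GoldTrigger(
                    f"T{t_counter}", trig.event_type, trig.char_start,
                    trig.char_end, trig.head_token,
                )
            themes = tuple(
                a if isinstance(a, ProteinMention) else rename(a)
                for a in ev.themes
            )
            cause = ev.cause
            if isinstance(cause, Event):
                cause = rename(cause)
            e_counter += 1
            out = Event(f"E{e_counter}", id_map[id(trig)], themes, cause)
            renamed[id(ev)] = out
            return out

        for ev in events:
            out = rename(ev)
            if out not in all_events:
                all_events.append(out)
        for trig in id_map.values():
            all_triggers.append(trig)
    # nested renames may append inner events first; keep id order
    all_events.sort(key=lambda e: int(e.ann_id[1:]))
    return write_a2(all_triggers, all_events, doc.text)


def train_independent(
    corpus: Iterable[Document],
    pa: PAConfig = PAConfig(),
    seed: int = 0,
    domain_adapt: bool = False,
):
    """Train the independent-pipeline baseline.

    This is the SEARN degeneration: beta = 1 (one iteration, pure optimal
    policy), no structural features, and 0/1 costs (0 iff the label follows
    from the gold standard), yielding a single hypothesis per stage.
    """
    from .searn_engine import SearnConfig, searn_train

    cfg = SearnConfig(
        beta=1.0,
        iterations=1,
        structural=False,
        zero_one_costs=True,
        seed=seed,
        pa=pa,
        domain_adapt=domain_adapt,
    )
    return searn_train(corpus, cfg)
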