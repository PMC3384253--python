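"""Reading and writing BioNLP-style standoff annotation.

A corpus directory holds, per document, four plain-text files plus a manifest:

* ``<doc_id>.txt`` -- the raw document text.
* ``<doc_id>.a1`` -- protein mentions, one per line:
  ``T1<TAB>Protein <start> <end><TAB><surface>``.
* ``<doc_id>.a2`` -- event triggers (T-lines, same shape as .a1 but typed with
  one of the nine event types) and events (E-lines such as
  ``E1<TAB>Binding:T5 Theme:T1 Theme2:T2`` or nested
  ``E2<TAB>Negative_regulation:T6 Theme:E1 Cause:T3``).
* ``<doc_id>.parses`` -- one blank-line-separated block per sentence; each row
  is ``idx<TAB>surface<TAB>lemma<TAB>pos<TAB>start<TAB>end[<TAB>head:label]*``
  with document-level 0-based half-open character offsets and collapsed
  Stanford-style dependency labels.  Sentence segmentation is taken from this
  file; no segmenter is run here.
* ``domains.tsv`` -- optional manifest mapping ``doc_id<TAB>domain`` where the
  domain is ``abstract`` or ``fullpaper``.

All offsets are 0-based half-open and validated against the .txt content on
load (``IntegrityError`` on mismatch); malformed lines raise ``ParseError``
naming the offending line.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

SIMPLE_TYPES = (
    "Gene_expression",
    "Transcription",
    "Protein_catabolism",
    "Phosphorylation",
    "Localization",
)
BINDING_TYPE = "Binding"
REGULATION_TYPES = ("Regulation", "Positive_regulation", "Negative_regulation")
EVENT_TYPES = SIMPLE_TYPES + (BINDING_TYPE,) + REGULATION_TYPES
NO_TRIGGER = "No_trigger"

ABSTRACT = "abstract"
FULLPAPER = "fullpaper"
DOMAINS = (ABSTRACT, FULLPAPER)


def is_simple(event_type: str) -> bool:
    return event_type in SIMPLE_TYPES


def is_regulation(event_type: str) -> bool:
    return event_type in REGULATION_TYPES


def event_class(event_type: str) -> str:
    """Map an event type onto its class: Simple, Binding or Regulation."""
    if event_type in SIMPLE_TYPES:
        return "Simple"
    if event_type == BINDING_TYPE:
        return "Binding"
    if event_type in REGULATION_TYPES:
        return "Regulation"
    raise ValueError(f"unknown event type {event_type!r}")


class StandoffError(ValueError):
    """Base class for standoff reading/writing failures."""


class ParseError(StandoffError):
    """A line does not match the expected standoff/parse-file grammar."""


class IntegrityError(StandoffError):
    """Annotations are inconsistent with the text or with each other."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Token:
    """A token with document-level character offsets.

    ``index`` is 0-based within its sentence; offsets are 0-based half-open
    into the document text, so ``text[char_start:char_end] == surface``.
    """

    index: int
    surface: str
    lemma: str
    pos: str
    char_start: int
    char_end: int


@dataclass(frozen=True)
class DependencyEdge:
    """A directed collapsed-dependency edge ``head --label--> dependent``."""

    head: int
    dependent: int
    label: str


@dataclass(frozen=True)
class ProteinMention:
    ann_id: str
    char_start: int
    char_end: int
    head_token: int | None = None


@dataclass(frozen=True)
class GoldTrigger:
    ann_id: str
    event_type: str
    char_start: int
    char_end: int
    head_token: int | None = None


Argument = Union[ProteinMention, "Event"]


@dataclass(frozen=True)
class Event:
    """A typed event: a trigger, one or more Themes, an optional Cause.

    Theme and Cause arguments are proteins or (for Regulation-class events)
    other events, so a document's events form a directed acyclic graph.
    """

    ann_id: str
    trigger: GoldTrigger
    themes: tuple[Argument, ...]
    cause: Argument | None = None

    def __post_init__(self) -> None:
        if not self.themes:
            raise IntegrityError(f"event {self.ann_id} has no Theme")
        etype = self.trigger.event_type
        if not is_regulation(etype):
            if self.cause is not None:
                raise IntegrityError(f"{etype} event {self.ann_id} has a Cause")
            if any(isinstance(t, Event) for t in self.themes):
                raise IntegrityError(
                    f"{etype} event {self.ann_id} has an event-valued Theme"
                )
        if is_simple(etype) and len(self.themes) != 1:
            raise IntegrityError(
                f"Simple event {self.ann_id} must have exactly one Theme"
            )


@dataclass
class Sentence:
    """A parsed sentence: the unit instance of structured prediction."""

    index: int
    char_start: int
    char_end: int
    tokens: tuple[Token, ...]
    edges: tuple[DependencyEdge, ...]
    proteins: list[ProteinMention] = field(default_factory=list)
    triggers: list[GoldTrigger] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)
    domain: str = ABSTRACT
    doc_id: str = ""
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def overlapping_tokens(self, char_start: int, char_end: int) -> list[int]:
        return [
            t.index
            for t in self.tokens
            if t.char_start < char_end and t.char_end > char_start
        ]

    def protein_by_id(self, ann_id: str) -> ProteinMention:
        cache = self._cache.setdefault("prot_by_id", {})
        if not cache:
            cache.update({p.ann_id: p for p in self.proteins})
        return cache[ann_id]


@dataclass
class Document:
    doc_id: str
    text: str
    domain: str
    sentences: list[Sentence]

    @property
    def proteins(self) -> list[ProteinMention]:
        return [p for s in self.sentences for p in s.proteins]

    @property
    def events(self) -> list[Event]:
        return [e for s in self.sentences for e in s.events]


# ---------------------------------------------------------------------------
# .a1 / .a2 parsing
# ---------------------------------------------------------------------------

_T_RE = re.compile(r"^(T\S+)\t(\S+) (\d+) (\d+)\t(.*)$")
_E_RE = re.compile(r"^(E\S+)\t(\S+):(\S+)((?: \S+:\S+)*)\s*$")


def _span_check(ann_id: str, start: int, end: int, surface: str, text: str | None,
                lineno: int) -> None:
    if end <= start:
        raise IntegrityError(
            f"line {lineno}: annotation {ann_id} has end <= start ({start}, {end})"
        )
    if text is not None:
        if end > len(text):
            raise IntegrityError(
                f"line {lineno}: annotation {ann_id} span exceeds text bounds"
            )
        if text[start:end] != surface:
            raise IntegrityError(
                f"line {lineno}: annotation {ann_id} surface {surface!r} does not "
                f"match text {text[start:end]!r}"
            )


def parse_a1(lines: str | Iterable[str], text: str | None = None) -> list[ProteinMention]:
    """Parse protein mentions from .a1 content.

    When ``text`` is supplied, spans are verified against it.
    """
    if isinstance(lines, str):
        lines = lines.splitlines()
    mentions: list[ProteinMention] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(lines, start=1):
        if not raw.strip():
            continue
        m = _T_RE.match(raw)
        if m is None or m.group(2) != "Protein":
            raise ParseError(f"line {lineno}: malformed .a1 line {raw!r}")
        ann_id, _, start, end, surface = m.groups()
        start, end = int(start), int(end)
        _span_check(ann_id, start, end, surface, text, lineno)
        if ann_id in seen:
            raise IntegrityError(f"line {lineno}: duplicate annotation id {ann_id}")
        seen.add(ann_id)
        mentions.append(ProteinMention(ann_id, start, end))
    return mentions


def parse_a2(
    lines: str | Iterable[str],
    proteins: Sequence[ProteinMention],
    text: str | None = None,
) -> tuple[list[GoldTrigger], list[Event]]:
    """Parse triggers and events from .a2 content, resolving all references.

    E-lines may reference other E-lines (nested events); reference cycles and
    dangling references raise ``IntegrityError``.
    """
    if isinstance(lines, str):
        lines = lines.splitlines()
    triggers: dict[str, GoldTrigger] = {}
    raw_events: dict[str, tuple[str, str, list[tuple[str, str]], int]] = {}
    order: list[str] = []
    prot_map = {p.ann_id: p for p in proteins}
    for lineno, raw in enumerate(lines, start=1):
        if not raw.strip():
            continue
        if raw.startswith("T"):
            m = _T_RE.match(raw)
            if m is None:
                raise ParseError(f"line {lineno}: malformed trigger line {raw!r}")
            ann_id, etype, start, end, surface = m.groups()
            if etype not in EVENT_TYPES:
                raise ParseError(f"line {lineno}: unknown event type {etype!r}")
            start, end = int(start), int(end)
            _span_check(ann_id, start, end, surface, text, lineno)
            if ann_id in triggers or ann_id in prot_map:
                raise IntegrityError(f"line {lineno}: duplicate annotation id {ann_id}")
            triggers[ann_id] = GoldTrigger(ann_id, etype, start, end)
        elif raw.startswith("E"):
            m = _E_RE.match(raw)
            if m is None:
                raise ParseError(f"line {lineno}: malformed event line {raw!r}")
            eid, etype, tid, args = m.groups()
            arglist = []
            for chunk in args.split():
                key, _, ref = chunk.partition(":")
                arglist.append((key, ref))
            if eid in raw_events:
                raise IntegrityError(f"line {lineno}: duplicate event id {eid}")
            raw_events[eid] = (etype, tid, arglist, lineno)
            order.append(eid)
        else:
            raise ParseError(f"line {lineno}: unrecognized .a2 line {raw!r}")

    resolved: dict[str, Event] = {}

    def resolve(eid: str, stack: tuple[str, ...]) -> Event:
        if eid in resolved:
            return resolved[eid]
        if eid in stack:
            raise IntegrityError(f"cyclic event references involving {eid}")
        etype, tid, arglist, lineno = raw_events[eid]
        if tid not in triggers:
            raise IntegrityError(f"line {lineno}: dangling trigger reference {tid}")
        trigger = triggers[tid]
        if trigger.event_type != etype:
            raise IntegrityError(
                f"line {lineno}: event type {etype} disagrees with trigger {tid}"
            )
        themes: list[Argument] = []
        cause: Argument | None = None

        def lookup(ref: str) -> Argument:
            if ref in prot_map:
                return prot_map[ref]
            if ref in raw_events:
                return resolve(ref, stack + (eid,))
            raise IntegrityError(f"line {lineno}: dangling argument reference {ref}")

        for key, ref in arglist:
            if key.startswith("Theme"):
                themes.append(lookup(ref))
            elif key == "Cause":
                if cause is not None:
                    raise IntegrityError(f"line {lineno}: event {eid} has two Causes")
                cause = lookup(ref)
            else:
                raise ParseError(f"line {lineno}: unknown argument key {key!r}")
        resolved[eid] = Event(eid, trigger, tuple(themes), cause)
        return resolved[eid]

    events = [resolve(eid, ()) for eid in order]
    return list(triggers.values()), events


def write_a2(
    triggers: Sequence[GoldTrigger],
    events: Sequence[Event],
    text: str | None = None,
) -> str:
    """Serialize triggers and events to .a2 text.

    Multi-Theme events are written with keys Theme, Theme2, Theme3, ...
    (the shared-task dialect).  Round-trips through :func:`parse_a2`.
    """
    lines = []
    for t in triggers:
        if not t.ann_id:
            raise StandoffError("trigger without an assigned id")
        surface = text[t.char_start:t.char_end] if text is not None else ""
        lines.append(f"{t.ann_id}\t{t.event_type} {t.char_start} {t.char_end}\t{surface}")
    for e in events:
        if not e.ann_id or not e.trigger.ann_id:
            raise StandoffError("event without an assigned id")
        parts = [f"{e.ann_id}\t{e.trigger.event_type}:{e.trigger.ann_id}"]
        for i, theme in enumerate(e.themes):
            key = "Theme" if i == 0 else f"Theme{i + 1}"
            if not theme.ann_id:
                raise StandoffError("argument without an assigned id")
            parts.append(f"{key}:{theme.ann_id}")
        if e.cause is not None:
            parts.append(f"Cause:{e.cause.ann_id}")
        lines.append(" ".join(parts))
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Parse-file reading/writing
# ---------------------------------------------------------------------------


def parse_parses(lines: str, text: str) -> list[Sentence]:
    """Read the CoNLL-style parse file into sentences with tokens and edges.

    Every token surface is checked against the document text; duplicate or
    non-contiguous token indices and invalid dependency references raise
    ``IntegrityError``.  A block with no dependency columns yields a sentence
    whose dependency graph has no edges.
    """
    sentences: list[Sentence] = []
    block: list[str] = []
    blocks: list[list[str]] = []
    for raw in lines.splitlines():
        if raw.strip():
            block.append(raw)
        elif block:
            blocks.append(block)
            block = []
    if block:
        blocks.append(block)

    for si, rows in enumerate(blocks):
        tokens: list[Token] = []
        edges: list[DependencyEdge] = []
        pending: list[tuple[int, list[str]]] = []
        for raw in rows:
            cols = raw.split("\t")
            if len(cols) < 6:
                raise ParseError(f"sentence {si}: malformed parse row {raw!r}")
            idx = int(cols[0])
            surface, lemma, pos = cols[1], cols[2], cols[3]
            start, end = int(cols[4]), int(cols[5])
            if idx != len(tokens):
                raise IntegrityError(
                    f"sentence {si}: token indices not contiguous at {idx}"
                )
            if text[start:end] != surface:
                raise IntegrityError(
                    f"sentence {si}: token {idx} surface {surface!r} does not match "
                    f"text {text[start:end]!r}"
                )
            tokens.append(Token(idx, surface, lemma, pos, start, end))
            pending.append((idx, cols[6:]))
        n = len(tokens)
        for idx, depcols in pending:
            for col in depcols:
                if not col:
                    continue
                head_s, _, label = col.partition(":")
                head = int(head_s)
                if not label or not (0 <= head < n):
                    raise IntegrityError(
                        f"sentence {si}: bad dependency column {col!r} on token {idx}"
                    )
                if head == idx:
                    raise IntegrityError(
                        f"sentence {si}: self-dependency on token {idx}"
                    )
                edges.append(DependencyEdge(head, idx, label))
        sentences.append(
            Sentence(
                index=si,
                char_start=tokens[0].char_start,
                char_end=tokens[-1].char_end,
                tokens=tuple(tokens),
                edges=tuple(edges),
            )
        )
    return sentences


def write_parses(sentences: Sequence[Sentence]) -> str:
    blocks = []
    for s in sentences:
        incoming: dict[int, list[str]] = {}
        for e in s.edges:
            incoming.setdefault(e.dependent, []).append(f"{e.head}:{e.label}")
        rows = []
        for t in s.tokens:
            cols = [
                str(t.index), t.surface, t.lemma, t.pos,
                str(t.char_start), str(t.char_end),
            ] + incoming.get(t.index, [])
            rows.append("\t".join(cols))
        blocks.append("\n".join(rows))
    return "\n\n".join(blocks) + "\n"


# ---------------------------------------------------------------------------
# Document assembly
# ---------------------------------------------------------------------------


def _sentence_of(sentences: list[Sentence], start: int, end: int,
                 what: str) -> Sentence:
    for s in sentences:
        if s.char_start <= start and end <= s.char_end:
            return s
    raise IntegrityError(f"{what} span [{start},{end}) is not inside any sentence")


def build_document(
    doc_id: str,
    text: str,
    sentences: list[Sentence],
    proteins: Sequence[ProteinMention] = (),
    triggers: Sequence[GoldTrigger] = (),
    events: Sequence[Event] = (),
    domain: str = ABSTRACT,
) -> Document:
    """Attach annotations to sentences and compute annotation head tokens.

    Sentence spans must be disjoint, ordered and within the text; each
    annotation is assigned to the sentence containing its span, and its
    syntactic head token (within-sentence index) is computed.
    """
    from .linguistic_graph import head_token_for_span  # circular at module load

    if domain not in DOMAINS:
        raise ValueError(f"unknown domain {domain!r}")
    prev_end = 0
    for s in sentences:
        if s.char_start < prev_end or s.char_end > len(text):
            raise IntegrityError(f"sentence spans out of order/bounds in {doc_id}")
        prev_end = s.char_end
        s.doc_id = doc_id
        s.domain = domain

    new_prot: dict[str, ProteinMention] = {}
    for p in proteins:
        sent = _sentence_of(sentences, p.char_start, p.char_end, f"protein {p.ann_id}")
        head = head_token_for_span(sent, p.char_start, p.char_end)
        attached = replace(p, head_token=head)
        sent.proteins.append(attached)
        new_prot[p.ann_id] = attached

    new_trig: dict[str, GoldTrigger] = {}
    trig_sent: dict[str, Sentence] = {}
    for t in triggers:
        sent = _sentence_of(sentences, t.char_start, t.char_end, f"trigger {t.ann_id}")
        head = head_token_for_span(sent, t.char_start, t.char_end)
        attached = replace(t, head_token=head)
        sent.triggers.append(attached)
        new_trig[t.ann_id] = attached
        trig_sent[t.ann_id] = sent

    rebuilt: dict[str, Event] = {}

    def rebuild(e: Event) -> Event:
        if e.ann_id in rebuilt:
            return rebuilt[e.ann_id]
        themes = tuple(
            new_prot[a.ann_id] if isinstance(a, ProteinMention) else rebuild(a)
            for a in e.themes
        )
        cause = None
        if e.cause is not None:
            cause = (
                new_prot[e.cause.ann_id]
                if isinstance(e.cause, ProteinMention)
                else rebuild(e.cause)
            )
        out = Event(e.ann_id, new_trig[e.trigger.ann_id], themes, cause)
        rebuilt[e.ann_id] = out
        return out

    for e in events:
        ev = rebuild(e)
        trig_sent[ev.trigger.ann_id].events.append(ev)

    return Document(doc_id=doc_id, text=text, domain=domain, sentences=sentences)


# ---------------------------------------------------------------------------
# Corpus directories
# ---------------------------------------------------------------------------

MANIFEST = "domains.tsv"


def load_document(directory: str | Path, doc_id: str, domain: str = ABSTRACT) -> Document:
    directory = Path(directory)
    text = (directory / f"{doc_id}.txt").read_text()
    proteins = parse_a1((directory / f"{doc_id}.a1").read_text(), text)
    sentences = parse_parses((directory / f"{doc_id}.parses").read_text(), text)
    a2_path = directory / f"{doc_id}.a2"
    triggers: list[GoldTrigger] = []
    events: list[Event] = []
    if a2_path.exists():
        triggers, events = parse_a2(a2_path.read_text(), proteins, text)
    return build_document(doc_id, text, sentences, proteins, triggers, events, domain)


def read_manifest(directory: str | Path) -> dict[str, str]:
    path = Path(directory) / MANIFEST
    domains: dict[str, str] = {}
    if path.exists():
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            if not raw.strip():
                continue
            doc_id, _, domain = raw.partition("\t")
            if domain not in DOMAINS:
                raise ParseError(f"{MANIFEST} line {lineno}: unknown domain {domain!r}")
            domains[doc_id] = domain
    return domains


def load_corpus(directory: str | Path) -> list[Document]:
    directory = Path(directory)
    domains = read_manifest(directory)
    docs = []
    for txt in sorted(directory.glob("*.txt")):
        doc_id = txt.stem
        docs.append(load_document(directory, doc_id, domains.get(doc_id, ABSTRACT)))
    return docs


def write_corpus(docs: Sequence[Document], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for doc in docs:
        (directory / f"{doc.doc_id}.txt").write_text(doc.text)
        a1 = "".join(
            f"{p.ann_id}\tProtein {p.char_start} {p.char_end}\t"
            f"{doc.text[p.char_start:p.char_end]}\n"
            for s in doc.sentences
            for p in s.proteins
        )
        (directory / f"{doc.doc_id}.a1").write_text(a1)
        triggers = [t for s in doc.sentences for t in s.triggers]
        events = [e for s in doc.sentences for e in s.events]
        (directory / f"{doc.doc_id}.a2").write_text(write_a2(triggers, events, doc.text))
        (directory / f"{doc.doc_id}.parses").write_text(write_parses(doc.sentences))
        manifest.append(f"{doc.doc_id}\t{doc.domain}\n")
    (directory / MANIFEST).write_text("".join(manifest))
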