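"""Template-based synthetic corpus generation.

Emits decomposition-compatible documents — text, protein annotations, gold
events, and hand-authored dependency parses that are consistent with the
annotation — across the two domains (abstracts and full papers).  Sentences
are drawn from a family of templates covering the structures the extraction
task exhibits: Simple events, single- and multi-Theme Binding with the
grouping-relevant parse shapes, Regulation events over proteins and over
other events (nesting up to depth three), optional protein Causes, the
"overexpression"-style dual Simple+Regulation annotation that exercises the
event-construction dictionary, and the context-ambiguous bare/modified
"regulation" pattern.  Because parses are authored alongside the gold
events, the optimal policy can reconstruct every gold structure exactly,
which isolates learning behavior from parser noise; a ``parse_noise`` knob
randomly relabels edges to exercise the string-fallback features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .standoff_io import (
    ABSTRACT,
    FULLPAPER,
    DependencyEdge,
    Document,
    Event,
    GoldTrigger,
    ProteinMention,
    Sentence,
    Token,
)

#: Trigger lemma lexicon; with domain-specific vocabulary enabled, the first
#: lemma is shared, the second appears only in abstracts, the third only in
#: full papers.
TRIGGER_LEXICON: dict[str, tuple[str, str, str]] = {
    "Gene_expression": ("expression", "production", "synthesis"),
    "Transcription": ("transcription", "cotranscription", "retranscription"),
    "Protein_catabolism": ("degradation", "proteolysis", "breakdown"),
    "Phosphorylation": ("phosphorylation", "autophosphorylation",
                        "hyperphosphorylation"),
    "Localization": ("localization", "secretion", "translocation"),
    "Binding": ("interaction", "association", "complex"),
    "Regulation": ("regulation", "modulation", "control"),
    "Positive_regulation": ("activation", "induction", "upregulation"),
    "Negative_regulation": ("inhibition", "suppression", "downregulation"),
}

SIMPLE_POOL = ("Gene_expression", "Transcription", "Protein_catabolism",
               "Phosphorylation", "Localization")
REG_POOL = ("Regulation", "Positive_regulation", "Negative_regulation")

#: (lemma, past/participle surface) verb pairs per Regulation type, used by
#: the nested-verb template.
REG_VERBS: dict[str, tuple[tuple[str, str], ...]] = {
    "Regulation": (("modulate", "modulated"),),
    "Positive_regulation": (("induce", "induced"), ("stimulate", "stimulated")),
    "Negative_regulation": (("suppress", "suppressed"), ("inhibit", "inhibited")),
}

#: Template-mix weights inside the non-nested branch.
W_SIMPLE, W_BINDING, W_REGDICT, W_DISTRACTOR = 0.45, 0.35, 0.05, 0.15

_NOISE_LABELS = ("dep", "mod", "rel")

PROT = ("@PROT@", "@PROT@", "NN")  # placeholder filled with PROT<k> at assembly
_DOT = (".", ".", ".")
_OF = ("of", "of", "IN")
_BY = ("by", "by", "IN")


@dataclass(frozen=True)
class GeneratorConfig:
    n_docs: int = 10
    sentences_per_doc: int = 5
    seed: int = 0
    p_nested: float = 0.4
    p_cause: float = 0.3
    p_binding_multi: float = 0.5
    domain_mix: float = 0.25
    domain_specific_vocab: bool = False
    parse_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.n_docs < 1 or self.sentences_per_doc < 1:
            raise ValueError("corpus must contain at least one document/sentence")
        for name in ("p_nested", "p_cause", "p_binding_multi", "domain_mix",
                     "parse_noise"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")


# ---------------------------------------------------------------------------
# Templates: (tokens, edges, event specs).  Event specs are
# (event_type, trigger_token, themes, cause) in bottom-up order; theme/cause
# refs are ("P", token_index) or ("E", earlier_spec_index).
# ---------------------------------------------------------------------------


def _pick(rng: np.random.Generator, seq: Sequence):
    return seq[int(rng.integers(len(seq)))]


def _lemma_for(rng, cfg: GeneratorConfig, domain: str, etype: str) -> str:
    lex = TRIGGER_LEXICON[etype]
    if cfg.domain_specific_vocab:
        pool = (lex[0], lex[1]) if domain == ABSTRACT else (lex[0], lex[2])
    else:
        pool = lex
    return _pick(rng, pool)


def _tpl_simple(rng, cfg, domain):
    stype = _pick(rng, SIMPLE_POOL)
    lemma = _lemma_for(rng, cfg, domain, stype)
    if rng.random() < 0.5:
        tokens = [(lemma, lemma, "NN"), _OF, PROT, _DOT]
        edges = [(0, 2, "prep_of")]
        events = [(stype, 0, [("P", 2)], None)]
    else:
        tokens = [PROT, (lemma, lemma, "NN"), ("was", "be", "VBD"),
                  ("observed", "observe", "VBN"), _DOT]
        edges = [(1, 0, "nn"), (3, 1, "nsubjpass"), (3, 2, "auxpass")]
        events = [(stype, 1, [("P", 0)], None)]
    return tokens, edges, events


def _tpl_reg_over_simple(rng, cfg, domain):
    rtype = _pick(rng, REG_POOL)
    stype = _pick(rng, SIMPLE_POOL)
    rl = _lemma_for(rng, cfg, domain, rtype)
    sl = _lemma_for(rng, cfg, domain, stype)
    tokens = [(rl, rl, "NN"), _OF, PROT, (sl, sl, "NN")]
    edges = [(0, 3, "prep_of"), (3, 2, "nn")]
    cause = None
    if rng.random() < cfg.p_cause:
        tokens += [_BY, PROT]
        edges.append((0, 5, "prep_by"))
        cause = ("P", 5)
    tokens.append(_DOT)
    events = [(stype, 3, [("P", 2)], None), (rtype, 0, [("E", 0)], cause)]
    return tokens, edges, events


def _tpl_reg_over_protein(rng, cfg, domain):
    rtype = _pick(rng, REG_POOL)
    rl = _lemma_for(rng, cfg, domain, rtype)
    tokens = [(rl, rl, "NN"), _OF, PROT]
    edges = [(0, 2, "prep_of")]
    cause = None
    if rng.random() < cfg.p_cause:
        tokens += [_BY, PROT]
        edges.append((0, 4, "prep_by"))
        cause = ("P", 4)
    tokens.append(_DOT)
    events = [(rtype, 0, [("P", 2)], cause)]
    return tokens, edges, events


#: Non-protein causer nouns; annotation-free, so a Cause edge exists exactly
#: when the causer slot holds an annotated protein — gold stays a function of
#: the observable sentence.
_PLAIN_CAUSERS = (("treatment", "treatment", "NN"),
                  ("agonist", "agonist", "NN"),
                  ("stress", "stress", "NN"))


def _tpl_nested_verb(rng, cfg, domain):
    outer_t = _pick(rng, REG_POOL)
    inner_t = _pick(rng, REG_POOL)
    stype = _pick(rng, SIMPLE_POOL)
    o_lemma, o_surf = _pick(rng, REG_VERBS[outer_t])
    i_lemma, i_surf = _pick(rng, REG_VERBS[inner_t])
    sl = _lemma_for(rng, cfg, domain, stype)
    outer_prot = rng.random() < cfg.p_cause
    inner_prot = rng.random() < cfg.p_cause
    subj = PROT if outer_prot else _pick(rng, _PLAIN_CAUSERS)
    mid = PROT if inner_prot else _pick(rng, _PLAIN_CAUSERS)
    tokens = [subj, (o_surf, o_lemma, "VBD"), mid, (i_surf, i_lemma, "VBN"),
              (sl, sl, "NN"), _OF, PROT, _DOT]
    edges = [(1, 0, "nsubj"), (1, 4, "dobj"), (4, 3, "amod"), (3, 2, "nn"),
             (4, 6, "prep_of")]
    events = [
        (stype, 4, [("P", 6)], None),
        (inner_t, 3, [("E", 0)], ("P", 2) if inner_prot else None),
        (outer_t, 1, [("E", 1)], ("P", 0) if outer_prot else None),
    ]
    return tokens, edges, events


def _tpl_ambig_regulation(rng, cfg, domain):
    stype = _pick(rng, SIMPLE_POOL)
    sl = _lemma_for(rng, cfg, domain, stype)
    mod = _pick(rng, (None, "positive", "negative"))
    if mod is None:
        tokens = [("regulation", "regulation", "NN"), _OF, PROT,
                  (sl, sl, "NN"), _DOT]
        edges = [(0, 3, "prep_of"), (3, 2, "nn")]
        rtype, rtok = "Regulation", 0
        events = [(stype, 3, [("P", 2)], None), (rtype, rtok, [("E", 0)], None)]
    else:
        rtype = ("Positive_regulation" if mod == "positive"
                 else "Negative_regulation")
        tokens = [(mod, mod, "JJ"), ("regulation", "regulation", "NN"), _OF,
                  PROT, (sl, sl, "NN"), _DOT]
        edges = [(1, 0, "amod"), (1, 4, "prep_of"), (4, 3, "nn")]
        events = [(stype, 4, [("P", 3)], None), (rtype, 1, [("E", 0)], None)]
    return tokens, edges, events


def _tpl_binding_multi(rng, cfg, domain):
    bl = _lemma_for(rng, cfg, domain, "Binding")
    tokens = [(bl, bl, "NNS"), _OF, PROT, ("and", "and", "CC"), PROT,
              ("with", "with", "IN"), PROT, _DOT]
    edges = [(0, 2, "prep_of"), (0, 4, "prep_of"), (2, 4, "conj_and"),
             (0, 6, "prep_with")]
    events = [
        ("Binding", 0, [("P", 2), ("P", 6)], None),
        ("Binding", 0, [("P", 4), ("P", 6)], None),
    ]
    return tokens, edges, events


def _tpl_binding_single(rng, cfg, domain):
    if rng.random() < 0.5:
        bl = _lemma_for(rng, cfg, domain, "Binding")
        tokens = [(bl, bl, "NN"), _OF, PROT, _DOT]
        edges = [(0, 2, "prep_of")]
        events = [("Binding", 0, [("P", 2)], None)]
    else:
        tokens = [PROT, ("binds", "bind", "VBZ"), PROT, _DOT]
        edges = [(1, 0, "nsubj"), (1, 2, "dobj")]
        events = [("Binding", 1, [("P", 0), ("P", 2)], None)]
    return tokens, edges, events


def _tpl_regdict(rng, cfg, domain):
    tokens = [("overexpression", "overexpression", "NN"), _OF, PROT, _DOT]
    edges = [(0, 2, "prep_of")]
    events = [
        ("Gene_expression", 0, [("P", 2)], None),
        ("Positive_regulation", 0, [("E", 0)], None),
    ]
    return tokens, edges, events


def _tpl_distractor(rng, cfg, domain):
    tokens = [PROT, ("was", "be", "VBD"), ("detected", "detect", "VBN"),
              ("in", "in", "IN"), ("cells", "cell", "NNS"), _DOT]
    edges = [(2, 0, "nsubjpass"), (2, 1, "auxpass"), (2, 4, "prep_in")]
    return tokens, edges, []


_NESTED_TEMPLATES = (_tpl_reg_over_simple, _tpl_reg_over_protein,
                     _tpl_nested_verb, _tpl_ambig_regulation)


def _sample_template(rng, cfg: GeneratorConfig, domain: str):
    if rng.random() < cfg.p_nested:
        return _pick(rng, _NESTED_TEMPLATES)(rng, cfg, domain)
    r = rng.random()
    if r < W_SIMPLE:
        return _tpl_simple(rng, cfg, domain)
    if r < W_SIMPLE + W_BINDING:
        if rng.random() < cfg.p_binding_multi:
            return _tpl_binding_multi(rng, cfg, domain)
        return _tpl_binding_single(rng, cfg, domain)
    if r < W_SIMPLE + W_BINDING + W_REGDICT:
        return _tpl_regdict(rng, cfg, domain)
    return _tpl_distractor(rng, cfg, domain)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def _assemble_document(doc_id: str, domain: str, raw_sentences, rng,
                       cfg: GeneratorConfig) -> Document:
    text_parts: list[str] = []
    offset = 0
    prot_count = 0
    staged = []  # (tokens, edges, mentions, specs)
    for tokens_spec, edge_spec, event_spec in raw_sentences:
        tokens: list[Token] = []
        mentions: list[tuple[int, str]] = []  # (token index, ann id)
        for i, (surface, lemma, pos) in enumerate(tokens_spec):
            if surface == PROT[0]:
                prot_count += 1
                surface = f"PROT{prot_count}"
                lemma = surface.lower()
                mentions.append((i, f"T{prot_count}"))
            start = offset
            end = start + len(surface)
            tokens.append(Token(i, surface, lemma, pos, start, end))
            text_parts.append(surface)
            offset = end + 1  # single space between tokens and sentences
        edges = []
        for h, d, label in edge_spec:
            if cfg.parse_noise > 0 and rng.random() < cfg.parse_noise:
                label = _pick(rng, _NOISE_LABELS)
            edges.append(DependencyEdge(h, d, label))
        staged.append((tokens, edges, mentions, event_spec))

    text = " ".join(text_parts)
    sentences: list[Sentence] = []
    trig_counter = prot_count
    ev_counter = 0
    for si, (tokens, edges, mentions, specs) in enumerate(staged):
        proteins = [
            ProteinMention(ann_id, tokens[i].char_start, tokens[i].char_end,
                           head_token=i)
            for i, ann_id in mentions
        ]
        prot_by_tok = {p.head_token: p for p in proteins}
        triggers: dict[tuple[int, str], GoldTrigger] = {}
        events: list[Event] = []
        for etype, tok, theme_refs, cause_ref in specs:
            if (tok, etype) not in triggers:
                trig_counter += 1
                t = tokens[tok]
                triggers[(tok, etype)] = GoldTrigger(
                    f"T{trig_counter}", etype, t.char_start, t.char_end,
                    head_token=tok,
                )

            def resolve(ref):
                if ref[0] == "P":
                    return prot_by_tok[ref[1]]
                return events[ref[1]]

            ev_counter += 1
            events.append(
                Event(
                    f"E{ev_counter}",
                    triggers[(tok, etype)],
                    tuple(resolve(r) for r in theme_refs),
                    resolve(cause_ref) if cause_ref is not None else None,
                )
            )
        sentences.append(
            Sentence(
                index=si,
                char_start=tokens[0].char_start,
                char_end=tokens[-1].char_end,
                tokens=tuple(tokens),
                edges=tuple(edges),
                proteins=proteins,
                triggers=list(triggers.values()),
                events=events,
                domain=domain,
                doc_id=doc_id,
            )
        )
    return Document(doc_id=doc_id, text=text, domain=domain,
                    sentences=sentences)


def generate_corpus(cfg: GeneratorConfig) -> list[Document]:
    """Generate a deterministic synthetic corpus (same cfg => same corpus)."""
    docs = []
    for di in range(cfg.n_docs):
        rng = np.random.default_rng([cfg.seed, di])
        domain = FULLPAPER if rng.random() < cfg.domain_mix else ABSTRACT
        raw = [
            _sample_template(rng, cfg, domain)
            for _ in range(cfg.sentences_per_doc)
        ]
        docs.append(_assemble_document(f"SYN{di:04d}", domain, raw, rng, cfg))
    return docs


def generate_sentences(cfg: GeneratorConfig) -> list[Sentence]:
    """Convenience: the corpus flattened to sentences."""
    return [s for doc in generate_corpus(cfg) for s in doc.sentences]
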