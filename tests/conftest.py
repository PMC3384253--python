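"""Shared fixtures: hand-built sentences and small synthetic corpora."""

from __future__ import annotations

import pytest

from eventsearn.standoff_io import (
    DependencyEdge,
    Document,
    ProteinMention,
    Sentence,
    Token,
)
from eventsearn.synthetic_corpus import GeneratorConfig, generate_corpus
from eventsearn.worked_example import demo_document


def make_sentence(rows, edges, proteins=(), doc_id="TST0001"):
    """Build a sentence from (surface, lemma, pos) rows and (h, d, label)
    edges; protein spec is (token_index, ann_id)."""
    tokens = []
    offset = 0
    for i, (surface, lemma, pos) in enumerate(rows):
        tokens.append(Token(i, surface, lemma, pos, offset, offset + len(surface)))
        offset += len(surface) + 1
    sent = Sentence(
        index=0,
        char_start=0,
        char_end=tokens[-1].char_end,
        tokens=tuple(tokens),
        edges=tuple(DependencyEdge(*e) for e in edges),
        doc_id=doc_id,
    )
    for tok_idx, ann_id in proteins:
        t = tokens[tok_idx]
        sent.proteins.append(
            ProteinMention(ann_id, t.char_start, t.char_end, head_token=tok_idx)
        )
    return sent


@pytest.fixture
def demo_doc() -> Document:
    """The nested-events demonstration document."""
    return demo_document()


@pytest.fixture
def demo_sentence(demo_doc):
    return demo_doc.sentences[0]


@pytest.fixture(scope="session")
def small_corpus():
    """100 synthetic sentences at generator defaults."""
    return generate_corpus(GeneratorConfig(n_docs=20, sentences_per_doc=5, seed=42))


@pytest.fixture
def binding_sentence():
    """'interactions of A and B with C' with the grouping-relevant parse."""
    rows = [
        ("interactions", "interaction", "NNS"),
        ("of", "of", "IN"),
        ("A", "a", "NN"),
        ("and", "and", "CC"),
        ("B", "b", "NN"),
        ("with", "with", "IN"),
        ("C", "c", "NN"),
        (".", ".", "."),
    ]
    edges = [
        (0, 2, "prep_of"),
        (0, 4, "prep_of"),
        (2, 4, "conj_and"),
        (0, 6, "prep_with"),
    ]
    return make_sentence(rows, edges,
                         proteins=[(2, "T1"), (4, "T2"), (6, "T3")])
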