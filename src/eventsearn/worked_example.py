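"""A canonical demonstration sentence with nested events, plus the
cost-estimation scenarios it supports.

The sentence "SQ 22536 suppressed gp41-induced IL-10 production in
monocytes." carries three nested gold events:

    E3: Gene_expression(production, Theme=IL-10)
    E2: Positive_regulation(induced, Theme=E3, Cause=gp41)
    E1: Negative_regulation(suppressed, Theme=E2)

Two costing scenarios probe how focused cost estimation informs the learner
about downstream consequences of trigger decisions once rollouts are made by
a hypothesis that replicates the sentence's argument structure:

* labeling the non-trigger token "SQ" as Negative_regulation, with the
  rollout attaching one protein Theme to it while everything else stays
  gold, creates one spurious event -> cost 1;
* labeling "production" as Negative_regulation, with the rollout attaching
  IL-10 as its Theme and completing the nested structure on top of it,
  corrupts all three events -> 3 false positives + 3 false negatives,
  cost 6.
"""

from __future__ import annotations

from .searn_engine import (
    GoldGraphPolicy,
    SearnConfig,
    SentenceState,
    apply_action,
    estimate_action_costs,
)
from .linguistic_graph import trigger_candidates
from .standoff_io import (
    ABSTRACT,
    DependencyEdge,
    Document,
    Event,
    GoldTrigger,
    ProteinMention,
    Sentence,
    Token,
)
from .state import decompose

_TEXT = "SQ 22536 suppressed gp41-induced IL-10 production in monocytes."

_TOKENS = (
    # index, surface, lemma, pos, start, end
    (0, "SQ", "sq", "NN", 0, 2),
    (1, "22536", "22536", "CD", 3, 8),
    (2, "suppressed", "suppress", "VBD", 9, 19),
    (3, "gp41", "gp41", "NN", 20, 24),
    (4, "induced", "induce", "VBN", 25, 32),
    (5, "IL-10", "il-10", "NN", 33, 38),
    (6, "production", "production", "NN", 39, 49),
    (7, "in", "in", "IN", 50, 52),
    (8, "monocytes", "monocyte", "NNS", 53, 62),
    (9, ".", ".", ".", 62, 63),
)

_EDGES = (
    (1, 0, "nn"),        # 22536 <- SQ
    (2, 1, "nsubj"),     # suppressed <- 22536
    (2, 6, "dobj"),      # suppressed -> production
    (6, 4, "amod"),      # production -> induced
    (4, 3, "nn"),        # induced -> gp41
    (6, 5, "nn"),        # production -> IL-10
    (2, 8, "prep_in"),   # suppressed -> monocytes
)


def demo_document() -> Document:
    """The demonstration sentence as a fully annotated document."""
    tokens = tuple(Token(*row) for row in _TOKENS)
    edges = tuple(DependencyEdge(*row) for row in _EDGES)
    gp41 = ProteinMention("T1", 20, 24, head_token=3)
    il10 = ProteinMention("T2", 33, 38, head_token=5)
    t_sup = GoldTrigger("T3", "Negative_regulation", 9, 19, head_token=2)
    t_ind = GoldTrigger("T4", "Positive_regulation", 25, 32, head_token=4)
    t_prod = GoldTrigger("T5", "Gene_expression", 39, 49, head_token=6)
    e3 = Event("E3", t_prod, (il10,))
    e2 = Event("E2", t_ind, (e3,), cause=gp41)
    e1 = Event("E1", t_sup, (e2,))
    sentence = Sentence(
        index=0,
        char_start=0,
        char_end=63,
        tokens=tokens,
        edges=edges,
        proteins=[gp41, il10],
        triggers=[t_sup, t_ind, t_prod],
        events=[e1, e2, e3],
        domain=ABSTRACT,
        doc_id="DEMO0001",
    )
    return Document("DEMO0001", _TEXT, ABSTRACT, [sentence])


def _gold_prefix_until(sentence, gold, stop_token: int) -> SentenceState:
    """Trigger-stage prefix: gold labels for every candidate before a token."""
    state = SentenceState()
    for tok in trigger_candidates(sentence):
        if tok == stop_token:
            break
        apply_action(sentence, state, "trigger", tok,
                     gold.trigger_labels.get(tok, "No_trigger"))
    return state


def demo_trigger_costs(focused: bool = True) -> dict[str, float]:
    """Focused-costing estimates for the two scripted trigger scenarios.

    Returns the cost of labeling "production" resp. "SQ" as
    Negative_regulation under structure-faithful rollouts.
    """
    doc = demo_document()
    sentence = doc.sentences[0]
    gold = decompose(sentence)
    cfg = SearnConfig(focused=focused)

    # "production" (token 6) mislabeled; the rollout keeps the gold argument
    # graph, so the wrong type propagates through both nesting levels.
    prefix = _gold_prefix_until(sentence, gold, 6)
    labels, costs = estimate_action_costs(
        sentence, gold, prefix, "trigger", 6,
        lambda li, s: GoldGraphPolicy(gold), cfg,
    )
    production_cost = costs[labels.index("Negative_regulation")]

    # "SQ" (token 0) labeled as a trigger; the rollout attaches gp41 as its
    # Theme only under that label and otherwise reproduces gold.
    prefix = _gold_prefix_until(sentence, gold, 0)
    labels, costs = estimate_action_costs(
        sentence, gold, prefix, "trigger", 0,
        lambda li, s: GoldGraphPolicy(
            gold,
            conditional_themes={(0, ("prot", "T1")): "Negative_regulation"},
        ),
        cfg,
    )
    sq_cost = costs[labels.index("Negative_regulation")]
    return {
        "production_as_negative_regulation": production_cost,
        "sq_as_negative_regulation": sq_cost,
    }
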