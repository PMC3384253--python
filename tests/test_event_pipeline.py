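"""Event construction rules, regulation dictionary, independent baseline."""

from eventsearn.csc_pa_learner import PAConfig, train_csc
from eventsearn.event_pipeline import (
    build_regulation_dictionary,
    construct_event_signatures,
    construct_events,
    predict_document,
    predict_signatures,
    train_independent,
)
from eventsearn.feature_extraction import theme_features, trigger_features
from eventsearn.linguistic_graph import (
    build_cause_agenda,
    build_theme_agenda,
    order_actions,
    trigger_candidates,
)
from eventsearn.searn_engine import (
    STAGE_LABELS,
    OptimalPolicy,
    continue_policy,
)
from eventsearn.standoff_io import parse_a2
from eventsearn.state import SentenceState, decompose, sentence_gold_signatures
from eventsearn.synthetic_corpus import GeneratorConfig, generate_corpus

from conftest import make_sentence


class TestBindingConstruction:
    def test_grouped_cross_product(self, binding_sentence):
        """'interactions of A and B with C' -> two Binding events with two
        Themes each (A+C and B+C)."""
        state = SentenceState(trigger_labels={0: "Binding"})
        for pid in ("T1", "T2", "T3"):
            state.add_theme(0, ("prot", pid))
        sigs = construct_event_signatures(binding_sentence, state)
        assert sigs == {
            (0, "Binding", frozenset({("P", "T1"), ("P", "T3")}), None),
            (0, "Binding", frozenset({("P", "T2"), ("P", "T3")}), None),
        }

    def test_cross_product_size_matches_group_enumeration(self, binding_sentence):
        """Number of constructed events equals the product of group sizes."""
        state = SentenceState(trigger_labels={0: "Binding"})
        state.add_theme(0, ("prot", "T1"))
        state.add_theme(0, ("prot", "T2"))
        sigs = construct_event_signatures(binding_sentence, state)
        # one group (both prep_of) -> 2 single-theme events
        assert len(sigs) == 2
        assert all(len(s[2]) == 1 for s in sigs)

    def test_same_token_themes_collapse_to_one_event(self):
        # "PROT1/PROT2 interactions": both mentions head at token 0
        sent = make_sentence(
            [("PROT1/PROT2", "prot1/prot2", "NN"),
             ("interactions", "interaction", "NNS")],
            [(1, 0, "nn")],
        )
        from eventsearn.standoff_io import ProteinMention
        sent.proteins.extend([
            ProteinMention("T1", 0, 5, head_token=0),
            ProteinMention("T2", 6, 11, head_token=0),
        ])
        state = SentenceState(trigger_labels={1: "Binding"})
        state.add_theme(1, ("prot", "T1"))
        state.add_theme(1, ("prot", "T2"))
        sigs = construct_event_signatures(sent, state)
        assert sigs == {
            (1, "Binding", frozenset({("P", "T1"), ("P", "T2")}), None)
        }

    def test_bind_lemma_collapses_to_one_event(self):
        sent = make_sentence(
            [("PROT1", "prot1", "NN"), ("binds", "bind", "VBZ"),
             ("PROT2", "prot2", "NN")],
            [(1, 0, "nsubj"), (1, 2, "dobj")],
            proteins=[(0, "T1"), (2, "T2")],
        )
        state = SentenceState(trigger_labels={1: "Binding"})
        state.add_theme(1, ("prot", "T1"))
        state.add_theme(1, ("prot", "T2"))
        sigs = construct_event_signatures(sent, state)
        assert sigs == {
            (1, "Binding", frozenset({("P", "T1"), ("P", "T2")}), None)
        }


class TestConstructionBasics:
    def test_trigger_without_theme_produces_no_event(self, binding_sentence):
        state = SentenceState(trigger_labels={0: "Binding"})
        assert construct_event_signatures(binding_sentence, state) == set()

    def test_gold_decomposition_reconstructs_gold(self, small_corpus):
        regdict = build_regulation_dictionary(small_corpus)
        for doc in small_corpus:
            for s in doc.sentences:
                gold = decompose(s)
                state = continue_policy(s, SentenceState(), OptimalPolicy(gold))
                assert construct_event_signatures(s, state, regdict) == \
                    set(gold.event_signatures)

    def test_demo_decomposition_builds_three_nested_events(self, demo_sentence):
        gold = decompose(demo_sentence)
        state = continue_policy(demo_sentence, SentenceState(),
                                OptimalPolicy(gold))
        events = construct_events(demo_sentence, state)
        assert len(events) == 3


class TestRegulationDictionary:
    def test_dual_annotation_creates_entry(self):
        docs = generate_corpus(
            GeneratorConfig(n_docs=30, sentences_per_doc=5, seed=1)
        )
        regdict = build_regulation_dictionary(docs)
        assert regdict.get("overexpression") == "Positive_regulation"

    def test_corpus_without_dual_annotation_gives_empty_dictionary(self):
        docs = generate_corpus(
            GeneratorConfig(n_docs=5, sentences_per_doc=5, seed=1,
                            p_nested=1.0)  # nested branch has no dict pattern
        )
        assert build_regulation_dictionary(docs) == {}

    def test_tie_broken_lexicographically(self):
        from eventsearn.standoff_io import (
            Document, Event, GoldTrigger, ProteinMention,
        )

        def doc(doc_id, rtype):
            sent = make_sentence(
                [("overexpress", "overexpress", "NN"), ("of", "of", "IN"),
                 ("PROT1", "prot1", "NN")],
                [(0, 2, "prep_of")],
                proteins=[(2, "T1")],
                doc_id=doc_id,
            )
            t1 = GoldTrigger("T2", "Gene_expression", 0, 11, head_token=0)
            t2 = GoldTrigger("T3", rtype, 0, 11, head_token=0)
            inner = Event("E1", t1, (sent.proteins[0],))
            outer = Event("E2", t2, (inner,))
            sent.triggers = [t1, t2]
            sent.events = [inner, outer]
            text = "overexpress of PROT1"
            return Document(doc_id, text, "abstract", [sent])

        docs = [doc("D1", "Positive_regulation"), doc("D2", "Negative_regulation")]
        regdict = build_regulation_dictionary(docs)
        assert regdict["overexpress"] == "Negative_regulation"


class TestIndependentBaseline:
    def test_single_hypothesis_with_degenerate_config(self, small_corpus):
        model = train_independent(small_corpus[:5], PAConfig(C=1.0, R=2, seed=0))
        assert len(model.hypotheses) == 1
        assert model.weights == [1.0]
        assert model.config.zero_one_costs
        assert not model.config.structural

    def test_matches_directly_coded_pipeline(self, small_corpus):
        """On a 20-sentence fixture, train_independent equals a straight
        supervised pipeline coded here from the stage primitives: 0/1-cost
        examples off the gold decomposition, one PA classifier per stage,
        greedy agenda-driven decoding."""
        corpus = small_corpus[:4]  # 20 sentences
        pa = PAConfig(C=1.0, R=5, seed=0)
        model = train_independent(corpus, pa, seed=0)

        # -- oracle training ------------------------------------------------
        from eventsearn.csc_pa_learner import CSCExample
        from eventsearn.feature_extraction import cause_features
        from eventsearn.searn_engine import _stage_seed

        examples = {"trigger": [], "theme": [], "cause": []}
        for doc in corpus:
            for s in doc.sentences:
                gold = decompose(s)
                state = SentenceState()
                for tok in trigger_candidates(s):
                    lab = gold.trigger_labels.get(tok, "No_trigger")
                    fv = trigger_features(s, tok, state, structural=False)
                    costs = [0.0 if L == lab else 1.0
                             for L in STAGE_LABELS["trigger"]]
                    examples["trigger"].append(CSCExample(fv, costs))
                    state.trigger_labels[tok] = lab

                def gold_theme_ok(arg):
                    if arg[0] == "prot":
                        return True
                    return frozenset(state.themes_of(arg[1])) == \
                        gold.themes_by_trigger.get(arg[1], frozenset())

                while True:
                    pend = [p for p in build_theme_agenda(s, state)
                            if p.key not in state.decided_theme]
                    if not pend:
                        break
                    p = order_actions(pend)[0]
                    lab = ("Theme" if p.key in gold.theme_edges
                           and gold_theme_ok(p.argument) else "No_Theme")
                    fv = theme_features(s, p, state, structural=False)
                    costs = [0.0 if L == lab else 1.0
                             for L in STAGE_LABELS["theme"]]
                    examples["theme"].append(CSCExample(fv, costs))
                    state.decided_theme.add(p.key)
                    if lab == "Theme":
                        state.add_theme(p.trigger, p.argument)
                while True:
                    pend = [p for p in build_cause_agenda(s, state)
                            if p.key not in state.decided_cause]
                    if not pend:
                        break
                    p = order_actions(pend)[0]
                    lab = ("Cause" if p.key in gold.cause_edges
                           and gold_theme_ok(p.argument) else "No_Cause")
                    fv = cause_features(s, p, state, structural=False)
                    costs = [0.0 if L == lab else 1.0
                             for L in STAGE_LABELS["cause"]]
                    examples["cause"].append(CSCExample(fv, costs))
                    state.decided_cause.add(p.key)
                    if lab == "Cause":
                        state.add_cause(p.trigger, p.argument)

        clfs = {
            st: train_csc(examples[st],
                          PAConfig(C=1.0, R=5, seed=_stage_seed(0, 1, st)),
                          labels=STAGE_LABELS[st])
            for st in examples
        }

        # -- oracle decoding and comparison --------------------------------
        regdict = build_regulation_dictionary(corpus)
        for doc in corpus:
            got = predict_signatures(doc, model)
            for s, model_sigs in zip(doc.sentences, got):
                state = SentenceState()
                for tok in trigger_candidates(s):
                    fv = trigger_features(s, tok, state, structural=False)
                    state.trigger_labels[tok] = \
                        STAGE_LABELS["trigger"][clfs["trigger"].predict(fv)]
                while True:
                    pend = [p for p in build_theme_agenda(s, state)
                            if p.key not in state.decided_theme]
                    if not pend:
                        break
                    p = order_actions(pend)[0]
                    fv = theme_features(s, p, state, structural=False)
                    lab = STAGE_LABELS["theme"][clfs["theme"].predict(fv)]
                    state.decided_theme.add(p.key)
                    if lab == "Theme":
                        state.add_theme(p.trigger, p.argument)
                while True:
                    pend = [p for p in build_cause_agenda(s, state)
                            if p.key not in state.decided_cause]
                    if not pend:
                        break
                    p = order_actions(pend)[0]
                    from eventsearn.feature_extraction import cause_features
                    fv = cause_features(s, p, state, structural=False)
                    lab = STAGE_LABELS["cause"][clfs["cause"].predict(fv)]
                    state.decided_cause.add(p.key)
                    if lab == "Cause":
                        state.add_cause(p.trigger, p.argument)
                oracle_sigs = construct_event_signatures(s, state, regdict)
                assert oracle_sigs == model_sigs


class TestPredictDocument:
    def test_no_proteins_means_no_events(self, small_corpus):
        from eventsearn.standoff_io import Document
        model = train_independent(small_corpus[:5], PAConfig(C=1.0, R=2, seed=0))
        doc = small_corpus[5]
        stripped = Document(doc.doc_id, doc.text, doc.domain, doc.sentences)
        saved = [(s.proteins, s.events, s.triggers) for s in doc.sentences]
        try:
            for s in doc.sentences:
                s.proteins, s.events, s.triggers = [], [], []
                s._cache.clear()
            sigs = predict_signatures(stripped, model)
            assert all(not s for s in sigs)
        finally:
            for s, (p, e, t) in zip(doc.sentences, saved):
                s.proteins, s.events, s.triggers = p, e, t
                s._cache.clear()

    def test_output_is_deterministic_and_valid_a2(self, small_corpus):
        model = train_independent(small_corpus[:8], PAConfig(C=1.0, R=3, seed=0))
        doc = small_corpus[2]
        a2_1 = predict_document(doc, model)
        a2_2 = predict_document(doc, model)
        assert a2_1 == a2_2
        proteins = [p for s in doc.sentences for p in s.proteins]
        triggers, events = parse_a2(a2_1, proteins, doc.text)
        assert isinstance(events, list)

    def test_gold_oracle_policy_reproduces_gold_events(self, small_corpus):
        regdict = build_regulation_dictionary(small_corpus)
        doc = small_corpus[0]
        for s in doc.sentences:
            gold = decompose(s)
            state = continue_policy(s, SentenceState(), OptimalPolicy(gold))
            assert construct_event_signatures(s, state, regdict) == \
                sentence_gold_signatures(s)
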