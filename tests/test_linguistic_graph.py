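"""Dependency paths, head reduction, agendas, ordering, cycle checks."""

import itertools

import numpy as np
import pytest

from eventsearn.linguistic_graph import (
    CandidatePair,
    build_cause_agenda,
    build_theme_agenda,
    creates_directed_cycle,
    order_actions,
    reduce_trigger_to_head,
    shortest_path,
    trigger_candidates,
)
from eventsearn.standoff_io import GoldTrigger, IntegrityError
from eventsearn.state import SentenceState

from conftest import make_sentence


# ---------------------------------------------------------------------------
# Head reduction
# ---------------------------------------------------------------------------


class TestHeadReduction:
    def test_single_token_trigger_unchanged(self):
        sent = make_sentence(
            [("binding", "binding", "NN"), ("activity", "activity", "NN")],
            [(1, 0, "nn")],
        )
        trig = GoldTrigger("T1", "Binding", 0, 7)
        out = reduce_trigger_to_head(trig, sent)
        assert (out.char_start, out.char_end, out.head_token) == (0, 7, 0)
        # idempotent
        assert reduce_trigger_to_head(out, sent) == out

    def test_multi_token_trigger_reduces_to_syntactic_head(self):
        # "binding activity": activity heads binding, span covers both
        sent = make_sentence(
            [("the", "the", "DT"), ("binding", "binding", "NN"),
             ("activity", "activity", "NN"), ("increased", "increase", "VBD")],
            [(2, 1, "nn"), (3, 2, "nsubj")],
        )
        trig = GoldTrigger("T1", "Binding", 4, 20)  # "binding activity"
        out = reduce_trigger_to_head(trig, sent)
        assert out.head_token == 2
        assert sent.tokens[2].surface == "activity"

    def test_span_overlapping_no_token_is_error(self):
        sent = make_sentence([("a", "a", "NN")], [])
        with pytest.raises(IntegrityError):
            reduce_trigger_to_head(GoldTrigger("T1", "Binding", 50, 60), sent)


# ---------------------------------------------------------------------------
# Shortest paths
# ---------------------------------------------------------------------------


def _brute_force_paths(n, edges, a, b):
    """All simple paths a->b over the undirected view, as step strings."""
    adj = {}
    for h, d, label in edges:
        adj.setdefault(h, []).append((d, f"down:{label}"))
        adj.setdefault(d, []).append((h, f"up:{label}"))
    results = []

    def walk(u, visited, steps):
        if u == b:
            results.append(tuple(steps))
            return
        for v, s in adj.get(u, ()):
            if v not in visited:
                walk(v, visited | {v}, steps + [s])

    walk(a, {a}, [])
    return results


class TestShortestPath:
    def test_single_edge(self):
        sent = make_sentence(
            [("binds", "bind", "VBZ"), ("B", "b", "NN")], [(0, 1, "dobj")]
        )
        path = shortest_path(sent, 0, 1)
        assert path.edges == (("dobj", "down"),)
        assert path.length == 1
        assert (path.first_lemma, path.last_lemma) == ("bind", "b")

    def test_disconnected_returns_none(self):
        sent = make_sentence([("a", "a", "NN"), ("b", "b", "NN")], [])
        assert shortest_path(sent, 0, 1) is None

    def test_same_endpoint_rejected(self):
        sent = make_sentence([("a", "a", "NN"), ("b", "b", "NN")], [])
        with pytest.raises(ValueError):
            shortest_path(sent, 1, 1)

    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        """Dijkstra equals the brute-force shortest-simple-path oracle,
        including the lexicographic tie-break, over many graphs <= 8 nodes."""
        rng = np.random.default_rng(123)
        labels = ["dobj", "nsubj", "prep_of", "conj_and", "amod"]
        for _ in range(40):
            n = int(rng.integers(3, 9))
            m = int(rng.integers(1, n * 2))
            edges = []
            for _ in range(m):
                h, d = rng.integers(n), rng.integers(n)
                if h != d:
                    edges.append((int(h), int(d), labels[int(rng.integers(5))]))
            rows = [(f"w{i}", f"w{i}", "NN") for i in range(n)]
            sent = make_sentence(rows, edges)
            for a, b in itertools.permutations(range(n), 2):
                expected = _brute_force_paths(n, edges, a, b)
                got = shortest_path(sent, a, b)
                if not expected:
                    assert got is None
                    continue
                best_len = min(len(p) for p in expected)
                best = min(p for p in expected if len(p) == best_len)
                got_steps = tuple(f"{d}:{l}" for l, d in got.edges)
                assert len(got.edges) == best_len
                assert got_steps == best


# ---------------------------------------------------------------------------
# Agendas
# ---------------------------------------------------------------------------


def _reg_sentence():
    # "inhibition of PROT1 expression ." with PROT2 also present
    rows = [
        ("inhibition", "inhibition", "NN"), ("of", "of", "IN"),
        ("PROT1", "prot1", "NN"), ("expression", "expression", "NN"),
        ("near", "near", "IN"), ("PROT2", "prot2", "NN"), (".", ".", "."),
    ]
    edges = [(0, 3, "prep_of"), (3, 2, "nn"), (0, 5, "prep_near")]
    return make_sentence(rows, edges, proteins=[(2, "T1"), (5, "T2")])


class TestThemeAgenda:
    def test_initial_agenda_is_trigger_protein_cross_product(self):
        sent = _reg_sentence()
        state = SentenceState(trigger_labels={3: "Gene_expression"})
        agenda = build_theme_agenda(sent, state)
        assert [(p.trigger, p.argument) for p in agenda] == [
            (3, ("prot", "T1")), (3, ("prot", "T2")),
        ]

    def test_themed_trigger_spawns_regulation_pairs(self):
        sent = _reg_sentence()
        state = SentenceState(
            trigger_labels={0: "Negative_regulation", 3: "Gene_expression"}
        )
        state.add_theme(3, ("prot", "T1"))
        agenda = build_theme_agenda(sent, state)
        assert (0, ("trig", 3)) in [p.key for p in agenda]
        # non-Regulation triggers spawn no event-argument pairs
        assert all(p.argument != ("trig", 0) for p in agenda)

    def test_cycle_closing_pair_excluded(self):
        sent = _reg_sentence()
        state = SentenceState(
            trigger_labels={0: "Negative_regulation", 3: "Regulation"}
        )
        state.add_theme(0, ("trig", 3))
        state.add_theme(3, ("prot", "T1"))
        agenda = build_theme_agenda(sent, state)
        assert (3, ("trig", 0)) not in [p.key for p in agenda]

    def test_agenda_never_offers_cycle_creating_pair(self):
        sent = _reg_sentence()
        state = SentenceState(
            trigger_labels={0: "Regulation", 3: "Regulation"}
        )
        state.add_theme(0, ("trig", 3))
        state.add_theme(3, ("prot", "T1"))
        for p in build_theme_agenda(sent, state):
            assert not creates_directed_cycle(state, p.key)


class TestCauseAgenda:
    def test_regulation_trigger_with_theme_gets_all_arguments(self):
        sent = _reg_sentence()
        state = SentenceState(
            trigger_labels={0: "Negative_regulation", 3: "Gene_expression"}
        )
        state.add_theme(3, ("prot", "T1"))
        state.add_theme(0, ("trig", 3))
        agenda = build_cause_agenda(sent, state)
        # proteins T1, T2 plus the other themed trigger 3
        assert [(p.trigger, p.argument) for p in agenda] == [
            (0, ("prot", "T1")), (0, ("prot", "T2")), (0, ("trig", 3)),
        ]

    def test_simple_trigger_contributes_no_cause_pairs(self):
        sent = _reg_sentence()
        state = SentenceState(trigger_labels={3: "Gene_expression"})
        state.add_theme(3, ("prot", "T1"))
        assert build_cause_agenda(sent, state) == []

    def test_regulation_trigger_without_theme_contributes_no_pairs(self):
        sent = _reg_sentence()
        state = SentenceState(trigger_labels={0: "Negative_regulation"})
        assert build_cause_agenda(sent, state) == []


# ---------------------------------------------------------------------------
# Action ordering and cycles
# ---------------------------------------------------------------------------


def _pair(length, rank):
    path = None
    if length is not None:
        from eventsearn.linguistic_graph import DependencyPath
        path = DependencyPath(tuple(("dobj", "down") for _ in range(length)),
                              "a", "b")
    return CandidatePair(0, ("prot", f"T{rank}"), "theme", path, rank)


class TestOrderActions:
    def test_sorted_by_increasing_path_length(self):
        pairs = [_pair(3, 0), _pair(1, 1), _pair(2, 2)]
        assert [p.path.length for p in order_actions(pairs)] == [1, 2, 3]

    def test_equal_lengths_keep_insertion_order(self):
        pairs = [_pair(2, 0), _pair(2, 1), _pair(2, 2)]
        assert [p.insertion_rank for p in order_actions(pairs)] == [0, 1, 2]

    def test_pathless_pairs_sort_last(self):
        pairs = [_pair(None, 0), _pair(5, 1)]
        assert [p.insertion_rank for p in order_actions(pairs)] == [1, 0]

    def test_is_a_permutation(self):
        pairs = [_pair(2, 0), _pair(None, 1), _pair(1, 2), _pair(2, 3)]
        out = order_actions(pairs)
        assert sorted(p.insertion_rank for p in out) == [0, 1, 2, 3]


class TestDirectedCycles:
    def test_empty_state_never_cycles(self):
        assert not creates_directed_cycle(SentenceState(), (1, ("trig", 2)))

    def test_two_cycle(self):
        state = SentenceState()
        state.add_theme(1, ("trig", 2))
        assert creates_directed_cycle(state, (2, ("trig", 1)))

    def test_chain_closure_matches_reachability_oracle(self):
        state = SentenceState()
        state.add_theme(1, ("trig", 2))
        state.add_theme(2, ("trig", 3))
        assert creates_directed_cycle(state, (3, ("trig", 1)))
        assert not creates_directed_cycle(state, (1, ("trig", 3)))

    def test_cause_edges_participate(self):
        state = SentenceState()
        state.add_cause(1, ("trig", 2))
        assert creates_directed_cycle(state, (2, ("trig", 1)))

    def test_protein_argument_never_cycles(self):
        state = SentenceState()
        state.add_theme(1, ("prot", "T1"))
        assert not creates_directed_cycle(state, (2, ("prot", "T1")))


def test_trigger_candidates_are_noun_verb_adjective(demo_sentence):
    cands = trigger_candidates(demo_sentence)
    pos = [demo_sentence.tokens[i].pos for i in cands]
    assert all(p[0] in "NVJ" for p in pos)
    assert 1 not in cands  # "22536" is CD
    assert 7 not in cands  # "in" is IN
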