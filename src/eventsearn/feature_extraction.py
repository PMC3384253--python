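"""Sparse feature extraction for the three classification stages.

All features are binary indicators named by namespaced template strings
("trig:", "theme:", "cause:"); conjunctions are realized by concatenating
template name and values.  Structural features — the ones that look at
previously predicted actions — are emitted only when ``structural=True``,
which is what makes jointly trained classifiers aware of each other's
decisions; with ``structural=False`` every vector is a pure function of the
sentence and the target site.

Domain adaptation follows the feature-augmentation recipe: every feature gets
a domain-conjoined copy, so for any instance exactly the original and one
domain-tagged version are active and the learner can split shared from
domain-specific weight mass.
"""

from __future__ import annotations

from .linguistic_graph import CandidatePair, dep_neighbors, path_between
from .standoff_io import DOMAINS, NO_TRIGGER, Sentence
from .state import SentenceState

FeatureVector = dict[str, float]

#: Cap on the length of the "textual string between" fallback feature; longer
#: gaps collapse to a bucketed length marker to bound sparsity.
BETWEEN_CAP = 10


def _arg_head(sentence: Sentence, arg) -> int:
    if arg[0] == "prot":
        return sentence.protein_by_id(arg[1]).head_token
    return arg[1]


def _arg_type(state: SentenceState, arg) -> str:
    if arg[0] == "prot":
        return "Protein"
    return state.trigger_labels.get(arg[1], NO_TRIGGER)


def between_string(sentence: Sentence, a: int, b: int) -> str:
    """Concatenated lemmas of the tokens strictly between two token indices."""
    lo, hi = (a, b) if a < b else (b, a)
    lemmas = [t.lemma for t in sentence.tokens[lo + 1:hi]]
    if len(lemmas) > BETWEEN_CAP:
        return f"len>{BETWEEN_CAP}"
    return "_".join(lemmas) if lemmas else "<adjacent>"


def trigger_features(
    sentence: Sentence,
    token: int,
    state: SentenceState,
    structural: bool,
) -> FeatureVector:
    """Features for labeling one candidate token with an event type.

    The lemma alone decides most cases; lemma-PoS and lemma-context
    conjunctions separate readings like bare "regulation" from "positive
    regulation".  Structural templates expose the event types already
    assigned to the adjacent and dependency-linked tokens.
    """
    tok = sentence.tokens[token]
    f: FeatureVector = {}
    f[f"trig:lemma={tok.lemma}"] = 1.0
    f[f"trig:lemma+pos={tok.lemma}|{tok.pos}"] = 1.0
    if token > 0:
        f[f"trig:lemma+prev={tok.lemma}|{sentence.tokens[token - 1].lemma}"] = 1.0
    if token < len(sentence.tokens) - 1:
        f[f"trig:lemma+next={tok.lemma}|{sentence.tokens[token + 1].lemma}"] = 1.0
    for nb in dep_neighbors(sentence, token):
        f[f"trig:lemma+dep={tok.lemma}|{sentence.tokens[nb].lemma}"] = 1.0
    if structural:
        labels = state.trigger_labels
        for rel, idx in (("prev", token - 1), ("next", token + 1)):
            if idx in labels:
                f[f"trig:lemma+{rel}type={tok.lemma}|{labels[idx]}"] = 1.0
        for nb in dep_neighbors(sentence, token):
            if nb in labels:
                f[f"trig:deptype={labels[nb]}"] = 1.0
    return f


def _pair_base_features(
    sentence: Sentence,
    pair: CandidatePair,
    state: SentenceState,
    ns: str,
) -> FeatureVector:
    t = pair.trigger
    trig_tok = sentence.tokens[t]
    etype = state.trigger_labels.get(t, NO_TRIGGER)
    arg_type = _arg_type(state, pair.argument)
    f: FeatureVector = {}
    if pair.path is not None:
        p = pair.path.unlexicalized()
        f[f"{ns}:path={p}"] = 1.0
        f[f"{ns}:path+triglemma={p}|{trig_tok.lemma}"] = 1.0
        f[f"{ns}:path+trigpos={p}|{trig_tok.pos}"] = 1.0
        f[f"{ns}:path+trigtype={p}|{etype}"] = 1.0
        f[f"{ns}:path+argtype={p}|{arg_type}"] = 1.0
        f[f"{ns}:path+first={p}|{pair.path.first_lemma}"] = 1.0
        f[f"{ns}:path+last={p}|{pair.path.last_lemma}"] = 1.0
    between = between_string(sentence, t, _arg_head(sentence, pair.argument))
    f[f"{ns}:between+trigtype={between}|{etype}"] = 1.0
    return f


def _undirected_theme_cycle(state: SentenceState, pair: CandidatePair) -> bool:
    # Does (trigger, argument) close an undirected cycle with predicted
    # Themes, i.e. are the endpoints already connected ignoring direction?
    src = ("trig", pair.trigger)
    dst = pair.argument
    adj: dict = {}
    for t, a in state.theme_edges:
        u, v = ("trig", t), a
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
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


def theme_features(
    sentence: Sentence,
    pair: CandidatePair,
    state: SentenceState,
    structural: bool,
) -> FeatureVector:
    """Features for one Theme-assignment action.

    Path templates (path alone and conjoined with trigger lemma/PoS/type,
    argument type, endpoint lemmas) carry most signal; the textual-string
    fallback covers mis-parsed, disconnected pairs.  Structural indicators
    flag undirected Theme cycles, mixed protein/event Theme combinations,
    arguments shared with a same-type trigger, and triggers already holding
    three Themes.
    """
    f = _pair_base_features(sentence, pair, state, "theme")
    if structural:
        t = pair.trigger
        themes = state.themes_of(t)
        if _undirected_theme_cycle(state, pair):
            f["theme:undirected-cycle"] = 1.0
        has_prot = any(a[0] == "prot" for a in themes)
        has_event = any(a[0] == "trig" for a in themes)
        if has_prot and pair.argument[0] == "trig":
            f["theme:prot-theme+event-arg"] = 1.0
        if has_event and pair.argument[0] == "prot":
            f["theme:event-theme+prot-arg"] = 1.0
        etype = state.trigger_labels.get(t, NO_TRIGGER)
        for t2, a2 in state.theme_edges:
            if t2 != t and a2 == pair.argument \
                    and state.trigger_labels.get(t2) == etype:
                f["theme:arg-shared-same-type"] = 1.0
                break
        if len(themes) >= 3:
            f["theme:three-themes"] = 1.0
    return f


def cause_features(
    sentence: Sentence,
    pair: CandidatePair,
    state: SentenceState,
    structural: bool,
) -> FeatureVector:
    """Features for one Cause-assignment action.

    Extends the Theme templates with conjunctions of the candidate's path and
    the path(s) from the trigger to its already-assigned Theme(s).  The acting
    trigger must hold at least one Theme.
    """
    t = pair.trigger
    themes = state.themes_of(t)
    if not themes:
        raise ValueError(
            f"cause_features: trigger {t} has no assigned Theme"
        )
    f = _pair_base_features(sentence, pair, state, "cause")
    p = pair.path.unlexicalized() if pair.path is not None else "NOPATH"
    for arg in themes:
        head = _arg_head(sentence, arg)
        tpath = path_between(sentence, t, head) if head != t else None
        tp = tpath.unlexicalized() if tpath is not None else "NOPATH"
        f[f"cause:path+themepath={p}|{tp}"] = 1.0
    if structural:
        if any(a[0] == "prot" for a in state.causes_of(t)):
            f["cause:has-protein-cause"] = 1.0
        if pair.argument[0] == "trig":
            f["cause:event-arg"] = 1.0
    return f


def augment_domain(fv: FeatureVector, domain: str) -> FeatureVector:
    """Feature augmentation for supervised domain adaptation.

    Returns the original features plus one domain-conjoined copy of each, so
    ``|output| == 2 * |input|``.
    """
    if domain not in DOMAINS:
        raise ValueError(f"unknown domain {domain!r}")
    out = dict(fv)
    for name, value in fv.items():
        out[f"{domain}|{name}"] = value
    return out


def dump_vocabulary(vectors, path) -> None:
    """Write the union of feature names to a text file (debugging aid)."""
    names = sorted({name for fv in vectors for name in fv})
    with open(path, "w") as fh:
        fh.write("\n".join(names) + "\n")
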