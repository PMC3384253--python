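"""Search-based structured prediction (SEARN) for event extraction.

A sentence is predicted through a sequence of multiclass actions: trigger
labels left to right, then Theme candidate pairs, then Cause candidate pairs,
the pair stages following the agenda order of increasing dependency path
length.  Training starts from the optimal policy (derived from the gold
standard) and over the iterations stochastically hands actions to the learned
classifier ensemble: at iteration i the optimal policy acts with probability
(1 - beta)^(i-1).  Each action taken generates one cost-sensitive example,
its cost vector estimated by rolling out the remaining actions with the
current interpolated policy and measuring the event-level loss — optionally
restricted to the part of the output graph connected with the action
(*focused costing*), and optionally weighting false positives and false
negatives differently to steer the precision/recall balance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .csc_pa_learner import CSCExample, LinearCSCClassifier, PAConfig, train_csc
from .feature_extraction import (
    augment_domain,
    cause_features,
    theme_features,
    trigger_features,
)
from .linguistic_graph import (
    build_cause_agenda,
    build_theme_agenda,
    order_actions,
    trigger_candidates,
)
from .standoff_io import EVENT_TYPES, NO_TRIGGER, Document, Sentence
from .state import ArgRef, GoldDecomposition, SentenceState, Signature, decompose

TRIGGER_LABELS = (NO_TRIGGER,) + EVENT_TYPES
THEME_LABELS = ("No_Theme", "Theme")
CAUSE_LABELS = ("No_Cause", "Cause")
STAGES = ("trigger", "theme", "cause")
STAGE_LABELS = {"trigger": TRIGGER_LABELS, "theme": THEME_LABELS,
                "cause": CAUSE_LABELS}
#: Index of the negative class of each stage (score-offset target).
NEGATIVE_INDEX = 0


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LossConfig:
    """Weights multiplying false-positive and false-negative event counts.

    The defaults (1, 1) give the shared task's unweighted loss; raising
    ``w_fp`` trains toward precision, raising ``w_fn`` toward recall.
    """

    w_fp: float = 1.0
    w_fn: float = 1.0

    def __post_init__(self) -> None:
        if self.w_fp <= 0 or self.w_fn <= 0:
            raise ValueError("loss weights must be positive")


@dataclass(frozen=True)
class SearnConfig:
    beta: float = 0.3
    iterations: int = 12
    loss: LossConfig = field(default_factory=LossConfig)
    samples_per_action: int = 1
    focused: bool = True
    structural: bool = True
    domain_adapt: bool = False
    zero_one_costs: bool = False
    seed: int = 0
    pa: PAConfig = field(default_factory=PAConfig)

    def __post_init__(self) -> None:
        if not (0.0 < self.beta <= 1.0):
            raise ValueError("beta must be in (0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.samples_per_action < 1:
            raise ValueError("samples_per_action must be >= 1")


# ---------------------------------------------------------------------------
# Event-level loss
# ---------------------------------------------------------------------------


def _to_signatures(events) -> frozenset[Signature]:
    from .state import event_signature  # Event objects or ready signatures

    out = set()
    for e in events:
        out.add(e if isinstance(e, tuple) else event_signature(e))
    return frozenset(out)


def event_loss(
    gold,
    predicted,
    cfg: LossConfig = LossConfig(),
    component: set | None = None,
) -> float:
    """Weighted count of false-positive plus false-negative events.

    Events match when trigger head token, event type, Theme set (recursively
    for nested arguments) and Cause all agree.  With ``component`` given
    (focused costing), only events whose trigger node belongs to that
    connected component are counted.
    """
    gold_sigs = _to_signatures(gold)
    pred_sigs = _to_signatures(predicted)
    if component is not None:
        gold_sigs = frozenset(s for s in gold_sigs if ("trig", s[0]) in component)
        pred_sigs = frozenset(s for s in pred_sigs if ("trig", s[0]) in component)
    fp = len(pred_sigs - gold_sigs)
    fn = len(gold_sigs - pred_sigs)
    return cfg.w_fp * fp + cfg.w_fn * fn


# ---------------------------------------------------------------------------
# Policies
# ---------------------------------------------------------------------------


class OptimalPolicy:
    """The gold-derived policy: picks the action minimizing final loss
    assuming all later actions are optimal.

    For triggers it returns the gold event type (or No_trigger).  A Theme is
    asserted only when the trigger's predicted type is correct, the edge is
    in the gold standard, and an event-valued argument has been recognized
    correctly (type and Theme set); a Cause additionally requires the acting
    trigger to already hold at least one correct Theme.  Mislabeled triggers
    therefore receive no arguments — avoiding the false-positive events they
    would otherwise incur.
    """

    source = "optimal"

    def __init__(self, gold: GoldDecomposition):
        self.gold = gold

    def _arg_correct(self, state: SentenceState, arg: ArgRef) -> bool:
        if arg[0] == "prot":
            return True
        tok = arg[1]
        if state.trigger_labels.get(tok) != self.gold.trigger_labels.get(tok):
            return False
        assigned = frozenset(state.themes_of(tok))
        return assigned == self.gold.themes_by_trigger.get(tok, frozenset())

    def decide(self, stage: str, sentence: Sentence, state: SentenceState, site) -> str:
        g = self.gold
        if stage == "trigger":
            return g.trigger_labels.get(site, NO_TRIGGER)
        t, arg = site.trigger, site.argument
        if state.trigger_labels.get(t) != g.trigger_labels.get(t):
            return STAGE_LABELS[stage][NEGATIVE_INDEX]
        edges = g.theme_edges if stage == "theme" else g.cause_edges
        if (t, arg) not in edges or not self._arg_correct(state, arg):
            return STAGE_LABELS[stage][NEGATIVE_INDEX]
        if stage == "cause":
            ok = any(
                (t, a) in g.theme_edges and self._arg_correct(state, a)
                for a in state.themes_of(t)
            )
            if not ok:
                return "No_Cause"
            return "Cause"
        return "Theme"


class EnsemblePolicy:
    """Weighted ensemble of per-iteration stage classifiers.

    In deterministic mode (test-time default) per-label scores are the
    mixture-weighted sum over hypotheses; in stochastic mode one hypothesis
    is sampled per action by mixture weight, as during training rollouts.
    Optional per-stage offsets are added to the negative-class score to trade
    recall against precision at prediction time.
    """

    source = "learned"

    def __init__(
        self,
        hypotheses: Sequence[dict[str, LinearCSCClassifier]],
        weights: Sequence[float],
        structural: bool = True,
        domain_adapt: bool = False,
        offsets: dict[str, float] | None = None,
        stochastic: bool = False,
        rng: np.random.Generator | None = None,
    ):
        if not hypotheses:
            raise ValueError("ensemble needs at least one hypothesis")
        if len(weights) != len(hypotheses):
            raise ValueError("one mixture weight per hypothesis required")
        self.hypotheses = list(hypotheses)
        self.weights = [float(w) for w in weights]
        self.structural = structural
        self.domain_adapt = domain_adapt
        self.offsets = dict(offsets or {})
        self.stochastic = stochastic
        self.rng = rng
        self._cum = np.cumsum(self.weights)

    def decide(self, stage: str, sentence: Sentence, state: SentenceState, site) -> str:
        fv = extract_features(
            stage, sentence, state, site, self.structural, self.domain_adapt
        )
        if self.stochastic:
            u = self.rng.random() * self._cum[-1]
            h = self.hypotheses[int(np.searchsorted(self._cum, u, side="right"))]
            scores = h[stage].scores(fv)
        else:
            scores = np.zeros(len(STAGE_LABELS[stage]))
            for w, h in zip(self.weights, self.hypotheses):
                if w > 0:
                    scores = scores + w * h[stage].scores(fv)
        scores[NEGATIVE_INDEX] += self.offsets.get(stage, 0.0)
        return STAGE_LABELS[stage][int(np.argmax(scores))]


class InterpolatedPolicy:
    """Stochastic mixture of the optimal policy and the learned ensemble."""

    def __init__(
        self,
        optimal: OptimalPolicy,
        learned: EnsemblePolicy | None,
        optimal_policy_prob: float,
        rng: np.random.Generator,
    ):
        self.optimal = optimal
        self.learned = learned
        self.optimal_policy_prob = optimal_policy_prob
        self.rng = rng
        self.source = "optimal"

    def decide(self, stage, sentence, state, site) -> str:
        if self.learned is None or self.rng.random() < self.optimal_policy_prob:
            self.source = "optimal"
            return self.optimal.decide(stage, sentence, state, site)
        self.source = "learned"
        return self.learned.decide(stage, sentence, state, site)


class GoldGraphPolicy:
    """A scripted rollout policy that replicates the gold *graph structure*.

    Triggers receive their gold types unless overridden; Theme/Cause pairs
    are asserted whenever the corresponding token-level edge exists in the
    gold standard, regardless of the types currently assigned — emulating a
    learned hypothesis that has captured the argument structure of the
    sentence.  ``conditional_themes`` maps an extra edge to the trigger label
    that must be present for it to fire, which scripts scenarios like "this
    token, if mislabeled as a trigger, would be given a Theme".
    """

    source = "scripted"

    def __init__(
        self,
        gold: GoldDecomposition,
        trigger_overrides: dict[int, str] | None = None,
        conditional_themes: dict[tuple[int, ArgRef], str] | None = None,
    ):
        self.gold = gold
        self.trigger_overrides = dict(trigger_overrides or {})
        self.conditional_themes = dict(conditional_themes or {})

    def decide(self, stage, sentence, state, site) -> str:
        if stage == "trigger":
            if site in self.trigger_overrides:
                return self.trigger_overrides[site]
            return self.gold.trigger_labels.get(site, NO_TRIGGER)
        key = (site.trigger, site.argument)
        if stage == "theme":
            if key in self.gold.theme_edges:
                return "Theme"
            required = self.conditional_themes.get(key)
            if required is not None and \
                    state.trigger_labels.get(site.trigger) == required:
                return "Theme"
            return "No_Theme"
        return "Cause" if key in self.gold.cause_edges else "No_Cause"


# ---------------------------------------------------------------------------
# Feature dispatch and policy execution
# ---------------------------------------------------------------------------


def extract_features(
    stage: str,
    sentence: Sentence,
    state: SentenceState,
    site,
    structural: bool,
    domain_adapt: bool,
) -> dict[str, float]:
    if stage == "trigger":
        fv = trigger_features(sentence, site, state, structural)
    elif stage == "theme":
        fv = theme_features(sentence, site, state, structural)
    else:
        fv = cause_features(sentence, site, state, structural)
    if domain_adapt:
        fv = augment_domain(fv, sentence.domain)
    return fv


def apply_action(
    sentence: Sentence, state: SentenceState, stage: str, site, label: str,
    source: str = "scripted",
) -> None:
    """Apply one decided action to the state and advance stage progress."""
    if stage == "trigger":
        cands = trigger_candidates(sentence)
        state.trigger_labels[site] = label
        state.next_trigger_pos = cands.index(site) + 1
    elif stage == "theme":
        state.decided_theme.add(site.key)
        if label == "Theme":
            state.add_theme(site.trigger, site.argument)
    else:
        state.decided_cause.add(site.key)
        if label == "Cause":
            state.add_cause(site.trigger, site.argument)
    state.action_log.append((stage, site, label, source))


def continue_policy(sentence: Sentence, state: SentenceState, policy) -> SentenceState:
    """Complete all remaining actions of a (possibly partial) state.

    Triggers are processed left to right; the Theme agenda is re-derived
    after every action so pairs spawned by newly Themed triggers enter the
    queue, and the next pending pair is always the one with the shortest
    dependency path (insertion order breaking ties); then the Cause agenda
    runs the same way.
    """
    cands = trigger_candidates(sentence)
    while state.next_trigger_pos < len(cands):
        tok = cands[state.next_trigger_pos]
        label = policy.decide("trigger", sentence, state, tok)
        apply_action(sentence, state, "trigger", tok, label,
                     getattr(policy, "source", "?"))
    for stage, decided in (("theme", state.decided_theme),
                           ("cause", state.decided_cause)):
        build = build_theme_agenda if stage == "theme" else build_cause_agenda
        while True:
            pending = [p for p in build(sentence, state) if p.key not in decided]
            if not pending:
                break
            pair = order_actions(pending)[0]
            label = policy.decide(stage, sentence, state, pair)
            apply_action(sentence, state, stage, pair, label,
                         getattr(policy, "source", "?"))
    return state


def run_policy(
    sentence: Sentence,
    policy,
    gold: GoldDecomposition | None = None,
    mode: str = "test",
    rng: np.random.Generator | None = None,
    offsets: dict[str, float] | None = None,
) -> SentenceState:
    """Predict one sentence's full action sequence.

    ``policy`` may be a :class:`TrainedPolicy` or any object with a
    ``decide`` method.  In ``train`` mode the optimal policy (from ``gold``,
    or derived from the sentence's own annotation) is stochastically
    interpolated with the learned ensemble; in ``test`` mode only the learned
    ensemble acts.
    """
    if mode not in ("train", "test"):
        raise ValueError(f"unknown mode {mode!r}")
    decide = policy
    if isinstance(policy, TrainedPolicy):
        if mode == "test":
            if not policy.hypotheses:
                raise ValueError("test mode requires at least one learned hypothesis")
            decide = policy.ensemble(offsets=offsets)
        else:
            if gold is None:
                gold = decompose(sentence)
            if rng is None:
                raise ValueError("train mode requires an rng")
            learned = None
            if policy.hypotheses:
                learned = policy.ensemble(stochastic=True, rng=rng)
            decide = InterpolatedPolicy(
                OptimalPolicy(gold), learned, policy.optimal_policy_prob, rng
            )
    return continue_policy(sentence, SentenceState(), decide)


# ---------------------------------------------------------------------------
# Cost estimation
# ---------------------------------------------------------------------------


def action_component(
    gold: GoldDecomposition,
    state: SentenceState,
    stage: str,
    site,
) -> set:
    """Connected component (weak connectivity) of the union of the gold and
    predicted argument graphs that touches the action site."""
    adj: dict = {}

    def connect(t: int, arg: ArgRef) -> None:
        u, v = ("trig", t), arg
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    for t, a in gold.theme_edges | gold.cause_edges:
        connect(t, a)
    for t, a in list(state.theme_edges) + list(state.cause_edges):
        connect(t, a)
    if stage == "trigger":
        seeds = [("trig", site)]
    else:
        seeds = [("trig", site.trigger), site.argument]
    seen: set = set()
    stack = list(seeds)
    while stack:
        u = stack.pop()
        if u in seen:
            continue
        seen.add(u)
        stack.extend(adj.get(u, ()))
    return seen


def estimate_action_costs(
    sentence: Sentence,
    gold: GoldDecomposition,
    prefix: SentenceState,
    stage: str,
    site,
    rollout_policy: Callable[[int, int], object],
    cfg: SearnConfig,
    regdict: dict[str, str] | None = None,
) -> tuple[tuple[str, ...], list[float]]:
    """Cost one action site: per candidate label, force the label, roll out
    the remaining actions, construct events and measure the event loss.

    ``rollout_policy(label_index, sample)`` supplies a fresh policy object per
    rollout.  Costs are averaged over ``cfg.samples_per_action`` rollouts and
    shifted so the cheapest label costs 0.  With ``cfg.focused`` the loss
    counts only events connected with the action site in the union of the
    gold and rolled-out graphs.
    """
    from .event_pipeline import construct_event_signatures

    labels = STAGE_LABELS[stage]
    regdict = regdict or {}
    costs: list[float] = []
    for li, label in enumerate(labels):
        total = 0.0
        for s in range(cfg.samples_per_action):
            st = prefix.copy()
            apply_action(sentence, st, stage, site, label)
            continue_policy(sentence, st, rollout_policy(li, s))
            predicted = construct_event_signatures(sentence, st, regdict)
            component = (
                action_component(gold, st, stage, site) if cfg.focused else None
            )
            total += event_loss(gold.event_signatures, predicted, cfg.loss,
                                component)
        costs.append(total / cfg.samples_per_action)
    m = min(costs)
    return tuple(labels), [c - m for c in costs]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def mixture_weights(beta: float, n: int) -> list[float]:
    """Normalized ensemble weights of n hypotheses: h = beta*h_new + (1-beta)*h
    unrolled, so earlier hypotheses matter geometrically less."""
    if n == 0:
        return []
    unnorm = [beta * (1.0 - beta) ** (n - 1 - i) for i in range(n)]
    total = sum(unnorm)
    return [w / total for w in unnorm]


@dataclass
class TrainedPolicy:
    """The learned ensemble returned by training (optimal policy stripped)."""

    hypotheses: list[dict[str, LinearCSCClassifier]]
    weights: list[float]
    beta: float
    iteration: int
    config: SearnConfig
    regdict: dict[str, str] = field(default_factory=dict)

    @property
    def optimal_policy_prob(self) -> float:
        return (1.0 - self.beta) ** self.iteration

    def ensemble(
        self,
        offsets: dict[str, float] | None = None,
        stochastic: bool = False,
        rng: np.random.Generator | None = None,
    ) -> EnsemblePolicy:
        return EnsemblePolicy(
            self.hypotheses,
            self.weights,
            structural=self.config.structural,
            domain_adapt=self.config.domain_adapt,
            offsets=offsets,
            stochastic=stochastic,
            rng=rng,
        )

    # -- serialization ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cfg = asdict(self.config)
        data = {
            "beta": self.beta,
            "iteration": self.iteration,
            "weights": self.weights,
            "config": cfg,
            "regdict": self.regdict,
            "hypotheses": [
                {stage: clf.to_json() for stage, clf in h.items()}
                for h in self.hypotheses
            ],
        }
        (directory / "model.json").write_text(json.dumps(data))

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedPolicy":
        data = json.loads((Path(directory) / "model.json").read_text())
        cfg = dict(data["config"])
        cfg["loss"] = LossConfig(**cfg["loss"])
        cfg["pa"] = PAConfig(**cfg["pa"])
        return cls(
            hypotheses=[
                {stage: LinearCSCClassifier.from_json(c) for stage, c in h.items()}
                for h in data["hypotheses"]
            ],
            weights=data["weights"],
            beta=data["beta"],
            iteration=data["iteration"],
            config=SearnConfig(**cfg),
            regdict=data["regdict"],
        )


def _stage_seed(seed: int, iteration: int, stage: str) -> int:
    return (seed * 1000003 + iteration * 1009 + STAGES.index(stage) * 101) % (2**31)


def searn_train(
    corpus: Iterable[Document],
    cfg: SearnConfig,
    progress: Callable[[str], None] | None = None,
) -> TrainedPolicy:
    """Run the SEARN loop and return the learned policy ensemble.

    Per iteration: every sentence is predicted with the current interpolated
    policy; every action taken generates one cost-sensitive example whose
    costs come from rollouts with that same policy (or 0/1 costs against the
    optimal action when ``cfg.zero_one_costs``, the independent-pipeline
    degeneration); one classifier per stage is trained on the iteration's
    examples and appended to the ensemble.  All randomness is derived from
    ``cfg.seed`` keyed by (iteration, sentence, action, label, sample), so
    training is reproducible.
    """
    from .event_pipeline import build_regulation_dictionary

    corpus = list(corpus)
    sentences = [s for doc in corpus for s in doc.sentences]
    if not sentences:
        raise ValueError("searn_train requires a non-empty corpus")
    regdict = build_regulation_dictionary(corpus)
    golds = [decompose(s) for s in sentences]

    hypotheses: list[dict[str, LinearCSCClassifier]] = []
    for it in range(1, cfg.iterations + 1):
        opt_prob = (1.0 - cfg.beta) ** (it - 1)
        weights = mixture_weights(cfg.beta, len(hypotheses))
        examples: dict[str, list[CSCExample]] = {stage: [] for stage in STAGES}

        def make_policy(rng: np.random.Generator, gold: GoldDecomposition):
            learned = None
            if hypotheses:
                learned = EnsemblePolicy(
                    hypotheses, weights, structural=cfg.structural,
                    domain_adapt=cfg.domain_adapt, stochastic=True, rng=rng,
                )
            return InterpolatedPolicy(OptimalPolicy(gold), learned, opt_prob, rng)

        for si, (sentence, gold) in enumerate(zip(sentences, golds)):
            rng = np.random.default_rng([cfg.seed, it, si])
            state = continue_policy(
                sentence, SentenceState(), make_policy(rng, gold)
            )
            optimal = OptimalPolicy(gold)
            replay = SentenceState()
            for ai, (stage, site, label, _) in enumerate(state.action_log):
                fv = extract_features(
                    stage, sentence, replay, site, cfg.structural,
                    cfg.domain_adapt,
                )
                if cfg.zero_one_costs:
                    opt_label = optimal.decide(stage, sentence, replay, site)
                    costs = [
                        0.0 if lab == opt_label else 1.0
                        for lab in STAGE_LABELS[stage]
                    ]
                else:
                    def rollout(li: int, s: int, _ai=ai):
                        r = np.random.default_rng([cfg.seed, it, si, _ai, li, s])
                        return make_policy(r, gold)

                    _, costs = estimate_action_costs(
                        sentence, gold, replay, stage, site, rollout, cfg,
                        regdict,
                    )
                if any(c > 0 for c in costs):
                    examples[stage].append(CSCExample(fv, costs))
                apply_action(sentence, replay, stage, site, label)

        h_new: dict[str, LinearCSCClassifier] = {}
        for stage in STAGES:
            pa = replace(cfg.pa, seed=_stage_seed(cfg.seed, it, stage))
            if examples[stage]:
                h_new[stage] = train_csc(
                    examples[stage], pa, labels=STAGE_LABELS[stage]
                )
            else:
                h_new[stage] = LinearCSCClassifier(STAGE_LABELS[stage], pa)
        hypotheses.append(h_new)
        if progress is not None:
            sizes = {st: len(examples[st]) for st in STAGES}
            progress(f"iteration {it}/{cfg.iterations}: examples {sizes}")

    return TrainedPolicy(
        hypotheses=hypotheses,
        weights=mixture_weights(cfg.beta, len(hypotheses)),
        beta=cfg.beta,
        iteration=cfg.iterations,
        config=cfg,
        regdict=regdict,
    )
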