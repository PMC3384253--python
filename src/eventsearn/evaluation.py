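"""Event-level evaluation: matching, P/R/F tables, score-offset sweeps.

An event counts as correct only when all of its elements are identified
correctly: trigger head token, event type, the full Theme set (recursively
for event-valued arguments) and the Cause.  Trigger matching is approximate
in the head-token sense — both sides are head-reduced, so single-word span
variation does not cost anything.  Reports are micro-averaged with per-type
rows and Simple/Binding/Regulation/TOTAL class rollups, printed on a 0-100
scale with two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .standoff_io import (
    BINDING_TYPE,
    EVENT_TYPES,
    REGULATION_TYPES,
    SIMPLE_TYPES,
    Document,
)
from .state import Signature, sentence_gold_signatures


@dataclass(frozen=True)
class OffsetTriple:
    """Score offsets added to the negative class of each stage.

    Positive values favor No_Trigger/No_Theme/No_Cause and under-generate;
    negative values over-generate.
    """

    trigger_offset: float = 0.0
    theme_offset: float = 0.0
    cause_offset: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "trigger": self.trigger_offset,
            "theme": self.theme_offset,
            "cause": self.cause_offset,
        }


def match_events(
    gold: frozenset[Signature] | set[Signature],
    predicted: frozenset[Signature] | set[Signature],
) -> tuple[int, int, int, dict[str, tuple[int, int, int]]]:
    """TP/FP/FN counts with a per-event-type breakdown.

    The type of an event is its top-level event type; a nested prediction
    whose inner argument is wrong fails the outer event too (set matching on
    recursive signatures).
    """
    gold = frozenset(gold)
    predicted = frozenset(predicted)
    per_type: dict[str, list[int]] = {t: [0, 0, 0] for t in EVENT_TYPES}
    for s in gold & predicted:
        per_type[s[1]][0] += 1
    for s in predicted - gold:
        per_type[s[1]][1] += 1
    for s in gold - predicted:
        per_type[s[1]][2] += 1
    tp = len(gold & predicted)
    fp = len(predicted - gold)
    fn = len(gold - predicted)
    return tp, fp, fn, {t: tuple(v) for t, v in per_type.items()}


_CLASS_ROWS = (
    ("Simple (TOTAL)", SIMPLE_TYPES),
    ("Binding", (BINDING_TYPE,)),
    ("Regulation (TOTAL)", REGULATION_TYPES),
    ("TOTAL", EVENT_TYPES),
)


class EvalReport:
    """Micro-averaged counts and R/P/F per event type and class."""

    def __init__(self, per_type: Mapping[str, tuple[int, int, int]]):
        self.per_type = {t: tuple(per_type.get(t, (0, 0, 0))) for t in EVENT_TYPES}

    def counts(self, row: str) -> tuple[int, int, int]:
        if row in self.per_type:
            return self.per_type[row]
        for name, types in _CLASS_ROWS:
            if name == row:
                tp = sum(self.per_type[t][0] for t in types)
                fp = sum(self.per_type[t][1] for t in types)
                fn = sum(self.per_type[t][2] for t in types)
                return tp, fp, fn
        raise KeyError(row)

    def recall(self, row: str) -> float:
        tp, _, fn = self.counts(row)
        return 100.0 * tp / (tp + fn) if tp + fn else 0.0

    def precision(self, row: str) -> float:
        tp, fp, _ = self.counts(row)
        return 100.0 * tp / (tp + fp) if tp + fp else 0.0

    def fscore(self, row: str) -> float:
        r, p = self.recall(row), self.precision(row)
        return 2.0 * p * r / (p + r) if p + r else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = list(EVENT_TYPES) + [name for name, _ in _CLASS_ROWS]
        records = []
        for row in rows:
            tp, fp, fn = self.counts(row)
            records.append(
                {
                    "row": row,
                    "TP": tp,
                    "FP": fp,
                    "FN": fn,
                    "Recall": round(self.recall(row), 2),
                    "Precision": round(self.precision(row), 2),
                    "Fscore": round(self.fscore(row), 2),
                }
            )
        return pd.DataFrame.from_records(records).set_index("row")

    def __str__(self) -> str:
        return self.to_frame().to_string(
            float_format=lambda v: f"{v:.2f}"
        )


def score_sentences(
    gold_by_sentence: Sequence[frozenset[Signature]],
    pred_by_sentence: Sequence[set[Signature]],
) -> EvalReport:
    if len(gold_by_sentence) != len(pred_by_sentence):
        raise ValueError("gold and predicted sentence lists differ in length")
    totals = {t: [0, 0, 0] for t in EVENT_TYPES}
    for gold, pred in zip(gold_by_sentence, pred_by_sentence):
        _, _, _, per_type = match_events(gold, pred)
        for t, (tp, fp, fn) in per_type.items():
            totals[t][0] += tp
            totals[t][1] += fp
            totals[t][2] += fn
    return EvalReport({t: tuple(v) for t, v in totals.items()})


def score_corpus(
    gold_docs: Sequence[Document],
    predictions: Mapping[str, Sequence[set[Signature]]],
) -> EvalReport:
    """Score per-document predicted signature lists against gold documents.

    ``predictions`` maps doc_id to one signature set per sentence; a missing
    or extra document id is an error.
    """
    gold_ids = {d.doc_id for d in gold_docs}
    if gold_ids != set(predictions):
        raise ValueError(
            f"document ids mismatch: gold {sorted(gold_ids)} vs "
            f"predicted {sorted(predictions)}"
        )
    gold_all: list[frozenset[Signature]] = []
    pred_all: list[set[Signature]] = []
    for doc in gold_docs:
        pred = predictions[doc.doc_id]
        if len(pred) != len(doc.sentences):
            raise ValueError(f"sentence count mismatch in {doc.doc_id}")
        gold_all.extend(sentence_gold_signatures(s) for s in doc.sentences)
        pred_all.extend(pred)
    return score_sentences(gold_all, pred_all)


def sweep_offsets(
    policy,
    gold_docs: Sequence[Document],
    offsets: Sequence[OffsetTriple],
) -> list[tuple[OffsetTriple, EvalReport]]:
    """Re-run prediction for every offset triple and score each run.

    Shifting a stage's negative-class score traces out recall-precision
    curves: a large positive trigger offset suppresses every event, zero
    offsets reproduce the unmodified prediction.
    """
    from .event_pipeline import predict_signatures

    results = []
    for triple in offsets:
        preds = {
            doc.doc_id: predict_signatures(doc, policy, offsets=triple.as_dict())
            for doc in gold_docs
        }
        results.append((triple, score_corpus(gold_docs, preds)))
    return results
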