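"""Multiclass cost-sensitive passive-aggressive learning.

Each training example is a sparse binary feature vector plus a per-label cost
vector; the learner keeps one sparse weight vector per label.  For an example
whose predicted label carries positive cost, the PA-II prediction-based
update is applied:

    yhat = argmax_k w(k).x          (predicted label, ties -> lowest index)
    y    = argmin_k c(k)            (cheapest label, ties -> lowest index)
    loss = w(yhat).x - w(y).x + sqrt(c(yhat))
    tau  = loss / (||x||^2 + 1/(2C))
    w(y) += tau.x ;  w(yhat) -= tau.x

Zero-cost predictions leave the weights untouched (the passive case).
Training runs R rounds over a seeded shuffle of the examples and averages
the weight vectors after every example visit, as in the averaged perceptron;
prediction after training uses the averaged weights.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class PAConfig:
    """Aggressiveness C, number of rounds R, shuffle seed."""

    C: float = 1.0
    R: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("aggressiveness C must be positive")
        if self.R < 1:
            raise ValueError("number of rounds R must be >= 1")


@dataclass(frozen=True)
class CSCExample:
    """A sparse feature vector with one non-negative cost per label."""

    x: dict[str, float]
    costs: tuple[float, ...]

    def __init__(self, x: dict[str, float], costs: Sequence[float]):
        costs = tuple(float(c) for c in costs)
        if any(c < 0 for c in costs):
            raise ValueError("costs must be non-negative")
        object.__setattr__(self, "x", dict(x))
        object.__setattr__(self, "costs", costs)


class LinearCSCClassifier:
    """K-class linear classifier with one sparse weight vector per label.

    During training the current weights ``w`` are used; after training,
    prediction reads the averaged weights ``w_avg``.
    """

    def __init__(self, labels: Sequence[str], config: PAConfig = PAConfig()):
        self.labels = list(labels)
        self.config = config
        self.w: list[dict[str, float]] = [{} for _ in self.labels]
        self.w_avg: list[dict[str, float]] = [{} for _ in self.labels]

    @property
    def K(self) -> int:
        return len(self.labels)

    def scores(self, x: dict[str, float], averaged: bool = True) -> np.ndarray:
        weights = self.w_avg if averaged else self.w
        return np.array(
            [sum(wk.get(f, 0.0) * v for f, v in x.items()) for wk in weights]
        )

    def predict(self, x: dict[str, float], averaged: bool = True) -> int:
        s = self.scores(x, averaged=averaged)
        return int(np.argmax(s))  # argmax takes the lowest index on ties

    # -- serialization ------------------------------------------------------

    def to_json(self) -> dict:
        return {
            "labels": self.labels,
            "config": {"C": self.config.C, "R": self.config.R,
                       "seed": self.config.seed},
            "w": self.w,
            "w_avg": self.w_avg,
        }

    @classmethod
    def from_json(cls, data: dict) -> "LinearCSCClassifier":
        clf = cls(data["labels"], PAConfig(**data["config"]))
        clf.w = [dict(d) for d in data["w"]]
        clf.w_avg = [dict(d) for d in data["w_avg"]]
        return clf

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json()))

    @classmethod
    def load(cls, path: str | Path) -> "LinearCSCClassifier":
        return cls.from_json(json.loads(Path(path).read_text()))


def predict_scores(clf: LinearCSCClassifier, x: dict[str, float],
                   averaged: bool = True) -> np.ndarray:
    """Per-label scores w(k).x as a dense vector."""
    return clf.scores(x, averaged=averaged)


def pa_update(clf: LinearCSCClassifier, example: CSCExample) -> LinearCSCClassifier:
    """Apply one PA-II cost-sensitive update in place; returns the classifier."""
    if len(example.costs) != clf.K:
        raise ValueError(
            f"example has {len(example.costs)} costs for {clf.K} labels"
        )
    _apply_update(clf.w, example, clf.config.C)
    return clf


def _apply_update(
    w: list[dict[str, float]],
    example: CSCExample,
    C: float,
) -> tuple[int, int, float] | None:
    """Core update; returns (yhat, y, tau) when an update happened."""
    x, costs = example.x, example.costs
    scores = [sum(wk.get(f, 0.0) * v for f, v in x.items()) for wk in w]
    yhat = max(range(len(w)), key=lambda k: (scores[k], -k))
    if costs[yhat] <= 0.0:
        return None
    y = min(range(len(w)), key=lambda k: (costs[k], k))
    loss = scores[yhat] - scores[y] + math.sqrt(costs[yhat])
    norm2 = sum(v * v for v in x.values())
    tau = loss / (norm2 + 1.0 / (2.0 * C))
    wy, wyhat = w[y], w[yhat]
    for f, v in x.items():
        wy[f] = wy.get(f, 0.0) + tau * v
        wyhat[f] = wyhat.get(f, 0.0) - tau * v
    return yhat, y, tau


def train_csc(
    examples: Sequence[CSCExample],
    config: PAConfig,
    labels: Sequence[str] | None = None,
) -> LinearCSCClassifier:
    """Train a classifier on cost-sensitive examples.

    Examples whose cost vectors are entirely zero carry no training signal
    and are dropped up front.  The examples are reshuffled with a seeded
    generator at the start of every round; the returned classifier predicts
    with the average of the T*R post-example weight snapshots.
    """
    if not examples:
        raise ValueError("train_csc requires at least one example")
    K = len(examples[0].costs)
    for ex in examples:
        if len(ex.costs) != K:
            raise ValueError("inconsistent number of labels across examples")
    if labels is None:
        labels = [str(k) for k in range(K)]
    elif len(labels) != K:
        raise ValueError("label list does not match cost-vector length")
    clf = LinearCSCClassifier(labels, config)

    active = [ex for ex in examples if any(c > 0 for c in ex.costs)]
    if not active:
        return clf

    rng = np.random.default_rng(config.seed)
    T = len(active)
    N = T * config.R  # total snapshots entering the average
    # Averaged weights via the lazy-delta trick: a delta applied at global
    # step i is contained in the (N - i + 1) snapshots taken at steps i..N.
    u: list[dict[str, float]] = [{} for _ in range(K)]
    step = 0
    for _ in range(config.R):
        order = rng.permutation(T)
        for idx in order:
            step += 1
            ex = active[idx]
            res = _apply_update(clf.w, ex, config.C)
            if res is None:
                continue
            yhat, y, tau = res
            remain = N - step + 1
            uy, uyhat = u[y], u[yhat]
            for f, v in ex.x.items():
                uy[f] = uy.get(f, 0.0) + tau * v * remain
                uyhat[f] = uyhat.get(f, 0.0) - tau * v * remain
    clf.w_avg = [{f: v / N for f, v in uk.items()} for uk in u]
    return clf
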