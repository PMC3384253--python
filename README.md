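# eventsearn

Biomedical event extraction with search-based structured prediction.

Molecular-biology articles describe *events* — typed relations such as
`Gene_expression`, `Binding` or `Negative_regulation` anchored on a trigger
word, taking protein Themes and, for the Regulation class, an optional Cause
that may itself be another event.  Given sentences with pre-annotated
protein mentions, lemmas and collapsed dependency parses (BioNLP standoff
layout), `eventsearn` extracts the nested event graph.  It is written for
text-mining researchers who want a compact, fully inspectable implementation
of the joint-vs-pipeline comparison for this task.

## The model

Extraction is decomposed into a sequence of multiclass *actions* per
sentence:

1. **trigger recognition** — label each noun/verb/adjective token with one of
   the nine event types or `No_trigger`;
2. **Theme assignment** — classify trigger–argument candidate pairs, ordered
   by increasing dependency-path length, with pairs between Regulation
   triggers and newly Themed triggers added dynamically (nested events);
3. **Cause assignment** — the same for Regulation triggers holding a Theme;
4. **event construction** — deterministic rules turn the labeled graph into
   events (nominal Binding Themes are grouped by the first dependency label
   and combined by cross product; a lemma dictionary regenerates the dual
   Simple+Regulation annotations such as "overexpression").

The stages are learned either **independently** (each classifier trained on
the gold decomposition with 0/1 costs) or **jointly with SEARN**: starting
from the optimal policy π derived from the gold standard, each iteration
predicts every sentence with the current policy, prices every possible
action y_t by rolling out the remaining actions and measuring the
event-level loss ℓ = w_FP·FP + w_FN·FN (optionally *focused* on the part of
the output graph connected with the action), and trains a new per-stage
hypothesis h_new on those cost-sensitive examples, interpolating
h ← β·h_new + (1−β)·h.  During training the optimal policy acts with
probability (1−β)^(iteration−1).  The base learner is a multiclass
cost-sensitive passive-aggressive classifier (PA-II, prediction-based):

    ŷ = argmax_k w(k)·x,   y = argmin_k c(k)
    ℓ = w(ŷ)·x − w(y)·x + √c(ŷ),   τ = ℓ / (‖x‖² + 1/(2C))
    w(y) += τ·x,   w(ŷ) −= τ·x

with per-round shuffling and averaged weights.  Setting β = 1, dropping the
structural features and using 0/1 costs makes SEARN collapse exactly onto
the independent pipeline, which keeps the comparison fair.  Raising w_FN
(or w_FP) steers the learned system toward recall (or precision) without
any score thresholding.  Feature augmentation (one domain-tagged copy of
every feature) adapts the model across the abstract and full-paper domains.

## Worked example

The package ships a demonstration sentence — *"SQ 22536 suppressed
gp41-induced IL-10 production in monocytes."* — whose gold annotation is the
nested chain `Negative_regulation(suppressed) → Positive_regulation(induced,
Cause gp41) → Gene_expression(production, Theme IL-10)`:

```python
>>> from eventsearn.worked_example import demo_trigger_costs
>>> demo_trigger_costs(focused=True)
{'production_as_negative_regulation': 6.0, 'sq_as_negative_regulation': 1.0}
```

These are second-iteration cost estimates for two trigger actions.  Labeling
the non-trigger "SQ" as `Negative_regulation` while the rollout attaches one
protein Theme to it creates one spurious event — cost **1.0**.  Mistyping
"production" as `Negative_regulation` while the rollout keeps the sentence's
argument structure corrupts all three nested events — 3 false positives plus
3 false negatives, cost **6.0**.  This is the signal that teaches the jointly
trained classifiers that some trigger mistakes are far more expensive than
others.

A full synthetic round trip from the shell:

```bash
eventsearn simulate --out corpus --n-docs 12 --sentences-per-doc 5 --p-nested 0.5 --seed 3
eventsearn train    --corpus corpus --model model --mode searn --beta 0.3 --iterations 2 --rounds 3 --seed 0
eventsearn predict  --model model --corpus corpus --out-dir pred
eventsearn evaluate --corpus corpus --pred pred
```

prints a per-type/per-class table ending in

```
Simple (TOTAL)       41   1   0  100.00      97.62   98.80
Binding              17   0   0  100.00     100.00  100.00
Regulation (TOTAL)   39   1   0  100.00      97.50   98.73
TOTAL                97   2   0  100.00      97.98   98.98
```

(TP/FP/FN, then recall, precision and F-score on the 0–100 scale).
`eventsearn sweep` re-runs prediction over a grid of negative-class score
offsets to trace recall-precision curves.

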