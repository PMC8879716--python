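# Methods

## Problem and model

The package predicts whether two drugs interact, given (a) a
multi-relational knowledge graph (KG) of biomedical triples in which
drugs appear as entities, (b) SMILES strings for a subset of the drugs,
and (c) a table of known interacting pairs. Prediction is binary link
prediction: no interaction *type* is modeled.

**Structural features.** SMILES are treated as plain character
sequences. Strings longer than 250 characters are excluded. A
vocabulary keeps the most frequent characters (frequency-descending,
ties by codepoint) up to a cap of 251 including one reserved
unknown slot; each drug becomes a count vector over that vocabulary,
with unseen characters pooled in the unknown slot. PCA (fitted only on
drugs that have SMILES, so zero rows cannot bias the mean) reduces the
counts to `d_struct` dimensions, 64 by default. Component signs follow
a fixed convention — the largest-magnitude loading on each axis is made
positive — so results are reproducible across runs and row orders.
Drugs without SMILES keep an all-zero structural row rather than being
dropped, so topology-only prediction still covers them. The character
cap of 251 reads the published preprocessing as a bag-of-characters
over a frequency-capped alphabet; a positional one-hot reading does not
compose with the downstream PCA step and was rejected.

**Topological features.** The KG is indexed undirected (aggregation
never uses edge direction; the relation label is kept on each edge),
with duplicate and reversed-duplicate triples collapsed and self-loops
dropped. Each drug's encoder input is a sampled receptive field: at
every hop each entity contributes exactly `sample_size` neighbors,
sampled without replacement when the degree allows and with replacement
otherwise, so tensor shapes are degree-independent
(`sample_size**h` entities at hop `h`). Isolated entities self-pad with
a reserved null relation. Sampling is driven by a stream keyed on
(global seed, entity id, hop): fields are bit-reproducible, identical
for repeated occurrences of an entity, and static across training
epochs — a deliberate choice that makes end-to-end runs exactly
repeatable; resampling per epoch would add variance without changing
the desk-scale conclusions.

Neighbor relevance is the softmax, over the sample axis, of inner
products between the *partner* drug's entity embedding (pair-conditioned
attention) and each edge's relation embedding. The weighted neighbor
mean `n` combines with the entity's own vector `v` by one of three
aggregators — `sum`: act(W(v+n)+b); `concat`: act(W[v‖n]+b); `neigh`:
act(Wn+b) — applied for two hops, rectifier inside, tanh on the final
hop. Defaults: two hops, `sample_size` 8, `concat`, 32-d embeddings.
Entity/relation embeddings initialize uniform in [−0.05, 0.05], layer
weights Glorot-uniform, biases zero.

**Fusion and scoring.** Comprehensive features are
`tanh((A+B)W+b)` (sum; requires `d_struct == d_topo`) or
`tanh([A‖B]W+b)` (concat; any widths, output width `d_topo`). The pair
score is the sigmoid of the inner product of the two fused vectors; a
score strictly above 0.5 is called an interaction (exactly 0.5 is not).
The loss is binary cross-entropy summed over pairs, with probabilities
clipped at 1e−7 where probabilities are handled directly; training uses
the numerically stable logits form and per-batch means for optimizer
scaling.

## Training

There is no deep-learning framework dependency: a ~250-line
reverse-mode autodiff engine over numpy arrays (`smilegnn._autodiff`)
supplies gradients for the gather/attention/linear/tanh graph, and its
correctness is pinned by finite-difference tests. The optimizer is
adaptive-moment gradient descent (Adam, β = 0.9/0.999) with a small
weight decay (1e−6). Negatives are uniform unordered non-positive pairs
at a 1:1 ratio. Desk-scale training defaults — batch 256, learning rate
2e−2, 25 epochs — were chosen by pilot runs on the synthetic benchmark
before the evaluation thresholds were run; the two published
hyperparameter regimes (batch 2048 / lr 2e−2 / 32-d and batch 1024 /
lr 1e−2 / 64-d) ship as YAML presets. Divergence (non-finite loss)
aborts with a diagnostic rather than silently continuing.

Evaluation is stratified k-fold (default 5) over pairs; a fold whose
held-out split is single-class is skipped with a warning. AUC is the
rank statistic (`sklearn.metrics.roc_auc_score`), F1 the positive-class
score at the strict 0.5 threshold; the test suite re-derives AUC by
brute-force concordant-pair counting. Grid search evaluates every
configuration by cross-validated mean AUC, breaking ties by higher F1
and then smaller embedding dimension. Novel-pair ranking scores all
candidate pairs, removes known positives, keeps scores strictly above
the threshold (default 0.9) and sorts non-increasing, ties broken by
drug id for determinism.

## Synthetic benchmark

`smilegnn.synthetic_data` generates the entire study so nothing
external is downloaded. Drugs (DrugBank-style `DB…` ids) and non-drug
entities are wired into a clustered multi-relational graph: the edge
budget is `mean_degree × n_nodes / 2`, every drug gets at least one
edge, and a drug's edges stay inside its latent cluster's entity block
with probability 0.9. SMILES-like strings (5–250 characters over a
29-symbol alphabet) are drawn from per-cluster character-frequency
profiles for 72% of drugs, mirroring the structure-record coverage of
the denser published regime. Positives are planted by an explicit
generative mechanism recorded in the ground truth: with probability
`signal_strength` a positive is either two drugs adjacent to a shared
KG entity (topology) or a pair whose character-count cosine lies above
the corpus's 0.88 quantile (structure); otherwise it is uniform random.
`signal_mode=none` makes all positives random — the null model.

Defaults (200 drugs, 400 entities, positive rate 0.1) were calibrated
once, by pilot, so that the desk-scale model has enough interactions
per drug (~20) to generalize rather than memorize: at the published
interaction-subgraph density of 0.033 a 200-drug graph carries only
~6–7 interactions per drug, an order of magnitude fewer than the real
corpora the method was designed for, and held-out performance collapses
to memorization. The structure-similarity quantile must leave the
similar-pair pool larger than the number of structure-mechanism draws,
or draws fall back to random and dilute the signal.

What the generator does *not* emulate: chemically valid molecules
(strings only exercise the character-level featurizer), relation
semantics (relations are uniform labels), degree heavy tails,
and the label noise of real interaction databases (real "negatives"
include unrecorded true interactions). Passing the synthetic benchmark
therefore shows that the implementation can recover a planted
structural/topological signal at desk scale — not that it reproduces
published headline metrics, which require the original large KGs.

## Numerical and design choices

* Probability clip 1e−7 in the direct-probability loss; stable
  logits-form loss in training.
* Scores are clipped away from exactly 0/1 when reported (float
  sigmoid saturates beyond |logit| ≈ 37).
* Density is reported at 4 significant figures, matching the published
  table format; the whole-KG density cells of that table are not
  reproducible from printed counts and are out of scope.
* Duplicate triples and self-loops are dropped with a logged count.
* Drug entities are recognized by a configurable prefix rule (default
  `DB`) or an explicit predicate.
* The n-quads reader is a line-oriented subset parser
  (`<iri> <iri> <iri|literal> <iri> .`, 4th term discarded) that counts
  malformed lines against a 5% threshold instead of aborting on the
  first error, and accepts relative IRIs; both behaviors are required
  by the input contract and are not provided by W3C-strict RDF
  parsers.
* Ranking ties and vocabulary ties have deterministic order (score
  then ids; frequency then codepoint).

## Known limitations

* Pair-conditioned attention makes a drug's embedding depend on its
  partner, so embeddings are not cacheable per drug; scoring all
  `O(n²)` candidate pairs is quadratic in drugs.
* Static receptive fields trade sampling diversity for exact
  reproducibility; on large graphs with high-degree hubs this can
  under-expose rare neighbors.
* The structural channel is character-composition only — no
  ring/branch grammar, no 3-D information — by design.
* Negative "labels" are unrecorded pairs, so reported metrics inherit
  the usual open-world bias of interaction databases.
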