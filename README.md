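# smilegnn

Drug–drug interaction (DDI) prediction that fuses two complementary views
of a drug: its **structure**, read off the SMILES string as a
character-composition vector, and its **topology**, learned from the
neighborhood of the drug in a biomedical knowledge graph (KG).

Concurrent prescriptions interact far more often than databases record,
and screening every pair in the lab is infeasible. Treating DDI
prediction as link prediction over known interaction records lets a
model propose high-confidence novel pairs for manual review. Structure
alone misses drugs that act through shared pathways; topology alone
misses drugs that are poorly connected in the KG (and many drugs lack
either a structure record or rich KG context). This package implements
the fused approach for researchers who want a self-contained,
CPU-friendly reference implementation with a fully synthetic benchmark —
no external database downloads.

## Model

Each drug *i* gets two vectors:

* **Structural** `B_i`: the SMILES string (≤ 250 characters; longer
  records are excluded) is counted into a bag-of-characters vector over
  a frequency-capped vocabulary (default 251 symbols including a
  reserved unknown slot), then PCA-reduced to `d_struct` dimensions
  (default 64). Drugs without a SMILES record keep a zero row.
* **Topological** `A_i`: a graph neural encoder aggregates a sampled
  receptive field within two hops of the drug. Each entity keeps a
  fixed-width sample of neighbors (`sample_size` per hop, with
  replacement below degree); a neighbor's weight is the softmax of the
  inner product between the partner drug's embedding and the edge's
  relation embedding; self and neighborhood combine through one of
  three aggregators — `sum`: σ(W(v + n) + b), `concat`: σ(W[v‖n] + b),
  `neigh`: σ(Wn + b) — with a rectifier on the inner hop and tanh on
  the final hop.

The **comprehensive feature** fuses the two, by elementwise sum
(`tanh((A + B)W + b)`, requires matching dimensions) or concatenation
(`tanh([A‖B]W + b)`, any dimensions). A pair's score is
`σ(f_i · f_j) ∈ (0, 1)`; an interaction is called when the score
strictly exceeds 0.5. Training minimizes the binary cross-entropy
`Σ −[y log ŷ + (1−y) log(1−ŷ)]` over labeled pairs, with negatives drawn
uniformly from unrecorded pairs at a 1:1 ratio. Evaluation reports
accuracy, rank-statistic AUC and F1 under stratified k-fold
cross-validation. Because no deep-learning framework is required, the
model trains through a small reverse-mode autodiff engine on numpy
arrays (`smilegnn._autodiff`), whose gradients are verified against
finite differences in the test suite.

## Worked example

```python
from smilegnn import (SimulationConfig, TrainConfig, simulate, index_graph,
                      build_structural_features, evaluate_cv, train,
                      rank_novel_pairs, ddi_subgraph_density)

cfg = SimulationConfig(n_drugs=80, n_other_entities=160, seed=11)
ds = simulate(cfg, out_dir="data")      # triples.tsv, smiles.tsv, pairs.tsv
kg = index_graph(ds.triples)
print("entities:", kg.n_entities, "edges:", kg.n_edges)
print("DDI subgraph density:", ddi_subgraph_density(ds.pairs, kg).formatted(4))

drugs = [kg.entities[i] for i in kg.drug_ids]
struct = build_structural_features(ds.smiles, drugs, d_struct=32, seed=11)
tc = TrainConfig(embed_dim=32, d_struct=32, epochs=20, seed=11)
metrics = evaluate_cv(kg, struct, ds.pairs, tc)
print("5-fold  ACC %.4f  AUC %.4f  F1 %.4f"
      % (metrics.accuracy, metrics.auc, metrics.f1))

model = train(kg, struct, ds.pairs, tc)
cands = [(a, b) for i, a in enumerate(sorted(drugs)) for b in sorted(drugs)[i+1:]]
for p in rank_novel_pairs(model, cands, ds.pairs, threshold=0.9, top_k=5).pairs:
    print(p.drug1_id, p.drug2_id, f"{p.score:.6f}")
```

prints

```
entities: 240 edges: 951
DDI subgraph density: 1.000e-01
5-fold  ACC 0.7785  AUC 0.8911  F1 0.8032
DB00038 DB00052 1.000000
DB00041 DB00061 1.000000
DB00028 DB00071 1.000000
DB00013 DB00044 1.000000
DB00013 DB00041 1.000000
```

The density line is the interaction subgraph's `2L/(N(N−1))` — here 80
drugs and 316 positive pairs. The cross-validated AUC of ~0.89 shows
the model recovering the generator's planted signal (pairs that share
KG neighbors or have similar character composition are more likely to
interact); the final lines are the highest-scoring pairs *not* in the
training positives, the candidates one would take to manual review.

The same workflow is available from the shell:

```bash
smilegnn simulate --seed 11 --out data/
smilegnn density  --triples data/triples.tsv --pairs data/pairs.tsv
smilegnn evaluate --triples data/triples.tsv --smiles data/smiles.tsv \
                  --pairs data/pairs.tsv --seed 11
smilegnn rank     --triples data/triples.tsv --smiles data/smiles.tsv \
                  --pairs data/pairs.tsv --threshold 0.9 --top-k 10 \
                  --out ranked.tsv
```

Presets mirroring the two published hyperparameter regimes ship in
`src/smilegnn/presets/` (`kegg.yaml`: batch 2048, lr 2e-2, 32-d
embeddings; `pdd.yaml`: batch 1024, lr 1e-2, 64-d embeddings) and can be
passed to any subcommand via `--config`.

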