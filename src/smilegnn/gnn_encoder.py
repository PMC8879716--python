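"""Topological drug embeddings from a sampled two-hop receptive field.

Each drug's embedding is computed by repeatedly aggregating a
fixed-width sampled neighborhood (KGNN-style): hop h holds
``sample_size**h`` entities, neighbors are weighted by a softmax over
inner products between the *partner* drug's embedding and each edge's
relation embedding, and three aggregators (sum / concat / neigh) combine
self and neighborhood information.  Inner layers use a rectifier, the
final layer tanh, so outputs live in (-1, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat, constant, parameter, softmax
from .knowledge_graph import KnowledgeGraph

AGGREGATORS = ("sum", "concat", "neigh")

__all__ = [
    "GnnParameters",
    "ReceptiveField",
    "FieldTable",
    "TopologicalEmbedding",
    "init_gnn_params",
    "sample_receptive_field",
    "build_field_table",
    "relation_attention",
    "aggregate_layer",
    "encode_batch",
    "encode_topology",
]


@dataclass
class TopologicalEmbedding:
    """Per-drug GNN output vectors, row-aligned with `drug_ids`."""

    drug_ids: list[str]
    vectors: np.ndarray  # (n_drugs, d_topo)

    def __post_init__(self):
        if self.vectors.shape[0] != len(self.drug_ids):
            raise ValueError("vectors must align with drug_ids")
        if not np.isfinite(self.vectors).all():
            raise ValueError("non-finite embedding values")


@dataclass
class GnnParameters:
    """Trainable state of the topological encoder.

    relation_embeddings has ``n_relations + 1`` rows; the extra final row
    is the reserved null relation used to self-pad isolated entities.
    """

    entity_embeddings: Tensor
    relation_embeddings: Tensor
    weights: list[Tensor]  # one per hop/layer
    biases: list[Tensor]
    n_hops: int
    sample_size: int
    aggregator_type: str
    d_topo: int

    def trainable(self) -> list[Tensor]:
        return [self.entity_embeddings, self.relation_embeddings,
                *self.weights, *self.biases]


def init_gnn_params(kg: KnowledgeGraph, d_topo: int = 32, n_hops: int = 2,
                    sample_size: int = 8, aggregator_type: str = "concat",
                    seed: int = 0) -> GnnParameters:
    """Embeddings uniform in [-0.05, 0.05]; layer weights Glorot-uniform."""
    if aggregator_type not in AGGREGATORS:
        raise ValueError(f"unknown aggregator {aggregator_type!r}; choose from {AGGREGATORS}")
    if sample_size < 1 or n_hops < 1:
        raise ValueError("sample_size and n_hops must be >= 1")
    rng = np.random.default_rng(seed)
    ent = parameter(rng.uniform(-0.05, 0.05, size=(kg.n_entities, d_topo)))
    rel = parameter(rng.uniform(-0.05, 0.05, size=(kg.n_relations + 1, d_topo)))
    in_dim = 2 * d_topo if aggregator_type == "concat" else d_topo
    weights, biases = [], []
    for _ in range(n_hops):
        limit = np.sqrt(6.0 / (in_dim + d_topo))
        weights.append(parameter(rng.uniform(-limit, limit, size=(in_dim, d_topo))))
        biases.append(parameter(np.zeros(d_topo)))
    return GnnParameters(entity_embeddings=ent, relation_embeddings=rel,
                         weights=weights, biases=biases, n_hops=n_hops,
                         sample_size=sample_size, aggregator_type=aggregator_type,
                         d_topo=d_topo)


@dataclass
class ReceptiveField:
    """Sampled neighborhood layers for one seed entity.

    entities[h] has shape (sample_size**h,); relations[h] aligns with
    entities[h] and holds the relation on the edge from the hop-(h-1)
    parent (relations[0] is None — hop 0 is the seed itself).
    """

    entities: list[np.ndarray]
    relations: list[np.ndarray | None]


def _sample_children(kg: KnowledgeGraph, entity: int, sample_size: int,
                     rng_seed: int, hop: int) -> tuple[np.ndarray, np.ndarray]:
    adj = kg.adjacency[entity]
    if len(adj) == 0:
        # isolated entity: self-padding with the reserved null relation
        return (np.full(sample_size, entity, dtype=np.int64),
                np.full(sample_size, kg.null_relation, dtype=np.int64))
    # per-(seed, entity, hop) stream so repeated occurrences sample alike
    rng = np.random.default_rng([rng_seed, entity, hop])
    idx = rng.choice(len(adj), size=sample_size, replace=len(adj) < sample_size)
    return adj[idx, 0].copy(), adj[idx, 1].copy()


def sample_receptive_field(kg: KnowledgeGraph, seed_entity: int, n_hops: int,
                           sample_size: int, rng_seed: int) -> ReceptiveField:
    """Fixed-width sampled neighborhood, deterministic given `rng_seed`."""
    if not 0 <= seed_entity < kg.n_entities:
        raise KeyError(f"entity id {seed_entity} not in graph "
                       f"(0..{kg.n_entities - 1})")
    entities = [np.array([seed_entity], dtype=np.int64)]
    relations: list[np.ndarray | None] = [None]
    for hop in range(1, n_hops + 1):
        parents = entities[-1]
        child_e = np.empty(len(parents) * sample_size, dtype=np.int64)
        child_r = np.empty_like(child_e)
        for i, p in enumerate(parents):
            e, r = _sample_children(kg, int(p), sample_size, rng_seed, hop)
            child_e[i * sample_size:(i + 1) * sample_size] = e
            child_r[i * sample_size:(i + 1) * sample_size] = r
        entities.append(child_e)
        relations.append(child_r)
    return ReceptiveField(entities=entities, relations=relations)


@dataclass
class FieldTable:
    """Stacked receptive fields for a list of seed entities.

    entities[h] has shape (n_seeds, sample_size**h); row order follows
    `seed_ids`.  Used to gather per-pair fields cheaply during training.
    """

    seed_ids: np.ndarray
    entities: list[np.ndarray]
    relations: list[np.ndarray | None]
    row_of: dict[int, int]

    def rows(self, seed_entities: np.ndarray) -> np.ndarray:
        return np.array([self.row_of[int(e)] for e in seed_entities])


def build_field_table(kg: KnowledgeGraph, seed_entities, n_hops: int,
                      sample_size: int, rng_seed: int) -> FieldTable:
    seed_entities = np.asarray(seed_entities, dtype=np.int64)
    fields = [sample_receptive_field(kg, int(e), n_hops, sample_size, rng_seed)
              for e in seed_entities]
    entities = [np.stack([f.entities[h] for f in fields])
                for h in range(n_hops + 1)]
    relations: list[np.ndarray | None] = [None]
    relations += [np.stack([f.relations[h] for f in fields])
                  for h in range(1, n_hops + 1)]
    return FieldTable(seed_ids=seed_entities, entities=entities,
                      relations=relations,
                      row_of={int(e): i for i, e in enumerate(seed_entities)})


def _attention_weights(query: Tensor, rel_vecs: Tensor) -> Tensor:
    """Softmax over the trailing neighbor axis of query·relation scores.

    query: (m, d); rel_vecs: (m, P, s, d) -> weights (m, P, s).
    """
    m, d = query.shape
    q = query.reshape(m, 1, 1, d)
    scores = (q * rel_vecs).sum(axis=-1)
    return softmax(scores, axis=-1)


def relation_attention(query_drug_vec: np.ndarray, relation_ids: np.ndarray,
                       params: GnnParameters) -> np.ndarray:
    """Neighbor weights for one query drug: softmax_k(query · r_k).

    relation_ids may have any shape (..., sample_size); weights sum to 1
    along the last axis.
    """
    rel = params.relation_embeddings.data[np.asarray(relation_ids)]
    scores = rel @ np.asarray(query_drug_vec, dtype=float)
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _aggregate(self_v: Tensor, summary: Tensor, W: Tensor, b: Tensor,
               aggregator_type: str, activation: str) -> Tensor:
    if aggregator_type == "sum":
        x = self_v + summary
    elif aggregator_type == "concat":
        x = concat([self_v, summary], axis=-1)
    elif aggregator_type == "neigh":
        x = summary
    else:
        raise ValueError(f"unknown aggregator {aggregator_type!r}; choose from {AGGREGATORS}")
    z = x.matmul(W) + b
    if activation == "relu":
        return z.relu()
    if activation == "tanh":
        return z.tanh()
    if activation == "linear":
        return z
    raise ValueError(f"unknown activation {activation!r}")


def aggregate_layer(self_vecs: np.ndarray, neighbor_summary: np.ndarray,
                    W: np.ndarray, b: np.ndarray, aggregator_type: str,
                    activation: str = "tanh") -> np.ndarray:
    """One aggregation step on plain arrays (shares math with training)."""
    out = _aggregate(constant(self_vecs), constant(neighbor_summary),
                     constant(W), constant(b), aggregator_type, activation)
    return out.data


def encode_batch(table: FieldTable, seed_entities: np.ndarray,
                 query_entities: np.ndarray, params: GnnParameters) -> Tensor:
    """Encode a batch of seeds, attention conditioned on `query_entities`.

    Returns an autodiff Tensor of shape (m, d_topo); gradients flow into
    every GnnParameters tensor.
    """
    m = len(seed_entities)
    s, H, d = params.sample_size, params.n_hops, params.d_topo
    rows = table.rows(seed_entities)
    E, R = params.entity_embeddings, params.relation_embeddings

    q = E.take(np.asarray(query_entities, dtype=np.int64))  # (m, d)
    vs = [E.take(table.entities[h][rows]) for h in range(H + 1)]
    rel_ids = [None] + [table.relations[h][rows] for h in range(1, H + 1)]

    for layer in range(1, H + 1):
        activation = "tanh" if layer == H else "relu"
        W, b = params.weights[layer - 1], params.biases[layer - 1]
        new_vs = []
        for h in range(H - layer + 1):
            P = s ** h
            nbr_v = vs[h + 1].reshape(m, P, s, d)
            rel_v = R.take(rel_ids[h + 1]).reshape(m, P, s, d)
            alpha = _attention_weights(q, rel_v)            # (m, P, s)
            summary = (alpha.reshape(m, P, s, 1) * nbr_v).sum(axis=2)
            new_vs.append(_aggregate(vs[h], summary, W, b,
                                     params.aggregator_type, activation))
        vs = new_vs
    return vs[0].reshape(m, d)


def encode_topology(kg: KnowledgeGraph, drug_pair: tuple[str, str],
                    params: GnnParameters, rng_seed: int
                    ) -> tuple[TopologicalEmbedding, TopologicalEmbedding]:
    """Pair-conditioned embeddings for both drugs of a pair.

    Each drug aggregates its own sampled receptive field; the attention
    query is the partner drug's entity embedding.
    """
    ids = [kg.resolve_drug(d) for d in drug_pair]
    table = build_field_table(kg, ids, params.n_hops, params.sample_size, rng_seed)
    seeds = np.array(ids)
    queries = seeds[::-1].copy()
    out = encode_batch(table, seeds, queries, params).data
    return (TopologicalEmbedding(drug_ids=[drug_pair[0]], vectors=out[:1]),
            TopologicalEmbedding(drug_ids=[drug_pair[1]], vectors=out[1:]))
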