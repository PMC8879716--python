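"""Receptive-field sampling and the layered neighborhood aggregation."""

import numpy as np
import pytest

from smilegnn.gnn_encoder import (aggregate_layer, build_field_table,
                                  encode_batch, encode_topology,
                                  init_gnn_params, relation_attention,
                                  sample_receptive_field)
from smilegnn.knowledge_graph import Triple, index_graph


def star_kg(n_leaves=3):
    return index_graph([Triple("DBc", f"r{i}", f"E{i}") for i in range(n_leaves)])


class TestSampling:
    def test_star_center_hop1_equals_neighbors(self):
        kg = star_kg(3)
        f = sample_receptive_field(kg, kg.entity_index["DBc"], n_hops=1,
                                   sample_size=3, rng_seed=0)
        leaves = {kg.entity_index[f"E{i}"] for i in range(3)}
        assert set(f.entities[1]) == leaves  # without replacement at degree == size

    def test_low_degree_samples_with_replacement(self):
        kg = index_graph([Triple("DBa", "r", "E1")])
        f = sample_receptive_field(kg, kg.entity_index["DBa"], 1, 4, rng_seed=0)
        assert np.all(f.entities[1] == kg.entity_index["E1"])
        assert len(f.entities[1]) == 4

    def test_deterministic_given_seed(self):
        kg = star_kg(6)
        e = kg.entity_index["DBc"]
        f1 = sample_receptive_field(kg, e, 2, 3, rng_seed=42)
        f2 = sample_receptive_field(kg, e, 2, 3, rng_seed=42)
        for h in range(3):
            np.testing.assert_array_equal(f1.entities[h], f2.entities[h])

    def test_shapes_are_degree_independent(self):
        kg = star_kg(5)
        for s in (2, 4, 7):
            f = sample_receptive_field(kg, 0, 2, s, rng_seed=1)
            assert [len(a) for a in f.entities] == [1, s, s * s]

    def test_isolated_entity_self_pads_with_null_relation(self):
        kg = index_graph([Triple("DBa", "r", "E1"), Triple("DBb", "r", "E2")])
        # make an isolated node by pointing at an entity with one edge removed:
        # instead, sample from a degree-0 view via a fresh graph is impossible
        # (every parsed entity has an edge), so check the padding path directly
        kg.adjacency[0] = np.empty((0, 2), dtype=np.int64)
        f = sample_receptive_field(kg, 0, 1, 3, rng_seed=0)
        assert np.all(f.entities[1] == 0)
        assert np.all(f.relations[1] == kg.null_relation)

    def test_unknown_entity_raises(self):
        with pytest.raises(KeyError):
            sample_receptive_field(star_kg(), 99, 1, 2, rng_seed=0)


class TestAttention:
    def test_equal_relations_give_uniform_weights(self):
        kg = star_kg(4)
        params = init_gnn_params(kg, d_topo=8, seed=0)
        params.relation_embeddings.data[:] = 1.0
        w = relation_attention(np.ones(8), np.array([0, 1, 2, 3]), params)
        np.testing.assert_allclose(w, 0.25)

    def test_weights_sum_to_one(self):
        kg = star_kg(4)
        params = init_gnn_params(kg, d_topo=8, seed=1)
        rng = np.random.default_rng(0)
        w = relation_attention(rng.normal(size=8),
                               rng.integers(0, 4, size=(5, 6)), params)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0)

    def test_dominant_relation_takes_all_weight(self):
        kg = star_kg(3)
        params = init_gnn_params(kg, d_topo=4, seed=2)
        params.relation_embeddings.data[:] = 0.0
        params.relation_embeddings.data[1] = 50.0  # margin 50 on a unit query
        w = relation_attention(np.array([1.0, 0, 0, 0]), np.array([0, 1, 2]), params)
        assert w[1] > 1 - 1e-8


class TestAggregateLayer:
    def test_neigh_ignores_self_vectors(self):
        rng = np.random.default_rng(3)
        W, b = rng.normal(size=(4, 4)), rng.normal(size=4)
        summary = rng.normal(size=(5, 4))
        out1 = aggregate_layer(rng.normal(size=(5, 4)), summary, W, b, "neigh")
        out2 = aggregate_layer(rng.normal(size=(5, 4)), summary, W, b, "neigh")
        np.testing.assert_array_equal(out1, out2)

    def test_sum_identity_reduction(self):
        self_v = np.random.default_rng(4).normal(size=(3, 4))
        out = aggregate_layer(self_v, np.zeros((3, 4)), np.eye(4), np.zeros(4),
                              "sum", activation="linear")
        np.testing.assert_allclose(out, self_v)

    def test_concat_halves_width(self):
        rng = np.random.default_rng(5)
        out = aggregate_layer(rng.normal(size=(2, 6)), rng.normal(size=(2, 6)),
                              rng.normal(size=(12, 6)), np.zeros(6), "concat")
        assert out.shape == (2, 6)

    def test_unknown_aggregator_rejected(self):
        with pytest.raises(ValueError, match="aggregator"):
            aggregate_layer(np.zeros((1, 2)), np.zeros((1, 2)), np.eye(2),
                            np.zeros(2), "mean")


class TestEncoding:
    def test_output_bounded_by_final_tanh(self, path_graph_kg):
        params = init_gnn_params(path_graph_kg, d_topo=6, sample_size=2, seed=0)
        e1, e2 = encode_topology(path_graph_kg, ("DB00001", "DB00002"), params, 0)
        for emb in (e1, e2):
            assert np.all(np.abs(emb.vectors) < 1.0)

    def test_bit_reproducible_under_fixed_seeds(self, path_graph_kg):
        params = init_gnn_params(path_graph_kg, d_topo=6, sample_size=2, seed=3)
        a1, _ = encode_topology(path_graph_kg, ("DB00001", "DB00002"), params, 5)
        a2, _ = encode_topology(path_graph_kg, ("DB00001", "DB00002"), params, 5)
        np.testing.assert_array_equal(a1.vectors, a2.vectors)

    def test_missing_drug_errors_with_id(self, path_graph_kg):
        params = init_gnn_params(path_graph_kg, d_topo=4, sample_size=2, seed=0)
        with pytest.raises(KeyError, match="DB99999"):
            encode_topology(path_graph_kg, ("DB00001", "DB99999"), params, 0)

    def test_two_hop_path_graph_matches_unrolled_oracle(self, path_graph_kg):
        """Hand-unrolled two-layer computation, scalar loops only."""
        kg = path_graph_kg
        s = 2  # max degree of the path
        params = init_gnn_params(kg, d_topo=5, n_hops=2, sample_size=s,
                                 aggregator_type="concat", seed=9)
        eid1, eid2 = kg.entity_index["DB00001"], kg.entity_index["DB00002"]
        table = build_field_table(kg, [eid1], 2, s, rng_seed=7)
        got = encode_batch(table, np.array([eid1]), np.array([eid2]), params).data[0]

        E = params.entity_embeddings.data
        R = params.relation_embeddings.data
        (W1, W2), (b1, b2) = [w.data for w in params.weights], [b.data for b in params.biases]
        q = E[eid2]
        field = sample_receptive_field(kg, eid1, 2, s, rng_seed=7)

        def att(rels):
            sc = np.array([R[r] @ q for r in rels])
            w = np.exp(sc - sc.max())
            return w / w.sum()

        def agg(self_v, nbrs, rels, W, b, act):
            w = att(rels)
            summary = sum(wi * vi for wi, vi in zip(w, nbrs))
            z = np.concatenate([self_v, summary]) @ W + b
            return np.maximum(z, 0) if act == "relu" else np.tanh(z)

        v0 = E[field.entities[0][0]]
        v1 = [E[e] for e in field.entities[1]]
        v2 = [E[e] for e in field.entities[2]]
        r1, r2 = field.relations[1], field.relations[2]
        new_v0 = agg(v0, v1, r1, W1, b1, "relu")
        new_v1 = [agg(v1[i], v2[i * s:(i + 1) * s], r2[i * s:(i + 1) * s],
                      W1, b1, "relu") for i in range(s)]
        expected = agg(new_v0, new_v1, r1, W2, b2, "tanh")
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_neigh_one_hop_output_independent_of_own_embedding(self, path_graph_kg):
        kg = path_graph_kg
        params = init_gnn_params(kg, d_topo=4, n_hops=1, sample_size=2,
                                 aggregator_type="neigh", seed=1)
        eid = kg.entity_index["DB00001"]
        table = build_field_table(kg, [eid], 1, 2, rng_seed=0)
        qid = np.array([kg.entity_index["DB00002"]])
        before = encode_batch(table, np.array([eid]), qid, params).data.copy()
        params.entity_embeddings.data[eid] += 10.0  # perturb the drug itself
        after = encode_batch(table, np.array([eid]), qid, params).data
        np.testing.assert_array_equal(before, after)

    def test_neigh_and_sum_genuinely_differ(self, path_graph_kg):
        kg = path_graph_kg
        out = {}
        for agg in ("neigh", "sum"):
            params = init_gnn_params(kg, d_topo=4, sample_size=2,
                                     aggregator_type=agg, seed=2)
            e1, _ = encode_topology(kg, ("DB00001", "DB00002"), params, 0)
            out[agg] = e1.vectors
        assert not np.allclose(out["neigh"], out["sum"])

    def test_relabeling_equivariance_on_regular_graph(self):
        """Entity relabeling (with embeddings carried along) leaves a
        drug's embedding unchanged on a graph where sampling is
        exhaustive (cycle, degree == sample_size)."""
        names = [f"DB{i}" for i in range(6)]
        triples = [Triple(names[i], "r", names[(i + 1) % 6]) for i in range(6)]
        kg1 = index_graph(triples)
        kg2 = index_graph(triples[::-1])  # different first-appearance order
        params1 = init_gnn_params(kg1, d_topo=4, n_hops=2, sample_size=2, seed=0)
        params2 = init_gnn_params(kg2, d_topo=4, n_hops=2, sample_size=2, seed=0)
        # carry embeddings across the relabeling
        for name in names:
            params2.entity_embeddings.data[kg2.entity_index[name]] = \
                params1.entity_embeddings.data[kg1.entity_index[name]]
        a1, _ = encode_topology(kg1, ("DB0", "DB3"), params1, 0)
        a2, _ = encode_topology(kg2, ("DB0", "DB3"), params2, 0)
        np.testing.assert_allclose(a1.vectors, a2.vectors, atol=1e-12)
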