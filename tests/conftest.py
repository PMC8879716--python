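import numpy as np
import pytest

from smilegnn import (SimulationConfig, SmileGNNClassifier, TrainConfig,
                      build_structural_features, index_graph, simulate)
from smilegnn.knowledge_graph import Triple


@pytest.fixture(scope="session")
def tiny_sim():
    """Small planted-signal synthetic study shared by training tests."""
    cfg = SimulationConfig(n_drugs=40, n_other_entities=80, seed=3)
    ds = simulate(cfg)
    kg = index_graph(ds.triples)
    drugs = [kg.entities[i] for i in kg.drug_ids]
    struct = build_structural_features(ds.smiles, drugs, d_struct=16, seed=3)
    return ds, kg, struct


@pytest.fixture(scope="session")
def tiny_model(tiny_sim):
    """A quickly trained model over the tiny synthetic study."""
    ds, kg, struct = tiny_sim
    X = np.array([(a, b) for a, b, _ in ds.pairs.pairs], dtype=object)
    clf = SmileGNNClassifier(kg=kg, struct_features=struct, embed_dim=16,
                             sample_size=4, epochs=10, batch_size=128, seed=3)
    clf.fit(X, ds.pairs.labels())
    return clf


@pytest.fixture(scope="session")
def tiny_config():
    return TrainConfig(embed_dim=16, d_struct=16, sample_size=4, epochs=5,
                       batch_size=128, n_folds=2, seed=3)


@pytest.fixture()
def path_graph_kg():
    """Seven-node path DB00001 - E1 - E2 - E3 - E4 - E5 - DB00002."""
    names = ["DB00001", "E1", "E2", "E3", "E4", "E5", "DB00002"]
    triples = [Triple(names[i], f"r{i % 2}", names[i + 1]) for i in range(6)]
    return index_graph(triples)
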