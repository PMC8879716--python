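"""Self-contained synthetic inputs: KG triples, SMILES-like strings, DDI labels.

The generator emulates the shape of real drug knowledge bases: drug
entities (DrugBank-style ``DB…`` ids) wired to non-drug entities in a
clustered multi-relational graph, character strings over a SMILES-like
alphabet whose character-frequency profiles carry latent cluster
structure, and labeled drug pairs whose positives are planted by an
explicit generative mechanism (shared KG neighbor, structural
similarity, or pure chance), so ground truth is exactly known.

Default sizes mirror the denser of the two regimes the method targets:
72% of drugs carry a structure record and the interaction subgraph has
density ≈ 0.033.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fusion_predictor import DrugPairDataset
from .knowledge_graph import KnowledgeGraph, Triple, index_graph, write_triples
from .smiles_features import SmilesRecord, build_char_vocabulary, encode_smiles

SIGNAL_MODES = ("topology", "structure", "both", "none")

# characters available to the random string generator
SMILES_ALPHABET = "CNOSPFIcnos123456789=#()[]@+-"

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate_kg",
           "simulate_smiles", "plant_ddi_labels", "simulate"]


@dataclass(frozen=True)
class SimulationConfig:
    n_drugs: int = 200
    n_other_entities: int = 400
    n_relations: int = 8
    mean_degree: int = 8
    smiles_fraction: float = 0.72
    positive_rate: float = 0.1
    signal_mode: str = "both"
    signal_strength: float = 1.0
    n_clusters: int = 5
    within_cluster_p: float = 0.9  # chance a drug edge stays in its cluster
    structure_similarity_quantile: float = 0.88
    seed: int = 0

    def __post_init__(self):
        if self.signal_mode not in SIGNAL_MODES:
            raise ValueError(f"signal_mode must be one of {SIGNAL_MODES}")
        for name in ("smiles_fraction", "positive_rate", "signal_strength",
                     "within_cluster_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_drugs", "n_other_entities", "n_relations",
                     "mean_degree", "n_clusters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticDataset:
    triples: list[Triple]
    smiles: list[SmilesRecord]
    pairs: DrugPairDataset
    truth: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_triples(self.triples, out / "triples.tsv")
        with open(out / "smiles.tsv", "w", encoding="utf-8") as fh:
            fh.write("drug_id\tsmiles\n")
            for rec in self.smiles:
                fh.write(f"{rec.drug_id}\t{rec.smiles}\n")
        self.pairs.to_tsv(out / "pairs.tsv")
        (out / "truth.json").write_text(json.dumps(self.truth, indent=1))


def _drug_name(i: int) -> str:
    return f"DB{i + 1:05d}"


def _entity_name(i: int) -> str:
    return f"ENT{i + 1:05d}"


def _kg_plan(config: SimulationConfig):
    """Deterministic wiring plan shared by simulate_kg and the truth record."""
    rng = np.random.default_rng([config.seed, 1])
    drug_cluster = rng.integers(config.n_clusters, size=config.n_drugs)
    # non-drug entities partitioned evenly across clusters
    entity_cluster = np.arange(config.n_other_entities) * config.n_clusters \
        // config.n_other_entities
    return rng, drug_cluster, entity_cluster


def simulate_kg(config: SimulationConfig) -> list[Triple]:
    """Random clustered multi-relational graph over drugs + other entities.

    Total edge budget is mean_degree × n_nodes / 2; every drug gets at
    least one edge, and a drug edge lands inside its cluster's entity
    block with probability `within_cluster_p`.
    """
    n_total = config.n_drugs + config.n_other_entities
    n_edges = round(config.mean_degree * n_total / 2)
    if n_edges < config.n_drugs:
        raise ValueError(
            f"mean_degree {config.mean_degree} cannot give every one of "
            f"{config.n_drugs} drugs an edge (budget {n_edges})")
    rng, drug_cluster, entity_cluster = _kg_plan(config)
    cluster_entities = [np.flatnonzero(entity_cluster == c)
                       for c in range(config.n_clusters)]

    n_drug_edges = max(config.n_drugs, round(0.75 * n_edges))
    n_ee_edges = n_edges - n_drug_edges

    # each drug owns one guaranteed edge; the rest go to random drugs
    drug_of_edge = np.concatenate([
        np.arange(config.n_drugs),
        rng.integers(config.n_drugs, size=n_drug_edges - config.n_drugs),
    ])
    triples: list[Triple] = []
    for d in drug_of_edge:
        own = cluster_entities[drug_cluster[d]]
        if len(own) and rng.random() < config.within_cluster_p:
            tail = int(rng.choice(own))
        else:
            tail = int(rng.integers(config.n_other_entities))
        rel = int(rng.integers(config.n_relations))
        triples.append(Triple(_drug_name(int(d)), f"REL{rel}", _entity_name(tail)))
    for _ in range(n_ee_edges):
        a, b = rng.choice(config.n_other_entities, size=2, replace=False)
        rel = int(rng.integers(config.n_relations))
        triples.append(Triple(_entity_name(int(a)), f"REL{rel}", _entity_name(int(b))))
    return triples


def simulate_smiles(config: SimulationConfig) -> list[SmilesRecord]:
    """SMILES-like strings for a `smiles_fraction` subset of drugs.

    Drugs in the same latent cluster draw characters from the same
    frequency profile, giving the structural featurizer a learnable
    signal; strings are 5–250 characters, so all pass the length rule.
    """
    rng = np.random.default_rng([config.seed, 2])
    n_with = round(config.smiles_fraction * config.n_drugs)
    with_smiles = np.sort(rng.choice(config.n_drugs, size=n_with, replace=False))
    _, drug_cluster, _ = _kg_plan(config)
    alphabet = np.array(list(SMILES_ALPHABET))
    profiles = rng.dirichlet(np.full(len(alphabet), 0.4),
                             size=config.n_clusters)
    records = []
    for d in with_smiles:
        length = int(rng.integers(5, 251))
        chars = rng.choice(alphabet, size=length, p=profiles[drug_cluster[d]])
        records.append(SmilesRecord(_drug_name(int(d)), "".join(chars)))
    return records


def _structure_similar_pairs(smiles: list[SmilesRecord],
                             quantile: float) -> list[tuple[str, str]]:
    """Unordered pairs whose character-count cosine exceeds the given
    corpus quantile — the generative notion of 'structurally similar'."""
    if len(smiles) < 2:
        return []
    vocab = build_char_vocabulary(smiles)
    counts = np.stack([encode_smiles(r, vocab).counts for r in smiles]).astype(float)
    norms = np.linalg.norm(counts, axis=1)
    norms[norms == 0] = 1.0
    unit = counts / norms[:, None]
    cos = unit @ unit.T
    iu = np.triu_indices(len(smiles), k=1)
    threshold = np.quantile(cos[iu], quantile)
    ids = [r.drug_id for r in smiles]
    out = []
    for i, j in zip(*iu):
        if cos[i, j] >= threshold:
            a, b = ids[i], ids[j]
            out.append((min(a, b), max(a, b)))
    return out


def plant_ddi_labels(kg: KnowledgeGraph, smiles: list[SmilesRecord],
                     config: SimulationConfig
                     ) -> tuple[DrugPairDataset, dict]:
    """Labeled drug pairs with a recorded generative mechanism per positive.

    Each positive is drawn, with probability `signal_strength`, from a
    signal mechanism — *topology*: two drugs adjacent to a shared KG
    entity; *structure*: a structurally similar pair — and otherwise
    uniformly at random.  Negatives are uniform non-positive pairs at a
    1:1 ratio.  Mode ``none`` makes every positive random (null model).
    """
    rng = np.random.default_rng([config.seed, 3])
    drug_names = sorted(kg.entities[i] for i in kg.drug_ids)
    n_drugs = len(drug_names)
    n_pos = round(config.positive_rate * n_drugs * (n_drugs - 1) / 2)
    if n_pos < 1:
        raise ValueError("positive_rate too small: no positive pairs to plant")

    # entities adjacent to >= 2 drugs anchor the shared-neighbor mechanism
    drug_set = set(kg.drug_ids)
    hubs = []
    for eid in range(kg.n_entities):
        if eid in drug_set:
            continue
        dn = [int(n) for n, _ in kg.adjacency[eid] if int(n) in drug_set]
        if len(set(dn)) >= 2:
            hubs.append(sorted(set(dn)))
    struct_pool = _structure_similar_pairs(
        smiles, config.structure_similarity_quantile)
    rng.shuffle(struct_pool)
    struct_iter = iter(struct_pool)

    def random_pair() -> tuple[str, str]:
        a, b = rng.choice(n_drugs, size=2, replace=False)
        a, b = drug_names[int(a)], drug_names[int(b)]
        return (min(a, b), max(a, b))

    def topology_pair() -> tuple[str, str] | None:
        if not hubs:
            return None
        members = hubs[int(rng.integers(len(hubs)))]
        i, j = rng.choice(len(members), size=2, replace=False)
        a, b = kg.entities[members[int(i)]], kg.entities[members[int(j)]]
        return (min(a, b), max(a, b))

    positives: dict[tuple[str, str], str] = {}
    max_tries = 200 * n_pos
    tries = 0
    while len(positives) < n_pos and tries < max_tries:
        tries += 1
        mechanism = "random"
        if config.signal_mode != "none" and rng.random() < config.signal_strength:
            mode = config.signal_mode
            if mode == "both":
                mode = "topology" if rng.random() < 0.5 else "structure"
            if mode == "topology":
                pair = topology_pair()
                mechanism = "topology"
            else:
                pair = next(struct_iter, None)
                mechanism = "structure"
            if pair is None:  # mechanism pool exhausted; fall back
                pair, mechanism = random_pair(), "random"
        else:
            pair = random_pair()
        if pair not in positives:
            positives[pair] = mechanism
    if len(positives) < n_pos:
        raise ValueError(f"could not plant {n_pos} positive pairs "
                         f"(graph too small or rate too high)")

    max_pairs = n_drugs * (n_drugs - 1) // 2
    if 2 * n_pos > max_pairs:
        raise ValueError(f"positive_rate {config.positive_rate} leaves no room "
                         f"for 1:1 negatives among {max_pairs} pairs")
    negatives: set[tuple[str, str]] = set()
    while len(negatives) < n_pos:
        pair = random_pair()
        if pair not in positives and pair not in negatives:
            negatives.add(pair)

    pairs = [(a, b, 1) for a, b in positives]
    pairs += [(a, b, 0) for a, b in sorted(negatives)]
    truth = {
        "config": config.to_dict(),
        "mechanism": {f"{a}|{b}": m for (a, b), m in positives.items()},
        "n_structure_pool": len(struct_pool),
        "n_topology_hubs": len(hubs),
    }
    return DrugPairDataset(pairs=pairs), truth


def simulate(config: SimulationConfig,
             out_dir: str | Path | None = None) -> SyntheticDataset:
    """Full synthetic study: KG, SMILES table, labeled pairs, ground truth."""
    triples = simulate_kg(config)
    smiles = simulate_smiles(config)
    kg = index_graph(triples)
    pairs, truth = plant_ddi_labels(kg, smiles, config)
    _, drug_cluster, _ = _kg_plan(config)
    truth["drug_clusters"] = {_drug_name(i): int(c)
                              for i, c in enumerate(drug_cluster)}
    ds = SyntheticDataset(triples=triples, smiles=smiles, pairs=pairs, truth=truth)
    if out_dir is not None:
        ds.write(out_dir)
    return ds
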