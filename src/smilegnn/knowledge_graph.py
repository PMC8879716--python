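"""Multi-relational knowledge graph: triple parsing, indexing, density.

Triples arrive either as 3-column TSV (no header, ``#`` comments) or as
a line-oriented n-quads subset ``<iri> <iri> <iri|literal> <iri> .``
where the 4th (graph) term is discarded.  The indexed graph stores an
undirected adjacency view with the relation kept on every edge, which is
what the neighborhood-sampling encoder consumes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Triple",
    "KnowledgeGraph",
    "DensityReport",
    "TripleParseError",
    "parse_triples",
    "index_graph",
    "graph_density",
    "ddi_subgraph_density",
    "write_triples",
]


class TripleParseError(ValueError):
    """Raised when too many lines of a triple file are malformed."""


@dataclass(frozen=True)
class Triple:
    head: str
    relation: str
    tail: str

    def __post_init__(self):
        if not (self.head and self.relation and self.tail):
            raise ValueError("triple fields must be non-empty")


# one n-quads statement: 3 IRI terms (or a literal tail) + optional graph term
_IRI = r"<([^<>\s]*)>"
_LIT = r'"((?:[^"\\]|\\.)*)"(?:\^\^<[^<>\s]*>|@[A-Za-z0-9\-]+)?'
_NQUAD_RE = re.compile(
    rf"^\s*{_IRI}\s+{_IRI}\s+(?:{_IRI}|{_LIT})\s*(?:{_IRI}\s*)?\.\s*$"
)


def _parse_nquad_line(line: str) -> Triple | None:
    m = _NQUAD_RE.match(line)
    if m is None:
        return None
    head, rel, tail_iri, tail_lit, _graph = m.groups()
    tail = tail_iri if tail_iri is not None else tail_lit
    if not (head and rel and tail):
        return None
    return Triple(head, rel, tail)


def _parse_tsv_line(line: str) -> Triple | None:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 3 or not all(p.strip() for p in parts[:3]):
        return None
    return Triple(parts[0].strip(), parts[1].strip(), parts[2].strip())


def parse_triples(path: str | Path, dialect: str = "tsv",
                  malformed_threshold: float = 0.05) -> list[Triple]:
    """Read triples from `path`.

    Malformed lines are tolerated (and logged) as long as their fraction
    stays at or below `malformed_threshold`; above it a
    :class:`TripleParseError` listing the offending line numbers is raised.
    """
    if dialect not in ("tsv", "nquads"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    line_parser = _parse_tsv_line if dialect == "tsv" else _parse_nquad_line

    triples: list[Triple] = []
    bad_lines: list[int] = []
    n_considered = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        n_considered += 1
        t = line_parser(line)
        if t is None:
            bad_lines.append(lineno)
        else:
            triples.append(t)
    if n_considered == 0:
        raise TripleParseError(f"{path}: no statements found")
    if bad_lines:
        frac = len(bad_lines) / n_considered
        if frac > malformed_threshold:
            raise TripleParseError(
                f"{path}: {len(bad_lines)}/{n_considered} malformed lines "
                f"(> {malformed_threshold:.0%} threshold) at lines {bad_lines[:20]}"
            )
        logger.warning("%s: skipped %d malformed lines: %s",
                       path, len(bad_lines), bad_lines[:20])
    return triples


def write_triples(triples: Iterable[Triple], path: str | Path) -> None:
    """Write triples as 3-column TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in triples:
            fh.write(f"{t.head}\t{t.relation}\t{t.tail}\n")


@dataclass
class KnowledgeGraph:
    """Indexed multi-relational graph with an undirected adjacency view.

    `adjacency[i]` is an int array of shape (degree, 2) holding
    (neighbor entity id, relation id) pairs; each undirected edge appears
    in both endpoints' lists.
    """

    entities: list[str]
    relations: list[str]
    adjacency: list[np.ndarray]
    drug_ids: list[int]
    n_edges: int
    entity_index: dict[str, int] = field(repr=False, default_factory=dict)
    relation_index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if not self.entity_index:
            self.entity_index = {e: i for i, e in enumerate(self.entities)}
        if not self.relation_index:
            self.relation_index = {r: i for i, r in enumerate(self.relations)}

    @property
    def n_entities(self) -> int:
        return len(self.entities)

    @property
    def n_relations(self) -> int:
        return len(self.relations)

    @property
    def null_relation(self) -> int:
        """Reserved relation id used to self-pad isolated entities."""
        return len(self.relations)

    def degree(self, entity_id: int) -> int:
        return len(self.adjacency[entity_id])

    def is_drug(self, entity_id: int) -> bool:
        return entity_id in self._drug_set

    @property
    def _drug_set(self) -> set[int]:
        if not hasattr(self, "_drug_set_cache"):
            object.__setattr__(self, "_drug_set_cache", set(self.drug_ids))
        return self._drug_set_cache

    def resolve_drug(self, drug: str) -> int:
        try:
            eid = self.entity_index[drug]
        except KeyError:
            raise KeyError(f"drug {drug!r} not present in the knowledge graph") from None
        return eid


def index_graph(triples: Sequence[Triple],
                drug_id_predicate: Callable[[str], bool] | str = "DB") -> KnowledgeGraph:
    """Assign contiguous ids (first-appearance order), dedupe, and index.

    `drug_id_predicate` is either a prefix string (DrugBank-style ids
    start with "DB") or a callable on the entity string.  Duplicate
    triples — including reversed duplicates under the undirected view —
    collapse to a single edge; self-loops are dropped.
    """
    if not triples:
        raise ValueError("cannot index an empty triple list")
    if isinstance(drug_id_predicate, str):
        prefix = drug_id_predicate
        is_drug = lambda e: e.startswith(prefix)  # noqa: E731
    else:
        is_drug = drug_id_predicate

    entities: list[str] = []
    entity_index: dict[str, int] = {}
    relations: list[str] = []
    relation_index: dict[str, int] = {}

    def ent_id(name: str) -> int:
        if name not in entity_index:
            entity_index[name] = len(entities)
            entities.append(name)
        return entity_index[name]

    def rel_id(name: str) -> int:
        if name not in relation_index:
            relation_index[name] = len(relations)
            relations.append(name)
        return relation_index[name]

    edges: set[tuple[int, int, int]] = set()  # (min, max, rel)
    n_selfloops = 0
    n_dups = 0
    for t in triples:
        h, r, ta = ent_id(t.head), rel_id(t.relation), ent_id(t.tail)
        if h == ta:
            n_selfloops += 1
            continue
        key = (min(h, ta), max(h, ta), r)
        if key in edges:
            n_dups += 1
        else:
            edges.add(key)
    if n_selfloops or n_dups:
        logger.info("index_graph: dropped %d self-loops, %d duplicate triples",
                    n_selfloops, n_dups)

    adj_lists: list[list[tuple[int, int]]] = [[] for _ in entities]
    for a, b, r in sorted(edges):
        adj_lists[a].append((b, r))
        adj_lists[b].append((a, r))
    adjacency = [
        np.array(sorted(lst), dtype=np.int64).reshape(-1, 2) for lst in adj_lists
    ]

    drug_ids = [i for i, e in enumerate(entities) if is_drug(e)]
    if not drug_ids:
        raise ValueError("no drug entities identified in the graph; "
                         "check the drug id rule (default prefix 'DB')")
    return KnowledgeGraph(entities=entities, relations=relations,
                          adjacency=adjacency, drug_ids=drug_ids,
                          n_edges=len(edges),
                          entity_index=entity_index, relation_index=relation_index)


@dataclass(frozen=True)
class DensityReport:
    """d(G) = 2L / (N(N-1)), the filled fraction of possible edges."""

    n_nodes: int
    n_edges: int
    density: float

    def formatted(self, sig: int = 4) -> str:
        """Density at `sig` significant figures (Table-style, e.g. 9.128e-04)."""
        return f"{self.density:.{sig - 1}e}"

    def to_dict(self) -> dict:
        return {"n_nodes": self.n_nodes, "n_edges": self.n_edges,
                "density": self.density, "density_4sf": self.formatted()}


def graph_density(n_nodes: int, n_edges: int) -> DensityReport:
    """Undirected graph density 2L/(N(N-1)) for N nodes and L edges."""
    if n_nodes < 2:
        raise ValueError(f"density needs at least 2 nodes, got {n_nodes}")
    if n_edges < 0:
        raise ValueError("edge count must be non-negative")
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"{n_edges} edges exceeds the maximum "
                         f"{max_edges} for {n_nodes} nodes")
    d = 2.0 * n_edges / (n_nodes * (n_nodes - 1))
    return DensityReport(n_nodes=n_nodes, n_edges=n_edges, density=d)


def ddi_subgraph_density(pairs, kg: KnowledgeGraph) -> DensityReport:
    """Density of the interaction subgraph: drug entities as nodes,
    distinct unordered positive pairs as edges."""
    n_drugs = len(kg.drug_ids)
    if n_drugs < 2:
        raise ValueError("fewer than 2 drug entities in the graph")
    known = {e for e in kg.entity_index}
    positive_edges = set()
    for d1, d2, label in pairs.pairs:
        if label != 1:
            continue
        if d1 not in known or d2 not in known:
            raise KeyError(f"pair ({d1}, {d2}) references drugs absent from the graph")
        positive_edges.add((min(d1, d2), max(d1, d2)))
    return graph_density(n_drugs, len(positive_edges))
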