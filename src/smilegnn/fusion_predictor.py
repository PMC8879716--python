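"""Fusing structural + topological drug features and scoring pairs.

The comprehensive drug feature is tanh((A + B)·W + b) for the sum method
(requires matching dimensions) or tanh([A ‖ B]·W + b) for concat, where
A holds topological embeddings and B the PCA-reduced structural vectors.
A pair's interaction score is the sigmoid of the inner product of the
two comprehensive features; a pair is called interacting when the score
strictly exceeds 0.5.  Training minimizes summed binary cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._autodiff import Tensor, concat, constant, parameter
from .gnn_encoder import TopologicalEmbedding
from .smiles_features import StructuralFeatureMatrix

EPS = 1e-7  # probability clip for loss stability
DECISION_THRESHOLD = 0.5  # "exceeds 0.5" is strict: score == 0.5 -> no DDI

__all__ = [
    "FusionParameters",
    "ComprehensiveFeature",
    "PairScore",
    "DrugPairDataset",
    "init_fusion_params",
    "fuse_sum",
    "fuse_concat",
    "fuse",
    "score_pair",
    "bce_loss",
    "write_predictions",
]


@dataclass
class FusionParameters:
    aggregation_method: str  # "sum" or "concat"
    W: Tensor  # sum: (d_topo, d_topo); concat: (d_topo + d_struct, d_topo)
    b: Tensor  # (d_topo,)

    def trainable(self) -> list[Tensor]:
        return [self.W, self.b]


def init_fusion_params(d_topo: int, d_struct: int, method: str = "concat",
                       seed: int = 0) -> FusionParameters:
    if method == "sum" and d_struct != d_topo:
        raise ValueError(f"sum fusion requires d_struct == d_topo "
                         f"(got {d_struct} vs {d_topo})")
    if method not in ("sum", "concat"):
        raise ValueError(f"unknown fusion method {method!r}")
    rng = np.random.default_rng(seed)
    in_dim = d_topo if method == "sum" else d_topo + d_struct
    limit = np.sqrt(6.0 / (in_dim + d_topo))
    return FusionParameters(aggregation_method=method,
                            W=parameter(rng.uniform(-limit, limit, (in_dim, d_topo))),
                            b=parameter(np.zeros(d_topo)))


@dataclass
class ComprehensiveFeature:
    """Fused per-drug vectors; every coordinate lies in (-1, 1)."""

    drug_ids: list[str]
    vectors: np.ndarray

    def __post_init__(self):
        if self.vectors.shape[0] != len(self.drug_ids):
            raise ValueError("vectors must align with drug_ids")


def _fuse_tensors(A: Tensor, B: Tensor, params: FusionParameters) -> Tensor:
    """Shared autodiff path used by both the public ops and training."""
    if params.aggregation_method == "sum":
        if A.shape[-1] != B.shape[-1]:
            raise ValueError(f"sum fusion needs equal dims, got topological "
                             f"{A.shape[-1]} vs structural {B.shape[-1]}")
        x = A + B
    else:
        x = concat([A, B], axis=-1)
    expected = params.W.shape[0]
    if x.shape[-1] != expected:
        raise ValueError(f"fusion weight expects input width {expected}, "
                         f"got {x.shape[-1]}")
    return (x.matmul(params.W) + params.b).tanh()


def _check_alignment(A: TopologicalEmbedding, B: StructuralFeatureMatrix) -> None:
    if A.drug_ids != B.drug_ids:
        raise ValueError("topological and structural features must list the "
                         "same drugs in the same order")


def fuse_sum(A: TopologicalEmbedding, B: StructuralFeatureMatrix,
             params: FusionParameters) -> ComprehensiveFeature:
    """tanh((A + B)·W + b); requires d_struct == d_topo."""
    _check_alignment(A, B)
    if params.aggregation_method != "sum":
        raise ValueError("params were initialized for a different method")
    out = _fuse_tensors(constant(A.vectors), constant(B.features), params)
    return ComprehensiveFeature(drug_ids=list(A.drug_ids), vectors=out.data)


def fuse_concat(A: TopologicalEmbedding, B: StructuralFeatureMatrix,
                params: FusionParameters) -> ComprehensiveFeature:
    """tanh([A ‖ B]·W + b); output width d_topo for any d_struct."""
    _check_alignment(A, B)
    if params.aggregation_method != "concat":
        raise ValueError("params were initialized for a different method")
    out = _fuse_tensors(constant(A.vectors), constant(B.features), params)
    return ComprehensiveFeature(drug_ids=list(A.drug_ids), vectors=out.data)


def fuse(A: TopologicalEmbedding, B: StructuralFeatureMatrix,
         params: FusionParameters) -> ComprehensiveFeature:
    return (fuse_sum if params.aggregation_method == "sum" else fuse_concat)(A, B, params)


@dataclass(frozen=True)
class PairScore:
    drug1_id: str
    drug2_id: str
    score: float
    predicted_label: int

    def __post_init__(self):
        if not 0.0 < self.score < 1.0:
            raise ValueError("sigmoid scores lie strictly in (0, 1)")


def score_pair(f1: np.ndarray, f2: np.ndarray,
               drug1_id: str = "drug1", drug2_id: str = "drug2") -> PairScore:
    """sigmoid(f1 · f2); interaction called only when the score exceeds 0.5."""
    f1 = np.asarray(f1, dtype=float).ravel()
    f2 = np.asarray(f2, dtype=float).ravel()
    if f1.shape != f2.shape:
        raise ValueError(f"feature dims differ: {f1.shape} vs {f2.shape}")
    z = float(f1 @ f2)
    score = float(1.0 / (1.0 + np.exp(-z)))
    score = min(max(score, np.nextafter(0.0, 1.0)), np.nextafter(1.0, 0.0))
    return PairScore(drug1_id=drug1_id, drug2_id=drug2_id, score=score,
                     predicted_label=int(score > DECISION_THRESHOLD))


def bce_loss(labels: np.ndarray, scores: np.ndarray,
             reduction: str = "sum") -> float:
    """Binary cross-entropy over all pairs, summed (mean also available).

    Scores are clipped to [EPS, 1 - EPS] before taking logs.
    """
    y = np.asarray(labels, dtype=float).ravel()
    p = np.asarray(scores, dtype=float).ravel()
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} scores")
    p = np.clip(p, EPS, 1.0 - EPS)
    losses = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    if reduction == "sum":
        return float(losses.sum())
    if reduction == "mean":
        return float(losses.mean())
    raise ValueError(f"unknown reduction {reduction!r}")


@dataclass
class DrugPairDataset:
    """Labeled unordered drug pairs (no self-pairs, no duplicates)."""

    pairs: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for d1, d2, label in self.pairs:
            if d1 == d2:
                raise ValueError(f"self-pair ({d1}, {d2}) not allowed")
            if label not in (0, 1):
                raise ValueError(f"label must be 0/1, got {label!r}")
            key = (min(d1, d2), max(d1, d2))
            if key in seen:
                raise ValueError(f"duplicate unordered pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def drugs(self) -> list[str]:
        """Drug index set N_d, in first-appearance order."""
        out, seen = [], set()
        for d1, d2, _ in self.pairs:
            for d in (d1, d2):
                if d not in seen:
                    seen.add(d)
                    out.append(d)
        return out

    def positives(self) -> set[tuple[str, str]]:
        return {(min(a, b), max(a, b)) for a, b, lab in self.pairs if lab == 1}

    def labels(self) -> np.ndarray:
        return np.array([lab for _, _, lab in self.pairs], dtype=int)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DrugPairDataset":
        pairs = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            d1, d2, lab = line.split("\t")[:3]
            if lab.lower() == "label":  # tolerate a header row
                continue
            pairs.append((d1, d2, int(lab)))
        return cls(pairs=pairs)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for d1, d2, lab in self.pairs:
                fh.write(f"{d1}\t{d2}\t{lab}\n")


def write_predictions(scores: list[PairScore], path: str | Path) -> None:
    """Prediction table: ids, score at 6 decimals, hard label."""
    df = pd.DataFrame(
        [(s.drug1_id, s.drug2_id, f"{s.score:.6f}", s.predicted_label) for s in scores],
        columns=["drug1_id", "drug2_id", "score", "predicted_label"],
    )
    df.to_csv(path, sep="\t", index=False)
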