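"""End-to-end training, cross-validated evaluation, and novel-pair ranking.

`SmileGNNClassifier` is a scikit-learn style estimator: X is an (n, 2)
array of drug id pairs, y their binary interaction labels.  fit() learns
entity/relation embeddings, the hop aggregator weights and the fusion
layer jointly by adaptive-moment gradient descent on the pair-level
binary cross-entropy; predict_proba() scores new pairs.  The module
functions (train, evaluate_cv, grid_search, …) are thin wrappers over
the estimator.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ._autodiff import Adam, bce_with_logits, constant
from .fusion_predictor import (DrugPairDataset, PairScore, _fuse_tensors,
                               init_fusion_params)
from .gnn_encoder import build_field_table, encode_batch, init_gnn_params
from .knowledge_graph import KnowledgeGraph
from .smiles_features import StructuralFeatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "EvalMetrics", "RankedPrediction",
           "SmileGNNClassifier", "sample_negatives", "train", "evaluate_cv",
           "rank_novel_pairs", "grid_search"]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run (YAML-serializable)."""

    batch_size: int = 256
    learning_rate: float = 2e-2
    embed_dim: int = 32          # d_topo, the GNN embedding width
    d_struct: int = 64           # PCA-reduced structural width
    aggregator_type: str = "concat"
    fusion_method: str = "concat"
    n_hops: int = 2
    sample_size: int = 8
    epochs: int = 25
    n_folds: int = 5
    negative_ratio: float = 1.0
    weight_decay: float = 1e-6
    use_structure: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        for name in ("batch_size", "learning_rate", "embed_dim", "d_struct",
                     "n_hops", "sample_size", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class SmileGNNClassifier(BaseEstimator, ClassifierMixin):
    """Pair classifier fusing KG neighborhood embeddings with SMILES features.

    Parameters
    ----------
    kg : KnowledgeGraph
        Indexed multi-relational graph the drugs live in.
    struct_features : StructuralFeatureMatrix or None
        Per-drug PCA-reduced structural vectors.  None (or
        ``use_structure=False``) zeroes the structural channel, giving
        the topology-only ablation.
    embed_dim, n_hops, sample_size, aggregator_type
        Topological encoder settings (two sampled hops by default).
    fusion_method : {"concat", "sum"}
        How structural and topological vectors combine before the final
        tanh projection; "sum" requires matching dimensions.
    lr, batch_size, epochs, weight_decay
        Optimizer settings (adaptive-moment gradient descent).

    Attributes
    ----------
    classes_ : ndarray [0, 1]
    gnn_params_, fusion_params_ : trained parameter bundles
    loss_history_ : summed training BCE per epoch
    """

    def __init__(self, kg: KnowledgeGraph | None = None,
                 struct_features: StructuralFeatureMatrix | None = None,
                 embed_dim: int = 32, n_hops: int = 2, sample_size: int = 8,
                 aggregator_type: str = "concat", fusion_method: str = "concat",
                 lr: float = 2e-2, batch_size: int = 256, epochs: int = 25,
                 weight_decay: float = 1e-6, use_structure: bool = True,
                 seed: int = 0):
        self.kg = kg
        self.struct_features = struct_features
        self.embed_dim = embed_dim
        self.n_hops = n_hops
        self.sample_size = sample_size
        self.aggregator_type = aggregator_type
        self.fusion_method = fusion_method
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.weight_decay = weight_decay
        self.use_structure = use_structure
        self.seed = seed

    # -- internals -----------------------------------------------------
    def _validate_pairs(self, X) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=object)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError(f"X must be an (n, 2) array of drug id pairs, "
                             f"got shape {X.shape}")
        left = np.array([self.kg.resolve_drug(str(d)) for d in X[:, 0]])
        right = np.array([self.kg.resolve_drug(str(d)) for d in X[:, 1]])
        return left, right

    def _struct_by_entity(self) -> np.ndarray:
        """(n_entities, d_struct) matrix, zero for entities without SMILES."""
        if not self.use_structure or self.struct_features is None:
            return np.zeros((self.kg.n_entities, self.embed_dim))
        sf = self.struct_features
        mat = np.zeros((self.kg.n_entities, sf.d_struct))
        for i, did in enumerate(sf.drug_ids):
            eid = self.kg.entity_index.get(did)
            if eid is not None and not sf.missing_mask[i]:
                mat[eid] = sf.features[i]
        return mat

    def _forward(self, left: np.ndarray, right: np.ndarray):
        """Pair logits as an autodiff Tensor of shape (m,)."""
        A_l = encode_batch(self._table, left, right, self.gnn_params_)
        A_r = encode_batch(self._table, right, left, self.gnn_params_)
        B_l = constant(self._struct_mat[left])
        B_r = constant(self._struct_mat[right])
        f_l = _fuse_tensors(A_l, B_l, self.fusion_params_)
        f_r = _fuse_tensors(A_r, B_r, self.fusion_params_)
        return (f_l * f_r).sum(axis=-1)

    # -- estimator API -------------------------------------------------
    def fit(self, X, y):
        if self.kg is None:
            raise ValueError("a KnowledgeGraph must be supplied via kg=")
        y = np.asarray(y, dtype=float).ravel()
        left, right = self._validate_pairs(X)
        if len(y) != len(left):
            raise ValueError("X and y lengths differ")
        self.classes_ = np.array([0, 1])

        self._struct_mat = self._struct_by_entity()
        d_struct = self._struct_mat.shape[1]
        self._table = build_field_table(self.kg, np.array(self.kg.drug_ids),
                                        self.n_hops, self.sample_size, self.seed)
        self.gnn_params_ = init_gnn_params(
            self.kg, d_topo=self.embed_dim, n_hops=self.n_hops,
            sample_size=self.sample_size, aggregator_type=self.aggregator_type,
            seed=self.seed)
        self.fusion_params_ = init_fusion_params(
            self.embed_dim, d_struct, method=self.fusion_method,
            seed=self.seed + 1)
        params = self.gnn_params_.trainable() + self.fusion_params_.trainable()
        opt = Adam(params, lr=self.lr, weight_decay=self.weight_decay)
        rng = np.random.default_rng([self.seed, 17])

        n = len(y)
        self.loss_history_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                opt.zero_grad()
                logits = self._forward(left[idx], right[idx])
                loss = bce_with_logits(logits, y[idx], reduction="mean")
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
            if not np.isfinite(epoch_loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={epoch_loss}; "
                    f"lower the learning rate (current {self.lr})")
            self.loss_history_.append(epoch_loss)
            logger.info(json.dumps({"event": "epoch", "epoch": epoch,
                                    "loss_sum": epoch_loss}))
        return self

    def decision_function(self, X) -> np.ndarray:
        left, right = self._validate_pairs(X)
        out = np.empty(len(left))
        for start in range(0, len(left), 4096):
            sl = slice(start, start + 4096)
            out[sl] = self._forward(left[sl], right[sl]).data
        return out

    def predict_proba(self, X) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        # interaction is called only when the score strictly exceeds 0.5
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)

    def score_pairs(self, pairs) -> list[PairScore]:
        pairs = np.asarray(pairs, dtype=object)
        probs = self.predict_proba(pairs)[:, 1]
        return [PairScore(str(a), str(b), float(np.clip(p, 1e-15, 1 - 1e-15)),
                          int(p > 0.5))
                for (a, b), p in zip(pairs, probs)]


# ---------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------

def sample_negatives(positives: DrugPairDataset, ratio: float = 1.0,
                     rng_seed: int = 0,
                     drugs: list[str] | None = None) -> DrugPairDataset:
    """Uniform unordered non-positive drug pairs, labeled 0.

    Sampled from the positives' drug index set (or an explicit `drugs`
    list), disjoint from the positive set and from each other; count is
    ``round(ratio × n_positives)``.
    """
    pos = positives.positives()
    drugs = sorted(set(drugs if drugs is not None else positives.drugs))
    n = len(drugs)
    count = round(ratio * len(pos))
    available = n * (n - 1) // 2 - len(pos)
    if available == 0 and count > 0:
        raise ValueError(f"no non-positive pairs left among {n} drugs")
    if count > available:
        # forced regime: every remaining non-positive pair is returned
        logger.warning("only %d non-positive pairs available (requested %d)",
                       available, count)
        count = available
    rng = np.random.default_rng(rng_seed)
    out: set[tuple[str, str]] = set()
    while len(out) < count:
        i, j = rng.choice(n, size=2, replace=False)
        a, b = drugs[int(i)], drugs[int(j)]
        key = (min(a, b), max(a, b))
        if key not in pos and key not in out:
            out.add(key)
    return DrugPairDataset(pairs=[(a, b, 0) for a, b in sorted(out)])


def _classifier_from_config(kg, struct_features, config: TrainConfig,
                            seed: int | None = None) -> SmileGNNClassifier:
    return SmileGNNClassifier(
        kg=kg, struct_features=struct_features, embed_dim=config.embed_dim,
        n_hops=config.n_hops, sample_size=config.sample_size,
        aggregator_type=config.aggregator_type,
        fusion_method=config.fusion_method, lr=config.learning_rate,
        batch_size=config.batch_size, epochs=config.epochs,
        weight_decay=config.weight_decay, use_structure=config.use_structure,
        seed=config.seed if seed is None else seed)


def train(kg: KnowledgeGraph, struct_features: StructuralFeatureMatrix | None,
          dataset: DrugPairDataset, config: TrainConfig) -> SmileGNNClassifier:
    """Fit the full model on a labeled pair dataset."""
    if len(dataset) == 0:
        raise ValueError("empty pair dataset")
    X = np.array([(a, b) for a, b, _ in dataset.pairs], dtype=object)
    return _classifier_from_config(kg, struct_features, config).fit(
        X, dataset.labels())


@dataclass
class EvalMetrics:
    """Per-fold ACC / AUC / F1 and their arithmetic means."""

    fold_accuracy: list[float] = field(default_factory=list)
    fold_auc: list[float] = field(default_factory=list)
    fold_f1: list[float] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def f1(self) -> float:
        return float(np.mean(self.fold_f1))

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "auc": self.auc, "f1": self.f1,
                "fold_accuracy": self.fold_accuracy, "fold_auc": self.fold_auc,
                "fold_f1": self.fold_f1}


def evaluate_cv(kg: KnowledgeGraph,
                struct_features: StructuralFeatureMatrix | None,
                dataset: DrugPairDataset, config: TrainConfig) -> EvalMetrics:
    """Stratified k-fold cross-validation of held-out pair prediction.

    AUC is the rank statistic, F1 the positive-class score at the strict
    0.5 threshold.  A fold whose held-out split contains a single class
    is skipped with a warning.
    """
    X = np.array([(a, b) for a, b, _ in dataset.pairs], dtype=object)
    y = dataset.labels()
    if config.n_folds > int((y == 1).sum()):
        raise ValueError("more folds than positive pairs")
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                          random_state=config.seed)
    metrics = EvalMetrics()
    for k, (tr, te) in enumerate(skf.split(X, y)):
        if len(np.unique(y[te])) < 2:
            logger.warning("fold %d held-out split is single-class; skipped", k)
            continue
        clf = _classifier_from_config(kg, struct_features, config)
        clf.fit(X[tr], y[tr])
        scores = clf.predict_proba(X[te])[:, 1]
        pred = (scores > 0.5).astype(int)
        metrics.fold_accuracy.append(float((pred == y[te]).mean()))
        metrics.fold_auc.append(float(roc_auc_score(y[te], scores)))
        metrics.fold_f1.append(float(f1_score(y[te], pred, zero_division=0)))
        logger.info(json.dumps({"event": "fold", "fold": k,
                                "accuracy": metrics.fold_accuracy[-1],
                                "auc": metrics.fold_auc[-1],
                                "f1": metrics.fold_f1[-1]}))
    if not metrics.fold_auc:
        raise ValueError("every fold was degenerate; cannot evaluate")
    return metrics


@dataclass
class RankedPrediction:
    """High-scoring candidate pairs, novel w.r.t. the known positives,
    sorted by non-increasing score."""

    pairs: list[PairScore]
    threshold: float

    def __post_init__(self):
        scores = [p.score for p in self.pairs]
        if any(b > a for a, b in zip(scores, scores[1:])):
            raise ValueError("ranked predictions must be sorted non-increasing")


def rank_novel_pairs(model: SmileGNNClassifier, candidate_pairs,
                     known_positives: set[tuple[str, str]] | DrugPairDataset,
                     threshold: float = 0.9,
                     top_k: int | None = None) -> RankedPrediction:
    """Score candidates, drop known interactions, keep score > threshold,
    rank from highest to lowest."""
    if isinstance(known_positives, DrugPairDataset):
        known = known_positives.positives()
    else:
        known = {(min(a, b), max(a, b)) for a, b in known_positives}
    novel = [(a, b) for a, b in candidate_pairs
             if (min(a, b), max(a, b)) not in known]
    if not novel:
        return RankedPrediction(pairs=[], threshold=threshold)
    scored = model.score_pairs(novel)
    kept = [s for s in scored if s.score > threshold]
    kept.sort(key=lambda s: (-s.score, s.drug1_id, s.drug2_id))
    if top_k is not None:
        kept = kept[:top_k]
    return RankedPrediction(pairs=kept, threshold=threshold)


def grid_search(config_grid, kg: KnowledgeGraph,
                struct_features: StructuralFeatureMatrix | None,
                dataset: DrugPairDataset
                ) -> tuple[TrainConfig, list[tuple[TrainConfig, EvalMetrics]]]:
    """Exhaustive sweep; winner is the highest mean cross-validated AUC,
    ties broken by higher F1 then lower embed_dim.

    `config_grid` is either a list of TrainConfig or a dict mapping
    field names to candidate value lists.
    """
    if isinstance(config_grid, dict):
        keys = sorted(config_grid)
        configs = [TrainConfig(**dict(zip(keys, vals)))
                   for vals in itertools.product(*(config_grid[k] for k in keys))]
    else:
        configs = list(config_grid)
    if not configs:
        raise ValueError("empty configuration grid")
    results = []
    for cfg in configs:
        m = evaluate_cv(kg, struct_features, dataset, cfg)
        logger.info(json.dumps({"event": "grid", "config": cfg.to_dict(),
                                "auc": m.auc, "f1": m.f1}))
        results.append((cfg, m))
    best = max(results, key=lambda cm: (cm[1].auc, cm[1].f1, -cm[0].embed_dim))
    return best[0], results
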