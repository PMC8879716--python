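"""SMILES structural features: character bag counts reduced by PCA.

A SMILES string is treated as a plain character sequence.  Each drug
gets a count vector over a frequency-capped character vocabulary (with a
reserved unknown slot), and PCA compresses those counts to a small dense
structural vector.  Drugs without a SMILES record keep an all-zero row,
so topology-only prediction still works for them; SMILES longer than
250 characters are excluded outright.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

MAX_SMILES_LEN = 250  # strings longer than this are excluded
DEFAULT_VOCAB_CAP = 251
DEFAULT_STRUCT_DIM = 64

__all__ = [
    "SmilesRecord",
    "CharVocabulary",
    "RawSmilesVector",
    "StructuralFeatureMatrix",
    "SmilesTooLongError",
    "EmptyCorpusError",
    "read_smiles_table",
    "build_char_vocabulary",
    "encode_smiles",
    "reduce_dimensions",
    "SmilesVectorizer",
    "StructuralFeaturizer",
    "build_structural_features",
]


class SmilesTooLongError(ValueError):
    """The record exceeds the 250-character retention rule."""


class EmptyCorpusError(ValueError):
    """No SMILES records remain after the length-exclusion rule."""


@dataclass(frozen=True)
class SmilesRecord:
    drug_id: str
    smiles: str

    @property
    def excluded(self) -> bool:
        return len(self.smiles) > MAX_SMILES_LEN


@dataclass(frozen=True)
class CharVocabulary:
    """Ordered character vocabulary with a trailing reserved unknown slot.

    `symbols` holds the real characters (frequency-descending, ties by
    codepoint); index `len(symbols)` is the unknown slot, so
    `size == len(symbols) + 1`.
    """

    symbols: tuple[str, ...]
    _index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("vocabulary symbols must be distinct")
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(self.symbols)})

    @property
    def size(self) -> int:
        return len(self.symbols) + 1

    @property
    def unknown_index(self) -> int:
        return len(self.symbols)

    def index_of(self, char: str) -> int:
        return self._index.get(char, self.unknown_index)


@dataclass(frozen=True)
class RawSmilesVector:
    drug_id: str
    counts: np.ndarray  # int vector, length = vocabulary size


@dataclass
class StructuralFeatureMatrix:
    """Per-drug reduced structural vectors, aligned with `drug_ids`.

    Rows flagged in `missing_mask` (no SMILES record) are exactly zero.
    """

    drug_ids: list[str]
    features: np.ndarray  # (n_drugs, d_struct)
    missing_mask: np.ndarray  # bool, True = no SMILES

    def __post_init__(self):
        if self.features.shape[0] != len(self.drug_ids):
            raise ValueError("features rows must align with drug_ids")
        if self.missing_mask.shape[0] != len(self.drug_ids):
            raise ValueError("missing_mask must align with drug_ids")

    @property
    def d_struct(self) -> int:
        return self.features.shape[1]

    def row(self, drug_id: str) -> np.ndarray:
        return self.features[self.drug_ids.index(drug_id)]

    def to_tsv(self, path: str | Path, sidecar: dict | None = None) -> None:
        df = pd.DataFrame(self.features,
                          columns=[f"f{i}" for i in range(self.d_struct)])
        df.insert(0, "drug_id", self.drug_ids)
        df.to_csv(path, sep="\t", index=False)
        if sidecar is not None:
            Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_smiles_table(path: str | Path) -> list[SmilesRecord]:
    """Read a `drug_id,smiles` table (TSV or CSV, header required)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else None
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str).fillna("")
    if not {"drug_id", "smiles"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns drug_id, smiles; got {list(df.columns)}")
    if df["drug_id"].duplicated().any():
        dups = df.loc[df["drug_id"].duplicated(), "drug_id"].tolist()
        raise ValueError(f"{path}: duplicate drug_id values {dups[:5]}")
    return [SmilesRecord(r.drug_id, r.smiles) for r in df.itertuples()]


def build_char_vocabulary(records: list[SmilesRecord],
                          cap: int = DEFAULT_VOCAB_CAP) -> CharVocabulary:
    """Frequency-capped character vocabulary over retained SMILES.

    Keeps the `cap - 1` most frequent characters (ties broken by
    codepoint) plus the unknown slot; records failing the length rule
    are excluded before counting.
    """
    if cap < 2:
        raise ValueError("cap must allow at least one symbol plus the unknown slot")
    counts: Counter[str] = Counter()
    n_retained = 0
    for rec in records:
        if rec.excluded:
            continue
        n_retained += 1
        counts.update(rec.smiles)
    if n_retained == 0:
        raise EmptyCorpusError("no SMILES records remain after the 250-character rule")
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    symbols = tuple(c for c, _ in ordered[: cap - 1])
    return CharVocabulary(symbols=symbols)


def encode_smiles(record: SmilesRecord, vocab: CharVocabulary) -> RawSmilesVector:
    """Character count vector; unseen characters pool in the unknown slot."""
    if record.excluded:
        raise SmilesTooLongError(
            f"{record.drug_id}: SMILES of length {len(record.smiles)} exceeds {MAX_SMILES_LEN}")
    counts = np.zeros(vocab.size, dtype=np.int64)
    for ch in record.smiles:
        counts[vocab.index_of(ch)] += 1
    return RawSmilesVector(drug_id=record.drug_id, counts=counts)


def _fix_component_signs(components: np.ndarray) -> np.ndarray:
    """Flip each principal axis so its largest-|loading| entry is positive."""
    flip = np.ones(components.shape[0])
    for k, comp in enumerate(components):
        if comp[np.argmax(np.abs(comp))] < 0:
            flip[k] = -1.0
    return flip


def reduce_dimensions(raw: np.ndarray, d_struct: int, seed: int = 0,
                      drug_ids: list[str] | None = None,
                      missing_mask: np.ndarray | None = None) -> StructuralFeatureMatrix:
    """PCA-project count vectors to `d_struct` dimensions.

    The decomposition is fitted only on rows with SMILES (zero rows for
    structure-less drugs would bias the mean); those rows stay zero in
    the output.  Component signs follow a fixed convention: the loading
    of largest magnitude on each axis is positive.
    """
    raw = np.asarray(raw, dtype=float)
    n, p = raw.shape
    if drug_ids is None:
        drug_ids = [f"row{i}" for i in range(n)]
    if missing_mask is None:
        missing_mask = np.zeros(n, dtype=bool)
    missing_mask = np.asarray(missing_mask, dtype=bool)

    present = ~missing_mask
    X = raw[present]
    if X.shape[0] == 0:
        raise EmptyCorpusError("no rows with SMILES to fit the projection on")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if d_struct > rank:
        raise ValueError(
            f"requested {d_struct} components but the centered matrix has rank "
            f"{rank}; achievable maximum is {rank}")
    pca = PCA(n_components=d_struct, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(X)
    flip = _fix_component_signs(pca.components_)
    scores = scores * flip

    features = np.zeros((n, d_struct))
    features[present] = scores
    return StructuralFeatureMatrix(drug_ids=list(drug_ids), features=features,
                                   missing_mask=missing_mask)


class SmilesVectorizer(BaseEstimator, TransformerMixin):
    """Bag-of-characters count encoder for SMILES records.

    Parameters
    ----------
    cap : int
        Maximum vocabulary size including the reserved unknown slot.

    Attributes
    ----------
    vocabulary_ : CharVocabulary
    excluded_ids_ : list of drug ids dropped by the 250-character rule.
    """

    def __init__(self, cap: int = DEFAULT_VOCAB_CAP):
        self.cap = cap

    def fit(self, X: list[SmilesRecord], y=None):
        self.vocabulary_ = build_char_vocabulary(X, cap=self.cap)
        self.excluded_ids_ = [r.drug_id for r in X if r.excluded]
        return self

    def transform(self, X: list[SmilesRecord]) -> tuple[list[str], np.ndarray]:
        vecs = [encode_smiles(r, self.vocabulary_) for r in X if not r.excluded]
        ids = [v.drug_id for v in vecs]
        mat = (np.stack([v.counts for v in vecs])
               if vecs else np.zeros((0, self.vocabulary_.size), dtype=np.int64))
        return ids, mat


class StructuralFeaturizer(BaseEstimator, TransformerMixin):
    """records -> StructuralFeatureMatrix (counts then PCA), sklearn-style.

    `transform(drug_ids)` emits one row per requested drug; drugs absent
    from the fitted table get a zero row and a missing-mask flag.
    """

    def __init__(self, d_struct: int = DEFAULT_STRUCT_DIM,
                 cap: int = DEFAULT_VOCAB_CAP, seed: int = 0):
        self.d_struct = d_struct
        self.cap = cap
        self.seed = seed

    def fit(self, X: list[SmilesRecord], y=None):
        self.vectorizer_ = SmilesVectorizer(cap=self.cap).fit(X)
        ids, counts = self.vectorizer_.transform(X)
        # cap the dimension at the achievable rank rather than erroring,
        # so small corpora still featurize
        rank = np.linalg.matrix_rank(counts - counts.mean(axis=0))
        self.n_components_ = min(self.d_struct, rank)
        reduced = reduce_dimensions(counts, self.n_components_, seed=self.seed,
                                    drug_ids=ids)
        self.feature_table_ = dict(zip(reduced.drug_ids, reduced.features))
        return self

    def transform(self, drug_ids: list[str]) -> StructuralFeatureMatrix:
        feats = np.zeros((len(drug_ids), self.n_components_))
        missing = np.ones(len(drug_ids), dtype=bool)
        for i, did in enumerate(drug_ids):
            if did in self.feature_table_:
                feats[i] = self.feature_table_[did]
                missing[i] = False
        return StructuralFeatureMatrix(drug_ids=list(drug_ids), features=feats,
                                       missing_mask=missing)


def build_structural_features(records: list[SmilesRecord], drug_ids: list[str],
                              d_struct: int = DEFAULT_STRUCT_DIM,
                              cap: int = DEFAULT_VOCAB_CAP,
                              seed: int = 0) -> StructuralFeatureMatrix:
    """One-call pipeline: vocabulary, counts, PCA, aligned to `drug_ids`."""
    return StructuralFeaturizer(d_struct=d_struct, cap=cap, seed=seed).fit(records).transform(drug_ids)
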