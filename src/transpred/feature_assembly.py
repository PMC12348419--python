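"""Embedding pooling, the dummy feature, META fingerprints, and the
sample x feature interchange matrix."""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingMatrix",
    "FeatureMatrix",
    "mean_pool",
    "dummy_feature",
    "meta_feature",
    "meta_std_feature",
    "build_feature_matrix",
    "META_BLOCK_DIMS",
]

#: (AAC, PAAC, Multi-PSSM) block dimensions of the META feature.
META_BLOCK_DIMS = (20, 400, 1600)


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Per-residue embedding rows for one protein (n residues x d dims)."""

    accession: str
    values: np.ndarray

    def __post_init__(self):
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError(f"{self.accession}: embedding must be a non-empty 2-D array")


@dataclass
class FeatureMatrix:
    """Named samples x named feature dimensions, the interchange object
    between encoders, outlier detection, and classifiers."""

    sample_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray
    feature_id: str = ""

    def __post_init__(self):
        self.sample_ids = tuple(self.sample_ids)
        self.feature_names = tuple(self.feature_names)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError("values shape does not match ids/names")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_names)
        )

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "accession"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, feature_id: str = "") -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        return cls(
            sample_ids=tuple(df.index.astype(str)),
            feature_names=tuple(df.columns.astype(str)),
            values=df.to_numpy(dtype=float),
            feature_id=feature_id,
        )

    def subset(self, sample_ids) -> "FeatureMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return FeatureMatrix(
            sample_ids=tuple(sample_ids),
            feature_names=self.feature_names,
            values=self.values[rows],
            feature_id=self.feature_id,
        )


def mean_pool(emb: EmbeddingMatrix) -> np.ndarray:
    """Arithmetic mean over all residue positions -> one d-vector."""
    return emb.values.mean(axis=0)


def dummy_feature(accession: str, global_seed: int, dim: int = 1024) -> np.ndarray:
    """Deterministic uniform-random vector keyed by (accession, seed).

    A stable 64-bit digest of the accession is mixed with the global
    seed so the output is independent of dataset order and of the
    process hash seed.
    """
    digest = hashlib.sha256(accession.encode()).digest()
    key = int.from_bytes(digest[:8], "little")
    rng = np.random.default_rng([global_seed & 0xFFFFFFFFFFFFFFFF, key])
    return rng.random(dim)


def _check_block(name: str, vec: np.ndarray, dim: int) -> np.ndarray:
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (dim,):
        raise ValueError(f"{name} block must have dimension {dim}, got {vec.shape}")
    return vec


def meta_feature(aac: np.ndarray, paac: np.ndarray, multipssm: np.ndarray) -> np.ndarray:
    """Plain concatenation AAC | PAAC | Multi-PSSM -> 2020 dimensions."""
    blocks = [
        _check_block("AAC", aac, META_BLOCK_DIMS[0]),
        _check_block("PAAC", paac, META_BLOCK_DIMS[1]),
        _check_block("Multi-PSSM", multipssm, META_BLOCK_DIMS[2]),
    ]
    return np.concatenate(blocks)


def meta_std_feature(aac: np.ndarray, paac: np.ndarray, multipssm: np.ndarray) -> np.ndarray:
    """Per-sample fingerprint: z-score each block independently within
    this sample, then concatenate.  A constant block maps to zeros."""
    blocks = [
        _check_block("AAC", aac, META_BLOCK_DIMS[0]),
        _check_block("PAAC", paac, META_BLOCK_DIMS[1]),
        _check_block("Multi-PSSM", multipssm, META_BLOCK_DIMS[2]),
    ]
    out = []
    for block in blocks:
        sd = block.std()
        if sd == 0:
            out.append(np.zeros_like(block))
        else:
            out.append((block - block.mean()) / sd)
    return np.concatenate(out)


def build_feature_matrix(
    vectors: dict[str, np.ndarray],
    feature_id: str,
    feature_names: tuple[str, ...] | None = None,
) -> FeatureMatrix:
    """Stack per-protein vectors into a FeatureMatrix.

    Rows are sorted by accession; entries whose value is None (missing
    constituent data) are dropped with a logged warning.  All remaining
    vectors must share one length.
    """
    present = {acc: v for acc, v in vectors.items() if v is not None}
    missing = sorted(set(vectors) - set(present))
    if missing:
        logger.warning(
            "feature %s: dropping %d samples with missing data: %s",
            feature_id, len(missing), missing,
        )
    if not present:
        raise ValueError(f"feature {feature_id}: no samples with data")
    lengths = {len(v) for v in present.values()}
    if len(lengths) != 1:
        raise ValueError(f"feature {feature_id}: inconsistent vector lengths {lengths}")
    dim = lengths.pop()
    ids = tuple(sorted(present))
    if feature_names is None:
        feature_names = tuple(f"{feature_id}:{i}" for i in range(dim))
    values = np.vstack([np.asarray(present[acc], dtype=float) for acc in ids])
    return FeatureMatrix(
        sample_ids=ids, feature_names=feature_names, values=values, feature_id=feature_id
    )
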