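"""Fixed-length k-mer frequency vectors over a 20-letter alphabet.

Counting is overlapping, with denominator ``L - k + 1`` (the length for
k=1, length minus one for k=2, and so on), so every vector sums to 1.
Feature names are ordered lexicographically and prefixed with the
feature id so that concatenated vectors have globally unique names.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from . import AA_ALPHABET, TDI_ALPHABET

__all__ = [
    "KmerVector",
    "kmer_frequencies",
    "named_feature",
    "combine_features",
    "kmer_names",
    "FEATURE_DEFS",
]


@dataclass(frozen=True)
class KmerVector:
    """Named, normalized k-mer frequencies (one block per feature id)."""

    feature_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        if len(self.feature_names) != len(self.values):
            raise ValueError("names and values have different lengths")

    @property
    def dim(self) -> int:
        return len(self.values)


def kmer_names(alphabet: str, k: int) -> tuple[str, ...]:
    """All k-mers over ``alphabet`` in lexicographic order."""
    return tuple("".join(p) for p in product(sorted(alphabet), repeat=k))


def kmer_frequencies(seq: str, k: int, alphabet: str = AA_ALPHABET) -> KmerVector:
    """Overlapping k-mer frequencies of ``seq``.

    The value for k-mer ``w`` is its overlapping-substring count divided
    by ``len(seq) - k + 1``.  Raises for sequences shorter than ``k`` or
    containing letters outside ``alphabet``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(seq) < k:
        raise ValueError(f"sequence of length {len(seq)} shorter than k={k}")
    bad = set(seq) - set(alphabet)
    if bad:
        raise ValueError(f"characters {sorted(bad)} outside the alphabet")
    names = kmer_names(alphabet, k)
    index = {name: i for i, name in enumerate(names)}
    counts = np.zeros(len(names))
    for i in range(len(seq) - k + 1):
        counts[index[seq[i : i + k]]] += 1
    return KmerVector(feature_names=names, values=counts / (len(seq) - k + 1))


#: feature id -> (sequence kind, alphabet, k)
FEATURE_DEFS: dict[str, tuple[str, str, int]] = {
    "AAC": ("aa", AA_ALPHABET, 1),
    "PAAC": ("aa", AA_ALPHABET, 2),
    "AA-KMER3": ("aa", AA_ALPHABET, 3),
    "3Di-COMP": ("3di", TDI_ALPHABET, 1),
    "3Di-KMER2": ("3di", TDI_ALPHABET, 2),
    "3Di-KMER3": ("3di", TDI_ALPHABET, 3),
}


def named_feature(
    feature_id: str,
    seq_aa: str | None = None,
    seq_3di: str | None = None,
) -> KmerVector:
    """Compute one of the named k-mer features for a single protein.

    Dispatches to :func:`kmer_frequencies` with the alphabet and k
    implied by ``feature_id``; the resulting feature names are prefixed
    with the id (``"AAC:A"``, ``"3Di-KMER2:AC"``, …).
    """
    if feature_id not in FEATURE_DEFS:
        raise KeyError(f"unknown feature id {feature_id!r}")
    kind, alphabet, k = FEATURE_DEFS[feature_id]
    seq = seq_aa if kind == "aa" else seq_3di
    if seq is None:
        raise ValueError(
            f"feature {feature_id!r} requires "
            f"{'an amino-acid' if kind == 'aa' else 'a 3Di'} sequence"
        )
    vec = kmer_frequencies(seq, k, alphabet)
    names = tuple(f"{feature_id}:{n}" for n in vec.feature_names)
    return KmerVector(feature_names=names, values=vec.values)


def combine_features(parts: list[KmerVector]) -> KmerVector:
    """Concatenate feature blocks, preserving order and values.

    Used to build the COMB features (AA k-mers next to 3Di k-mers of
    the same k).  Feature names must be globally unique.
    """
    if not parts:
        raise ValueError("no parts to combine")
    names: list[str] = []
    for part in parts:
        names.extend(part.feature_names)
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate feature names after concatenation: {dupes[:5]}")
    values = np.concatenate([part.values for part in parts])
    return KmerVector(feature_names=tuple(names), values=values)
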