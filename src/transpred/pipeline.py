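"""Convenience layer: compute a named feature matrix for a dataset.

Maps a feature id (AAC, PAAC, AA-KMER3, 3Di-COMP, 3Di-KMER2, 3Di-KMER3,
COMB-KMER1/2/3, MULTI-PSSM, META, META-STD, EMB, DUMMY) to the encoder
calls that produce one vector per protein, then stacks them into a
:class:`~transpred.feature_assembly.FeatureMatrix`.
"""

from __future__ import annotations

import numpy as np

from .feature_assembly import (
    EmbeddingMatrix,
    FeatureMatrix,
    build_feature_matrix,
    dummy_feature,
    mean_pool,
    meta_feature,
    meta_std_feature,
)
from .kmer_features import combine_features, named_feature
from .pssm_features import (
    Pssm,
    conservation_profile,
    multi_pssm,
    multi_pssm_feature_names,
)
from .seq_io import ProteinRecord, TdiRecord

__all__ = ["compute_feature_matrix", "KNOWN_FEATURES"]

_COMB_PARTS = {
    "COMB-KMER1": ("AAC", "3Di-COMP"),
    "COMB-KMER2": ("PAAC", "3Di-KMER2"),
    "COMB-KMER3": ("AA-KMER3", "3Di-KMER3"),
}

KNOWN_FEATURES = (
    "AAC", "PAAC", "AA-KMER3", "3Di-COMP", "3Di-KMER2", "3Di-KMER3",
    "COMB-KMER1", "COMB-KMER2", "COMB-KMER3",
    "MULTI-PSSM", "META", "META-STD", "EMB", "DUMMY",
)


def _multi_pssm_vector(pssms: dict[tuple[str, int], Pssm]) -> np.ndarray:
    profiles = {cfg: conservation_profile(p) for cfg, p in pssms.items()}
    return multi_pssm(profiles)


def compute_feature_matrix(
    feature_id: str,
    proteins: list[ProteinRecord],
    tdis: list[TdiRecord] | None = None,
    pssms: dict[str, dict[tuple[str, int], Pssm]] | None = None,
    embeddings: dict[str, EmbeddingMatrix] | None = None,
    dummy_seed: int = 0,
    dummy_dim: int = 1024,
) -> FeatureMatrix:
    """One row per protein for the requested feature.

    Proteins missing a required constituent (3Di sequence, PSSM set,
    embedding) are dropped with a logged warning.
    """
    if feature_id not in KNOWN_FEATURES:
        raise KeyError(f"unknown feature id {feature_id!r}")
    tdi_by_acc = {t.accession: t.tdi_seq for t in (tdis or [])}
    vectors: dict[str, np.ndarray | None] = {}
    names: tuple[str, ...] | None = None

    for rec in proteins:
        acc = rec.accession
        tdi = tdi_by_acc.get(acc)
        try:
            if feature_id in ("AAC", "PAAC", "AA-KMER3"):
                vec = named_feature(feature_id, seq_aa=rec.aa_seq)
            elif feature_id in ("3Di-COMP", "3Di-KMER2", "3Di-KMER3"):
                if tdi is None:
                    vectors[acc] = None
                    continue
                vec = named_feature(feature_id, seq_3di=tdi)
            elif feature_id in _COMB_PARTS:
                if tdi is None:
                    vectors[acc] = None
                    continue
                aa_id, tdi_id = _COMB_PARTS[feature_id]
                vec = combine_features([
                    named_feature(aa_id, seq_aa=rec.aa_seq),
                    named_feature(tdi_id, seq_3di=tdi),
                ])
            elif feature_id == "MULTI-PSSM":
                if not pssms or acc not in pssms:
                    vectors[acc] = None
                    continue
                vectors[acc] = _multi_pssm_vector(pssms[acc])
                names = multi_pssm_feature_names()
                continue
            elif feature_id in ("META", "META-STD"):
                if not pssms or acc not in pssms:
                    vectors[acc] = None
                    continue
                aac = named_feature("AAC", seq_aa=rec.aa_seq).values
                paac = named_feature("PAAC", seq_aa=rec.aa_seq).values
                mp = _multi_pssm_vector(pssms[acc])
                fn = meta_feature if feature_id == "META" else meta_std_feature
                vectors[acc] = fn(aac, paac, mp)
                continue
            elif feature_id == "EMB":
                if not embeddings or acc not in embeddings:
                    vectors[acc] = None
                    continue
                vectors[acc] = mean_pool(embeddings[acc])
                continue
            else:  # DUMMY
                vectors[acc] = dummy_feature(acc, dummy_seed, dim=dummy_dim)
                continue
        except ValueError:
            vectors[acc] = None
            continue
        vectors[acc] = vec.values
        names = vec.feature_names

    return build_feature_matrix(vectors, feature_id, feature_names=names)
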