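"""Seeded synthetic fixtures for every pipeline stage.

Generates paired AA/3Di sequences whose class-conditional residue
compositions are separated by a tunable signal strength delta (delta=0
means both classes share one generating distribution), integer log-odds
PSSMs in all four search configurations, per-residue embedding matrices
with class signal, planted feature-space outliers, and a miniature
OBO/GAF ontology fixture.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import AA_ALPHABET, TDI_ALPHABET
from .feature_assembly import EmbeddingMatrix, FeatureMatrix
from .pssm_features import MULTI_PSSM_ORDER, Pssm
from .seq_io import ProteinRecord, TdiRecord

__all__ = [
    "SyntheticSpec",
    "gen_labeled_sequences",
    "gen_pssms",
    "gen_embeddings",
    "plant_outliers",
    "write_demo_obo",
    "write_demo_gaf",
    "save_embeddings_tsv",
    "load_embeddings_tsv",
]


@dataclass(frozen=True)
class SyntheticSpec:
    n_per_class: tuple[int, int] = (27, 27)
    length_range: tuple[int, int] = (120, 240)
    signal_strength: float = 0.0  # delta; 0 => identical class distributions
    concentration: float = 50.0  # Dirichlet concentration (per-protein spread)
    embedding_dim: int = 1024
    embedding_signal: float = 0.0
    seed: int = 0
    labels: tuple[str, str] = ("amino_acid", "sugar")


def _class_composition(delta: float, sign_pattern: np.ndarray) -> np.ndarray:
    """Softmax-tilted composition: delta=0 is uniform for every class."""
    w = np.exp(delta * sign_pattern)
    return w / w.sum()


def _sign_patterns(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    pattern = rng.permutation(np.repeat([1.0, -1.0], 10))
    return pattern, -pattern


def gen_labeled_sequences(
    spec: SyntheticSpec,
) -> tuple[list[ProteinRecord], list[TdiRecord], dict[str, str]]:
    """Draw class-biased AA and 3Di sequences of equal per-protein length.

    Per class, a Dirichlet centered on a delta-tilted composition gives
    each protein its own residue distribution; the paired 3Di sequence
    uses an independent class bias over its own alphabet.
    """
    rng = np.random.default_rng(spec.seed)
    aa_pats = _sign_patterns(rng)
    tdi_pats = _sign_patterns(rng)
    proteins: list[ProteinRecord] = []
    tdis: list[TdiRecord] = []
    labels: dict[str, str] = {}
    counter = 0
    for cls in (0, 1):
        aa_center = _class_composition(spec.signal_strength, aa_pats[cls])
        tdi_center = _class_composition(spec.signal_strength, tdi_pats[cls])
        for _ in range(spec.n_per_class[cls]):
            counter += 1
            acc = f"SYN{counter:04d}"
            length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            aa_p = rng.dirichlet(aa_center * spec.concentration)
            tdi_p = rng.dirichlet(tdi_center * spec.concentration)
            aa_seq = "".join(rng.choice(list(AA_ALPHABET), size=length, p=aa_p))
            tdi_seq = "".join(rng.choice(list(TDI_ALPHABET), size=length, p=tdi_p))
            proteins.append(ProteinRecord(accession=acc, aa_seq=aa_seq))
            tdis.append(TdiRecord(accession=acc, tdi_seq=tdi_seq))
            labels[acc] = spec.labels[cls]
    return proteins, tdis, labels


def gen_pssms(
    records: list[ProteinRecord],
    labels: dict[str, str],
    signal: float = 0.0,
    seed: int = 0,
) -> dict[str, dict[tuple[str, int], Pssm]]:
    """Integer log-odds PSSMs for all four (database, iterations)
    configurations per protein, with an optional class-dependent shift."""
    rng = np.random.default_rng(seed)
    label_names = sorted(set(labels.values()))
    class_shift = {
        lab: signal * rng.normal(size=20) for lab in label_names
    }
    out: dict[str, dict[tuple[str, int], Pssm]] = {}
    for rec in records:
        shift = class_shift[labels[rec.accession]]
        out[rec.accession] = {}
        for db, iters in MULTI_PSSM_ORDER:
            raw = rng.normal(loc=shift, scale=3.0, size=(len(rec.aa_seq), 20))
            log_odds = np.clip(np.rint(raw), -10, 10).astype(int)
            out[rec.accession][(db, iters)] = Pssm(
                accession=rec.accession,
                sequence=rec.aa_seq,
                log_odds=log_odds,
                database_tag=db,
                iterations=iters,
            )
    return out


def gen_embeddings(
    records: list[ProteinRecord],
    labels: dict[str, str],
    dim: int = 1024,
    signal: float = 0.0,
    seed: int = 0,
) -> dict[str, EmbeddingMatrix]:
    """Per-residue embeddings: class mean vector plus isotropic noise."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(seed)
    label_names = sorted(set(labels.values()))
    class_mean = {lab: signal * rng.normal(size=dim) for lab in label_names}
    out = {}
    for rec in records:
        mu = class_mean[labels[rec.accession]]
        values = mu + rng.normal(size=(len(rec.aa_seq), dim))
        out[rec.accession] = EmbeddingMatrix(accession=rec.accession, values=values)
    return out


def save_embeddings_tsv(embeddings: dict[str, EmbeddingMatrix], path: str | Path) -> None:
    """Keyed text container: one row per residue, keyed by accession."""
    with Path(path).open("w") as fh:
        for acc in sorted(embeddings):
            for row in embeddings[acc].values:
                fh.write(acc + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def load_embeddings_tsv(path: str | Path) -> dict[str, EmbeddingMatrix]:
    rows: dict[str, list[list[float]]] = {}
    with Path(path).open() as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.setdefault(parts[0], []).append([float(v) for v in parts[1:]])
    return {
        acc: EmbeddingMatrix(accession=acc, values=np.array(vals))
        for acc, vals in rows.items()
    }


def plant_outliers(
    feature_matrix: FeatureMatrix,
    n_outliers: int,
    magnitude_sigma: float,
    seed: int = 0,
) -> tuple[FeatureMatrix, set[str]]:
    """Displace ``n_outliers`` random rows by ``magnitude_sigma`` times
    the per-column SD along a random sign direction; returns the new
    matrix and the planted accessions."""
    if magnitude_sigma <= 0:
        raise ValueError("magnitude_sigma must be > 0")
    n = len(feature_matrix.sample_ids)
    if n_outliers >= n:
        raise ValueError("n_outliers must be smaller than the number of samples")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=n_outliers, replace=False)
    values = feature_matrix.values.copy()
    sd = values.std(axis=0)
    sd[sd == 0] = 1.0
    for i in idx:
        direction = rng.choice([-1.0, 1.0], size=values.shape[1])
        values[i] += magnitude_sigma * sd * direction
    planted = {feature_matrix.sample_ids[i] for i in idx}
    return (
        FeatureMatrix(
            sample_ids=feature_matrix.sample_ids,
            feature_names=feature_matrix.feature_names,
            values=values,
            feature_id=feature_matrix.feature_id,
        ),
        planted,
    )


# --- miniature ontology fixture ---------------------------------------
#
# 12 molecular-function terms, including a diamond (T05 is_a T02/T03,
# both is_a T01), a deliberately wrong is_a edge (the channel term T09
# placed under the amino-acid transport term T02), a part_of edge that
# must never propagate, and one obsolete term.

_DEMO_TERMS = [
    ("GO:0000001", "transporter activity", []),
    ("GO:0000002", "amino acid transport", ["GO:0000001"]),
    ("GO:0000003", "organic acid transport", ["GO:0000001"]),
    ("GO:0000004", "sugar transport", ["GO:0000001"]),
    ("GO:0000005", "acidic amino acid transport", ["GO:0000002", "GO:0000003"]),
    ("GO:0000006", "hexose transport", ["GO:0000004"]),
    ("GO:0000007", "glucose transport", ["GO:0000006"]),
    ("GO:0000008", "sucrose transport", ["GO:0000004"]),
    ("GO:0000009", "glutamate-gated channel activity", ["GO:0000002"]),  # faulty edge
    ("GO:0000010", "proline transport", ["GO:0000002"]),
    ("GO:0000011", "xylose transport", ["GO:0000006"]),
    ("GO:0000012", "obsolete carbohydrate thing", []),
]

_DEMO_PART_OF = [("GO:0000007", "GO:0000001")]


def write_demo_obo(path: str | Path) -> None:
    """Write the 12-term ontology fixture (diamond, faulty edge,
    part_of relation, one obsolete term)."""
    lines = ["format-version: 1.2", "ontology: demo", ""]
    for term_id, name, parents in _DEMO_TERMS:
        lines.append("[Term]")
        lines.append(f"id: {term_id}")
        lines.append(f"name: {name}")
        lines.append("namespace: molecular_function")
        if term_id == "GO:0000012":
            lines.append("is_obsolete: true")
        for p in parents:
            lines.append(f"is_a: {p} ! parent")
        for child, parent in _DEMO_PART_OF:
            if child == term_id:
                lines.append(f"relationship: part_of {parent} ! whole")
        lines.append("")
    Path(path).write_text("\n".join(lines))


#: (accession, term, qualifier, evidence) rows of the GAF fixture,
#: including IEA and NOT cases that the default filters must drop.
DEMO_GAF_ROWS = [
    ("P00001", "GO:0000005", "enables", "IDA"),
    ("P00002", "GO:0000010", "enables", "IMP"),
    ("P00003", "GO:0000002", "enables", "IDA"),
    ("P00004", "GO:0000002", "enables", "TAS"),
    ("P00005", "GO:0000009", "enables", "IDA"),   # channel via faulty edge
    ("P00006", "GO:0000007", "enables", "IDA"),
    ("P00007", "GO:0000008", "enables", "IMP"),
    ("P00008", "GO:0000006", "enables", "IDA"),
    ("P00009", "GO:0000011", "enables", "IDA"),
    ("P00010", "GO:0000004", "enables", "IC"),
    ("P00011", "GO:0000002", "enables", "IEA"),   # electronic, dropped
    ("P00011", "GO:0000004", "enables", "IEA"),
    ("P00012", "GO:0000004", "NOT|enables", "IDA"),  # negated, dropped
    ("P00013", "GO:0000002", "enables", "IDA"),   # annotated with both classes
    ("P00013", "GO:0000004", "enables", "IDA"),
    ("P00014", "GO:0000010", "enables", "IDA"),   # fragment in the fixture
    ("P00015", "GO:0000007", "enables", "IDA"),   # non-standard residues
    ("P00016", "GO:0000005", "enables", "HDA"),
    ("P00017", "GO:0000006", "enables", "IPI"),
    ("P00018", "GO:0000099", "enables", "IDA"),   # unknown term, skipped
]


def write_demo_gaf(path: str | Path) -> None:
    """Write a GAF 2.2 fixture with 20 annotations (17 columns each)."""
    lines = ["!gaf-version: 2.2"]
    for acc, term, qualifier, evidence in DEMO_GAF_ROWS:
        cols = [""] * 17
        cols[0] = "UniProtKB"
        cols[1] = acc
        cols[2] = acc
        cols[3] = qualifier
        cols[4] = term
        cols[5] = "GO_REF:0000000"
        cols[6] = evidence
        cols[8] = "F"
        cols[11] = "protein"
        cols[12] = "taxon:3702"
        cols[13] = "20250101"
        cols[14] = "UniProt"
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")
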