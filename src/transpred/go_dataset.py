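"""Labeled two-class dataset construction from ontology annotations.

The pipeline: parse the ontology (OBO) and the annotation table (GAF
2.2), keep trusted evidence codes, propagate annotations up the is_a
hierarchy, assign one of two class labels per protein, exclude
overlapping and low-quality entries, and finally reduce sequence
redundancy by greedy identity clustering per class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from Bio import Align

from .seq_io import NONSTANDARD_CODES, ProteinRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GoGraph",
    "GoAnnotation",
    "DatasetConfig",
    "LabeledDataset",
    "parse_obo",
    "parse_gaf",
    "propagate_annotations",
    "filter_annotations",
    "assemble_labeled_dataset",
    "reduce_redundancy",
    "pairwise_identity",
    "DEFAULT_EVIDENCE_ALLOWLIST",
]

#: Experimental evidence codes plus curated non-electronic codes.
#: IEA (inferred from electronic annotation) is excluded by default.
DEFAULT_EVIDENCE_ALLOWLIST = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP",
     "HTP", "HDA", "HMP", "HGI", "HEP", "TAS", "IC"}
)


@dataclass(frozen=True)
class GoAnnotation:
    accession: str
    term: str
    evidence_code: str = "IDA"
    qualifier: str = "enables"

    @property
    def negated(self) -> bool:
        return self.qualifier.startswith("NOT")


@dataclass
class GoGraph:
    """Directed term graph; edges point child -> parent, typed by relation."""

    graph: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def is_a_subgraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.graph.nodes)
        for u, v, data in self.graph.edges(data=True):
            if data.get("type") == "is_a":
                g.add_edge(u, v)
        return g

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from ``term`` through is_a edges."""
        g = self.is_a_subgraph()
        if term not in g:
            return set()
        return nx.descendants(g, term)  # edges point child -> parent

    def namespace(self, term: str) -> str | None:
        return self.graph.nodes[term].get("namespace") if term in self.graph else None


@dataclass
class DatasetConfig:
    """Parameters of the labeled-dataset assembly."""

    class_terms: dict[str, str]
    evidence_allowlist: frozenset[str] = DEFAULT_EVIDENCE_ALLOWLIST
    identity_threshold: float = 0.70
    exclude_multilabel: bool = True
    require_reviewed: bool = True
    namespace: str | None = "molecular_function"

    def __post_init__(self):
        if len(self.class_terms) != 2:
            raise ValueError("binary tasks require exactly 2 class terms")
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity_threshold must be in (0, 1]")


@dataclass
class LabeledDataset:
    """Accession -> label assignment plus per-rule exclusion counts."""

    samples: list[tuple[str, str]]
    exclusion_counts: dict[str, int] = field(default_factory=dict)

    @property
    def label_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, label in self.samples:
            counts[label] = counts.get(label, 0) + 1
        return counts

    def accessions(self) -> list[str]:
        return [acc for acc, _ in self.samples]

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("accession\tlabel\n")
            for acc, label in self.samples:
                fh.write(f"{acc}\t{label}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LabeledDataset":
        samples = []
        with Path(path).open() as fh:
            header = fh.readline()
            if not header.startswith("accession"):
                raise ValueError(f"{path}: missing header")
            for line in fh:
                acc, label = line.rstrip("\n").split("\t")
                samples.append((acc, label))
        return cls(samples=samples)


def parse_obo(path: str | Path) -> GoGraph:
    """Parse an OBO 1.2-style ontology file.

    Obsolete terms are excluded; ``is_a`` edges are stored separately
    from all other relation types (``relationship:`` lines), which are
    kept with type ``other`` and never used for propagation.
    """
    graph = nx.MultiDiGraph()
    term_id = None
    in_term = False
    fields: dict[str, list[str]] = {}

    def flush():
        if term_id is None:
            return
        if any(v.startswith("true") for v in fields.get("is_obsolete", [])):
            return
        attrs = {}
        for key in ("name", "namespace"):
            if fields.get(key):
                attrs[key] = fields[key][0]
        graph.add_node(term_id, **attrs)
        for val in fields.get("is_a", []):
            parent = val.split("!")[0].strip()
            graph.add_edge(term_id, parent, type="is_a")
        for val in fields.get("relationship", []):
            parts = val.split("!")[0].split()
            if len(parts) < 2:
                raise ValueError(f"term {term_id}: malformed relationship {val!r}")
            graph.add_edge(term_id, parts[1], type="other", relation=parts[0])

    with Path(path).open() as fh:
        for raw in fh:
            line = raw.strip()
            if line == "[Term]":
                flush()
                term_id, in_term, fields = None, True, {}
            elif line.startswith("["):
                flush()
                term_id, in_term = None, False
            elif in_term and ":" in line:
                key, _, val = line.partition(":")
                key, val = key.strip(), val.strip()
                if key == "id":
                    term_id = val
                else:
                    fields.setdefault(key, []).append(val)
        flush()
    # nodes referenced only as parents
    for node in list(graph.nodes):
        graph.nodes[node].setdefault("name", node)
    return GoGraph(graph=graph)


def parse_gaf(path: str | Path) -> list[GoAnnotation]:
    """Parse a GAF 2.2 annotation file (17 tab-separated columns,
    comment lines starting with ``!``)."""
    annotations = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("!") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 7:
                raise ValueError(f"{path}:{lineno}: fewer than 7 GAF columns")
            annotations.append(
                GoAnnotation(
                    accession=cols[1],
                    term=cols[4],
                    evidence_code=cols[6],
                    qualifier=cols[3] or "enables",
                )
            )
    return annotations


def filter_annotations(
    annotations: list[GoAnnotation],
    allowlist: frozenset[str] = DEFAULT_EVIDENCE_ALLOWLIST,
) -> list[GoAnnotation]:
    """Keep annotations whose evidence code is trusted and whose
    qualifier is not negated."""
    return [
        a for a in annotations
        if a.evidence_code in allowlist and not a.negated
    ]


def propagate_annotations(
    annotations: list[GoAnnotation], graph: GoGraph
) -> list[GoAnnotation]:
    """Add ancestor-term annotations through the is_a hierarchy.

    For each annotation (p, t), annotations (p, t') are added for every
    t' reachable from t via is_a edges, inheriting the evidence code of
    the originating explicit annotation.  Annotations to unknown terms
    are skipped with a warning.  Idempotent.
    """
    is_a = graph.is_a_subgraph()
    if not nx.is_directed_acyclic_graph(is_a):
        raise ValueError("ontology is_a relation contains a cycle")
    seen: set[tuple[str, str]] = set()
    out: list[GoAnnotation] = []

    def add(ann: GoAnnotation):
        key = (ann.accession, ann.term)
        if key not in seen:
            seen.add(key)
            out.append(ann)

    for ann in annotations:
        if ann.term not in graph.terms:
            logger.warning("annotation to unknown term %s skipped", ann.term)
            continue
        add(ann)
        for anc in nx.descendants(is_a, ann.term):
            add(GoAnnotation(
                accession=ann.accession,
                term=anc,
                evidence_code=ann.evidence_code,
                qualifier=ann.qualifier,
            ))
    return out


def assemble_labeled_dataset(
    proteins: list[ProteinRecord],
    annotations: list[GoAnnotation],
    config: DatasetConfig,
    has_structure: set[str] | None = None,
) -> LabeledDataset:
    """Label proteins by their (propagated, filtered) class-term
    annotations and apply the curation filters.

    A protein gets label L iff it is annotated with ``class_terms[L]``;
    proteins matching both classes are excluded when
    ``exclude_multilabel``.  Fragments, unreviewed entries (when
    required), sequences with non-standard residues, and proteins
    without structural data (when ``has_structure`` is given) are
    excluded, with per-rule counts recorded.
    """
    annotated: dict[str, set[str]] = {}
    for ann in annotations:
        annotated.setdefault(ann.accession, set()).add(ann.term)

    counts = {
        "multilabel": 0, "fragment": 0, "unreviewed": 0,
        "nonstandard_residues": 0, "no_structure": 0,
    }
    samples: list[tuple[str, str]] = []
    for rec in proteins:
        terms = annotated.get(rec.accession, set())
        labels = [lab for lab, term in config.class_terms.items() if term in terms]
        if not labels:
            continue
        if len(labels) > 1:
            if config.exclude_multilabel:
                counts["multilabel"] += 1
                continue
            labels = [sorted(labels)[0]]
        if rec.fragment:
            counts["fragment"] += 1
            continue
        if config.require_reviewed and not rec.reviewed:
            counts["unreviewed"] += 1
            continue
        if NONSTANDARD_CODES & set(rec.aa_seq):
            counts["nonstandard_residues"] += 1
            continue
        if has_structure is not None and rec.accession not in has_structure:
            counts["no_structure"] += 1
            continue
        samples.append((rec.accession, labels[0]))

    dataset = LabeledDataset(samples=sorted(samples), exclusion_counts=counts)
    for label in config.class_terms:
        if dataset.label_counts.get(label, 0) == 0:
            raise ValueError(f"class {label!r} has zero members")
    return dataset


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = 0
_aligner.open_gap_score = -1
_aligner.extend_gap_score = -0.5


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: exact matches / alignment length."""
    aln = _aligner.align(seq_a, seq_b)[0]
    a, b = aln[0], aln[1]
    matches = sum(x == y and x != "-" for x, y in zip(a, b))
    return matches / len(a)


def reduce_redundancy(
    dataset: LabeledDataset,
    sequences: dict[str, str],
    threshold: float = 0.70,
) -> LabeledDataset:
    """Greedy per-class identity clustering; keep representatives only.

    Within each class, sequences are visited longest-first (ties broken
    by accession); a sequence is retained iff its identity to every
    previously retained representative of the class is strictly below
    ``threshold``.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    kept: list[tuple[str, str]] = []
    by_label: dict[str, list[str]] = {}
    for acc, label in dataset.samples:
        by_label.setdefault(label, []).append(acc)
    for label, accs in by_label.items():
        order = sorted(accs, key=lambda a: (-len(sequences[a]), a))
        reps: list[str] = []
        for acc in order:
            if all(
                pairwise_identity(sequences[acc], sequences[r]) < threshold
                for r in reps
            ):
                reps.append(acc)
        kept.extend((acc, label) for acc in reps)
    return LabeledDataset(
        samples=sorted(kept), exclusion_counts=dict(dataset.exclusion_counts)
    )
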