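"""FASTA I/O and sequence validation for amino-acid and 3Di sequences.

Both alphabets use the same 20 uppercase letters.  Long proteins whose
structures were predicted in overlapping windows arrive as multiple 3Di
fragments; :func:`merge_3di_fragments` reassembles them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import AA_ALPHABET, TDI_ALPHABET

__all__ = [
    "ProteinRecord",
    "TdiRecord",
    "FragmentSet",
    "read_fasta",
    "write_fasta",
    "filter_standard_residues",
    "split_into_fragments",
    "merge_3di_fragments",
    "NONSTANDARD_CODES",
    "FRAGMENT_LENGTH_THRESHOLD",
    "DEFAULT_WINDOW_LENGTH",
    "DEFAULT_OVERLAP",
]

NONSTANDARD_CODES = frozenset("BOUZX")

#: Proteins strictly longer than this are expected to arrive fragmented.
FRAGMENT_LENGTH_THRESHOLD = 2700
DEFAULT_WINDOW_LENGTH = 1400
DEFAULT_OVERLAP = 1200

_AF_HEADER = re.compile(r"^AF[-_]([A-Z0-9]+)[-_]F\d+")


class AlphabetError(ValueError):
    """A sequence contains a character outside the declared alphabet."""


@dataclass(frozen=True)
class ProteinRecord:
    """An accession with its amino-acid sequence and curation flags."""

    accession: str
    aa_seq: str
    reviewed: bool = True
    fragment: bool = False
    existence_evidence: int = 1
    gene_names: tuple[str, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.aa_seq)


@dataclass(frozen=True)
class TdiRecord:
    """The 3Di structural-state sequence paired to an accession."""

    accession: str
    tdi_seq: str

    def __len__(self) -> int:
        return len(self.tdi_seq)


@dataclass(frozen=True)
class FragmentSet:
    """Ordered overlapping 3Di fragments of one long protein."""

    accession: str
    fragments: tuple[str, ...]
    window_length: int = DEFAULT_WINDOW_LENGTH
    overlap: int = DEFAULT_OVERLAP


def _extract_accession(header: str) -> str:
    token = header.split()[0]
    m = _AF_HEADER.match(token)
    if m:
        return m.group(1)
    return token


def _validate(accession: str, seq: str, alphabet: str) -> str:
    seq = seq.upper()
    if not seq:
        raise AlphabetError(f"record {accession!r}: empty sequence")
    bad = set(seq) - set(alphabet)
    if bad:
        raise AlphabetError(
            f"record {accession!r}: characters {sorted(bad)} outside the "
            f"declared alphabet"
        )
    return seq


def read_fasta(path: str | Path, alphabet: Literal["AA", "3Di"] = "AA"):
    """Read a FASTA file into ``ProteinRecord`` or ``TdiRecord`` objects.

    The accession is the header token before the first whitespace, except
    for ``AF-<accession>-F<n>`` style headers, where the embedded
    accession is used.  Sequences are uppercased and validated against
    the 20-letter alphabet.

    Parameters
    ----------
    path:
        FASTA file to read.
    alphabet:
        ``"AA"`` yields :class:`ProteinRecord`, ``"3Di"`` yields
        :class:`TdiRecord`.
    """
    letters = AA_ALPHABET if alphabet == "AA" else TDI_ALPHABET
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = _extract_accession(rec.description or rec.id)
        seq = _validate(accession, str(rec.seq), letters)
        if alphabet == "AA":
            records.append(ProteinRecord(accession=accession, aa_seq=seq))
        else:
            records.append(TdiRecord(accession=accession, tdi_seq=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord | TdiRecord], path: str | Path) -> None:
    """Write records to a FASTA file (accession as the full header)."""
    seqrecords = []
    for rec in records:
        seq = rec.aa_seq if isinstance(rec, ProteinRecord) else rec.tdi_seq
        seqrecords.append(
            SeqRecord(Seq(seq), id=rec.accession, description="")
        )
    SeqIO.write(seqrecords, str(path), "fasta")


def filter_standard_residues(
    records: Iterable[ProteinRecord],
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Partition records by presence of non-standard residue codes.

    Records containing any of B, O, U, Z, or X are dropped; the two
    returned lists are disjoint and exhaustive.
    """
    kept, dropped = [], []
    for rec in records:
        if NONSTANDARD_CODES & set(rec.aa_seq):
            dropped.append(rec)
        else:
            kept.append(rec)
    return kept, dropped


def split_into_fragments(
    accession: str,
    seq: str,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    overlap: int = DEFAULT_OVERLAP,
) -> FragmentSet:
    """Split a sequence into overlapping windows (inverse of the merge).

    Every fragment except possibly the last has ``window_length``
    characters; consecutive fragments overlap by ``overlap`` positions.
    """
    if not 0 <= overlap < window_length:
        raise ValueError("require 0 <= overlap < window_length")
    step = window_length - overlap
    fragments = []
    start = 0
    while True:
        fragments.append(seq[start : start + window_length])
        if start + window_length >= len(seq):
            break
        start += step
    return FragmentSet(
        accession=accession,
        fragments=tuple(fragments),
        window_length=window_length,
        overlap=overlap,
    )


def merge_3di_fragments(fragset: FragmentSet) -> TdiRecord:
    """Merge overlapping 3Di fragments back into one sequence.

    Starts with the first fragment and, for each subsequent fragment,
    appends the suffix after the overlap (1-based positions
    ``overlap + 1 …  end``).  Consecutive fragments must agree on their
    shared overlap region.
    """
    frags = fragset.fragments
    if not frags:
        raise ValueError(f"{fragset.accession}: no fragments")
    if not fragset.overlap < fragset.window_length:
        raise ValueError("overlap must be smaller than window_length")
    merged = frags[0]
    for idx in range(1, len(frags)):
        frag = frags[idx]
        expected = merged[-fragset.overlap :] if fragset.overlap else ""
        actual = frag[: fragset.overlap]
        if expected != actual:
            for pos, (a, b) in enumerate(zip(expected, actual), start=1):
                if a != b:
                    raise ValueError(
                        f"{fragset.accession}: fragments {idx} and {idx + 1} "
                        f"disagree at overlap position {pos}"
                    )
            raise ValueError(
                f"{fragset.accession}: fragment {idx + 1} shorter than overlap"
            )
        merged += frag[fragset.overlap :]
    return TdiRecord(accession=fragset.accession, tdi_seq=merged)
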