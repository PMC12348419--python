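"""PSI-BLAST ASCII PSSM parsing and conservation-profile features.

A PSSM for a sequence of length ``n`` is an ``n x 20`` integer matrix of
log-odds scores.  Averaging its rows over all positions carrying each
residue type yields the 20x20 conservation profile; concatenating the
four profiles from {uniref50, uniref90} x {1, 3 iterations} gives the
1600-dimensional Multi-PSSM feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import AA_ALPHABET

__all__ = [
    "Pssm",
    "ConservationProfile",
    "parse_ascii_pssm",
    "write_ascii_pssm",
    "conservation_profile",
    "multi_pssm",
    "MULTI_PSSM_ORDER",
    "PSIBLAST_COLUMN_ORDER",
    "pssm_cache_path",
]

#: Column order used by PSI-BLAST ASCII output.
PSIBLAST_COLUMN_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Block order of the Multi-PSSM concatenation: (database_tag, iterations).
MULTI_PSSM_ORDER = (
    ("uniref50", 1),
    ("uniref50", 3),
    ("uniref90", 1),
    ("uniref90", 3),
)

#: Metadata of the homology search that produced cached PSSMs.
PSIBLAST_EVALUE = 0.002


class PssmParseError(ValueError):
    pass


@dataclass(frozen=True)
class Pssm:
    """Per-position integer log-odds matrix, columns in sorted AA order."""

    accession: str
    sequence: str
    log_odds: np.ndarray  # (n, 20) int
    database_tag: str = "uniref50"
    iterations: int = 3

    def __post_init__(self):
        if self.log_odds.shape != (len(self.sequence), 20):
            raise ValueError(
                f"{self.accession}: log_odds shape {self.log_odds.shape} does "
                f"not match sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class ConservationProfile:
    """20x20 mean log-odds per residue type; absent types are zero rows."""

    matrix: np.ndarray  # (20, 20)

    def __post_init__(self):
        if self.matrix.shape != (20, 20):
            raise ValueError("conservation profile must be 20x20")


def pssm_cache_path(root: str | Path, accession: str, database_tag: str, iterations: int) -> Path:
    """Cache layout ``<db>_<iters>/<accession>.pssm``."""
    return Path(root) / f"{database_tag}_{iterations}" / f"{accession}.pssm"


def parse_ascii_pssm(
    path: str | Path,
    accession: str | None = None,
    database_tag: str = "uniref50",
    iterations: int = 3,
) -> Pssm:
    """Parse the ASCII PSSM emitted by an iterative profile search.

    Reads the first 20 score columns (log-odds block) of each position
    row; the frequency block and trailing statistics are ignored.  The
    query sequence is reconstructed from the residue-letter column.
    Columns are re-ordered from the search tool's ``A R N D …`` layout
    into sorted alphabet order.
    """
    path = Path(path)
    rows: list[list[int]] = []
    letters: list[str] = []
    column_order = PSIBLAST_COLUMN_ORDER
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            # header line listing the 20 residue columns (possibly twice)
            if all(p in set(AA_ALPHABET) and len(p) == 1 for p in parts) and len(parts) >= 20:
                column_order = "".join(parts[:20])
                continue
            if not parts[0].isdigit():
                continue
            pos = int(parts[0])
            if len(parts) < 22:
                raise PssmParseError(
                    f"{path}:{lineno}: position row with fewer than 20 score columns"
                )
            letter = parts[1]
            try:
                scores = [int(p) for p in parts[2:22]]
            except ValueError as exc:
                raise PssmParseError(f"{path}:{lineno}: malformed score column") from exc
            if pos != len(rows) + 1:
                raise PssmParseError(
                    f"{path}:{lineno}: expected position {len(rows) + 1}, got {pos}"
                )
            letters.append(letter)
            rows.append(scores)
    if not rows:
        raise PssmParseError(f"{path}: no position rows found")
    matrix = np.array(rows, dtype=int)
    # re-order columns into sorted alphabet order
    perm = [column_order.index(a) for a in AA_ALPHABET]
    matrix = matrix[:, perm]
    return Pssm(
        accession=accession or path.stem.removesuffix(".pssm"),
        sequence="".join(letters),
        log_odds=matrix,
        database_tag=database_tag,
        iterations=iterations,
    )


def write_ascii_pssm(pssm: Pssm, path: str | Path) -> None:
    """Write a PSSM in the standard ASCII layout (round-trips with
    :func:`parse_ascii_pssm`; the frequency block is written as zeros)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    perm = [AA_ALPHABET.index(a) for a in PSIBLAST_COLUMN_ORDER]
    with path.open("w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted, "
            "and observed percentages\n"
        )
        header = " ".join(PSIBLAST_COLUMN_ORDER)
        fh.write(f"            {header}   {header}\n")
        for i, letter in enumerate(pssm.sequence):
            scores = " ".join(f"{v:3d}" for v in pssm.log_odds[i, perm])
            freqs = " ".join("0" for _ in range(20))
            fh.write(f"{i + 1:5d} {letter}  {scores}  {freqs}  0.00 0.00\n")
        fh.write("\n")


def conservation_profile(pssm: Pssm) -> ConservationProfile:
    """Average log-odds rows per residue type into a 20x20 profile.

    The row for residue type ``a`` is the mean of the log-odds rows at
    all positions where the sequence has ``a``; rows for residue types
    absent from the sequence are all zeros.
    """
    matrix = np.zeros((20, 20))
    seq = np.array(list(pssm.sequence))
    for i, a in enumerate(AA_ALPHABET):
        mask = seq == a
        if mask.any():
            matrix[i] = pssm.log_odds[mask].mean(axis=0)
    return ConservationProfile(matrix=matrix)


def multi_pssm(profiles: dict[tuple[str, int], ConservationProfile]) -> np.ndarray:
    """Concatenate the four conservation profiles into one 1600-vector.

    Requires exactly the configurations in :data:`MULTI_PSSM_ORDER`;
    each 20x20 profile is flattened row-major and the blocks are joined
    in that fixed order.
    """
    missing = [cfg for cfg in MULTI_PSSM_ORDER if cfg not in profiles]
    if missing:
        raise KeyError(f"missing PSSM configurations: {missing}")
    return np.concatenate([profiles[cfg].matrix.ravel() for cfg in MULTI_PSSM_ORDER])


def multi_pssm_feature_names() -> tuple[str, ...]:
    names = []
    for db, iters in MULTI_PSSM_ORDER:
        for a in AA_ALPHABET:
            for b in AA_ALPHABET:
                names.append(f"MULTI-PSSM:{db}_{iters}:{a}>{b}")
    return tuple(names)
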