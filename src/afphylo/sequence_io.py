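"""Read, validate and write multi-FASTA nucleotide input.

Validation is deliberately forgiving: case is normalised, RNA ``U`` becomes
``T``, and every IUPAC ambiguity code (or any other stray character) becomes
``N``.  Ambiguous positions are *kept* as ``N`` rather than dropped so the
counting layer can skip exactly the k-mer windows they touch.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Iterable, List

from Bio import SeqIO

from .errors import DuplicateIdError, EmptyInputError, EmptySequenceError

__all__ = ["Sequence", "validate", "read_fasta", "write_fasta"]

# A, C, G, T pass through; U -> T; everything else (IUPAC ambiguity codes
# R,Y,S,W,K,M,B,D,H,V and any unknown) -> N.
_U_TO_T = str.maketrans("U", "T")
_NON_ACGTN = re.compile(r"[^ACGTN]")


def validate(raw: str) -> str:
    """Normalise a raw nucleotide string to the {A,C,G,T,N} alphabet.

    Total on strings and idempotent: whitespace is stripped, letters are
    uppercased, ``U`` maps to ``T`` and anything outside {A,C,G,T} maps
    to ``N``.
    """
    s = "".join(raw.split()).upper().translate(_U_TO_T)
    return _NON_ACGTN.sub("N", s)


@dataclass(frozen=True)
class Sequence:
    """A validated nucleotide sequence with an identifier.

    ``residues`` is guaranteed to contain only A, C, G, T, N.
    """

    id: str
    residues: str = field(repr=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise EmptySequenceError("sequence identifier must be non-empty")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


def read_fasta(path: str | os.PathLike) -> List[Sequence]:
    """Load a multi-FASTA file into an ordered list of validated sequences.

    The identifier of each record is the first whitespace-delimited token of
    its header line.  Raises :class:`FileNotFoundError` for a missing file,
    :class:`EmptyInputError` for a file with no records,
    :class:`EmptySequenceError` for a record with an empty body, and
    :class:`DuplicateIdError` when two records share an id.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"FASTA file not found: {path}")
    seqs: List[Sequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = validate(str(rec.seq))
        if not residues:
            raise EmptySequenceError(f"record '{rec.id}' has an empty sequence body")
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate sequence id '{rec.id}'")
        seen.add(rec.id)
        seqs.append(Sequence(id=rec.id, residues=residues))
    if not seqs:
        raise EmptyInputError(f"no FASTA records found in {path}")
    return seqs


def write_fasta(seqs: Iterable[Sequence], path: str | os.PathLike, width: int = 70) -> None:
    """Write sequences as wrapped multi-FASTA."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")
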