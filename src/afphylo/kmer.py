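"""k-mer counting by the base-4 index transform.

A k-mer over {A,C,G,T} is mapped to an integer in ``[0, 4^k)`` by reading it
as a base-4 number with digits A=0, C=1, G=2, T=3.  The index addresses a
dense count array directly, and sliding the window one base to the right is a
single arithmetic update::

    idx_next = (idx * 4 + code(next_base)) mod 4^k

which drops the oldest digit and appends the new one, so counting is one pass
over the sequence.  Windows containing ``N`` are skipped entirely: after an
``N`` the index is rebuilt from the next k clean bases, and skipped windows
do not contribute to ``total_windows``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence as PySequence, Union

import numpy as np

from .errors import EmptyInputError, ParameterError
from .sequence_io import Sequence

__all__ = [
    "MAX_K",
    "kmer_index",
    "index_to_kmer",
    "KmerSpectrum",
    "count_kmers",
    "FrequencyMatrix",
    "build_frequency_matrix",
    "write_spectrum_tsv",
]

#: Upper bound on k: the dense count array has 4^k cells.
MAX_K = 14

_BASES = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
# byte-level translation: ACGT -> 0..3; any other byte stays >3 and is
# treated as an ambiguous position.
_CODE_TABLE = bytes.maketrans(b"ACGT", bytes([0, 1, 2, 3]))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _check_k(k: int) -> None:
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ParameterError(f"k must be an integer >= 1, got {k!r}")
    if k > MAX_K:
        raise ParameterError(
            f"k={k} exceeds the supported maximum of {MAX_K} "
            f"(the count array has 4^k cells)"
        )


def kmer_index(word: str) -> int:
    """Map an N-free k-mer to its base-4 integer index.

    Bijective over the ``4^k`` words of length k; ``AAA... -> 0`` and
    ``TTT... -> 4^k - 1``.
    """
    idx = 0
    for ch in word:
        code = _CODE.get(ch)
        if code is None:
            raise ParameterError(f"invalid character {ch!r} in k-mer {word!r}")
        idx = idx * 4 + code
    return idx


def index_to_kmer(idx: int, k: int) -> str:
    """Inverse of :func:`kmer_index` for a given k."""
    _check_k(k)
    if not 0 <= idx < 4**k:
        raise ParameterError(f"index {idx} out of range for k={k}")
    out = []
    for _ in range(k):
        out.append(_BASES[idx % 4])
        idx //= 4
    return "".join(reversed(out))


@dataclass
class KmerSpectrum:
    """Dense k-mer counts for a single sequence.

    ``counts[kmer_index(w)]`` is the number of N-free windows equal to ``w``;
    ``total_windows`` is their total, i.e. ``sum(counts)``.
    """

    k: int
    counts: np.ndarray
    total_windows: int
    seq_length: int
    label: Optional[str] = None

    @property
    def frequencies(self) -> np.ndarray:
        """Relative frequencies ``c_w / total_windows`` (all-zero if empty)."""
        if self.total_windows == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / float(self.total_windows)


def _reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


def _count_into(residues: str, k: int) -> tuple[np.ndarray, int]:
    four_k = 4**k
    data = residues.encode("ascii").translate(_CODE_TABLE)
    hits: List[int] = []
    append = hits.append
    idx = 0
    run = 0
    for c in data:
        if c > 3:  # ambiguous base: restart the window
            idx = 0
            run = 0
            continue
        idx = (idx * 4 + c) % four_k
        run += 1
        if run >= k:
            append(idx)
    if hits:
        counts = np.bincount(hits, minlength=four_k).astype(np.int64)
    else:
        counts = np.zeros(four_k, dtype=np.int64)
    return counts, len(hits)


def count_kmers(
    seq: Union[Sequence, str], k: int, add_reverse_complement: bool = False
) -> KmerSpectrum:
    """Count all k-mers of one sequence with the rolling index update.

    A sequence shorter than k yields an all-zero spectrum with
    ``total_windows == 0`` (not an error).  With ``add_reverse_complement``
    the counts of the reverse-complement strand are added in, for inputs of
    unknown orientation.
    """
    _check_k(k)
    if isinstance(seq, Sequence):
        residues, label = seq.residues, seq.id
    else:
        residues, label = seq, None
    counts, total = _count_into(residues, k)
    if add_reverse_complement:
        rc_counts, rc_total = _count_into(_reverse_complement(residues), k)
        counts += rc_counts
        total += rc_total
    return KmerSpectrum(
        k=k, counts=counts, total_windows=total, seq_length=len(residues), label=label
    )


@dataclass
class FrequencyMatrix:
    """The ``4^k``-by-N relative-frequency matrix over a sequence collection.

    Column j holds ``f_w = c_w / total_windows`` for sequence j; columns from
    an empty spectrum (no valid window) are all-zero and flagged in
    ``zero_columns``.
    """

    k: int
    labels: List[str]
    values: np.ndarray  # shape (4^k, N)
    zero_columns: List[str]


def build_frequency_matrix(
    spectra: PySequence[KmerSpectrum], labels: Optional[Iterable[str]] = None
) -> FrequencyMatrix:
    """Merge per-sequence spectra into the frequency matrix."""
    spectra = list(spectra)
    if not spectra:
        raise EmptyInputError("cannot build a frequency matrix from zero spectra")
    k = spectra[0].k
    if any(s.k != k for s in spectra):
        raise ParameterError("all spectra must share the same k")
    if labels is None:
        labels = [s.label if s.label is not None else f"seq{i}" for i, s in enumerate(spectra)]
    labels = list(labels)
    if len(labels) != len(spectra):
        raise ParameterError("labels and spectra length mismatch")
    values = np.column_stack([s.frequencies for s in spectra])
    zero_columns = [lab for lab, s in zip(labels, spectra) if s.total_windows == 0]
    return FrequencyMatrix(k=k, labels=labels, values=values, zero_columns=zero_columns)


def write_spectrum_tsv(spectrum: KmerSpectrum, fh) -> None:
    """Dump one spectrum as TSV rows (k-mer, count, frequency), index order."""
    freqs = spectrum.frequencies
    for idx in range(4**spectrum.k):
        fh.write(
            f"{index_to_kmer(idx, spectrum.k)}\t{int(spectrum.counts[idx])}\t{freqs[idx]:.10g}\n"
        )
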