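"""The seven pairwise k-mer distance measures and the N-by-N matrix.

Three geometric measures act on relative-frequency vectors:

    Ch(f1, f2) = max_w |f1_w - f2_w|
    Ma(f1, f2) = sum_w |f1_w - f2_w|
    Eu(f1, f2) = sqrt(sum_w (f1_w - f2_w)^2)

Four correlation-type measures map a normalised similarity to a dissimilarity
via ``(1 - correlation) / 2``, so identical inputs give 0, uncorrelated
inputs give 0.5 and anti-correlated inputs approach 1:

* ``d2`` — cosine of the raw count vectors.
* ``d2star`` / ``d2S`` — correlations of counts centred on an order-M Markov
  background (``c_w - n p_w``), with the d2star normaliser ``sqrt(n1 p1 n2 p2)``
  per word, or the d2S normaliser ``sqrt(c1_hat^2 + c2_hat^2)``.
* ``Hao`` — the composition-vector measure: relative deviation of observed
  k-mer frequencies from the order-(k-2) Markov prediction
  ``f0_w = f(prefix) f(suffix) / f(middle)``, compared by cosine.

Words whose background probability is zero under either sequence's model are
dropped from the d2S/d2star sums (their centred contribution is
ill-defined).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence as PySequence, TextIO, Tuple, Union

import numpy as np

from .background import MarkovModel, expected_probs, fit_markov
from .errors import MatrixError, ParameterError, UndefinedDistanceError
from .kmer import KmerSpectrum, count_kmers
from .sequence_io import Sequence

__all__ = [
    "MEASURES",
    "MeasureSpec",
    "DistanceMatrix",
    "geometric_distance",
    "d2_distance",
    "d2star_distance",
    "d2s_distance",
    "hao_distance",
    "pairwise_matrix",
    "write_phylip",
    "read_phylip",
    "write_tsv",
]

logger = logging.getLogger(__name__)

MEASURES = ("Ch", "Ma", "Eu", "Hao", "d2", "d2S", "d2star")
_GEOMETRIC = ("Ch", "Ma", "Eu")
_BACKGROUND = ("d2S", "d2star")


@dataclass(frozen=True)
class MeasureSpec:
    """A validated (measure, k, M) combination.

    M applies only to d2S and d2star (default 0); Hao fixes its background
    to order k-2 internally and needs k >= 3.
    """

    name: str
    k: int
    M: Optional[int] = None

    def __post_init__(self) -> None:
        if self.name not in MEASURES:
            raise ParameterError(
                f"unknown measure {self.name!r}; choose one of {', '.join(MEASURES)}"
            )
        if self.k < 1:
            raise ParameterError(f"k must be >= 1, got {self.k}")
        if self.name == "Hao" and self.k < 3:
            raise ParameterError("the Hao measure requires k >= 3")
        if self.name in _BACKGROUND:
            if self.M is None:
                object.__setattr__(self, "M", 0)
            elif self.M < 0:
                raise ParameterError(f"Markov order M must be >= 0, got {self.M}")
            elif self.M > self.k:
                raise ParameterError(f"M={self.M} must not exceed k={self.k}")
        elif self.M is not None:
            raise ParameterError(
                f"measure {self.name!r} takes no Markov order (got M={self.M})"
            )


def geometric_distance(f1: np.ndarray, f2: np.ndarray, name: str) -> float:
    """Chebyshev / Manhattan / Euclidean distance between frequency vectors."""
    if name not in _GEOMETRIC:
        raise ParameterError(f"unknown geometric measure {name!r}")
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    if f1.shape != f2.shape:
        raise ParameterError(f"vector length mismatch: {f1.shape} vs {f2.shape}")
    diff = f1 - f2
    if name == "Ch":
        return float(np.max(np.abs(diff)))
    if name == "Ma":
        return float(np.sum(np.abs(diff)))
    return float(math.sqrt(np.dot(diff, diff)))


def _check_pair(s1: KmerSpectrum, s2: KmerSpectrum) -> None:
    if s1.k != s2.k:
        raise ParameterError(f"spectra have different k: {s1.k} vs {s2.k}")
    if s1.total_windows == 0 or s2.total_windows == 0:
        raise UndefinedDistanceError(
            "distance undefined for an empty spectrum (no valid k-mer window)"
        )


def d2_distance(s1: KmerSpectrum, s2: KmerSpectrum) -> float:
    """Half one-minus-cosine of the raw count vectors."""
    _check_pair(s1, s2)
    c1 = s1.counts.astype(float)
    c2 = s2.counts.astype(float)
    num = float(np.dot(c1, c2))
    denom = math.sqrt(float(np.dot(c1, c1))) * math.sqrt(float(np.dot(c2, c2)))
    return 0.5 * (1.0 - num / denom)


def _centered(s: KmerSpectrum, p: np.ndarray) -> np.ndarray:
    return s.counts.astype(float) - s.total_windows * p


def d2star_distance(
    s1: KmerSpectrum, s2: KmerSpectrum, m1: MarkovModel, m2: MarkovModel
) -> float:
    """d2star: background-centred counts normalised by sqrt(n p) per word."""
    _check_pair(s1, s2)
    p1 = expected_probs(m1, s1.k)
    p2 = expected_probs(m2, s2.k)
    mask = (p1 > 0) & (p2 > 0)
    if not mask.any():
        raise UndefinedDistanceError("d2star undefined: all words have zero background probability")
    dropped = int(mask.size - mask.sum())
    if dropped:
        logger.debug("d2star: dropped %d words with zero background probability", dropped)
    c1h = _centered(s1, p1)[mask]
    c2h = _centered(s2, p2)[mask]
    w1 = s1.total_windows * p1[mask]
    w2 = s2.total_windows * p2[mask]
    num = float(np.sum(c1h * c2h / np.sqrt(w1 * w2)))
    n1 = float(np.sum(c1h * c1h / w1))
    n2 = float(np.sum(c2h * c2h / w2))
    if n1 == 0.0 or n2 == 0.0:
        raise UndefinedDistanceError("d2star undefined: a centred count vector has zero norm")
    return 0.5 * (1.0 - num / (math.sqrt(n1) * math.sqrt(n2)))


def d2s_distance(
    s1: KmerSpectrum, s2: KmerSpectrum, m1: MarkovModel, m2: MarkovModel
) -> float:
    """d2S: background-centred counts normalised by sqrt(c1^2 + c2^2) per word."""
    _check_pair(s1, s2)
    p1 = expected_probs(m1, s1.k)
    p2 = expected_probs(m2, s2.k)
    mask = (p1 > 0) & (p2 > 0)
    if not mask.any():
        raise UndefinedDistanceError("d2S undefined: all words have zero background probability")
    c1h = _centered(s1, p1)[mask]
    c2h = _centered(s2, p2)[mask]
    a = np.sqrt(c1h * c1h + c2h * c2h)
    nz = a > 0
    if not nz.any():
        raise UndefinedDistanceError("d2S undefined: all centred counts are zero")
    num = float(np.sum(c1h[nz] * c2h[nz] / a[nz]))
    n1 = float(np.sum(c1h[nz] * c1h[nz] / a[nz]))
    n2 = float(np.sum(c2h[nz] * c2h[nz] / a[nz]))
    if n1 == 0.0 or n2 == 0.0:
        raise UndefinedDistanceError("d2S undefined: a centred count vector has zero norm")
    return 0.5 * (1.0 - num / (math.sqrt(n1) * math.sqrt(n2)))


def composition_vector(
    spec_k: KmerSpectrum, spec_km1: KmerSpectrum, spec_km2: KmerSpectrum
) -> np.ndarray:
    """Hao/CVTree composition vector: (f - f0)/f0 against the order-(k-2)
    Markov prediction f0_w = f(prefix_{k-1}) f(suffix_{k-1}) / f(middle_{k-2});
    components with f0 = 0 are set to 0."""
    k = spec_k.k
    if k < 3:
        raise ParameterError("the Hao composition vector requires k >= 3")
    if spec_km1.k != k - 1 or spec_km2.k != k - 2:
        raise ParameterError("auxiliary spectra must have orders k-1 and k-2")
    f = spec_k.frequencies
    f1 = spec_km1.frequencies
    f2 = spec_km2.frequencies
    idx = np.arange(4**k)
    pre = idx >> 2  # first k-1 bases
    suf = idx % 4 ** (k - 1)  # last k-1 bases
    mid = pre % 4 ** (k - 2)  # middle k-2 bases
    with np.errstate(divide="ignore", invalid="ignore"):
        f0 = np.where(f2[mid] > 0, f1[pre] * f1[suf] / f2[mid], 0.0)
        a = np.where(f0 > 0, (f - f0) / f0, 0.0)
    return a


def hao_distance(
    s1: KmerSpectrum,
    s2: KmerSpectrum,
    aux1: Tuple[KmerSpectrum, KmerSpectrum],
    aux2: Tuple[KmerSpectrum, KmerSpectrum],
) -> float:
    """Hao composition-vector distance, half one-minus-cosine of the
    composition vectors.  ``aux1``/``aux2`` are each sequence's spectra at
    (k-1, k-2)."""
    _check_pair(s1, s2)
    a1 = composition_vector(s1, *aux1)
    a2 = composition_vector(s2, *aux2)
    n1 = math.sqrt(float(np.dot(a1, a1)))
    n2 = math.sqrt(float(np.dot(a2, a2)))
    if n1 == 0.0 or n2 == 0.0:
        raise UndefinedDistanceError("Hao undefined: zero-norm composition vector")
    corr = float(np.dot(a1, a2)) / (n1 * n2)
    return 0.5 * (1.0 - corr)


@dataclass
class DistanceMatrix:
    """A labelled symmetric distance matrix with zero diagonal."""

    labels: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise MatrixError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )

    def validate(self, tol: float = 1e-8) -> None:
        """Check symmetry, finite entries and zero diagonal."""
        v = self.values
        if not np.all(np.isfinite(v)):
            raise MatrixError("distance matrix contains NaN or infinite entries")
        if np.max(np.abs(v - v.T)) > tol:
            raise MatrixError("distance matrix is not symmetric")
        if np.max(np.abs(np.diag(v))) > tol:
            raise MatrixError("distance matrix diagonal is not zero")


def pairwise_matrix(
    sequences: PySequence[Union[Sequence, str]],
    spec: MeasureSpec,
    add_reverse_complement: bool = False,
) -> DistanceMatrix:
    """Compute the full N-by-N matrix for one measure.

    Spectra, background models and composition vectors are computed once per
    sequence and reused across all N(N-1)/2 pairs.
    """
    seqs = [
        s if isinstance(s, Sequence) else Sequence(id=f"seq{i}", residues=s)
        for i, s in enumerate(sequences)
    ]
    if len(seqs) < 2:
        raise ParameterError("pairwise distances need at least 2 sequences")
    labels = [s.id for s in seqs]
    spectra = [count_kmers(s, spec.k, add_reverse_complement) for s in seqs]

    models: List[MarkovModel] = []
    aux: List[Tuple[KmerSpectrum, KmerSpectrum]] = []
    if spec.name in _BACKGROUND:
        models = [fit_markov(s, spec.M) for s in seqs]
    elif spec.name == "Hao":
        aux = [
            (
                count_kmers(s, spec.k - 1, add_reverse_complement),
                count_kmers(s, spec.k - 2, add_reverse_complement),
            )
            for s in seqs
        ]

    n = len(seqs)
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                if spec.name in _GEOMETRIC:
                    d = geometric_distance(
                        spectra[i].frequencies, spectra[j].frequencies, spec.name
                    )
                elif spec.name == "d2":
                    d = d2_distance(spectra[i], spectra[j])
                elif spec.name == "d2star":
                    d = d2star_distance(spectra[i], spectra[j], models[i], models[j])
                elif spec.name == "d2S":
                    d = d2s_distance(spectra[i], spectra[j], models[i], models[j])
                else:  # Hao
                    d = hao_distance(spectra[i], spectra[j], aux[i], aux[j])
            except UndefinedDistanceError as exc:
                raise UndefinedDistanceError(
                    f"distance undefined for pair ({labels[i]}, {labels[j]}): {exc}"
                ) from exc
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values)


def write_phylip(dm: DistanceMatrix, fh: TextIO) -> None:
    """Relaxed PHYLIP square format: N, then one whitespace-separated row per
    taxon.  Values carry 17 significant digits so a written matrix reproduces
    the in-memory one exactly on re-read."""
    n = len(dm.labels)
    fh.write(f"{n}\n")
    for label, row in zip(dm.labels, dm.values):
        name = label if len(label) >= 10 else f"{label:<10s}"
        fh.write(name + "  " + "  ".join(f"{v:.17g}" for v in row) + "\n")


def read_phylip(fh: TextIO) -> DistanceMatrix:
    """Parse a relaxed PHYLIP square distance matrix."""
    header = fh.readline().split()
    if not header:
        raise MatrixError("empty PHYLIP matrix file")
    try:
        n = int(header[0])
    except ValueError as exc:
        raise MatrixError(f"bad PHYLIP header line: {header!r}") from exc
    labels: List[str] = []
    rows: List[List[float]] = []
    for line in fh:
        parts = line.split()
        if not parts:
            continue
        labels.append(parts[0])
        try:
            rows.append([float(x) for x in parts[1:]])
        except ValueError as exc:
            raise MatrixError(f"bad matrix row for taxon {parts[0]!r}") from exc
    if len(labels) != n or any(len(r) != n for r in rows):
        raise MatrixError(
            f"PHYLIP matrix is not {n}x{n}: got {len(labels)} rows"
        )
    return DistanceMatrix(labels=labels, values=np.array(rows))


def write_tsv(dm: DistanceMatrix, fh: TextIO) -> None:
    """TSV dialect preserving full labels (header row + labelled rows)."""
    fh.write("\t" + "\t".join(dm.labels) + "\n")
    for label, row in zip(dm.labels, dm.values):
        fh.write(label + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")
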