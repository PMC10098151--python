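"""Per-sequence Markov background models.

The d2S and d2star statistics centre observed k-mer counts on the counts
expected under a background model of the sequence itself.  The background is
an order-M Markov chain estimated by maximum likelihood from the sequence's
own (M+1)-mer and M-mer counts:

    P(b | c_1..c_M) = count(c_1..c_M b) / sum_b' count(c_1..c_M b')

and the probability of a k-mer ``w`` is the empirical frequency of its first
M bases times the product of transition probabilities along the word:

    p_w = f(w_1..w_M) * prod_{j=M+1..k} P(w_j | w_{j-M}..w_{j-1})

For M=0 this reduces to the i.i.d. model, p_w = prod_j p(w_j).  Contexts that
never occur in the sequence get a uniform transition row (and are flagged) so
short sequences degrade gracefully instead of erroring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .errors import ParameterError
from .kmer import count_kmers, kmer_index
from .sequence_io import Sequence

__all__ = ["MarkovModel", "fit_markov", "expected_kmer_prob", "expected_probs"]


@dataclass
class MarkovModel:
    """Order-M background model fitted from one sequence.

    ``state_freqs`` are the relative frequencies of all 4^M words (for M=0 a
    single entry 1.0, the empty word); ``transition[c]`` is the probability
    vector over A,C,G,T given context index ``c``; ``uniform_contexts`` flags
    contexts never observed, whose rows were set uniform.
    """

    order: int
    state_freqs: np.ndarray  # length 4^M
    transition: np.ndarray  # shape (4^M, 4)
    uniform_contexts: np.ndarray  # bool, length 4^M


def fit_markov(seq: Union[Sequence, str], M: int) -> MarkovModel:
    """Maximum-likelihood order-M model from a sequence's own word counts."""
    if not isinstance(M, (int, np.integer)) or M < 0:
        raise ParameterError(f"Markov order M must be an integer >= 0, got {M!r}")
    counts_m1 = count_kmers(seq, M + 1)
    if counts_m1.total_windows == 0:
        raise ParameterError(
            f"sequence has no N-free window of length {M + 1}; "
            f"use a smaller Markov order than M={M}"
        )
    trans_counts = counts_m1.counts.reshape(4**M, 4).astype(float)
    context_counts = trans_counts.sum(axis=1)
    uniform = context_counts == 0
    transition = np.empty_like(trans_counts)
    transition[uniform] = 0.25
    observed = ~uniform
    transition[observed] = trans_counts[observed] / context_counts[observed, None]
    if M == 0:
        state_freqs = np.array([1.0])
    else:
        state_freqs = count_kmers(seq, M).frequencies
    return MarkovModel(
        order=M,
        state_freqs=state_freqs,
        transition=transition,
        uniform_contexts=uniform,
    )


def expected_kmer_prob(model: MarkovModel, word: str) -> float:
    """Probability of one N-free k-mer under the background model."""
    M = model.order
    if len(word) < M:
        raise ParameterError(
            f"word {word!r} is shorter than the model order M={M}"
        )
    codes = [kmer_index(ch) for ch in word]  # single-char index == base code
    if M == 0:
        p = 1.0
        ctx = 0
        start = 0
    else:
        p = float(model.state_freqs[kmer_index(word[:M])])
        ctx = kmer_index(word[:M])
        start = M
    mod = 4**M
    for j in range(start, len(word)):
        p *= float(model.transition[ctx, codes[j]])
        ctx = (ctx * 4 + codes[j]) % mod
    return p


def expected_probs(model: MarkovModel, k: int) -> np.ndarray:
    """Vector of p_w for all 4^k words, addressed by the base-4 index.

    Built by extending word probabilities one base at a time: the context of
    a length-l word is its last M bases, i.e. ``index mod 4^M``.  Sums to 1
    whenever the state frequencies do.
    """
    M = model.order
    if k < M:
        raise ParameterError(f"k={k} must be >= the model order M={M}")
    p = model.state_freqs.astype(float).copy()
    mod = 4**M
    for length in range(M, k):
        ctx = np.arange(4**length) % mod
        p = (p[:, None] * model.transition[ctx]).ravel()
    return p
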