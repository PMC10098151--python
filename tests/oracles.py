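"""Independent naive reference implementations used as test oracles.

Everything here is deliberately written the slow, obvious way — dictionary
counting by substring, per-word Python loops over all 4^k words, exhaustive
enumeration — and shares no code with the package internals it checks.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Tuple

BASES = "ACGT"


def kmer_to_index(word: str) -> int:
    """Base-4 reading of a k-mer, digit by digit from a lookup string."""
    idx = 0
    for ch in word:
        idx = idx * 4 + BASES.index(ch)
    return idx


def all_kmers(k: int) -> List[str]:
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


def naive_count_dict(seq: str, k: int) -> Dict[str, int]:
    """Sliding-window substring counts, skipping windows containing N."""
    counts: Dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" in w:
            continue
        counts[w] = counts.get(w, 0) + 1
    return counts


def naive_counts_vector(seq: str, k: int) -> List[int]:
    counts = [0] * 4**k
    for w, c in naive_count_dict(seq, k).items():
        counts[kmer_to_index(w)] = c
    return counts


def naive_frequencies(seq: str, k: int) -> List[float]:
    counts = naive_counts_vector(seq, k)
    total = sum(counts)
    if total == 0:
        return [0.0] * len(counts)
    return [c / total for c in counts]


def naive_markov_prob(seq: str, M: int, word: str) -> float:
    """Background probability of ``word`` under the order-M ML model of
    ``seq``: empirical M-mer frequency of the first M bases times transition
    probabilities from (M+1)-mer vs M-context counts.  Contexts never seen
    get a uniform 1/4 row."""
    counts_m1 = naive_count_dict(seq, M + 1)
    if M == 0:
        total = sum(counts_m1.values())
        p = 1.0
        for ch in word:
            p *= counts_m1.get(ch, 0) / total
        return p
    freqs_m = naive_frequencies(seq, M)
    p = freqs_m[kmer_to_index(word[:M])]
    for j in range(M, len(word)):
        ctx = word[j - M : j]
        denom = sum(counts_m1.get(ctx + b, 0) for b in BASES)
        if denom == 0:
            p *= 0.25
        else:
            p *= counts_m1.get(ctx + word[j], 0) / denom
    return p


def _half_one_minus(num: float, n1: float, n2: float) -> float:
    return 0.5 * (1.0 - num / (math.sqrt(n1) * math.sqrt(n2)))


def naive_geometric(seq1: str, seq2: str, k: int, name: str) -> float:
    f1 = naive_frequencies(seq1, k)
    f2 = naive_frequencies(seq2, k)
    diffs = [abs(a - b) for a, b in zip(f1, f2)]
    if name == "Ch":
        return max(diffs)
    if name == "Ma":
        return sum(diffs)
    return math.sqrt(sum(d * d for d in diffs))


def naive_d2(seq1: str, seq2: str, k: int) -> float:
    c1 = naive_counts_vector(seq1, k)
    c2 = naive_counts_vector(seq2, k)
    num = sum(a * b for a, b in zip(c1, c2))
    n1 = sum(a * a for a in c1)
    n2 = sum(b * b for b in c2)
    return _half_one_minus(num, n1, n2)


def _centered_counts(seq: str, k: int, M: int) -> Tuple[List[float], List[float], int]:
    counts = naive_counts_vector(seq, k)
    n = sum(counts)
    probs = [naive_markov_prob(seq, M, w) for w in all_kmers(k)]
    centered = [c - n * p for c, p in zip(counts, probs)]
    return centered, probs, n


def naive_d2star(seq1: str, seq2: str, k: int, M: int) -> float:
    c1h, p1, n1 = _centered_counts(seq1, k, M)
    c2h, p2, n2 = _centered_counts(seq2, k, M)
    num = s1 = s2 = 0.0
    for a, b, pa, pb in zip(c1h, c2h, p1, p2):
        if pa <= 0 or pb <= 0:
            continue
        num += a * b / math.sqrt(n1 * pa * n2 * pb)
        s1 += a * a / (n1 * pa)
        s2 += b * b / (n2 * pb)
    return _half_one_minus(num, s1, s2)


def naive_d2s(seq1: str, seq2: str, k: int, M: int) -> float:
    c1h, p1, n1 = _centered_counts(seq1, k, M)
    c2h, p2, n2 = _centered_counts(seq2, k, M)
    num = s1 = s2 = 0.0
    for a, b, pa, pb in zip(c1h, c2h, p1, p2):
        if pa <= 0 or pb <= 0:
            continue
        denom = math.sqrt(a * a + b * b)
        if denom == 0:
            continue
        num += a * b / denom
        s1 += a * a / denom
        s2 += b * b / denom
    return _half_one_minus(num, s1, s2)


def naive_composition_vector(seq: str, k: int) -> List[float]:
    f_k = naive_frequencies(seq, k)
    f_k1 = naive_frequencies(seq, k - 1)
    f_k2 = naive_frequencies(seq, k - 2)
    out = []
    for w in all_kmers(k):
        pre = f_k1[kmer_to_index(w[:-1])]
        suf = f_k1[kmer_to_index(w[1:])]
        mid = f_k2[kmer_to_index(w[1:-1])]
        f0 = pre * suf / mid if mid > 0 else 0.0
        f = f_k[kmer_to_index(w)]
        out.append((f - f0) / f0 if f0 > 0 else 0.0)
    return out


def naive_hao(seq1: str, seq2: str, k: int) -> float:
    a1 = naive_composition_vector(seq1, k)
    a2 = naive_composition_vector(seq2, k)
    num = sum(x * y for x, y in zip(a1, a2))
    n1 = sum(x * x for x in a1)
    n2 = sum(y * y for y in a2)
    return _half_one_minus(num, n1, n2)


def random_dna(rng, length: int, n_fraction: float = 0.0) -> str:
    """Random sequence over ACGT with a given fraction of N positions."""
    chars = rng.choice(list("ACGT"), size=length)
    if n_fraction > 0:
        mask = rng.random(length) < n_fraction
        chars[mask] = "N"
    return "".join(chars)
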