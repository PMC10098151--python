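"""The seven distance measures against independent naive-loop oracles."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from afphylo import (
    MeasureSpec,
    count_kmers,
    d2_distance,
    d2s_distance,
    d2star_distance,
    fit_markov,
    geometric_distance,
    hao_distance,
    pairwise_matrix,
    read_phylip,
    write_phylip,
)
from afphylo.distances import write_tsv
from afphylo.errors import ParameterError, UndefinedDistanceError
from afphylo.sequence_io import Sequence

from oracles import (
    naive_d2,
    naive_d2s,
    naive_d2star,
    naive_geometric,
    naive_hao,
    random_dna,
)


def _spectrum_pair(rng, k, length_range=(300, 1500)):
    s1 = random_dna(rng, int(rng.integers(*length_range)))
    s2 = random_dna(rng, int(rng.integers(*length_range)))
    return s1, s2


class TestMeasureSpec:
    def test_background_measures_default_m_zero(self):
        assert MeasureSpec("d2star", k=4).M == 0
        assert MeasureSpec("d2S", k=4, M=1).M == 1

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(name="nope", k=3),
            dict(name="Hao", k=2),
            dict(name="Eu", k=3, M=1),
            dict(name="d2star", k=3, M=-1),
            dict(name="d2star", k=2, M=3),
            dict(name="Ma", k=0),
        ],
    )
    def test_invalid_combinations_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            MeasureSpec(**kwargs)


class TestGeometric:
    def test_disjoint_unit_vectors(self):
        f1 = np.array([1.0, 0, 0, 0])
        f2 = np.array([0, 1.0, 0, 0])
        assert geometric_distance(f1, f2, "Ch") == pytest.approx(1.0)
        assert geometric_distance(f1, f2, "Ma") == pytest.approx(2.0)
        assert geometric_distance(f1, f2, "Eu") == pytest.approx(math.sqrt(2))

    def test_identity_and_length_mismatch(self):
        f = np.array([0.25] * 4)
        for name in ("Ch", "Ma", "Eu"):
            assert geometric_distance(f, f, name) == 0.0
        with pytest.raises(ParameterError):
            geometric_distance(f, f[:3], "Eu")


class TestD2Family:
    def test_self_distance_zero(self, rng):
        seq = random_dna(rng, 500)
        s = count_kmers(seq, 3)
        m = fit_markov(seq, 0)
        assert d2_distance(s, s) == pytest.approx(0.0, abs=1e-12)
        assert d2star_distance(s, s, m, m) == pytest.approx(0.0, abs=1e-12)
        assert d2s_distance(s, s, m, m) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_word_sets_give_half(self):
        s1 = count_kmers("AAAA", 2)
        s2 = count_kmers("CCCC", 2)
        assert d2_distance(s1, s2) == pytest.approx(0.5)

    def test_zero_spectrum_is_undefined(self):
        s1 = count_kmers("AC", 3)
        s2 = count_kmers("ACGTAC", 3)
        with pytest.raises(UndefinedDistanceError):
            d2_distance(s1, s2)

    def test_d2star_near_half_for_unrelated_long_sequences(self):
        """Centred counts of independent uniform sequences are
        uncorrelated, so d2star sits near 0.5."""
        rng = np.random.default_rng(77)
        s1 = random_dna(rng, 50_000)
        s2 = random_dna(rng, 50_000)
        d = d2star_distance(
            count_kmers(s1, 5), count_kmers(s2, 5), fit_markov(s1, 0), fit_markov(s2, 0)
        )
        assert abs(d - 0.5) < 0.1


class TestHao:
    def test_self_distance_zero(self, rng):
        seq = random_dna(rng, 800)
        args = (count_kmers(seq, 4), (count_kmers(seq, 3), count_kmers(seq, 2)))
        assert hao_distance(args[0], args[0], args[1], args[1]) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_duplication_invariance(self, rng):
        """Concatenating a sequence with itself (junction windows removed)
        leaves all relative frequencies, hence the composition vector
        direction, unchanged."""
        k = 4
        seq = random_dna(rng, 1000)
        # insert an N at the junction so no window spans the boundary
        doubled = seq + "N" + seq
        other = random_dna(rng, 1000)

        def cv_args(s):
            return count_kmers(s, k), (count_kmers(s, k - 1), count_kmers(s, k - 2))

        a, aux_a = cv_args(seq)
        b, aux_b = cv_args(doubled)
        o, aux_o = cv_args(other)
        d_single = hao_distance(a, o, aux_a, aux_o)
        d_double = hao_distance(b, o, aux_b, aux_o)
        assert d_single == pytest.approx(d_double, abs=1e-6)


@pytest.mark.parametrize("M", [0, 1])
def test_all_measures_match_naive_oracles(rng, M):
    """Every measure equals its independent naive-loop implementation on
    random pairs across k = 2..6 (k = 3..6 for Hao)."""
    for trial in range(10):
        k = 2 + trial % 5
        s1, s2 = _spectrum_pair(rng, k)
        sp1, sp2 = count_kmers(s1, k), count_kmers(s2, k)
        m1, m2 = fit_markov(s1, M), fit_markov(s2, M)
        for name in ("Ch", "Ma", "Eu"):
            got = geometric_distance(sp1.frequencies, sp2.frequencies, name)
            assert got == pytest.approx(naive_geometric(s1, s2, k, name), abs=1e-10)
        assert d2_distance(sp1, sp2) == pytest.approx(naive_d2(s1, s2, k), abs=1e-10)
        assert d2star_distance(sp1, sp2, m1, m2) == pytest.approx(
            naive_d2star(s1, s2, k, M), abs=1e-10
        )
        assert d2s_distance(sp1, sp2, m1, m2) == pytest.approx(
            naive_d2s(s1, s2, k, M), abs=1e-10
        )
        if k >= 3:
            aux1 = (count_kmers(s1, k - 1), count_kmers(s1, k - 2))
            aux2 = (count_kmers(s2, k - 1), count_kmers(s2, k - 2))
            assert hao_distance(sp1, sp2, aux1, aux2) == pytest.approx(
                naive_hao(s1, s2, k), abs=1e-10
            )


@pytest.mark.parametrize(
    "spec",
    [
        MeasureSpec("Ch", 3),
        MeasureSpec("Ma", 3),
        MeasureSpec("Eu", 3),
        MeasureSpec("d2", 3),
        MeasureSpec("d2S", 3, 0),
        MeasureSpec("d2star", 3, 1),
        MeasureSpec("Hao", 4),
    ],
)
def test_matrix_contract_all_measures(rng, spec):
    """Pairwise matrices are symmetric, zero-diagonal and nonnegative;
    d2-family values stay in [0, 1] and Manhattan never exceeds 2."""
    seqs = [
        Sequence(id=f"s{i}", residues=random_dna(rng, 600)) for i in range(5)
    ]
    dm = pairwise_matrix(seqs, spec)
    v = dm.values
    assert np.allclose(v, v.T, atol=1e-12)
    assert np.all(np.diag(v) == 0)
    assert np.all(v >= 0)
    if spec.name in ("d2", "d2S", "d2star", "Hao"):
        assert np.all(v <= 1.0 + 1e-12)
    if spec.name == "Ma":
        assert np.all(v <= 2.0 + 1e-12)


def test_matrix_matches_independent_single_pair_calls(rng):
    seqs = [Sequence(id=f"s{i}", residues=random_dna(rng, 500)) for i in range(5)]
    spec = MeasureSpec("d2star", k=4, M=0)
    dm = pairwise_matrix(seqs, spec)
    for i in range(5):
        for j in range(i + 1, 5):
            d = d2star_distance(
                count_kmers(seqs[i], 4),
                count_kmers(seqs[j], 4),
                fit_markov(seqs[i], 0),
                fit_markov(seqs[j], 0),
            )
            assert dm.values[i, j] == pytest.approx(d, abs=1e-12)


def test_matrix_needs_two_sequences(rng):
    with pytest.raises(ParameterError):
        pairwise_matrix([Sequence(id="a", residues="ACGT")], MeasureSpec("Eu", 2))


def test_undefined_pair_reports_ids():
    seqs = [
        Sequence(id="ok", residues="ACGTACGTAC"),
        Sequence(id="tiny", residues="AC"),
    ]
    with pytest.raises(UndefinedDistanceError, match="tiny"):
        pairwise_matrix(seqs, MeasureSpec("d2", 4))


def test_phylip_round_trip(rng, tmp_path):
    seqs = [Sequence(id=f"taxon_{i}", residues=random_dna(rng, 400)) for i in range(4)]
    dm = pairwise_matrix(seqs, MeasureSpec("Eu", 3))
    path = tmp_path / "m.phylip"
    with open(path, "w") as fh:
        write_phylip(dm, fh)
    with open(path) as fh:
        again = read_phylip(fh)
    assert again.labels == dm.labels
    np.testing.assert_array_equal(again.values, dm.values)  # 17 sig digits: exact
    tsv = tmp_path / "m.tsv"
    with open(tsv, "w") as fh:
        write_tsv(dm, fh)
    header = tsv.read_text().splitlines()[0]
    assert header.split("\t")[1:] == dm.labels


def test_d2star_distance_increases_with_divergence(rng):
    """Mean d2star between descendants of a shared ancestor is nondecreasing
    in the per-site substitution probability (monotone signal response)."""
    rates = np.linspace(0.01, 0.4, 8)
    k, length, reps = 4, 1000, 20
    bases = np.array(list("ACGT"))

    def mutate(codes, p):
        hit = rng.random(len(codes)) < p
        out = codes.copy()
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.sum())) % 4
        return out

    means = []
    for p in rates:
        vals = []
        for _ in range(reps):
            anc = rng.integers(0, 4, size=length)
            c1 = "".join(bases[mutate(anc, p)])
            c2 = "".join(bases[mutate(anc, p)])
            vals.append(
                d2star_distance(
                    count_kmers(c1, k),
                    count_kmers(c2, k),
                    fit_markov(c1, 0),
                    fit_markov(c2, 0),
                )
            )
        means.append(np.mean(vals))
    rho = spearmanr(rates, means).statistic
    assert rho > 0.9
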