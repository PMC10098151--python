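# Methods

## The k-mer spectrum and its index transform

A sequence of length L over {A,C,G,T} has L−k+1 windows of length k. Each
N-free window is mapped to an integer in [0, 4^k) by reading it as a base-4
number (A=0, C=1, G=2, T=3), which addresses a dense count array directly.
Sliding the window one base right is `idx ← (4·idx + code) mod 4^k`, so
counting is a single pass; after an ambiguous base the index is rebuilt from
the next k clean bases. Windows containing N are skipped entirely and do not
contribute to the window total — skipping avoids biasing counts toward any
base, and keeping Ns in the sequence (rather than deleting them) preserves
position so only the affected windows are lost. k is capped at 14 because
the dense array has 4^k cells.

Only the forward strand is counted by default, which matches marker-gene
input (16S rRNA and similar) where orientation is fixed; a
`--reverse-complement` flag adds the counts of the reverse-complement strand
for inputs of unknown orientation.

## Background models

d2S and d2star centre each sequence's counts on the expectation under that
sequence's *own* order-M Markov background, the convention of the
d2-statistics literature: `ĉ_w = c_w − n·p_w`, where n is the number of
valid windows and

    p_w = f(w_1..w_M) · Π_{j=M+1..k} P(w_j | w_{j−M}..w_{j−1}).

Transition probabilities are maximum-likelihood ratios of (M+1)-mer to
M-context counts; the initial factor uses the empirical M-mer frequencies
(not the stationary distribution of the fitted chain — for a well-sampled
sequence the two coincide, and the empirical choice is exact for the
observed data). Contexts never observed get a uniform transition row and are
flagged, so short sequences degrade gracefully. The default order is M = 0
(an i.i.d. composition background): with gene-length input, higher orders
mostly add estimation noise. Words whose background probability is zero
under either model are dropped from the d2S/d2star sums — their centred
contribution is ill-defined — and the drop count is logged at debug level.

## The seven measures

Ch, Ma and Eu act on relative frequencies, not raw counts, so sequence
length does not dominate. The four correlation-type statistics (d2, d2S,
d2star, Hao) are mapped to dissimilarities by (1 − corr)/2: 0 for identical
spectra, 0.5 for uncorrelated ones. Negative correlations are possible for
the centred statistics and are not clipped, so those distances live in
[0, 1]. Hao's composition vector fixes its background to order k−2
(`f0_w = f(prefix)·f(suffix)/f(middle)`), hence k ≥ 3; components with
f0 = 0 are set to 0.

All distance kernels are vectorised over the 4^k-length arrays; spectra,
background models and composition vectors are computed once per sequence
and reused across all N(N−1)/2 pairs.

## Tree building

UPGMA merges the closest pair at height d_min/2 with size-weighted
arithmetic-mean linkage; the output is rooted and ultrametric, and on an
ultrametric input matrix it reproduces the input cophenetic distances
exactly. Neighbor joining follows Saitou–Nei (Q-criterion, standard limb
lengths, (d_ik + d_jk − d_ij)/2 reduction) and is exact on additive
matrices; it terminates with a trifurcating root and is serialised unrooted.

Numerical choices:

* **Tie-breaking.** When two pairs tie on the merge criterion, the
  lexicographically smallest (i, j) pair in the current matrix ordering is
  taken, making runs bit-reproducible across platforms.
* **Negative NJ limbs** are clamped to 0 with the deficit transferred to
  the sibling branch at a pairwise join; at the final trifurcation a
  negative limb is clamped without transfer, since no unique adjacent
  branch exists there.
* Input matrices are validated (symmetry within 1e-8, finite entries, zero
  diagonal) and then symmetrised exactly, so tie-breaking never depends on
  sub-tolerance asymmetries.
* Newick output carries 10 significant digits; PHYLIP matrices carry 17, so
  a dist-then-tree pipeline is byte-identical to the one-step pipeline.

## Tree comparison

Bipartitions are canonicalised as the split block not containing the
smallest leaf label; trivial splits are excluded, and rooted trees are
implicitly unrooted (the two root edges of a bifurcating root induce the
same split). RF is the size of the symmetric difference of the two split
sets. Relative accuracy is reported as rf_reference / rf_target so that
"x% more accurate than the reference" reads as a ratio above 1; the
opposite orientation is a reciprocal away. A target with RF 0 against an
imperfect reference yields a flagged infinite ratio; two perfect methods
score 1.

## The simulator

The generator emulates the situation the pipeline is designed for — a known
phylogeny with sequences diverged by substitution: random binary topologies
by sequential random joins (uniform over join choices, which gives
coalescent-shaped trees), branch lengths uniform on a configurable range,
an i.i.d. uniform root sequence, and Jukes–Cantor substitution along each
branch (per-site change probability ¾(1 − e^(−4t/3)) for branch length t in
expected substitutions per site). A clock-tree variant merges clusters at
strictly increasing heights, yielding exactly ultrametric matrices for the
UPGMA tests. All randomness flows from one user-visible seed.

Deliberately absent: indels (so alignment-free and aligned views of the
data coincide), rate heterogeneity across sites, unequal base frequencies
and transition/transversion bias. Passing the recovery tests therefore
shows the pipeline recovers substitution-driven divergence on clean data;
it says nothing about gappy, rearranged or compositionally skewed real
genomes, where alignment-free measures are used precisely because
alignment breaks down.

Default simulation conditions: 12 leaves, branch lengths uniform on
[0.01, 0.05] substitutions/site, 5,000-base sequences — deep enough that
pairwise divergence spans roughly 5–30%, the regime marker-gene
phylogenetics operates in. The validation experiments use 8–16 leaves for
the matrix-level checks, 20 replicates for stochastic recovery rates, and a
100-taxon, 1,500-base dataset (16S-like) for the benchmark-scale run.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| k | 9 (auto-drop to 6 for short input) | word length; 4^k cells per spectrum. Longer k sharpens resolution until spectra become sparse (counts per word ≈ L/4^k) |
| M | 0 | background Markov order for d2S/d2star |
| measure | d2star | generally the most accurate of the seven for phylogenetic reconstruction |
| method | nj | NJ handles non-ultrametric divergence; UPGMA assumes a molecular clock |

## Known limitations

* The (1 − corr)/2 transform is **not additive** in evolutionary time: the
  k-mer correlation of two sequences decays roughly like the k-th power of
  their per-site identity, so distances saturate toward 0.5 with depth.
  On deep trees this compresses old splits and NJ can misplace branches
  whose length is below the compression noise — observed as occasional
  single-split errors (RF 2) in 12-leaf recovery runs whose internal
  branches drop to ~0.01 substitutions/site, for every one of the seven
  measures. A log transform of the distances restores additivity and fixes
  those cases, but is not applied because the distance definitions are the
  contract of this package.
* With M > 0 on short sequences, unobserved contexts fall back to uniform
  rows; the background is then partly uninformative.
* d2-family distances between near-identical sequences are dominated by
  counting noise, so zero distance is attained only for identical spectra.
* UPGMA inherits its clock assumption: on strongly non-ultrametric input it
  produces systematically wrong topologies, which is expected behaviour.
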