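# Methods

## Model

The package estimates edit similarity between sequences without alignment.
Each sequence is summarized by an integer vector indexed by a shared list
of random *testing subsequences*: entry *i* counts how many prefix tokens
(length-*t* blocks) of testing subsequence *i* occur in the input, in
order, at strictly increasing start positions. Token occurrences may
overlap by up to *t* − 1 positions, so the relation matched is strictly
more permissive than the character-subsequence relation except at *t* = 1,
where it coincides with it. Entries therefore measure, per random probe,
how long a prefix of a long random subsequence the input can absorb —
similar sequences absorb similarly long prefixes of the same probes, which
is why cosine similarity between sketches tracks edit similarity.

Matching is greedy leftmost: after matching token *j* at position *i*, the
search for token *j* + 1 resumes at *i* + 1. Greediness is optimal here —
taking the earliest feasible occurrence never forecloses a longer prefix
match — but the package does not assume this: the test suite checks greedy
results against exhaustive search over all strictly increasing index lists
on ~1,000 random instances.

Two backends compute entries. The default is a linear scan using the
C-level substring search of Python strings, O(|L|·|s|) worst case but
fastest in practice. An opt-in index backend preprocesses the input into a
per-character next-pointer automaton (*t* = 1) or a token → sorted
start-positions table (*t* > 1) queried by binary search; it produces
bit-identical sketches and only pays off for very many short-token probes
against one long sequence.

### Coordinates and degenerate input

Positions are 0-based half-open internally; human-facing messages are
1-based. Input residues are uppercased; characters outside the alphabet
(e.g. `N`) are retained — preserving positions — but can never match a
token, since testing subsequences are generated over the alphabet. An
empty sequence yields an all-zero sketch. A sketch that is entirely zero
has cosine similarity 0 with everything, including another zero sketch:
it shares no testing-subsequence content with anything, and this choice
avoids NaNs in matrix pipelines.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| *t* | token size (characters) | from `recommend_t(n)` | large enough that random token hits are rare, small enough that entries are not all zero; anchored at decades t(10²)=2 … t(10⁹)=25, log-nearest decade between anchors (ties round up) |
| *k* | tokens per testing subsequence | 15 | entries fit in 4 bits; for *t* = 1, `choose_k(n, σ, threshold)` inverts the exact containment formula instead |
| \|L\| | testing-list size = sketch length | 1000 (pair experiments), 256 (phylogeny) | variance of the similarity estimate falls with \|L\|; these sizes keep desk-scale runs in seconds-to-minutes |
| seed | RNG seed | 0 | all generators are `numpy.random.default_rng(seed)`; identical seeds give byte-identical outputs |

The *t* = 1 containment combinatorics are exact big-integer computations;
probabilities are exact rationals (or, optionally, a floating binomial
tail for very large *n*, which equals the exact value to well below 1e-12
— an identity the tests verify rather than assume). For *t* > 1 the
analogous formula over the token alphabet overestimates badly because
overlapping tokens are not independent, so no *t* > 1 analogue is offered;
the empirical `recommend_t` table covers that need.

Testing lists are random by default (data-oblivious). For small
collections of closely related genomes, `sample_testing_list_from_input`
draws entries from the input itself: by default contiguous windows of
length *k·t* (sequence uniform among those long enough, start uniform), so
each sampled entry maxes out on its source sequence. An optional gapped
mode instead draws *k* non-overlapping token start positions uniformly,
via the bijection between such position lists and *k*-subsets of
`[0, n − kt + k − 1]`.

## Similarity metrics

Cosine is the primary score; pairwise matrices use a single row-normalized
matrix product, checked against the per-pair definition to 1e-9. Ten
alternative metrics are available for benchmarking. Conventions where the
standard definitions leave room: Hamming is reported as similarity
(fraction of equal entries); Jaccard similarity is 1 minus the fraction of
disagreeing entries among entries where either vector is nonzero; Canberra
terms with both coordinates zero contribute 0; Minkowski order is fixed at
p = 3 (p ∈ {1, 2} would duplicate Manhattan/Euclidean); correlations of
distance metrics with edit similarity are reported as |Pearson|, since the
sign is orientation-dependent.

In the correlation experiment the Lp-family distances (Manhattan, squared
Euclidean, Euclidean, Minkowski, Chebyshev) are computed between
unit-L2-normalized sketch vectors (`lp_normalized=True`, the default).
Raw sketches under the recommended parameters are sparse with small
entries, so unnormalized Lp magnitudes are dominated by vector-norm
fluctuations rather than by the shared-content signal; normalizing rows —
the same normalization the cosine pipeline applies — restores the
correlation with edit similarity, and matches the behaviour of the
pairwise-comparison pipeline this package is designed around. The
entry-agreement metrics (Hamming, Jaccard, Canberra, Bray-Curtis) operate
on the raw integer vectors, and `sketch_metric` always uses the raw
standard definitions.

## Synthetic data

Two generators define the study conditions.

**Mutation pairs** (`MutationPairConfig`): random DNA sequences of length
1,000; each is mutated by a uniform number of rounds in [0, 1000], each
round an insertion, deletion or substitution at a uniform position on the
evolving string (substitutions draw from Σ minus the current character;
deletion on an empty string is a no-op). Uniform rounds give full coverage
of the edit-similarity range (~0.45–1.0). Exact edit distances come from
edlib; the normalization denominator is the longer length so the
similarity stays in [0, 1] despite indels.

**IS phylogeny** (`PhyloSimConfig`): a perfect binary tree of genomes.
The root is 10,000 random bases; each generation every genome yields two
children by independent per-base substitution at rate 1e-4 ("point
mutations" are substitutions only — length changes are modelled by the IS
events), then one insertion-sequence element of 500 random bases — shared
across the generation, freshly drawn per generation — is inserted at an
independent uniform position per child. Per-generation IS strings and all
intermediate generations are retained for auditability. Leaf count is 2^g
and leaf length root_len + g·is_len exactly.

What these generators do *not* emulate: compositional bias, repeats,
rearrangements other than single insertions, rate heterogeneity along the
sequence, and any alignment ambiguity beyond unit-cost edits. Passing
tests on them demonstrates the estimator's fidelity to edit distance under
a clean mutation process, not performance on real genomes with repeat
structure.

## Evaluation protocols and problem sizes

- Mutation-pair correlation: 5,000 pairs (the package's desk-scale
  default; per-seed spread of Pearson r at this size is well under 0.01
  for cosine, and disjoint halves agree within 0.02). Sketch parameters
  |L| = 1000, t = 6, k = 15 for length-1,000 sequences.
- Phylogeny recovery: 5 generations (32 leaves of 12,500 bp), sketch
  parameters |L| = 256, t = 5, k = 15, compared against neighbor joining
  on exact edit distances and on a random symmetric matrix (the no-signal
  floor), averaged over 5 simulation seeds.
- Neighbor joining is delegated to biotite (with closed-form handling of
  n ≤ 3), Robinson–Foulds to dendropy: both are standard plumbing, not
  contributions of this package. The RF distance is the unrooted
  bipartition count normalized by the total number of internal edges of
  the two trees (2(n−3) for binary trees); identical topologies give 0,
  maximally different binary topologies give 1.

## Numerical and design choices

- Sketch compatibility is enforced through a SHA-256-derived digest of the
  testing list's content (alphabet, t, k, entries); mismatched digests are
  a hard error, CLI-overridable with `--force`.
- Ranking ties in the recall curve are broken by base-set order (stable
  sort on descending similarity), making curves deterministic.
- The binary sketch format packs entries into 4 bits when k ≤ 15 (two per
  byte), 8 bits when k ≤ 255; TSV and binary decode to identical sets.
- `choose_k` scans k upward and returns the first value clearing the
  threshold — minimal by the monotonicity of the containment probability
  in k (a tested invariant); if even k = n fails it returns n with a
  warning.
- Between-decade `recommend_t` interpolation uses the log-nearest decade
  with ties rounding up, computed in exact integer arithmetic
  (n² vs 10^(2e+1)) to avoid float edge cases.

## Limitations

- Cosine ignores vector magnitude: a sketch of all 1s and a sketch of all
  10s score 1.0 despite describing very different sequences. This is a
  known property of the score, acceptable because such pairs are rare
  under the recommended parameters.
- The scheme targets globally alignable sequences; for pairs sharing only
  a local overlap (e.g. read overlaps), prefix-token counting is skewed
  against the sequence missing the probe's start.
- Forward strand only; no reverse-complement canonicalization.
- Sketches are not updatable under edits and the scheme is not designed
  for streaming inputs.
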