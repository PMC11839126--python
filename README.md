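# subseqsketch

Alignment-free sequence similarity estimation by random subsequence
sketching, for bioinformaticians who need fast, global edit-similarity
estimates across large collections of DNA or protein sequences — nearest
neighbor search over sequence databases, phylogenetic distance matrices for
groups of related genomes, and other tasks where all-vs-all alignment is
too expensive.

## The method

A string *x* of length *k·t* over an alphabet Σ is viewed as *k* tokens of
length *t*. *x* is a **tokenized subsequence** of a host sequence *s* if
its tokens occur in *s*, in order, at strictly increasing start positions
`i₁ < i₂ < … < i_k ≤ n − t + 1`; token occurrences may overlap by up to
*t − 1* characters, so at *t* = 1 this is the classical subsequence
relation, and for *t* > 1 it is strictly more permissive.

The sketch is built from a **testing list** *L* — shared randomness: an
ordered list of |L| random strings of length *k·t*. The sketch of *s* is
the integer vector

    SubseqSketch(s)[i] = the largest m such that the first m tokens of
                         L[i] form a tokenized subsequence of s,

one entry in `[0, k]` per testing subsequence (greedy leftmost matching
attains this maximum; the test suite verifies it against exhaustive
search). Two sketches are comparable only if they came from the identical
list, enforced here by a content digest. Similarity is the cosine

    cos(a, b) = SubseqSketch(a)·SubseqSketch(b) / (‖SubseqSketch(a)‖₂ ‖SubseqSketch(b)‖₂),

computable for whole collections as one matrix product of row-normalized
sketch matrices. It correlates strongly with edit similarity
`1 − ED(a,b)/max(|a|,|b|)`.

Parameter choice: with *k* = 15 every entry fits in 4 bits; the token size
*t* comes from an empirical table indexed by input length (t = 6 at
n ≈ 10³, t = 9 at 10⁴, … 25 at 10⁹). For *t* = 1 the package also carries
the exact combinatorics: the number of length-*n* strings containing a
fixed length-*k* subsequence is

    Σ_{i=k..n} C(i−1, k−1) (|Σ|−1)^{i−k} |Σ|^{n−i},

independent of which *k*-mer is chosen, and equal to the binomial tail
Pr[Binomial(n, 1/|Σ|) ≥ k]; `choose_k` inverts it to find the smallest *k*
whose containment probability clears a threshold.

## Worked example

```python
import subseqsketch as sq

# shared randomness: 1000 testing subsequences, 15 tokens of size 6
L = sq.generate_testing_list(t=6, k=15, count=1000, seed=42)

a = sq.Sequence("a", sq.evaluation.random_sequence(1000, __import__("numpy").random.default_rng(0)))
b = sq.Sequence("b", sq.mutate_sequence(a.residues, 200, 1))   # 200 random edits

sa, sb = sq.sketch_sequence(a, L), sq.sketch_sequence(b, L)
print(round(sq.cosine_similarity(sa, sb), 3))      # 0.471
print(round(sq.edit_similarity(a.residues, b.residues), 3))  # 0.824

print(sq.choose_k(n=100, sigma=4, threshold=0.01))  # 36
print(sq.recommend_t(1_000_000))                    # 15
```

The cosine score 0.471 for the pair mutated by 200 edits sits well below
the 1.0 of an identical pair and above typical unrelated-pair scores
(~0.2 at these parameters); over many pairs the relationship between the
cosine and edit similarity is close to linear, with Pearson r ≈ 0.92 at
these parameters.

The same pipeline from the shell:

```bash
subseqsketch --seed 42 testlist --t 6 --k 15 --count 1000 --out testlist.tsv
subseqsketch sketch --testlist testlist.tsv --fasta genomes.fa --out sketches.tsv
subseqsketch similarity --a sketches.tsv --metric cosine --out cosine.tsv
subseqsketch distmatrix --fasta genomes.fa --out dist.phy   # PHYLIP, for NJ tools
subseqsketch choose-k --n 100 --sigma 4 --threshold 0.01    # prints 36
```

Evaluation protocols are built in: `eval-correlation` (mutation-pair
correlation between sketch metrics and exact edit similarity),
`simulate-phylogeny` / `eval-phylogeny` (genomes evolved on a perfect
binary tree by point mutations plus shared per-generation insertion
sequences; neighbor-joining trees scored by normalized Robinson–Foulds
distance against the ground truth), and `recall-curve` (recall of true
edit-distance nearest neighbors versus number of reported items).

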