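"""Evaluation protocols: mutation-pair correlation, IS-phylogeny, recall.

Three desk-scale experiments measure how well cosine similarity between
sketches tracks true edit similarity:

* mutation pairs — random DNA sequences, each mutated by a random number of
  single-character edits; Pearson correlation between exact edit similarity
  and each sketch metric over the pairs;
* IS phylogeny — a perfect binary tree of genomes evolved by per-base point
  mutations plus one shared insertion-sequence (IS) element per generation
  inserted at an independent position in each child; neighbor-joining trees
  built from sketch distances are compared with the ground-truth topology
  by normalized Robinson-Foulds distance;
* recall-item curves — fraction of true nearest neighbors (by edit
  distance) recovered among the top-m sketch-similar sequences.

Exact Levenshtein distances come from edlib; neighbor joining from biotite;
Robinson-Foulds from dendropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import edlib
import numpy as np
from biotite.sequence.phylo import neighbor_joining
from dendropy.calculate import treecompare

from .core import DNA, Alphabet, InvalidInputError, Sequence
from .similarity import SimilarityMatrix, pairwise_similarity, to_distance
from .sketch import TestingList, sketch_collection

# ---------------------------------------------------------------------------
# random sequences and the single-edit mutation model


def random_sequence(length: int, rng: np.random.Generator, alphabet: Alphabet = DNA) -> str:
    symbols = np.array(list(alphabet.symbols))
    return "".join(symbols[rng.integers(0, alphabet.size, size=length)])


def mutate_sequence(
    s: str,
    rounds: int,
    rng: np.random.Generator | int,
    alphabet: Alphabet = DNA,
) -> str:
    """Apply ``rounds`` single-character edits to ``s``.

    Each round draws an operation uniformly from {insert, delete,
    substitute} applied at a uniform position on the current (evolving)
    string; inserted characters are uniform over the alphabet, substituted
    characters uniform over the alphabet minus the current character.
    A delete drawn on an empty string is skipped.
    """
    if rounds < 0:
        raise InvalidInputError(f"rounds must be >= 0, got {rounds}")
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    chars = list(s)
    symbols = alphabet.symbols
    sigma = alphabet.size
    for _ in range(rounds):
        op = rng.integers(0, 3)
        if op == 0:  # insert
            pos = int(rng.integers(0, len(chars) + 1))
            chars.insert(pos, symbols[rng.integers(0, sigma)])
        elif op == 1:  # delete
            if chars:
                del chars[int(rng.integers(0, len(chars)))]
        else:  # substitute
            if chars:
                pos = int(rng.integers(0, len(chars)))
                old = chars[pos]
                choices = [c for c in symbols if c != old]
                chars[pos] = choices[rng.integers(0, len(choices))] if choices else old
    return "".join(chars)


def edit_distance(a: str, b: str) -> int:
    """Exact unit-cost Levenshtein distance (edlib)."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def edit_similarity(a: str, b: str) -> float:
    """1 - ED(a, b) / max(|a|, |b|); 1.0 when both strings are empty.

    The longer length is the denominator so that the value stays in [0, 1]
    even when indels make the two lengths differ.
    """
    m = max(len(a), len(b))
    if m == 0:
        return 1.0
    return 1.0 - edit_distance(a, b) / m


def pearson(x, y) -> float:
    """Product-moment correlation; raises on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise InvalidInputError("pearson needs two equal-length vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidInputError("pearson undefined for zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# mutation-pair correlation experiment


@dataclass(frozen=True)
class MutationPairConfig:
    """Conditions of the mutation-pair experiment.

    Defaults are the full-scale study conditions: 100,000 random DNA
    sequences of length 1,000, each mutated a uniform number of rounds in
    [0, 1000] to form its partner.
    """

    n_pairs: int = 100_000
    seq_len: int = 1_000
    max_rounds: int = 1_000
    alphabet: Alphabet = DNA
    seed: int = 0


@dataclass
class CorrelationResult:
    """Per-pair table plus Pearson correlation for each metric.

    ``correlations[metric]`` is the signed Pearson r for similarity metrics
    and |r| for distance metrics (orientation is metric-dependent; the
    magnitude is what is comparable across metrics).
    """

    edit_similarity: np.ndarray
    rounds: np.ndarray
    scores: dict[str, np.ndarray]
    correlations: dict[str, float]


def generate_mutation_pairs(
    cfg: MutationPairConfig,
) -> tuple[list[str], list[str], np.ndarray]:
    """Generate (originals, mutated partners, rounds per pair)."""
    rng = np.random.default_rng(cfg.seed)
    originals, partners = [], []
    rounds = rng.integers(0, cfg.max_rounds + 1, size=cfg.n_pairs)
    for r in rounds:
        s = random_sequence(cfg.seq_len, rng, cfg.alphabet)
        originals.append(s)
        partners.append(mutate_sequence(s, int(r), rng, cfg.alphabet))
    return originals, partners, rounds.astype(np.int64)


#: Lp-family distances are evaluated on unit-L2-normalized sketch rows in
#: the correlation experiment.  Raw integer vectors from this scheme are
#: sparse with small entries, so unnormalized Lp magnitudes are dominated
#: by norm fluctuations rather than by the shared-subsequence signal; the
#: pairwise-comparison pipeline normalizes sketch rows anyway for the
#: matrix-product cosine, and the entry-agreement metrics (Hamming,
#: Jaccard, Canberra, Bray-Curtis) stay on the raw integers.
LP_NORMALIZED_METRICS = ("manhattan", "sqeuclidean", "euclidean", "minkowski", "chebyshev")


def _row_normalize(X: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(X, axis=1, keepdims=True)
    return X / np.where(n == 0, 1, n)


def _pair_scores(A: np.ndarray, B: np.ndarray, metric: str, lp_normalized: bool) -> np.ndarray:
    """Row-wise metric between corresponding rows of A and B."""
    from .similarity import METRICS, _MINKOWSKI_P

    if metric not in METRICS:
        raise InvalidInputError(f"unknown metric {metric!r}")
    if metric in LP_NORMALIZED_METRICS and lp_normalized:
        A, B = _row_normalize(A), _row_normalize(B)
    D = A - B
    if metric == "cosine":
        return np.einsum("ij,ij->i", _row_normalize(A), _row_normalize(B))
    if metric == "correlation":
        Ac = A - A.mean(axis=1, keepdims=True)
        Bc = B - B.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(Ac, axis=1) * np.linalg.norm(Bc, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.einsum("ij,ij->i", Ac, Bc) / denom
        return np.where(denom == 0, 0.0, r)
    if metric == "hamming":
        return np.mean(A == B, axis=1)
    if metric == "jaccard":
        union = ((A != 0) | (B != 0)).sum(axis=1)
        mism = ((A != B) & ((A != 0) | (B != 0))).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(union == 0, 1.0, 1.0 - mism / np.maximum(union, 1))
    if metric == "canberra":
        denom = np.abs(A) + np.abs(B)
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = np.where(denom == 0, 0.0, np.abs(D) / np.where(denom == 0, 1, denom))
        return terms.sum(axis=1)
    if metric == "braycurtis":
        return np.abs(D).sum(axis=1) / np.abs(A + B).sum(axis=1)
    if metric == "manhattan":
        return np.abs(D).sum(axis=1)
    if metric == "sqeuclidean":
        return np.einsum("ij,ij->i", D, D)
    if metric == "euclidean":
        return np.linalg.norm(D, axis=1)
    if metric == "minkowski":
        return (np.abs(D) ** _MINKOWSKI_P).sum(axis=1) ** (1.0 / _MINKOWSKI_P)
    # chebyshev
    return np.abs(D).max(axis=1)


def correlation_experiment(
    cfg: MutationPairConfig,
    testing_list: TestingList | None = None,
    size: int = 1_000,
    t: int = 6,
    k: int = 15,
    metrics: tuple[str, ...] = ("cosine",),
    lp_normalized: bool = True,
) -> CorrelationResult:
    """Correlate sketch metrics with exact edit similarity on mutation pairs.

    Sketches both members of every pair against one shared testing list
    (generated from ``cfg.seed`` unless supplied) and reports, per metric,
    the Pearson correlation with edit similarity over all pairs.  With
    ``lp_normalized`` (the default) the Lp-family distances are computed
    between unit-L2-normalized sketch vectors (see
    :data:`LP_NORMALIZED_METRICS`); ``lp_normalized=False`` uses the raw
    integer vectors for every metric.
    """
    from .sketch import generate_testing_list
    from .similarity import is_similarity

    originals, partners, rounds = generate_mutation_pairs(cfg)
    if testing_list is None:
        testing_list = generate_testing_list(
            t=t, k=k, count=size, alphabet=cfg.alphabet, seed=cfg.seed
        )
    seqs_a = [Sequence(f"a{i}", s) for i, s in enumerate(originals)]
    seqs_b = [Sequence(f"b{i}", s) for i, s in enumerate(partners)]
    A = sketch_collection(seqs_a, testing_list).matrix().astype(float)
    B = sketch_collection(seqs_b, testing_list).matrix().astype(float)

    edit_sims = np.array(
        [edit_similarity(a, b) for a, b in zip(originals, partners)]
    )
    scores: dict[str, np.ndarray] = {}
    correlations: dict[str, float] = {}
    for metric in metrics:
        vals = _pair_scores(A, B, metric, lp_normalized)
        scores[metric] = vals
        if np.ptp(edit_sims) == 0 or np.ptp(vals) == 0:
            warnings.warn(
                f"correlation undefined for metric {metric!r}: constant column",
                stacklevel=2,
            )
            correlations[metric] = float("nan")
            continue
        r = pearson(edit_sims, vals)
        correlations[metric] = r if is_similarity(metric) else abs(r)
    return CorrelationResult(edit_sims, rounds, scores, correlations)


# ---------------------------------------------------------------------------
# IS-phylogeny simulation


@dataclass(frozen=True)
class PhyloSimConfig:
    """Conditions of the insertion-sequence phylogeny simulation.

    The root genome is a random sequence of ``root_len`` bases.  Each
    generation, every genome produces two children by independent per-base
    substitutions at rate ``point_mut_rate``; then one IS element of length
    ``is_len`` — shared by the whole generation but freshly random per
    generation — is inserted at an independent uniform position per child.
    """

    generations: int = 5
    root_len: int = 10_000
    point_mut_rate: float = 1e-4
    is_len: int = 500
    alphabet: Alphabet = DNA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise InvalidInputError("need at least one generation")
        if not (0 <= self.point_mut_rate <= 1):
            raise InvalidInputError("point mutation rate must be in [0, 1]")


@dataclass
class PhyloSim:
    """Simulated genomes with their ground-truth perfect binary tree."""

    leaf_sequences: list[Sequence]
    true_tree: str  # Newick
    is_elements: list[str] = field(default_factory=list)
    generations: list[list[str]] = field(default_factory=list)


def _point_mutate(s: str, rate: float, rng: np.random.Generator, alphabet: Alphabet) -> str:
    if rate <= 0:
        return s
    n = len(s)
    hits = np.flatnonzero(rng.random(n) < rate)
    if hits.size == 0:
        return s
    chars = list(s)
    symbols = alphabet.symbols
    for pos in hits:
        old = chars[pos]
        choices = [c for c in symbols if c != old]
        chars[pos] = choices[rng.integers(0, len(choices))]
    return "".join(chars)


def simulate_is_phylogeny(cfg: PhyloSimConfig) -> PhyloSim:
    """Evolve a perfect binary tree of genomes under the IS mutation model.

    Returns the final-generation sequences (leaf ``i`` named ``g{G}_{i}``),
    the ground-truth rooted Newick topology, the per-generation IS strings,
    and every intermediate generation for auditing.
    """
    rng = np.random.default_rng(cfg.seed)
    root = random_sequence(cfg.root_len, rng, cfg.alphabet)
    gens = [[root]]
    is_elements = []
    for g in range(1, cfg.generations + 1):
        is_seq = random_sequence(cfg.is_len, rng, cfg.alphabet)
        is_elements.append(is_seq)
        children = []
        for parent in gens[g - 1]:
            for _ in range(2):
                child = _point_mutate(parent, cfg.point_mut_rate, rng, cfg.alphabet)
                pos = int(rng.integers(0, len(child) + 1))
                children.append(child[:pos] + is_seq + child[pos:])
        gens.append(children)

    G = cfg.generations

    def newick(depth: int, idx: int) -> str:
        if depth == G:
            return f"g{G}_{idx}"
        return f"({newick(depth + 1, 2 * idx)},{newick(depth + 1, 2 * idx + 1)})"

    leaves = [Sequence(f"g{G}_{i}", s) for i, s in enumerate(gens[G])]
    return PhyloSim(leaves, newick(0, 0) + ";", is_elements, gens)


# ---------------------------------------------------------------------------
# tree building and comparison


def build_nj_tree(D: SimilarityMatrix) -> str:
    """Neighbor-joining tree (Newick, with branch lengths) from a square,
    symmetric, zero-diagonal distance matrix."""
    if D.row_ids != D.col_ids:
        raise InvalidInputError("neighbor joining needs a square matrix with matching ids")
    v = D.values
    if np.isnan(v).any():
        raise InvalidInputError("distance matrix contains NaN")
    if not np.allclose(v, v.T, atol=1e-9):
        raise InvalidInputError("distance matrix must be symmetric")
    if not np.allclose(np.diag(v), 0.0, atol=1e-9):
        raise InvalidInputError("distance matrix must have a zero diagonal")
    ids = D.row_ids
    if len(ids) == 1:
        return f"({ids[0]}:0.0);"
    if len(ids) == 2:
        h = v[0, 1] / 2
        return f"({ids[0]}:{h:g},{ids[1]}:{h:g});"
    if len(ids) == 3:
        # unique unrooted topology; branch lengths from the three-point equations
        x = (v[0, 1] + v[0, 2] - v[1, 2]) / 2
        y = (v[0, 1] + v[1, 2] - v[0, 2]) / 2
        z = (v[0, 2] + v[1, 2] - v[0, 1]) / 2
        return f"({ids[0]}:{x:g},{ids[1]}:{y:g},{ids[2]}:{z:g});"
    tree = neighbor_joining(np.asarray(v, dtype=np.float32))
    nwk = tree.to_newick(labels=ids, include_distance=True)
    return nwk if nwk.endswith(";") else nwk + ";"


def edit_distance_matrix(seqs: list[Sequence], normalized: bool = True) -> SimilarityMatrix:
    """All-vs-all exact edit distances (normalized by the longer length)."""
    n = len(seqs)
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = edit_distance(seqs[i].residues, seqs[j].residues)
            if normalized:
                d = d / max(len(seqs[i]), len(seqs[j]))
            v[i, j] = v[j, i] = d
    ids = [s.id for s in seqs]
    return SimilarityMatrix(ids, ids, v, "edit-distance")


def normalized_rf(t1: str, t2: str) -> float:
    """Normalized Robinson-Foulds distance between two Newick trees.

    Unrooted bipartition RF divided by the total number of internal edges
    of both trees (2(n-3) when both are binary); 0 means identical
    topologies, 1 maximal disagreement.  Trees on fewer than 4 shared
    leaves have a single unrooted topology and distance 0.
    """
    tns = dendropy.TaxonNamespace()
    try:
        tree1 = dendropy.Tree.get(
            data=t1, schema="newick", taxon_namespace=tns, preserve_underscores=True
        )
        tree2 = dendropy.Tree.get(
            data=t2, schema="newick", taxon_namespace=tns, preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises its own hierarchy
        raise InvalidInputError(f"could not parse Newick tree: {exc}") from exc
    leaves1 = {lf.taxon.label for lf in tree1.leaf_node_iter()}
    leaves2 = {lf.taxon.label for lf in tree2.leaf_node_iter()}
    if leaves1 != leaves2:
        raise InvalidInputError(
            "trees have different leaf sets: "
            f"{sorted(leaves1 ^ leaves2)[:5]} ... differ"
        )
    n = len(leaves1)
    if n < 4:
        return 0.0
    for tree in (tree1, tree2):
        tree.is_rooted = False
        tree.encode_bipartitions()
    rf = treecompare.symmetric_difference(tree1, tree2)
    internal = 0
    for tree in (tree1, tree2):
        internal += sum(
            1
            for e in tree.preorder_edge_iter()
            if e.head_node is not tree.seed_node
            and not e.head_node.is_leaf()
        )
    if internal == 0:
        return 0.0
    return rf / internal


def random_distance_matrix(ids: list[str], rng: np.random.Generator) -> SimilarityMatrix:
    """Symmetric uniform-random distances: the no-signal baseline for NJ."""
    n = len(ids)
    v = rng.random((n, n))
    v = np.triu(v, 1)
    v = v + v.T
    return SimilarityMatrix(ids, ids, v, "random-distance")


def phylogeny_experiment(
    cfg: PhyloSimConfig,
    testing_list: TestingList | None = None,
    size: int = 256,
    t: int = 5,
    k: int = 15,
    include_random: bool = True,
) -> dict[str, float]:
    """Simulate one IS phylogeny and score tree reconstructions by nRF.

    Returns ``{"edit": ..., "sketch": ..., "random": ...}`` — the
    normalized RF distance to the ground-truth tree of neighbor-joining
    trees built from exact edit distances, cosine sketch distances, and a
    random distance matrix.
    """
    from .sketch import generate_testing_list

    sim = simulate_is_phylogeny(cfg)
    if testing_list is None:
        testing_list = generate_testing_list(
            t=t, k=k, count=size, alphabet=cfg.alphabet, seed=cfg.seed
        )
    out: dict[str, float] = {}

    ed = edit_distance_matrix(sim.leaf_sequences)
    out["edit"] = normalized_rf(build_nj_tree(ed), sim.true_tree)

    sketches = sketch_collection(sim.leaf_sequences, testing_list)
    cos = pairwise_similarity(sketches, metric="cosine")
    out["sketch"] = normalized_rf(build_nj_tree(to_distance(cos)), sim.true_tree)

    if include_random:
        rng = np.random.default_rng(cfg.seed + 1)
        rnd = random_distance_matrix([s.id for s in sim.leaf_sequences], rng)
        out["random"] = normalized_rf(build_nj_tree(rnd), sim.true_tree)
    return out


# ---------------------------------------------------------------------------
# nearest-neighbor recall


def recall_item_curve(
    query,
    base,
    truth_topT: dict[str, list[str]],
    max_items: int,
    scores: SimilarityMatrix | None = None,
) -> np.ndarray:
    """Recall of the true top-T neighbors as the reported item budget grows.

    ``truth_topT`` maps each query id to the ids of its true T nearest
    neighbors in the base set (by edit distance).  Sequences in the base
    set are ranked per query by cosine sketch similarity (or by ``scores``,
    a precomputed query-by-base similarity matrix), ties broken by base-set
    order; entry ``m-1`` of the returned vector is the mean over queries of
    |top-m reported ∩ truth| / T.
    """
    base_ids = base.ids
    base_index = {bid: i for i, bid in enumerate(base_ids)}
    for qid, neighbors in truth_topT.items():
        for bid in neighbors:
            if bid not in base_index:
                raise InvalidInputError(
                    f"truth neighbor {bid!r} of query {qid!r} is not in the base set"
                )
    if scores is not None:
        if scores.row_ids != query.ids or scores.col_ids != base_ids:
            raise InvalidInputError("scores matrix ids do not match the sketch sets")
        sims = scores.values
    else:
        sims = pairwise_similarity(query, base, metric="cosine").values
    max_items = min(max_items, len(base_ids))
    recalls = np.zeros(max_items)
    n_queries = 0
    for qi, qid in enumerate(query.ids):
        if qid not in truth_topT:
            continue
        truth = set(truth_topT[qid])
        if not truth:
            continue
        n_queries += 1
        # stable sort on descending similarity keeps base order among ties
        order = np.argsort(-sims[qi], kind="stable")
        hits = np.cumsum(np.fromiter(
            (1 if base_ids[j] in truth else 0 for j in order[:max_items]),
            dtype=np.int64,
            count=max_items,
        ))
        recalls += hits / len(truth)
    if n_queries == 0:
        raise InvalidInputError("no query has a truth list")
    return np.minimum(recalls / n_queries, 1.0)
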