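"""Mutation model, edit similarity, phylogeny simulation, trees, recall."""

import numpy as np
import pytest

from subseqsketch import (
    InvalidInputError,
    MutationPairConfig,
    PhyloSimConfig,
    Sequence,
    SimilarityMatrix,
    build_nj_tree,
    correlation_experiment,
    edit_distance,
    edit_similarity,
    generate_testing_list,
    mutate_sequence,
    normalized_rf,
    pearson,
    recall_item_curve,
    simulate_is_phylogeny,
    sketch_collection,
)
from subseqsketch.evaluation import generate_mutation_pairs

from conftest import dp_edit_distance, random_string


class TestMutateSequence:
    def test_zero_rounds_is_identity(self):
        assert mutate_sequence("ACGTACGT", 0, 0) == "ACGTACGT"

    def test_length_changes_bounded_by_rounds(self, rng):
        for _ in range(50):
            s = random_string(rng, 30)
            rounds = int(rng.integers(0, 40))
            out = mutate_sequence(s, rounds, rng)
            assert abs(len(out) - len(s)) <= rounds
            assert edit_distance(s, out) <= rounds

    def test_deterministic_under_seed(self):
        s = random_string(np.random.default_rng(0), 100)
        assert mutate_sequence(s, 20, 5) == mutate_sequence(s, 20, 5)

    def test_empty_string_survives(self):
        out = mutate_sequence("", 10, 1)
        assert len(out) <= 10  # only inserts can apply


class TestEditSimilarity:
    def test_hand_values(self):
        assert edit_similarity("ACGT", "ACGT") == 1.0
        assert edit_similarity("ACGT", "AGT") == pytest.approx(0.75)
        assert edit_similarity("", "") == 1.0
        assert edit_similarity("", "AC") == 0.0

    def test_symmetric(self, rng):
        for _ in range(50):
            a = random_string(rng, int(rng.integers(0, 40)))
            b = random_string(rng, int(rng.integers(0, 40)))
            assert edit_similarity(a, b) == edit_similarity(b, a)

    def test_edlib_matches_dp_oracle_on_1000_pairs(self, rng):
        for _ in range(1000):
            a = random_string(rng, int(rng.integers(0, 25)))
            b = random_string(rng, int(rng.integers(0, 25)))
            assert edit_distance(a, b) == dp_edit_distance(a, b)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_value(self):
        assert pearson([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(InvalidInputError):
            pearson([1, 1, 1], [1, 2, 3])


class TestCorrelationExperiment:
    def test_degenerate_all_identical_pairs(self):
        cfg = MutationPairConfig(n_pairs=10, seq_len=50, max_rounds=0, seed=1)
        with pytest.warns(UserWarning):
            res = correlation_experiment(cfg, size=20, t=2, k=3)
        assert np.isnan(res.correlations["cosine"])
        assert (res.edit_similarity == 1.0).all()

    def test_cosine_tracks_edit_similarity_at_small_scale(self):
        cfg = MutationPairConfig(n_pairs=150, seq_len=300, max_rounds=300, seed=2)
        res = correlation_experiment(cfg, size=200, t=4, k=10)
        assert res.correlations["cosine"] > 0.7

    def test_rounds_distribution_covers_range(self):
        _, _, rounds = generate_mutation_pairs(
            MutationPairConfig(n_pairs=300, seq_len=20, max_rounds=100, seed=3)
        )
        assert rounds.min() >= 0 and rounds.max() <= 100
        assert len(np.unique(rounds // 10)) >= 8  # spread over bins


@pytest.fixture(scope="module")
def sim():
    return simulate_is_phylogeny(
        PhyloSimConfig(generations=4, root_len=400, point_mut_rate=1e-3,
                       is_len=30, seed=5)
    )


class TestPhyloSim:
    def test_leaf_count_and_lengths(self, sim):
        assert len(sim.leaf_sequences) == 2**4
        for leaf in sim.leaf_sequences:
            assert len(leaf) == 400 + 4 * 30

    def test_generation_sizes_double(self, sim):
        assert [len(g) for g in sim.generations] == [1, 2, 4, 8, 16]

    def test_is_element_present_at_insertion_generation(self, sim):
        # before any further mutation, every generation-g genome contains
        # that generation's IS verbatim
        for g in range(1, 5):
            for genome in sim.generations[g]:
                assert sim.is_elements[g - 1] in genome

    def test_true_tree_is_perfect_binary(self, sim):
        import dendropy

        tree = dendropy.Tree.get(
            data=sim.true_tree, schema="newick", preserve_underscores=True
        )
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        assert sorted(leaves) == sorted(s.id for s in sim.leaf_sequences)

    def test_deterministic_under_seed(self):
        cfg = PhyloSimConfig(generations=3, root_len=100, is_len=10, seed=9)
        a, b = simulate_is_phylogeny(cfg), simulate_is_phylogeny(cfg)
        assert [s.residues for s in a.leaf_sequences] == [
            s.residues for s in b.leaf_sequences
        ]


class TestNeighborJoining:
    def test_additive_four_taxon_matrix_recovers_topology(self):
        # tree ((a:1,b:2):1,(c:3,d:1):1) -> additive distances
        D = SimilarityMatrix(
            list("abcd"), list("abcd"),
            np.array([
                [0, 3, 6, 4],
                [3, 0, 7, 5],
                [6, 7, 0, 4],
                [4, 5, 4, 0],
            ], dtype=float),
            "cosine-distance",
        )
        nwk = build_nj_tree(D)
        assert normalized_rf(nwk, "((a,b),(c,d));") == 0.0

    def test_taxon_order_invariance(self, rng):
        ids = list("abcdef")
        v = rng.random((6, 6))
        v = np.triu(v, 1) + np.triu(v, 1).T
        D = SimilarityMatrix(ids, ids, v, "cosine-distance")
        nwk1 = build_nj_tree(D)
        perm = [3, 0, 5, 1, 4, 2]
        Dp = SimilarityMatrix(
            [ids[i] for i in perm], [ids[i] for i in perm],
            v[np.ix_(perm, perm)], "cosine-distance",
        )
        assert normalized_rf(nwk1, build_nj_tree(Dp)) == 0.0

    def test_three_taxa_solve_three_point_equations(self):
        import dendropy

        D = SimilarityMatrix(
            list("abc"), list("abc"),
            np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], dtype=float),
            "cosine-distance",
        )
        tree = dendropy.Tree.get(data=build_nj_tree(D), schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert pdm.distance(taxa["a"], taxa["b"]) == pytest.approx(5, abs=1e-4)
        assert pdm.distance(taxa["a"], taxa["c"]) == pytest.approx(9, abs=1e-4)
        assert pdm.distance(taxa["b"], taxa["c"]) == pytest.approx(8, abs=1e-4)

    def test_invalid_matrices_rejected(self):
        bad = SimilarityMatrix(
            list("ab"), list("ab"), np.array([[0.0, np.nan], [np.nan, 0.0]]), "x"
        )
        with pytest.raises(InvalidInputError):
            build_nj_tree(bad)
        asym = SimilarityMatrix(
            list("ab"), list("ab"), np.array([[0.0, 1.0], [2.0, 0.0]]), "x"
        )
        with pytest.raises(InvalidInputError):
            build_nj_tree(asym)


class TestNormalizedRF:
    def test_identical_trees(self):
        t = "(((a,b),(c,d)),((e,f),(g,h)));"
        assert normalized_rf(t, t) == 0.0

    def test_maximally_different_eight_leaf_pair(self):
        cat = "(((((((a,b),c),d),e),f),g),h);"
        mix = "(((a,e),(b,f)),((c,g),(d,h)));"
        assert normalized_rf(cat, mix) == 1.0

    def test_within_unit_interval(self, rng):
        import dendropy

        taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(10)])
        for s in range(5):
            t1 = dendropy.simulate.treesim.birth_death_tree(
                1.0, 0.0, taxon_namespace=taxa, num_extant_tips=10,
                rng=__import__("random").Random(s),
            ).as_string(schema="newick")
            t2 = dendropy.simulate.treesim.birth_death_tree(
                1.0, 0.0, taxon_namespace=taxa, num_extant_tips=10,
                rng=__import__("random").Random(100 + s),
            ).as_string(schema="newick")
            assert 0.0 <= normalized_rf(t1, t2) <= 1.0

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            normalized_rf("((a,b),(c,d));", "((a,b),(c,e));")


class TestRecallItemCurve:
    @pytest.fixture
    def sets(self, rng):
        L = generate_testing_list(t=2, k=5, count=40, seed=13)
        base_seqs = [Sequence(f"b{i}", random_string(rng, 80)) for i in range(30)]
        query_seqs = [Sequence(f"q{i}", random_string(rng, 80)) for i in range(5)]
        return (
            sketch_collection(query_seqs, L),
            sketch_collection(base_seqs, L),
            query_seqs,
            base_seqs,
        )

    def test_oracle_ranking_reaches_one_at_T(self, sets):
        query, base, query_seqs, base_seqs = sets
        T = 3
        truth = {}
        sims = np.zeros((len(query_seqs), len(base_seqs)))
        for qi, q in enumerate(query_seqs):
            for bi, b in enumerate(base_seqs):
                sims[qi, bi] = edit_similarity(q.residues, b.residues)
            order = np.argsort(-sims[qi], kind="stable")
            truth[q.id] = [base_seqs[j].id for j in order[:T]]
        # ranking by true edit similarity: recall must hit 1 already at m = T
        oracle = SimilarityMatrix(query.ids, base.ids, sims, "cosine")
        curve = recall_item_curve(query, base, truth, len(base_seqs), scores=oracle)
        assert curve[T - 1] == pytest.approx(1.0)
        # cosine-sketch ranking still reports everything at m = |base|
        curve2 = recall_item_curve(query, base, truth, len(base_seqs))
        assert curve2[-1] == pytest.approx(1.0)
        assert np.all(np.diff(curve2) >= -1e-12)  # recall is non-decreasing

    def test_random_ranking_baseline(self, rng):
        # with an uninformative sketch (all-equal vectors), ties are broken
        # by base order, so expected recall at m is about m/|base| when the
        # truth sets are random
        L = generate_testing_list(t=2, k=5, count=10, seed=14)
        base_seqs = [Sequence(f"b{i}", "ACGTACGTACGTACGTACGT") for i in range(40)]
        query_seqs = [Sequence(f"q{i}", "ACGTACGTACGTACGTACGT") for i in range(40)]
        query = sketch_collection(query_seqs, L)
        base = sketch_collection(base_seqs, L)
        T = 4
        truth = {
            q.id: list(np.random.default_rng(1000 + i).choice(
                [b.id for b in base_seqs], size=T, replace=False))
            for i, q in enumerate(query_seqs)
        }
        curve = recall_item_curve(query, base, truth, max_items=40)
        m = 20
        expected = m / 40
        assert abs(curve[m - 1] - expected) < 0.15  # Monte-Carlo tolerance

    def test_unknown_truth_id_rejected(self, sets):
        query, base, *_ = sets
        with pytest.raises(InvalidInputError):
            recall_item_curve(query, base, {query.ids[0]: ["nope"]}, 5)
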