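"""Jaccard similarity, UPGMA agglomeration, bootstrap supports, Newick I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

import bandpop as bp
from conftest import make_matrix


def naive_upgma_cophenetic(d):
    """Test-local UPGMA oracle: dict-of-clusters agglomeration, O(n^3)."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    dist = {
        (i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        (a, b), best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = best
        merged = clusters[a] + clusters[b]
        del clusters[a], clusters[b]
        for key in list(dist):
            if a in key or b in key:
                del dist[key]
        # distance of the merged cluster to the rest: mean over original
        # leaf pairs (the defining property of unweighted average linkage)
        for c, members in clusters.items():
            total = sum(d[i, j] for i in merged for j in members)
            dist[(min(c, next_id), max(c, next_id))] = total / (
                len(merged) * len(members)
            )
        clusters[next_id] = merged
        next_id += 1
    return coph


def _random_distance(rng, n):
    x = rng.random((n, n))
    d = (x + x.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


class TestJaccard:
    def test_identical_nonzero_vectors(self):
        assert bp.jaccard_similarity([1, 0, 1], [1, 0, 1]) == 1.0

    def test_disjoint_band_sets(self):
        assert bp.jaccard_similarity([1, 0, 0], [0, 1, 1]) == 0.0

    def test_counting_example(self):
        # a=2 shared, b=1 unique, c=0: J = 2/3
        assert bp.jaccard_similarity([1, 1, 0, 1], [1, 0, 0, 1]) == pytest.approx(2 / 3)

    def test_both_empty_is_undefined(self):
        with pytest.raises(ValueError, match="all-zero"):
            bp.jaccard_similarity([0, 0], [0, 0])

    def test_shared_absences_ignored(self):
        assert bp.jaccard_similarity([1, 0, 0, 0], [1, 0, 0, 0]) == 1.0


class TestSimilarityMatrix:
    def test_diagonal_and_symmetry(self, rng):
        m = make_matrix((rng.random((6, 20)) < 0.6).astype(int))
        sim = bp.similarity_matrix(m)
        assert np.allclose(np.diag(sim), 1.0)
        assert np.allclose(sim, sim.T)

    def test_matches_pairwise_brute_force(self, rng):
        m = make_matrix((rng.random((7, 25)) < 0.5).astype(int))
        sim = bp.similarity_matrix(m)
        for i in range(7):
            for j in range(7):
                if i == j:
                    continue
                assert sim.iloc[i, j] == pytest.approx(
                    bp.jaccard_similarity(m.scores[i], m.scores[j])
                )

    def test_all_zero_individual_named_in_error(self):
        m = make_matrix([[1, 0], [0, 0]], ids=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            bp.similarity_matrix(m)


class TestUpgma:
    def test_two_leaves(self):
        t = bp.upgma(np.array([[0, 0.4], [0.4, 0]]), ["A", "B"])
        assert t.root.height == pytest.approx(0.2)
        assert set(t.leaf_names) == {"A", "B"}

    def test_four_leaf_hand_example(self):
        # d(A,B)=0.2, d(C,D)=0.3, all cross-pairs 0.8:
        # merges (A,B)@0.1, (C,D)@0.15, root @ 0.4
        d = np.array(
            [
                [0.0, 0.2, 0.8, 0.8],
                [0.2, 0.0, 0.8, 0.8],
                [0.8, 0.8, 0.0, 0.3],
                [0.8, 0.8, 0.3, 0.0],
            ]
        )
        t = bp.upgma(d, ["A", "B", "C", "D"])
        assert t.root.height == pytest.approx(0.4)
        clades = {frozenset(node.leaves()) for node in t.internal_nodes()}
        assert frozenset({"A", "B"}) in clades
        assert frozenset({"C", "D"}) in clades

    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    def test_cophenetic_matches_scipy_reference(self, n):
        rng = np.random.default_rng(n)
        d = _random_distance(rng, n)
        labels = [f"L{i}" for i in range(n)]
        mine = bp.upgma(d, labels).cophenetic_matrix(labels).to_numpy()
        reference = squareform(cophenet(linkage(squareform(d), method="average")))
        np.testing.assert_allclose(mine, reference, atol=1e-10)

    @pytest.mark.parametrize("n", [5, 8])
    def test_cophenetic_matches_naive_oracle(self, n):
        rng = np.random.default_rng(100 + n)
        d = _random_distance(rng, n)
        mine = bp.upgma(d).cophenetic_matrix([str(i) for i in range(n)]).to_numpy()
        np.testing.assert_allclose(mine, naive_upgma_cophenetic(d), atol=1e-10)

    def test_ultrametric_input_reproduced_exactly(self):
        # a valid ultrametric: coph(A,B)=0.2, coph(.,C)=0.6
        d = np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
        t = bp.upgma(d, ["A", "B", "C"])
        np.testing.assert_allclose(
            t.cophenetic_matrix(["A", "B", "C"]).to_numpy(), d, atol=1e-12
        )

    def test_heights_non_decreasing_toward_root(self, rng):
        d = _random_distance(rng, 9)
        t = bp.upgma(d)

        def walk(node):
            for c in node.children:
                assert c.height <= node.height + 1e-12
                walk(c)

        walk(t.root)

    def test_cut_recovers_generator_populations(self):
        m, truth = bp.generate(seed=9)
        tree = bp.upgma(1.0 - bp.similarity_matrix(m))
        groups = tree.cut(truth.true_k)
        labels_true = dict(zip(m.individual_ids, m.population_labels))
        # Rand index between the 4-group cut and the true populations
        ids = list(m.individual_ids)
        same_true = same_cut = both = 0
        total = 0
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                t_same = labels_true[ids[i]] == labels_true[ids[j]]
                c_same = groups[ids[i]] == groups[ids[j]]
                total += 1
                if t_same == c_same:
                    both += 1
        assert both / total >= 0.95


class TestBootstrap:
    def test_well_separated_clusters_have_high_support(self):
        specs = [
            bp.PopulationSpec(
                name=f"c{i}",
                n_individuals=8,
                bands_per_primer=(30,),
                primers=("pr",),
                private_band_count=12,
                private_range=(0.85, 0.95),
                rare_fraction=0.0,
            )
            for i in range(2)
        ]
        for seed in range(5):
            m, _ = bp.generate(specs, seed=seed)
            tree = bp.bootstrap_support(m, replicates=200, seed=seed)
            pops = {p: set(m.population_individuals(p)) for p in m.populations}
            supports = {
                frozenset(node.leaves()): node.support
                for node in tree.internal_nodes()
            }
            defining = [
                s
                for leafset, s in supports.items()
                if set(leafset) in pops.values()
            ]
            assert defining and all(s >= 95 for s in defining)

    def test_single_band_supports_100(self):
        m = make_matrix([[1], [1], [1]])
        tree = bp.bootstrap_support(m, replicates=100, seed=0)
        assert all(node.support == 100.0 for node in tree.internal_nodes())

    def test_same_seed_identical_supports(self, rng):
        m = make_matrix((rng.random((8, 25)) < 0.5).astype(int))
        a = bp.bootstrap_support(m, replicates=100, seed=7)
        b = bp.bootstrap_support(m, replicates=100, seed=7)
        sa = [n.support for n in a.internal_nodes()]
        sb = [n.support for n in b.internal_nodes()]
        assert sa == sb

    def test_low_supports_retained_in_structure(self, rng):
        m = make_matrix((rng.random((10, 12)) < 0.5).astype(int))
        if not m.scores.any(axis=1).all():  # avoid all-zero rows
            m = make_matrix(np.clip(m.scores + np.eye(10, 12, dtype=int), 0, 1))
        tree = bp.bootstrap_support(m, replicates=100, seed=1)
        assert all(n.support is not None for n in tree.internal_nodes())


class TestNewick:
    def test_two_leaf_shape(self, tmp_path):
        t = bp.upgma(np.array([[0, 0.4], [0.4, 0]]), ["A", "B"])
        t.root.support = 100.0
        path = tmp_path / "t.nwk"
        bp.write_newick(t, path)
        assert path.read_text().strip() == "(A:0.2,B:0.2)100;"

    def test_round_trip_topology_heights_supports(self, tmp_path, rng):
        d = _random_distance(rng, 7)
        labels = [f"L{i}" for i in range(7)]
        t = bp.upgma(d, labels)
        for k, node in enumerate(t.internal_nodes()):
            node.support = float(50 + k)
        path = tmp_path / "t.nwk"
        bp.write_newick(t, path)
        back = bp.read_newick(path)
        assert set(back.leaf_names) == set(labels)
        np.testing.assert_allclose(
            back.cophenetic_matrix(labels).to_numpy(),
            t.cophenetic_matrix(labels).to_numpy(),
            atol=1e-6,
        )
        orig = {frozenset(n.leaves()): n.support for n in t.internal_nodes()}
        parsed = {frozenset(n.leaves()): n.support for n in back.internal_nodes()}
        assert parsed == orig

    def test_low_supports_hidden_at_threshold_but_retained(self, tmp_path):
        t = bp.upgma(np.array([[0, 0.4], [0.4, 0]]), ["A", "B"])
        t.root.support = 42.0
        assert t.to_newick(min_support=50) == "(A:0.2,B:0.2);"
        assert t.to_newick() == "(A:0.2,B:0.2)42;"
        assert t.root.support == 42.0

    def test_supports_omitted_when_absent(self, tmp_path):
        t = bp.upgma(np.array([[0, 0.4], [0.4, 0]]), ["A", "B"])
        path = tmp_path / "t.nwk"
        bp.write_newick(t, path)
        assert path.read_text().strip() == "(A:0.2,B:0.2);"
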