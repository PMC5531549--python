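import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bhlhkit import phylogeny as ph
from bhlhkit import synthetic_data as sd

from _oracles import least_squares_topology, random_additive_tree


def dendropy_splits(tree):
    """Split sets of a bhlhkit tree, as frozensets of leaf names."""
    tree.encode_bipartitions(suppress_unifurcations=False)
    taxa = list(tree.taxon_namespace)
    n = len(taxa)
    out = set()
    for edge in tree.preorder_edge_iter():
        if edge.bipartition is None:
            continue
        mask = edge.bipartition.split_bitmask
        size = bin(mask).count("1")
        if 1 < size < n - 1:
            out.add(frozenset(t.label for i, t in enumerate(taxa) if mask >> i & 1))
    return out


class TestPDistance:
    def test_quarter(self):
        assert ph.p_distance("AAAA", "AAAT") == pytest.approx(0.25)

    def test_pairwise_deletion(self):
        assert ph.p_distance("A-AA", "AGAA") == 0.0

    def test_identical(self):
        assert ph.p_distance("KDEL", "KDEL") == 0.0

    def test_no_comparable_sites_is_nan(self):
        assert math.isnan(ph.p_distance("A--", "-AA"))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ph.p_distance("AA", "AAA")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text("ACDE-", min_size=1, max_size=40), st.text("ACDE-", min_size=1, max_size=40))
    def test_symmetry(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        pa, pb = ph.p_distance(a, b), ph.p_distance(b, a)
        assert (math.isnan(pa) and math.isnan(pb)) or pa == pb


class TestPoissonCorrection:
    @pytest.mark.parametrize(
        "p,expected", [(0.0, 0.0), (0.5, math.log(2)), (0.25, -math.log(0.75))]
    )
    def test_analytic_values(self, p, expected):
        assert ph.poisson_correct(p) == pytest.approx(expected, abs=1e-12)

    def test_saturation(self):
        assert math.isinf(ph.poisson_correct(1.0))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = ph.neighbor_joining(ph.DistanceMatrix(["a", "b", "c"], d))
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        # la = (dab + dac - dbc)/2 etc.
        assert lengths["a"] == pytest.approx(2.0)
        assert lengths["b"] == pytest.approx(3.0)
        assert lengths["c"] == pytest.approx(7.0)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            ph.neighbor_joining(
                ph.DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float))
            )

    @pytest.mark.parametrize("n", [4, 5])
    def test_matches_bruteforce_least_squares(self, n):
        """NJ topology equals the exhaustive least-squares topology on
        random additive matrices."""
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            tree, leaves = random_additive_tree(n, rng)
            d = tree.leaf_distances(leaves)
            ids = [f"t{i}" for i in range(n)]
            nj = ph.neighbor_joining(ph.DistanceMatrix(ids, d))
            nj_splits = {
                frozenset(int(x[1:]) for x in s) for s in dendropy_splits(nj)
            }
            assert nj_splits == least_squares_topology(d)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(4, 12), st.integers(0, 10**6))
    def test_additive_matrices_recovered_exactly(self, n, seed):
        """On additive input NJ reproduces the generating tree: identical
        splits and patristic distances to 1e-9."""
        rng = np.random.default_rng(seed)
        tree, leaves = random_additive_tree(n, rng)
        d = tree.leaf_distances(leaves)
        ids = [f"t{i}" for i in range(n)]
        nj = ph.neighbor_joining(ph.DistanceMatrix(ids, d))
        assert np.abs(ph.patristic_matrix(nj, ids) - d).max() < 1e-9
        true_splits = {
            frozenset(f"t{i}" for i in s) for s in tree.splits(leaves)
        }
        assert dendropy_splits(nj) == true_splits

    def test_agrees_with_dendropy_nj_on_additive_input(self):
        """Independent cross-check against dendropy's own NJ."""
        import dendropy

        rng = np.random.default_rng(77)
        tree, leaves = random_additive_tree(6, rng)
        d = tree.leaf_distances(leaves)
        ids = [f"t{i}" for i in range(6)]
        nj = ph.neighbor_joining(ph.DistanceMatrix(ids, d))
        csv = "," + ",".join(ids) + "\n"
        for i, row in enumerate(d):
            csv += ids[i] + "," + ",".join(str(x) for x in row) + "\n"
        import io as _io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            _io.StringIO(csv), delimiter=","
        )
        ref = pdm.nj_tree()
        ref_splits = {
            frozenset(t.label for t in bp.leafset_taxa(ref.taxon_namespace))
            for bp in ref.encode_bipartitions()
            if 1 < len(bp.leafset_taxa(ref.taxon_namespace)) < 5
        }
        mine = dendropy_splits(nj)
        norm = lambda splits: {
            s if "t0" not in s else frozenset(ids) - s for s in splits
        }
        assert norm(mine) == norm(ref_splits)

    def test_equal_distance_matrix_total_length(self):
        """All-equal distances c on 4 taxa: NJ yields total length 2c
        (hand computation: first join gives two c/2 twigs and a zero
        internal edge, the final star three edges 0, c/2, c/2)."""
        c = 3.0
        d = np.full((4, 4), c)
        np.fill_diagonal(d, 0.0)
        tree = ph.neighbor_joining(ph.DistanceMatrix(list("abcd"), d))
        total = sum(e.length for e in tree.preorder_edge_iter() if e.length)
        assert total == pytest.approx(2 * c)


class TestBootstrap:
    IDS = ["a", "b", "c", "d"]
    ALN = ["AAAA", "AAAA", "TTTT", "TTTT"]

    def test_clean_split_gets_full_support(self):
        tree = ph.bootstrap_supports(self.IDS, self.ALN, n_reps=25, seed=0)
        assert set(tree.bipartition_support.values()) == {100.0}

    def test_single_replicate_support_is_0_or_100(self):
        aln = ["AACT", "AACA", "TTAG", "TTAC"]
        tree = ph.bootstrap_supports(self.IDS, aln, n_reps=1, seed=3)
        assert set(tree.bipartition_support.values()) <= {0.0, 100.0}

    def test_fixed_seed_reproducible(self):
        ids, rows, _ = sd.generate_subfamily_alignment(
            n_subfamilies=3, members_per_subfamily=3, seed=9
        )
        t1 = ph.bootstrap_supports(ids, rows, n_reps=30, seed=5)
        t2 = ph.bootstrap_supports(ids, rows, n_reps=30, seed=5)
        assert t1.bipartition_support == t2.bipartition_support
        assert ph.to_newick(t1) == ph.to_newick(t2)

    def test_supports_invariant_to_leaf_order(self):
        ids, rows, _ = sd.generate_subfamily_alignment(
            n_subfamilies=3, members_per_subfamily=3, seed=9
        )
        t1 = ph.bootstrap_supports(ids, rows, n_reps=30, seed=5)
        perm = list(range(len(ids)))[::-1]
        t2 = ph.bootstrap_supports(
            [ids[i] for i in perm], [rows[i] for i in perm], n_reps=30, seed=5
        )
        def named(tree):
            taxa = list(tree.taxon_namespace)
            return {
                frozenset(
                    t.label for i, t in enumerate(taxa) if mask >> i & 1
                ): s
                for mask, s in tree.bipartition_support.items()
            }
        def norm(d):
            all_ids = frozenset(ids)
            return {
                (s if "fam1_1" not in s else all_ids - s): v for s, v in d.items()
            }
        assert norm(named(t1)) == norm(named(t2))


class TestSubfamilies:
    def test_star_tree_all_singletons(self):
        # alignment with no phylogenetic signal at all
        ids = ["a", "b", "c", "d"]
        aln = ["AAAA", "CCCC", "GGGG", "TTTT"]
        tree = ph.bootstrap_supports(ids, aln, n_reps=10, seed=0)
        weak = ph.extract_subfamilies(tree, min_support=101)
        assert sorted(weak) == [["a"], ["b"], ["c"], ["d"]]

    def test_fully_supported_caterpillar_maximal_once(self):
        """One internal split {a,b}|{c,d} at 100%: the rooted side away
        from the midpoint node is reported once, the basal leaves stay
        singletons, and the clusters partition the leaf set."""
        tree = ph.bootstrap_supports(
            ["a", "b", "c", "d"], ["AAAA", "AAAA", "TTTT", "TTTT"], n_reps=10, seed=0
        )
        clusters = ph.extract_subfamilies(tree, 50)
        assert sorted(len(c) for c in clusters) == [1, 1, 2]
        flat = sorted(x for c in clusters for x in c)
        assert flat == ["a", "b", "c", "d"]

    def test_five_planted_subfamilies_recovered(self):
        ids, rows, truth = sd.generate_subfamily_alignment(seed=11)
        tree = ph.bootstrap_supports(ids, rows, n_reps=200, seed=11)
        clusters = ph.extract_subfamilies(tree, 50)
        got = {frozenset(c) for c in clusters if len(c) > 1}
        want = {
            frozenset(n for n in ids if truth[n] == g) for g in range(5)
        }
        assert got == want
        flat = sorted(x for c in clusters for x in c)
        assert flat == sorted(ids)  # partition of the leaf set
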