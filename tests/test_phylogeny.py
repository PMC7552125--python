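import numpy as np
import pytest

import strtrace as st
from strtrace.differentiation import DistanceMatrix
from strtrace.phylogeny import Tree, TreeNode, to_newick


def _tree_from_spec():
    """Hand-built additive 6-taxon tree with known branch lengths."""
    A, B, C, D, E, F = (TreeNode(x) for x in "ABCDEF")
    inner = TreeNode(children=[(D, 0.4), (E, 0.1)])
    sub = TreeNode(children=[(C, 0.15), (inner, 0.25), (F, 0.33)])
    return Tree(TreeNode(children=[(A, 0.3), (B, 0.2), (sub, 0.12)]))


class TestAlleleSharingDistance:
    def test_identical_and_disjoint_individuals(self):
        alleles = np.array(
            [[[1, 2], [3, 3]], [[1, 2], [3, 3]], [[5, 6], [7, 8]]], dtype=np.int32
        )
        m = st.GenotypeMatrix(["x", "y", "z"], ["P"] * 3, ["L1", "L2"], alleles)
        d = st.allele_sharing_distance(m)
        assert d[("x", "y")] == 0.0
        assert d[("x", "z")] == 1.0

    def test_multiset_semantics_het_vs_hom(self):
        alleles = np.array([[[1, 2]], [[1, 1]]], dtype=np.int32)
        m = st.GenotypeMatrix(["x", "y"], ["P", "P"], ["L"], alleles)
        assert st.allele_sharing_distance(m)[("x", "y")] == 0.5

    def test_missing_loci_skipped(self):
        alleles = np.array([[[1, 2], [-1, -1]], [[1, 2], [5, 5]]], dtype=np.int32)
        m = st.GenotypeMatrix(["x", "y"], ["P", "P"], ["L1", "L2"], alleles)
        assert st.allele_sharing_distance(m)[("x", "y")] == 0.0

    def test_no_comparable_loci_errors(self):
        alleles = np.array([[[1, 2], [-1, -1]], [[-1, -1], [5, 5]]], dtype=np.int32)
        m = st.GenotypeMatrix(["x", "y"], ["P", "P"], ["L1", "L2"], alleles)
        with pytest.raises(ValueError, match="x.*y"):
            st.allele_sharing_distance(m)


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        d = DistanceMatrix(["A", "B"], np.array([[0.0, 0.4], [0.4, 0.0]]))
        t = st.neighbor_joining(d)
        assert to_newick(t) == "(A:0.2,B:0.2);"

    def test_recovers_additive_four_taxon_tree(self):
        A, B, C, D = (TreeNode(x) for x in "ABCD")
        left = TreeNode(children=[(A, 0.1), (B, 0.3)])
        ref = Tree(TreeNode(children=[(left, 0.2), (C, 0.25), (D, 0.45)]))
        rebuilt = st.neighbor_joining(ref.path_lengths())
        assert np.allclose(rebuilt.path_lengths().values, ref.path_lengths().values, atol=1e-9)
        assert rebuilt.bipartitions() == ref.bipartitions()

    @pytest.mark.parametrize("n_taxa", [4, 6, 8])
    def test_additivity_round_trip_random_trees(self, n_taxa):
        """NJ returns a tree whose path metric equals any additive input."""
        rng = np.random.default_rng(n_taxa)
        nodes = [TreeNode(f"T{i}") for i in range(n_taxa)]
        lengths = rng.uniform(0.05, 0.5, size=2 * n_taxa)
        li = iter(lengths)
        while len(nodes) > 3:
            a = nodes.pop(int(rng.integers(len(nodes))))
            b = nodes.pop(int(rng.integers(len(nodes))))
            nodes.append(TreeNode(children=[(a, next(li)), (b, next(li))]))
        ref = Tree(TreeNode(children=[(n, next(li)) for n in nodes]))
        dm = ref.path_lengths()
        out = st.neighbor_joining(dm)
        assert np.allclose(out.path_lengths().values, dm.values, atol=1e-9)

    def test_label_order_invariance(self):
        ref = _tree_from_spec()
        dm = ref.path_lengths()
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(dm.labels))
        dm2 = DistanceMatrix(
            [dm.labels[i] for i in perm], dm.values[np.ix_(perm, perm)]
        )
        t1 = st.neighbor_joining(dm)
        t2 = st.neighbor_joining(dm2)
        assert t1.bipartitions() == t2.bipartitions()
        assert np.allclose(t1.path_lengths().values, t2.path_lengths().values, atol=1e-9)

    def test_asymmetric_input_rejected(self):
        dm = DistanceMatrix(["A", "B", "C"], np.zeros((3, 3)))
        dm.values = np.array([[0.0, 1.0, 2.0], [3.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            st.neighbor_joining(dm)


class TestNewick:
    def test_round_trip_identity(self, tmp_path):
        ref = _tree_from_spec()
        path = tmp_path / "t.nwk"
        st.write_newick(st.neighbor_joining(ref.path_lengths()), path)
        back = st.read_newick(path)
        assert np.allclose(
            back.path_lengths().values, ref.path_lengths().values, atol=1e-9
        )

    def test_labels_with_spaces_quoted(self):
        t = Tree(
            TreeNode(children=[(TreeNode("my cow"), 0.1), (TreeNode("B"), 0.1)])
        )
        s = to_newick(t)
        assert "'my cow'" in s
        assert sorted(st.read_newick(s).leaves()) == ["B", "my cow"]

    def test_dendropy_agrees_on_path_lengths(self):
        """Independent parser cross-check of the Newick writer."""
        dendropy = pytest.importorskip("dendropy")
        ref = _tree_from_spec()
        tree = st.neighbor_joining(ref.path_lengths())
        dt = dendropy.Tree.get(data=to_newick(tree), schema="newick")
        pdm = dt.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in dt.taxon_namespace}
        ours = tree.path_lengths()
        for i, a in enumerate(ours.labels):
            for b in ours.labels[i + 1 :]:
                assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                    ours[(a, b)], abs=1e-6
                )


class TestBootstrap:
    def test_supports_are_frequencies(self):
        spec = st.PopulationSpec(n_populations=2, fst=0.3, n_loci=12, sizes=(5, 5), seed=31)
        m = st.simulate_dataset(spec)
        support = st.bootstrap_support(m, n_reps=20, seed=1)
        assert all(0.0 <= v <= 1.0 for v in support.values())
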