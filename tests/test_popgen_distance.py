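import math

import numpy as np
import pytest

from hla_popgen import (
    DistanceMatrix,
    FrequencyTable,
    Locus,
    PhyloTree,
    da_distance,
    distance_matrix,
    neighbor_joining,
    nei_standard_distance,
)
from hla_popgen.errors import HlaPopgenError, InfiniteDistanceError

from conftest import cat, random_additive_matrix


def one_locus_table(name, freqs):
    return FrequencyTable(
        name, {Locus.A: {cat(f"A*{i + 1:02d}"): v for i, v in enumerate(freqs)}}
    )


class TestNeiDistance:
    def test_identical_tables_have_zero_distance(self, paper_fixtures):
        han = paper_fixtures.frequencies["Han"]
        assert nei_standard_distance(han, han) == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_closed_form(self):
        x = one_locus_table("X", [0.8, 0.2])
        y = one_locus_table("Y", [0.2, 0.8])
        d = nei_standard_distance(x, y, loci=[Locus.A])
        assert d == pytest.approx(-math.log(0.32 / 0.68), abs=1e-9)
        assert d == pytest.approx(0.753772, abs=1e-6)

    def test_han_manchu_reproduces_printed_value(self, paper_fixtures):
        d = nei_standard_distance(
            paper_fixtures.frequencies["Han"], paper_fixtures.frequencies["Manchu"]
        )
        assert d == pytest.approx(0.002084, abs=5e-4)

    def test_symmetric_and_nonnegative(self, paper_fixtures):
        f = paper_fixtures.frequencies
        for a, b in [("Han", "Korean"), ("Mongol", "Xibe"), ("Hui", "Manchu")]:
            dab = nei_standard_distance(f[a], f[b])
            dba = nei_standard_distance(f[b], f[a])
            assert dab == pytest.approx(dba, abs=1e-15)
            assert dab >= 0

    def test_disjoint_alleles_is_infinite_distance(self):
        x = one_locus_table("X", [1.0])
        y = FrequencyTable("Y", {Locus.A: {cat("A*99"): 1.0}})
        with pytest.raises(InfiniteDistanceError):
            nei_standard_distance(x, y, loci=[Locus.A])

    def test_renormalize_flag_scales_columns(self):
        x = FrequencyTable("X", {Locus.A: {cat("A*01"): 0.799, cat("A*02"): 0.199}})
        y = one_locus_table("Y", [0.8, 0.2])
        d = nei_standard_distance(x, y, loci=[Locus.A], renormalize=True)
        assert d == pytest.approx(0.0, abs=1e-6)

    def test_da_distance_differs_from_standard(self, paper_fixtures):
        f = paper_fixtures.frequencies
        assert da_distance(f["Han"], f["Korean"]) != pytest.approx(
            nei_standard_distance(f["Han"], f["Korean"]), abs=1e-4
        )


class TestDistanceMatrix:
    def test_matrix_is_symmetric_with_zero_diagonal(self, paper_fixtures):
        dm = distance_matrix(paper_fixtures.frequencies.values())
        np.testing.assert_allclose(dm.values, dm.values.T, atol=1e-15)
        np.testing.assert_allclose(np.diag(dm.values), 0, atol=1e-15)

    def test_han_neighbour_ranking(self, paper_fixtures):
        dm = distance_matrix(paper_fixtures.frequencies.values())
        d = {pop: dm.get("Han", pop) for pop in dm.labels if pop != "Han"}
        ranked = sorted(d, key=d.get)
        assert ranked == ["Manchu", "Mongol", "Hui", "Korean", "Xibe"]

    def test_identical_populations_off_diagonal_zero(self, paper_fixtures):
        han = paper_fixtures.frequencies["Han"]
        clone = FrequencyTable("Han2", han.freqs, han.sample_count)
        dm = distance_matrix([han, clone])
        assert dm.get("Han", "Han2") == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_labels_error(self, paper_fixtures):
        han = paper_fixtures.frequencies["Han"]
        with pytest.raises(HlaPopgenError, match="duplicate"):
            distance_matrix([han, han])


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = neighbor_joining(dm)
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.tree.leaf_node_iter()
        }
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_fewer_than_three_taxa_errors(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float))
        with pytest.raises(HlaPopgenError):
            neighbor_joining(dm)

    def test_recovers_additive_matrices_exactly(self):
        rng = np.random.default_rng(20140401)
        for _ in range(30):
            dm = random_additive_matrix(int(rng.integers(4, 11)), rng)
            pd = neighbor_joining(dm).patristic_distances()
            idx = [pd.labels.index(l) for l in dm.labels]
            np.testing.assert_allclose(pd.values[np.ix_(idx, idx)], dm.values, atol=1e-9)

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(7)
        dm = random_additive_matrix(6, rng)
        perm = list(rng.permutation(len(dm.labels)))
        shuffled = DistanceMatrix(
            [dm.labels[i] for i in perm], dm.values[np.ix_(perm, perm)]
        )
        a = neighbor_joining(dm).patristic_distances()
        b = neighbor_joining(shuffled).patristic_distances()
        assert a.labels == b.labels
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_newick_round_trip(self):
        rng = np.random.default_rng(3)
        dm = random_additive_matrix(7, rng)
        tree = neighbor_joining(dm)
        back = PhyloTree.from_newick(tree.to_newick())
        assert back.leaf_labels == tree.leaf_labels
        np.testing.assert_allclose(
            back.patristic_distances().values,
            tree.patristic_distances().values,
            atol=1e-6,
        )

    def test_agrees_with_independent_nj_implementation(self, paper_fixtures):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        dm = distance_matrix(paper_fixtures.frequencies.values())
        ours = neighbor_joining(dm).patristic_distances()
        theirs_tree = skbio_nj(SkbioDM(dm.values, ids=dm.labels), neg_as_zero=False)
        for i, a in enumerate(ours.labels):
            for j, b in enumerate(ours.labels):
                if i < j:
                    theirs = theirs_tree.find(a).distance(theirs_tree.find(b))
                    assert ours.values[i, j] == pytest.approx(theirs, abs=1e-6)
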