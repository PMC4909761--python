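import io
import math

import dendropy
import numpy as np
import pytest

from aoxaudit.njtree import (
    DistanceMatrix,
    assign_subfamily,
    distance_matrix,
    is_separated,
    nj,
    p_distance,
    path_lengths,
    poisson_distance,
    read_phylip,
    subfamily_of,
    to_newick,
    write_phylip,
)
from conftest import protein


def random_additive_matrix(rng: np.random.Generator, n_leaves: int):
    """Build a random binary tree and return its exact leaf-path distances.

    Independent of the NJ implementation: clusters are merged in random
    order with random positive branch lengths, accumulating leaf-to-leaf
    path lengths directly.
    """
    labels = [f"L{i}" for i in range(n_leaves)]
    dist = np.zeros((n_leaves, n_leaves))
    # each active cluster tracks (leaf index -> distance to cluster root)
    clusters = [{i: 0.0} for i in range(n_leaves)]
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        li, lj = rng.uniform(0.1, 2.0, size=2)
        a, b = clusters[i], clusters[j]
        for x, dx in a.items():
            for y, dy in b.items():
                dist[x, y] = dist[y, x] = dx + li + dy + lj
        merged = {x: dx + li for x, dx in a.items()}
        merged.update({y: dy + lj for y, dy in b.items()})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return DistanceMatrix(tuple(labels), dist)


class TestPDistance:
    def test_one_difference_in_three(self):
        assert p_distance(protein("a", "ACD"), protein("b", "ACE")) == \
            pytest.approx(1 / 3)

    def test_gapped_columns_excluded_pairwise(self):
        a = protein("a", "A-D", aligned=True)
        b = protein("b", "AED", aligned=True)
        assert p_distance(a, b) == 0.0

    def test_identity_is_zero(self):
        record = protein("a", "MKLVNQ")
        assert p_distance(record, record) == 0.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            p_distance(protein("a", "MK"), protein("b", "MKL"))

    def test_no_comparable_columns_rejected(self):
        a = protein("a", "A--", aligned=True)
        b = protein("b", "-AA", aligned=True)
        with pytest.raises(ValueError, match="comparable"):
            p_distance(a, b)

    def test_poisson_correction_exceeds_p(self):
        a, b = protein("a", "ACDEF"), protein("b", "ACDEW")
        assert poisson_distance(a, b) == pytest.approx(-math.log(1 - 0.2))


class TestDistanceMatrix:
    def test_identical_records_give_zero_matrix(self):
        records = [protein(f"s{i}", "MKLV") for i in range(3)]
        dm = distance_matrix(records)
        assert np.allclose(dm.values, 0.0)

    def test_label_order_preserved(self):
        records = [protein(x, "MK") for x in ("z", "a", "m")]
        assert distance_matrix(records).labels == ("z", "a", "m")

    def test_entries_match_pairwise_recomputation(self):
        rng = np.random.default_rng(5)
        records = [
            protein(f"s{i}", "".join(rng.choice(list("ACDEFGHIK"), 30)))
            for i in range(5)
        ]
        dm = distance_matrix(records)
        for i in range(5):
            for j in range(5):
                expected = 0.0 if i == j else p_distance(records[i], records[j])
                assert dm.values[i, j] == pytest.approx(expected)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # known tree: (a,b) and (c,d) cherries, leaf edges 1,2,3,4, internal 1
        values = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        dm = DistanceMatrix(("a", "b", "c", "d"), values)
        tree = nj(dm)
        recovered = path_lengths(tree)
        order = [recovered.labels.index(x) for x in dm.labels]
        assert np.allclose(recovered.values[np.ix_(order, order)], values,
                           atol=1e-9)
        assert frozenset({"a", "b"}) in set(tree.bipartitions()) or \
            frozenset({"c", "d"}) in set(tree.bipartitions())

    def test_three_taxon_closed_form(self):
        values = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        tree = nj(DistanceMatrix(("a", "b", "c"), values))
        lengths = {c.label: c.length for c in tree.root.children}
        assert lengths["a"] == pytest.approx((0.4 + 0.6 - 0.8) / 2)
        assert lengths["b"] == pytest.approx((0.4 + 0.8 - 0.6) / 2)
        assert lengths["c"] == pytest.approx((0.6 + 0.8 - 0.4) / 2)

    def test_two_taxa_single_edge(self):
        tree = nj(DistanceMatrix(("A", "B"), np.array([[0, 0.5], [0.5, 0]])))
        assert tree.total_branch_length() == pytest.approx(0.5)
        assert to_newick(tree) == "(A:0.250000,B:0.250000);"

    def test_random_additive_trees_recovered_exactly(self):
        rng = np.random.default_rng(20)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            dm = random_additive_matrix(rng, n)
            recovered = path_lengths(nj(dm))
            order = [recovered.labels.index(x) for x in dm.labels]
            assert np.allclose(recovered.values[np.ix_(order, order)],
                               dm.values, atol=1e-9)

    def test_total_length_invariant_under_input_permutation(self):
        rng = np.random.default_rng(8)
        dm = random_additive_matrix(rng, 8)
        base = nj(dm).total_branch_length()
        for _ in range(5):
            perm = rng.permutation(len(dm))
            shuffled = DistanceMatrix(
                tuple(dm.labels[i] for i in perm),
                dm.values[np.ix_(perm, perm)],
            )
            assert nj(shuffled).total_branch_length() == pytest.approx(base)

    def test_agrees_with_dendropy_on_generic_matrix(self):
        # a noisy (non-additive) matrix: topologies must still agree because
        # both implement the same Saitou-Nei criterion
        rng = np.random.default_rng(99)
        dm = random_additive_matrix(rng, 9)
        noisy = dm.values + rng.uniform(0, 0.05, dm.values.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        dm = DistanceMatrix(dm.labels, noisy)
        ours = nj(dm)
        csv = "," + ",".join(dm.labels) + "\n" + "\n".join(
            dm.labels[i] + "," + ",".join(str(v) for v in dm.values[i])
            for i in range(len(dm))
        )
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=io.StringIO(csv), delimiter=","
        )
        their = pdm.nj_tree()
        their.encode_bipartitions()
        ours_bips = {
            min(b, frozenset(ours.leaf_labels()) - b, key=sorted)
            for b in ours.bipartitions()
            if 2 <= len(b) <= len(dm) - 2
        }
        all_labels = frozenset(dm.labels)
        theirs_bips = set()
        for edge in their.preorder_edge_iter():
            bip = frozenset(
                lf.taxon.label for lf in edge.head_node.leaf_iter()
            )
            if 2 <= len(bip) <= len(dm) - 2:
                theirs_bips.add(min(bip, all_labels - bip, key=sorted))
        assert ours_bips == theirs_bips


class TestNewick:
    def test_round_trip_through_dendropy(self):
        rng = np.random.default_rng(4)
        dm = random_additive_matrix(rng, 7)
        tree = nj(dm)
        newick = to_newick(tree)
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        assert {lf.taxon.label for lf in parsed.leaf_node_iter()} == \
            tree.leaf_labels()
        assert parsed.length() == pytest.approx(tree.total_branch_length())

    def test_serialization_is_deterministic(self):
        dm = random_additive_matrix(np.random.default_rng(11), 6)
        tree = nj(dm)
        assert to_newick(tree) == to_newick(tree)
        assert to_newick(nj(dm)) == to_newick(tree)

    def test_label_with_space_is_quoted(self):
        dm = DistanceMatrix(("tax on", "B"), np.array([[0, 0.2], [0.2, 0]]))
        newick = to_newick(nj(dm))
        assert "'tax on'" in newick
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        assert {lf.taxon.label for lf in parsed.leaf_node_iter()} == {"tax on", "B"}


class TestIsSeparated:
    @staticmethod
    def _cherry_tree():
        values = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], float
        )
        return nj(DistanceMatrix(("A", "B", "C", "D"), values))

    def test_cherry_group_is_separated(self):
        assert is_separated(self._cherry_tree(), {"A", "B"}) is True

    def test_split_group_is_not(self):
        assert is_separated(self._cherry_tree(), {"A", "C"}) is False

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            is_separated(self._cherry_tree(), {"A", "Z"})

    def test_improper_group_rejected(self):
        tree = self._cherry_tree()
        with pytest.raises(ValueError):
            is_separated(tree, set())
        with pytest.raises(ValueError):
            is_separated(tree, {"A", "B", "C", "D"})

    def test_agrees_with_bipartition_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            dm = random_additive_matrix(rng, 8)
            tree = nj(dm)
            leaves = frozenset(tree.leaf_labels())
            bips = set(tree.bipartitions())
            for _ in range(20):
                size = int(rng.integers(1, 8))
                group = frozenset(rng.choice(sorted(leaves), size=size,
                                             replace=False))
                if not group or group == leaves:
                    continue
                oracle = any(b == group or b == leaves - group for b in bips)
                assert is_separated(tree, set(group)) == oracle


class TestAssignSubfamily:
    @staticmethod
    def _references():
        refs = [
            protein("r1", "MKLVNQERTASDFGHKLMNP", description="AOX1a"),
            protein("r2", "MKLVNQERTASDFGHKLMNW", description="AOX1b"),
            protein("r3", "WWLVNQERTASDFGHKAAAA", description="AOX2"),
        ]
        return refs

    def test_identical_full_length_query_gets_member_label(self):
        refs = self._references()
        query = protein("q", refs[2].residues)
        result = assign_subfamily(query, refs, fragment_threshold=10)
        assert result.label == "AOX2" and result.level == "member"
        assert result.distance == 0.0

    def test_fragment_is_truncated_to_subfamily(self):
        refs = self._references()
        query = protein("q", refs[0].residues)  # nearest is AOX1a
        result = assign_subfamily(query, refs, fragment_threshold=len(query.residues))
        assert result.label == "AOX1" and result.level == "subfamily"

    def test_equidistant_subfamilies_unresolved(self):
        refs = [
            protein("r1", "AAAA", description="AOX1a"),
            protein("r2", "CCCC", description="AOX2a"),
        ]
        query = protein("q", "AACC")
        result = assign_subfamily(query, refs, fragment_threshold=1)
        assert result.label == "unresolved" and result.margin == 0.0

    def test_no_references_rejected(self):
        with pytest.raises(ValueError):
            assign_subfamily(protein("q", "MK"), [])

    def test_subfamily_derivation(self):
        assert subfamily_of("AOX1a") == "AOX1"
        assert subfamily_of("aox2b") == "AOX2"
        with pytest.raises(ValueError):
            subfamily_of("PTOX")


def test_phylip_round_trip(tmp_path):
    dm = random_additive_matrix(np.random.default_rng(2), 5)
    path = tmp_path / "dm.phy"
    write_phylip(dm, path)
    back = read_phylip(path)
    assert back.labels == dm.labels
    assert np.allclose(back.values, dm.values, atol=1e-6)
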