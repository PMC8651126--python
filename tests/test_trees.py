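import dendropy
import numpy as np
import pandas as pd
import pytest

from virtax import trees
from virtax.synth import _mutate_protein

from conftest import random_protein


def _additive_four_taxon():
    # distances from ((a:1,b:2):1,(c:3,d:1))
    labels = ["a", "b", "c", "d"]
    mat = [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]]
    return pd.DataFrame(np.array(mat, dtype=float), index=labels, columns=labels)


def _random_additive_tree(rng, n_taxa):
    """Random binary tree with uniform branch lengths; returns
    (newick, leaf distance matrix)."""
    nodes = [(f"t{i}", {f"t{i}": 0.0}) for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (na, da), (nb, db) = nodes[i], nodes[j]
        la, lb = rng.uniform(0.1, 1.0, size=2)
        merged = {leaf: d + la for leaf, d in da.items()}
        merged.update({leaf: d + lb for leaf, d in db.items()})
        newick = f"({na}:{la:.6f},{nb}:{lb:.6f})"
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append((newick, merged))
        # record cross distances lazily below
    return nodes[0][0] + ";"


def _leaf_distances_from_newick(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    n = len(labels)
    mat = np.zeros((n, n))
    taxa = {t.label: t for t in tree.taxon_namespace}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                d = pdm.distance(taxa[a], taxa[b])
                mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


class TestIdentityDistance:
    def test_identical_and_symmetric(self):
        prots = {"a": "MKVLAWQPLE", "b": "MKVLAWQPLE", "c": "MKVLAWQPIE"}
        d = trees.identity_distance_matrix(prots)
        assert d.loc["a", "b"] == 0.0
        assert np.allclose(d.to_numpy(), d.to_numpy().T)
        assert np.allclose(np.diag(d.to_numpy()), 0.0)

    def test_one_mismatch_in_ten(self):
        prots = {"a": "MKVLAWQPLE", "b": "MKVLAWQPIE", "c": "MKVLAWQPLE"}
        d = trees.identity_distance_matrix(prots)
        assert d.loc["a", "b"] == pytest.approx(0.1)

    def test_too_few_sequences(self):
        with pytest.raises(ValueError):
            trees.identity_distance_matrix({"a": "MK", "b": "MK"})

    def test_empty_sequence(self):
        with pytest.raises(ValueError):
            trees.identity_distance_matrix({"a": "MK", "b": "", "c": "MK"})


class TestNeighborJoining:
    def test_additive_four_taxon_recovery(self):
        tree = trees.neighbor_joining(_additive_four_taxon())
        newick = trees.to_newick(tree)
        # exact branch lengths recovered
        got = _leaf_distances_from_newick(newick)
        want = _additive_four_taxon()
        assert np.allclose(got.loc[want.index, want.columns].to_numpy(),
                           want.to_numpy(), atol=1e-9)

    def test_three_taxon_closed_form(self):
        labels = ["a", "b", "c"]
        dist = pd.DataFrame([[0, 3, 4], [3, 0, 5], [4, 5, 0]],
                            index=labels, columns=labels, dtype=float)
        tree = trees.neighbor_joining(dist)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_consistency_on_random_additive_matrices(self, rng):
        for n_taxa in (5, 6, 7, 8):
            newick = _random_additive_tree(rng, n_taxa)
            dist = _leaf_distances_from_newick(newick)
            recovered = trees.neighbor_joining(dist)
            got = _leaf_distances_from_newick(trees.to_newick(recovered))
            assert np.allclose(got.loc[dist.index, dist.columns].to_numpy(),
                               dist.to_numpy(), atol=1e-6)

    def test_asymmetric_rejected(self):
        labels = ["a", "b", "c"]
        dist = pd.DataFrame([[0, 1, 2], [3, 0, 1], [2, 1, 0]],
                            index=labels, columns=labels, dtype=float)
        with pytest.raises(ValueError):
            trees.neighbor_joining(dist)

    def test_equidistant_deterministic(self):
        labels = list("abcd")
        mat = np.full((4, 4), 1.0)
        np.fill_diagonal(mat, 0.0)
        dist = pd.DataFrame(mat, index=labels, columns=labels)
        n1 = trees.to_newick(trees.neighbor_joining(dist))
        n2 = trees.to_newick(trees.neighbor_joining(dist))
        assert n1 == n2

    def test_no_negative_branch_lengths(self, rng):
        for _ in range(10):
            m = rng.random((5, 5))
            mat = (m + m.T) / 2
            np.fill_diagonal(mat, 0)
            labels = list("abcde")
            dist = pd.DataFrame(mat, index=labels, columns=labels)
            tree = trees.neighbor_joining(dist)
            for edge in tree.preorder_edge_iter():
                if edge.length is not None:
                    assert edge.length >= 0


class TestRooting:
    def test_outgroup_rooting(self):
        tree = trees.neighbor_joining(_additive_four_taxon())
        rooted = trees.root_with_outgroup(tree, "d")
        children = rooted.seed_node.child_nodes()
        assert len(children) == 2
        labels = [{lf.taxon.label for lf in c.leaf_iter()} for c in children]
        assert {"d"} in labels
        ingroup = next(s for s in labels if s != {"d"})
        assert ingroup == {"a", "b", "c"}
        # pendant edge split at midpoint
        assert children[0].edge.length == children[1].edge.length

    def test_rooting_idempotent_on_topology(self):
        tree = trees.neighbor_joining(_additive_four_taxon())
        r1 = trees.root_with_outgroup(tree, "d")
        r2 = trees.root_with_outgroup(r1, "d")
        s1 = {frozenset(lf.taxon.label for lf in c.leaf_iter())
              for c in r1.seed_node.child_nodes()}
        s2 = {frozenset(lf.taxon.label for lf in c.leaf_iter())
              for c in r2.seed_node.child_nodes()}
        assert s1 == s2

    def test_three_taxa(self):
        labels = ["a", "b", "c"]
        dist = pd.DataFrame([[0, 3, 4], [3, 0, 5], [4, 5, 0]],
                            index=labels, columns=labels, dtype=float)
        rooted = trees.root_with_outgroup(trees.neighbor_joining(dist), "c")
        groups = [{lf.taxon.label for lf in ch.leaf_iter()}
                  for ch in rooted.seed_node.child_nodes()]
        assert {"c"} in groups and {"a", "b"} in groups

    def test_missing_taxon(self):
        tree = trees.neighbor_joining(_additive_four_taxon())
        with pytest.raises(ValueError):
            trees.root_with_outgroup(tree, "zz")


def test_newick_round_trip_stable():
    tree = trees.neighbor_joining(_additive_four_taxon())
    n1 = trees.to_newick(tree)
    n2 = trees.to_newick(trees.from_newick(n1))
    assert n1 == n2


class TestAdhesinGroups:
    def test_planted_four_groups(self, rng):
        proteins = {}
        labels = {}
        for grp in range(4):
            anc = random_protein(rng, 150)
            for v in range(4):
                name = f"v{grp}{v}"
                proteins[name] = _mutate_protein(anc, 0.93, rng)  # ~86% pairwise
                labels[name] = grp
        groups = trees.adhesin_groups(proteins, linkage_identity=45)
        from sklearn.metrics import adjusted_rand_score

        ids = sorted(proteins)
        assert adjusted_rand_score([labels[i] for i in ids],
                                   [groups[i] for i in ids]) == 1.0

    def test_all_identical_single_group(self):
        proteins = {f"v{i}": "MKVLAWQPLE" for i in range(4)}
        assert set(trees.adhesin_groups(proteins).values()) == {1}

    def test_impossible_threshold_singletons(self):
        proteins = {f"v{i}": "MKVLAWQPLE" for i in range(3)}
        groups = trees.adhesin_groups(proteins, linkage_identity=101)
        assert len(set(groups.values())) == 3

    def test_too_few(self):
        with pytest.raises(ValueError):
            trees.adhesin_groups({"a": "MK"})
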