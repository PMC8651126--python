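import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from virtax import taxonomy
from virtax.gene_sharing import GenomeSignature
from virtax.taxonomy import (
    assign_genera,
    cgj_distance,
    cut_families,
    generalized_jaccard,
    organization_similarity,
    upgma,
)


class TestGeneralizedJaccard:
    def test_identical_nonzero(self):
        assert generalized_jaccard([1, 2, 3], [1, 2, 3]) == 1.0

    def test_hand_example(self):
        assert generalized_jaccard([1, 2, 0], [2, 1, 1]) == pytest.approx(0.4)

    def test_disjoint_supports(self):
        assert generalized_jaccard([1, 0, 2], [0, 3, 0]) == 0.0

    def test_both_zero_warns(self):
        with pytest.warns(UserWarning):
            assert generalized_jaccard([0, 0], [0, 0]) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            generalized_jaccard([-1, 0], [0, 1])

    def test_bounds_property(self, rng):
        for _ in range(50):
            x = rng.random(10)
            y = rng.random(10)
            assert 0 <= generalized_jaccard(x, y) <= 1


def _sig(order, genome_id="g", circular=False, content=None):
    content = content or {pc: 1.0 for pc in order}
    return GenomeSignature(genome_id, content, list(order), circular)


class TestOrganizationSimilarity:
    def test_identical_order(self):
        assert organization_similarity(_sig("abc"), _sig("abc")) == 1.0

    def test_hand_example_two_thirds(self):
        a = _sig(["p1", "p2", "p3"])
        b = _sig(["p1", "p3", "p2"])
        assert organization_similarity(a, b) == pytest.approx(2 / 3)

    def test_reversal_orientation_agnostic(self):
        assert organization_similarity(_sig("abcde"), _sig("edcba")) == 1.0

    def test_circular_rotation(self):
        a = _sig("abcde", circular=True)
        b = _sig("cdeab", circular=True)
        assert organization_similarity(a, b) == 1.0

    def test_no_shared_pcs(self):
        assert organization_similarity(_sig("abc"), _sig("xyz")) == 0.0


class TestCGJDistance:
    def test_identical(self):
        a = _sig("abc", content={"a": 2.0, "b": 3.0, "c": 1.0})
        d, jc, jo = cgj_distance(a, a, ["a", "b", "c"])
        assert d == 0.0 and jc == 1.0 and jo == 1.0

    def test_hand_composition(self):
        # engineered components: J_content = 0.25, J_org = 0.64 -> d = 0.6
        assert 1 - np.sqrt(0.25 * 0.64) == pytest.approx(0.6)
        a = GenomeSignature("a", {"p": 1.0, "q": 1.0}, ["p", "q"])
        b = GenomeSignature("b", {"p": 2.0, "q": 6.0}, ["p", "q"])
        d, jc, jo = cgj_distance(a, b, ["p", "q"])
        assert jc == pytest.approx(2 / 8)
        assert jo == 1.0
        assert d == pytest.approx(1 - np.sqrt(0.25))

    def test_zero_content_forces_distance_one(self):
        a = _sig("ab")
        b = _sig("cd")
        d, jc, jo = cgj_distance(a, b, ["a", "b", "c", "d"])
        assert jc == 0.0 and d == 1.0


class TestUPGMA:
    def test_two_leaves(self):
        dist = pd.DataFrame([[0, 0.6], [0.6, 0]], index=["a", "b"], columns=["a", "b"])
        newick, merges = upgma(dist)
        assert newick == "(a:0.3,b:0.3);"
        assert merges[0].distance == pytest.approx(0.6)

    def test_three_leaf_ultrametric(self):
        labels = ["a", "b", "c"]
        dist = pd.DataFrame([[0, 0.2, 0.8], [0.2, 0, 0.8], [0.8, 0.8, 0]],
                            index=labels, columns=labels)
        newick, merges = upgma(dist)
        assert newick == "((a:0.1,b:0.1):0.3,c:0.4);"
        assert [m.distance for m in merges] == pytest.approx([0.2, 0.8])

    def test_duplicates_merge_at_zero(self):
        labels = ["a", "b", "c"]
        dist = pd.DataFrame([[0, 0, 0.5], [0, 0, 0.5], [0.5, 0.5, 0]],
                            index=labels, columns=labels)
        _, merges = upgma(dist)
        assert merges[0].distance == 0.0

    def test_nan_rejected(self):
        dist = pd.DataFrame([[0, np.nan], [np.nan, 0]], index=["a", "b"],
                            columns=["a", "b"])
        with pytest.raises(ValueError):
            upgma(dist)


class TestCuts:
    def _merges(self, dist_df):
        return upgma(dist_df)

    def test_all_far_apart_singletons(self):
        labels = list("abcd")
        mat = np.full((4, 4), 0.9)
        np.fill_diagonal(mat, 0.0)
        dist = pd.DataFrame(mat, index=labels, columns=labels)
        _, merges = upgma(dist)
        fams = cut_families(merges, labels, h=0.8)
        assert len(set(fams.values())) == 4

    def test_h_zero_all_singletons(self):
        labels = list("abc")
        mat = np.array([[0, 0.1, 0.2], [0.1, 0, 0.2], [0.2, 0.2, 0]])
        dist = pd.DataFrame(mat, index=labels, columns=labels)
        _, merges = upgma(dist)
        assert len(set(cut_families(merges, labels, h=0.0).values())) == 3

    def test_monotone_coarsening(self):
        labels = list("abcde")
        rng = np.random.default_rng(5)
        m = rng.random((5, 5))
        mat = (m + m.T) / 2
        np.fill_diagonal(mat, 0)
        dist = pd.DataFrame(mat, index=labels, columns=labels)
        _, merges = upgma(dist)
        previous = None
        for h in (0.0, 0.2, 0.4, 0.6, 0.8, 1.01):
            part = cut_families(merges, labels, h=h)
            if previous is not None:
                # refinement: same-cluster pairs at smaller h stay together
                for a in labels:
                    for b in labels:
                        if previous[a] == previous[b]:
                            assert part[a] == part[b]
            previous = part


class TestAssignGenera:
    def test_pair_above_threshold(self):
        shared = pd.DataFrame([[100, 70], [70, 100]], index=["a", "b"],
                              columns=["a", "b"], dtype=float)
        genera = assign_genera({"a": 1, "b": 1}, shared, min_shared=60)
        assert genera["a"] == genera["b"]

    def test_single_linkage_chain(self):
        labels = ["A", "B", "C"]
        shared = pd.DataFrame([[100, 65, 20], [65, 100, 65], [20, 65, 100]],
                              index=labels, columns=labels, dtype=float)
        genera = assign_genera({x: 1 for x in labels}, shared, min_shared=60)
        assert len(set(genera.values())) == 1

    def test_families_separate_genera(self):
        labels = ["a", "b"]
        shared = pd.DataFrame([[100, 90], [90, 100]], index=labels,
                              columns=labels, dtype=float)
        genera = assign_genera({"a": 1, "b": 2}, shared, min_shared=60)
        assert genera["a"] != genera["b"]


class TestClassify:
    def test_small_set_exact_recovery(self, small_classification):
        asn, genomes, truth = small_classification
        ids = [g.id for g in genomes]
        ari_f = adjusted_rand_score([truth.families[g] for g in ids],
                                    [asn.families[g] for g in ids])
        ari_g = adjusted_rand_score([truth.genera[g] for g in ids],
                                    [asn.genera[g] for g in ids])
        assert ari_f == 1.0 and ari_g == 1.0

    def test_genus_refines_family(self, small_classification):
        asn, genomes, _ = small_classification
        by_genus: dict[str, set] = {}
        for g, genus in asn.genera.items():
            by_genus.setdefault(genus, set()).add(asn.families[g])
        assert all(len(fams) == 1 for fams in by_genus.values())

    def test_distance_matrix_properties(self, small_classification):
        asn, _, _ = small_classification
        d = asn.distance.to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1).all()

    def test_determinism(self, small_taxonomy_set):
        genomes, _ = small_taxonomy_set
        a1 = taxonomy.classify(genomes)
        a2 = taxonomy.classify(genomes)
        assert a1.newick == a2.newick
        assert a1.families == a2.families
        assert a1.genera == a2.genera
        pd.testing.assert_frame_equal(a1.distance, a2.distance)

    def test_pair_of_unrelated_genomes(self, rng):
        from virtax.synth import gen_taxonomy_set

        genomes, _ = gen_taxonomy_set(n_families=2, genera_per_family=1,
                                      genomes_per_genus=1, family_core=5,
                                      genus_core=5, private_genes=2, seed=9)
        asn = taxonomy.classify(genomes)
        assert len(set(asn.families.values())) == 2
        assert len(set(asn.genera.values())) == 2

    def test_single_genome_error(self, small_taxonomy_set):
        genomes, _ = small_taxonomy_set
        with pytest.raises(ValueError):
            taxonomy.classify(genomes[:1])

    def test_raising_family_cut_coarsens(self, small_classification):
        asn, genomes, _ = small_classification
        _, merges = upgma(asn.distance)
        labels = list(asn.distance.index)
        sizes = [len(set(cut_families(merges, labels, h).values()))
                 for h in (0.2, 0.5, 0.8, 1.01)]
        assert sizes == sorted(sizes, reverse=True)
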