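import numpy as np
import pandas as pd
import pytest

from virtax import host_range as hr
from virtax.host_range import EOPMatrix


def _matrix(values, viruses, hosts, isolation, **kw):
    frame = pd.DataFrame(values, index=viruses, columns=hosts, dtype=float)
    return EOPMatrix(frame, isolation, **kw)


class TestNormalize:
    def test_isolation_host_becomes_one(self):
        m = _matrix([[2e8, 2e5]], ["v"], ["h1", "h2"], {"v": "h1"})
        norm = hr.normalize_eop(m)
        assert norm.loc["v", "h1"] == 1.0
        assert norm.loc["v", "h2"] == pytest.approx(1e-3)

    def test_all_equal_row(self):
        m = _matrix([[5.0, 5.0, 5.0]], ["v"], list("abc"), {"v": "a"})
        assert (hr.normalize_eop(m).loc["v"] == 1.0).all()

    def test_scale_invariance(self):
        m1 = _matrix([[1e8, 1e5, 0]], ["v"], list("abc"), {"v": "a"})
        m2 = _matrix([[1e9, 1e6, 0]], ["v"], list("abc"), {"v": "a"})
        pd.testing.assert_frame_equal(hr.normalize_eop(m1), hr.normalize_eop(m2))

    def test_idempotent(self):
        m = _matrix([[2e8, 4e4, 0]], ["v"], list("abc"), {"v": "a"})
        n1 = hr.normalize_eop(m)
        n2 = hr.normalize_eop(EOPMatrix(n1, {"v": "a"}))
        pd.testing.assert_frame_equal(n1, n2)

    def test_substitute_reference_titer(self):
        # isolation host absent from the panel; external titer stands in
        m = _matrix([[2e8, 2e5]], ["v"], ["h1", "h2"], {"v": "offpanel"},
                    substitute_titer={"v": 2e8})
        norm = hr.normalize_eop(m)
        assert norm.loc["v", "h1"] == 1.0

    def test_zero_isolation_titer_error(self):
        m = _matrix([[0.0, 1.0]], ["v"], ["h1", "h2"], {"v": "h1"})
        with pytest.raises(ValueError, match="substitute"):
            hr.normalize_eop(m)

    def test_detection_floor(self):
        m = _matrix([[2e8, 500.0]], ["v"], ["h1", "h2"], {"v": "h1"},
                    detection_floor=1e3)
        norm = hr.normalize_eop(m)
        assert norm.loc["v", "h2"] == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            _matrix([[-1.0, 1.0]], ["v"], ["h1", "h2"], {"v": "h1"})


class TestBinLog10:
    def test_one_maps_to_zero(self):
        cats = hr.bin_log10(pd.DataFrame([[1.0]]))
        assert cats.iloc[0, 0] == 0

    def test_ten_maps_to_plus_one(self):
        cats = hr.bin_log10(pd.DataFrame([[10.0]]))
        assert cats.iloc[0, 0] == 1
        assert hr.format_category(1) == "+1"

    def test_round_half_away_from_zero(self):
        cats = hr.bin_log10(pd.DataFrame([[3.2e-3, 3.2e-4]]))
        assert cats.iloc[0, 0] == -2
        assert cats.iloc[0, 1] == -3

    def test_zero_is_not_infected(self):
        cats = hr.bin_log10(pd.DataFrame([[0.0]]))
        assert np.isnan(cats.iloc[0, 0])
        assert hr.format_category(cats.iloc[0, 0]) == "-"

    def test_negative_error(self):
        with pytest.raises(ValueError):
            hr.bin_log10(pd.DataFrame([[-0.1]]))

    def test_display_of_zero_category(self):
        assert hr.format_category(0) == "1"
        assert hr.format_category(-2) == "-2"


class TestHs:
    def test_identical(self):
        p = frozenset("abc")
        assert hr.hs(p, p) == 1.0

    def test_hand_example(self):
        assert hr.hs(frozenset("abc"), frozenset("bcd")) == 0.5

    def test_disjoint(self):
        assert hr.hs(frozenset("ab"), frozenset("cd")) == 0.0

    def test_both_empty_warns(self):
        with pytest.warns(UserWarning):
            assert hr.hs(frozenset(), frozenset()) == 0.0

    def test_sum_denominator_variant(self):
        assert hr.hs(frozenset("abc"), frozenset("bcd"), denominator="sum") == pytest.approx(2 / 6)

    def test_symmetry_and_identity_property(self, rng):
        hosts = list("abcdefgh")
        for _ in range(30):
            pa = frozenset(h for h in hosts if rng.random() < 0.5)
            pb = frozenset(h for h in hosts if rng.random() < 0.5)
            if not pa and not pb:
                continue
            assert hr.hs(pa, pb) == hr.hs(pb, pa)
            assert (hr.hs(pa, pb) == 1.0) == (pa == pb)


class TestClusterHosts:
    def test_identical_columns_merge_at_zero(self):
        cats = pd.DataFrame([[0, 0, -3], [-1, -1, 0]], columns=["h1", "h2", "h3"],
                            dtype=float)
        newick = hr.cluster_hosts(cats)
        assert "(h1:0,h2:0)" in newick or "(h2:0,h1:0)" in newick

    def test_two_close_one_far(self):
        cats = pd.DataFrame([[0, 0, -5], [0, -1, -6]], columns=["h1", "h2", "h3"],
                            dtype=float)
        newick = hr.cluster_hosts(cats)
        # h1 and h2 form the inner cluster; h3 joins last at the top level
        assert newick.count("(") == 2
        inner = newick[newick.rindex("(") + 1:]
        inner = inner[: inner.index(")")]
        assert {x.split(":")[0] for x in inner.split(",")} == {"h1", "h2"}

    def test_virus_row_permutation_invariance(self):
        cats = pd.DataFrame([[0, -1, -5], [-2, 0, -4], [0, 0, -6]],
                            columns=["h1", "h2", "h3"], dtype=float)
        n1 = hr.cluster_hosts(cats)
        n2 = hr.cluster_hosts(cats.iloc[[2, 0, 1]])
        assert n1 == n2

    def test_single_host_error(self):
        with pytest.raises(ValueError):
            hr.cluster_hosts(pd.DataFrame([[0]], columns=["h1"], dtype=float))


class TestAssociateAdhesin:
    def _matrices(self, rng, n=8):
        ids = [f"v{i}" for i in range(n)]
        m = rng.random((n, n)) * 100
        ident = (m + m.T) / 2
        np.fill_diagonal(ident, 100)
        identity = pd.DataFrame(ident, index=ids, columns=ids)
        return ids, identity

    def test_perfect_monotone(self, rng):
        ids, identity = self._matrices(rng)
        hs_mat = identity / 100.0  # strictly monotone transform
        res = hr.associate_adhesin(hs_mat, identity, n_perm=199, seed=1)
        assert res.rho_overall == pytest.approx(1.0)
        assert res.p_overall <= 1 / 200 + 1e-12

    def test_duplicated_virus_rows_same_rho(self, rng):
        ids, identity = self._matrices(rng, n=6)
        hs_mat = (identity / 100.0) ** 2
        r1 = hr.associate_adhesin(hs_mat, identity, n_perm=99, seed=3)
        # relabelling viruses leaves rho unchanged
        ren = {v: f"w{v}" for v in ids}
        r2 = hr.associate_adhesin(hs_mat.rename(index=ren, columns=ren),
                                  identity.rename(index=ren, columns=ren),
                                  n_perm=99, seed=3)
        assert r1.rho_overall == pytest.approx(r2.rho_overall)

    def test_too_few_viruses(self, rng):
        ids = ["a", "b", "c"]
        m = pd.DataFrame(np.eye(3), index=ids, columns=ids)
        with pytest.raises(ValueError):
            hr.associate_adhesin(m, m, n_perm=99)

    def test_nperm_floor(self, rng):
        ids, identity = self._matrices(rng)
        with pytest.raises(ValueError):
            hr.associate_adhesin(identity / 100, identity, n_perm=10)

    def test_per_group_summary(self, rng):
        ids, identity = self._matrices(rng)
        hs_mat = identity / 100.0
        groups = {v: 1 if i < 4 else 2 for i, v in enumerate(ids)}
        res = hr.associate_adhesin(hs_mat, identity, groups=groups, n_perm=99, seed=5)
        assert list(res.per_group["group"]) == [1, 2]
        assert (res.per_group["n_viruses"] == 4).all()


def test_read_eop_table(tmp_path):
    (tmp_path / "eop.tsv").write_text("virus\th1\th2\nv1\t2e8\t100\nv2\t0\t5e7\n")
    (tmp_path / "iso.tsv").write_text("v1\th1\nv2\th2\n")
    m = hr.read_eop_table(tmp_path / "eop.tsv", tmp_path / "iso.tsv",
                          detection_floor=1e3)
    norm = hr.normalize_eop(m)
    assert norm.loc["v1", "h1"] == 1.0
    assert norm.loc["v1", "h2"] == 0.0  # floored
    assert norm.loc["v2", "h2"] == 1.0
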