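"""Distance-based phylogenetics: identity distances, neighbor joining,
outgroup rooting and single-linkage sequence grouping.

Trees are dendropy objects; Newick strings are the interchange format.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import dendropy

from .align import global_identity
from .gene_sharing import _UnionFind


def identity_distance_matrix(proteins: dict[str, str]) -> pd.DataFrame:
    """d_ij = 1 - global alignment identity / 100, symmetric, zero diagonal."""
    if len(proteins) < 3:
        raise ValueError("need at least 3 sequences")
    for name, seq in proteins.items():
        if not seq:
            raise ValueError(f"empty sequence for {name}")
    ids = sorted(proteins)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pid = global_identity(proteins[ids[i]], proteins[ids[j]])
            d[i, j] = d[j, i] = 1.0 - pid / 100.0
    return pd.DataFrame(d, index=ids, columns=ids)


def neighbor_joining(dist: pd.DataFrame) -> dendropy.Tree:
    """Standard neighbor joining with deterministic tie-breaking.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch (which is itself clamped if it goes negative).
    The returned tree is unrooted (trifurcating seed node) for >3 taxa.
    """
    mat = dist.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be symmetric")
    labels = list(dist.index)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    taxa = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(node)
    active = list(range(n))
    D = mat.copy()

    def clamp(la: float, lb: float) -> tuple[float, float]:
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            la = max(la, 0.0)
            lb = 0.0
        return la, lb

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic tie-break: smallest Q, then smallest (i, j)
        best = np.unravel_index(np.argmin(q), q.shape)
        i, j = sorted((best[0], best[1]))
        di = 0.5 * sub[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        dj = sub[i, j] - di
        di, dj = clamp(di, dj)
        new_node = dendropy.Node()
        ni, nj = nodes[active[i]], nodes[active[j]]
        new_node.add_child(ni)
        new_node.add_child(nj)
        ni.edge.length = di
        nj.edge.length = dj
        new_dists = 0.5 * (sub[i, :] + sub[j, :] - sub[i, j])
        gi, gj = active[i], active[j]
        D = np.pad(D, ((0, 1), (0, 1)))
        for k_local, g in enumerate(active):
            D[-1, g] = D[g, -1] = new_dists[k_local]
        D[-1, -1] = 0.0
        nodes.append(new_node)
        active = [g for g in active if g not in (gi, gj)] + [len(nodes) - 1]

    # join the last three nodes on a common (unrooted) internal node
    root = dendropy.Node()
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def root_with_outgroup(tree: dendropy.Tree, taxon: str) -> dendropy.Tree:
    """Root on the midpoint of the outgroup leaf's pendant edge."""
    tree = tree.clone(depth=1)
    leaf = None
    for lf in tree.leaf_node_iter():
        if lf.taxon is not None and lf.taxon.label == taxon:
            leaf = lf
            break
    if leaf is None:
        raise ValueError(f"outgroup taxon {taxon!r} not found in tree")
    bl = leaf.edge.length if leaf.edge.length is not None else 0.0
    tree.reroot_at_edge(leaf.edge, update_bipartitions=False)
    # reroot_at_edge places the new root on the edge; set both halves
    for child in tree.seed_node.child_nodes():
        child.edge.length = bl / 2.0
    tree.is_rooted = True
    return tree


def adhesin_groups(proteins: dict[str, str], linkage_identity: float = 45.0) -> dict[str, int]:
    """Single-linkage clusters at global identity >= linkage_identity
    percent; group numbers ordered by decreasing size then smallest member."""
    if len(proteins) < 2:
        raise ValueError("need at least 2 sequences")
    ids = sorted(proteins)
    uf = _UnionFind(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if global_identity(proteins[a], proteins[b]) >= linkage_identity:
                uf.union(a, b)
    groups: dict[str, list[str]] = {}
    for x in ids:
        groups.setdefault(uf.find(x), []).append(x)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    return {x: i + 1 for i, grp in enumerate(ordered) for x in grp}
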