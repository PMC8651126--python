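"""Composite generalized Jaccard distances and two-rank demarcation.

Genome distance combines gene-content similarity (generalized Jaccard over
PC bitscore vectors) with gene-order similarity (normalized longest common
subsequence of shared-PC order) as d = 1 - sqrt(J_content * J_org).
Families are cut from a UPGMA dendrogram at distance 0.8; genera are
single-linkage components over symmetric shared-gene fractions above 60%.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gene_sharing
from .align import KarlinAltschulParams
from .gene_sharing import (
    GenomeSignature,
    HomologyGraph,
    ProteinCluster,
    Thresholds,
    _UnionFind,
)
from .genome_io import Genome, extract_proteome

logger = logging.getLogger(__name__)

DEFAULT_FAMILY_CUT = 0.8
DEFAULT_GENUS_MIN_SHARED = 60.0


def generalized_jaccard(x, y) -> float:
    """Sum of elementwise minima over sum of elementwise maxima, in [0,1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("vectors must be non-negative")
    denom = np.maximum(x, y).sum()
    if denom == 0:
        warnings.warn("generalized Jaccard of two zero vectors; defined as 0")
        return 0.0
    return float(np.minimum(x, y).sum() / denom)


def _lcs_length(a: list, b: list) -> int:
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0] * (len(b) + 1)
        for j, y in enumerate(b, start=1):
            if x == y:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev = cur
    return prev[-1]


def organization_similarity(sig_a: GenomeSignature, sig_b: GenomeSignature) -> float:
    """Gene-order similarity: best LCS of the shared-PC order over both
    orientations (and all rotations of circular genomes), normalized by
    the number of shared PCs."""
    shared = set(sig_a.order) & set(sig_b.order)
    if not shared:
        return 0.0
    # keep first occurrence of each shared PC, preserving order
    def reduce(order):
        seen = set()
        out = []
        for pc in order:
            if pc in shared and pc not in seen:
                seen.add(pc)
                out.append(pc)
        return out

    a = reduce(sig_a.order)
    b = reduce(sig_b.order)
    rotations = [b]
    if sig_b.circular and len(b) > 1:
        rotations = [b[i:] + b[:i] for i in range(len(b))]
    a_variants = [a]
    if sig_a.circular and len(a) > 1:
        a_variants = [a[i:] + a[:i] for i in range(len(a))]
    best = 0
    for av in a_variants:
        for rot in rotations:
            best = max(best, _lcs_length(av, rot), _lcs_length(av, rot[::-1]))
            if best == len(shared):
                return 1.0
    return best / len(shared)


def cgj_distance(sig_a: GenomeSignature, sig_b: GenomeSignature,
                 pc_ids: list[str]) -> tuple[float, float, float]:
    """(distance, J_content, J_org); d = 1 - sqrt(J_content * J_org)."""
    x = np.array([sig_a.content.get(pc, 0.0) for pc in pc_ids])
    y = np.array([sig_b.content.get(pc, 0.0) for pc in pc_ids])
    j_content = generalized_jaccard(x, y)
    j_org = organization_similarity(sig_a, sig_b)
    return 1.0 - float(np.sqrt(j_content * j_org)), j_content, j_org


def cgj_distance_matrix(sigs: list[GenomeSignature],
                        pc_ids: list[str]) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Symmetric CGJ distance matrix plus the two component matrices."""
    ids = [s.genome_id for s in sigs]
    n = len(ids)
    d = np.zeros((n, n))
    jc = np.ones((n, n))
    jo = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist, c, o = cgj_distance(sigs[i], sigs[j], pc_ids)
            d[i, j] = d[j, i] = dist
            jc[i, j] = jc[j, i] = c
            jo[i, j] = jo[j, i] = o
    return (pd.DataFrame(d, index=ids, columns=ids),
            pd.DataFrame(jc, index=ids, columns=ids),
            pd.DataFrame(jo, index=ids, columns=ids))


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class Merge:
    members_a: tuple
    members_b: tuple
    distance: float  # cophenetic distance at which the clusters merged


def upgma(dist: pd.DataFrame) -> tuple[str, list[Merge]]:
    """Average-linkage agglomeration; returns (newick, merge list).

    Branch heights equal half the merge distance (ultrametric tree).  Ties
    are broken toward the pair whose sorted member lists are smallest.
    """
    if dist.isna().any().any():
        raise ValueError("distance matrix contains NaN")
    labels = list(dist.index)
    if len(labels) == 1:
        return f"{labels[0]}:0.0;", []
    clusters: dict[tuple, dict] = {
        (lab,): {"newick": lab, "height": 0.0, "size": 1} for lab in labels
    }
    d = {frozenset((a,)) | frozenset((b,)): float(dist.loc[a, b])
         for i, a in enumerate(labels) for b in labels[i + 1:]}
    dget = {(ka, kb): float(dist.loc[ka, kb]) for ka in labels for kb in labels}
    # pairwise average distances between current clusters
    def cdist(ca: tuple, cb: tuple) -> float:
        return sum(dget[(x, y)] for x in ca for y in cb) / (len(ca) * len(cb))

    merges: list[Merge] = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i, ka in enumerate(keys):
            for kb in keys[i + 1:]:
                dd = cdist(ka, kb)
                cand = (dd, ka, kb)
                if best is None or cand < best:
                    best = cand
        dd, ka, kb = best
        merges.append(Merge(ka, kb, dd))
        height = dd / 2.0
        na, nb = clusters.pop(ka), clusters.pop(kb)
        newick = (f"({na['newick']}:{height - na['height']:.6g},"
                  f"{nb['newick']}:{height - nb['height']:.6g})")
        clusters[tuple(sorted(ka + kb))] = {"newick": newick, "height": height,
                                            "size": na["size"] + nb["size"]}
    final = next(iter(clusters.values()))
    return final["newick"] + ";", merges


def cut_tree(merges: list[Merge], labels: list[str], h: float) -> dict[str, int]:
    """Flat clusters from UPGMA merges: clusters joined while the merge
    distance is strictly below ``h``.  Returns label -> cluster index
    (indices ordered by decreasing size then smallest member)."""
    uf = _UnionFind(labels)
    for m in merges:
        if m.distance < h:
            uf.union(m.members_a[0], m.members_b[0])
    groups: dict[str, list[str]] = {}
    for lab in labels:
        groups.setdefault(uf.find(lab), []).append(lab)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    return {lab: i + 1 for i, grp in enumerate(ordered) for lab in grp}


def cut_families(merges: list[Merge], labels: list[str],
                 h: float = DEFAULT_FAMILY_CUT) -> dict[str, int]:
    return cut_tree(merges, labels, h)


def assign_genera(family_members: dict[str, int], shared_sym: pd.DataFrame,
                  min_shared: float = DEFAULT_GENUS_MIN_SHARED) -> dict[str, int]:
    """Single-linkage genera within each family over symmetric shared-gene
    fractions strictly above ``min_shared`` percent."""
    labels = sorted(family_members)
    uf = _UnionFind(labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if family_members[a] != family_members[b]:
                continue
            if float(shared_sym.loc[a, b]) > min_shared:
                uf.union(a, b)
    groups: dict[str, list[str]] = {}
    for lab in labels:
        groups.setdefault(uf.find(lab), []).append(lab)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    return {lab: i + 1 for i, grp in enumerate(ordered) for lab in grp}


# ---------------------------------------------------------------------------
# End-to-end classification


@dataclass
class TaxonomyAssignment:
    families: dict[str, str]  # genome id -> family label (F1, F2, ...)
    genera: dict[str, str]  # genome id -> genus label (G1, G2, ...)
    parameters: dict
    distance: pd.DataFrame
    j_content: pd.DataFrame
    j_org: pd.DataFrame
    shared_directed: pd.DataFrame
    shared_symmetric: pd.DataFrame
    newick: str
    clusters: list[ProteinCluster] = field(default_factory=list, repr=False)
    graph: HomologyGraph | None = field(default=None, repr=False)

    def table(self) -> pd.DataFrame:
        ids = sorted(self.families)
        return pd.DataFrame(
            {"genome_id": ids,
             "family": [self.families[g] for g in ids],
             "genus": [self.genera[g] for g in ids]}
        ).set_index("genome_id")


def classify(genomes: list[Genome],
             thresholds: Thresholds | None = None,
             family_cut: float = DEFAULT_FAMILY_CUT,
             genus_min_shared: float = DEFAULT_GENUS_MIN_SHARED,
             params: KarlinAltschulParams | None = None,
             prefilter: bool = True) -> TaxonomyAssignment:
    """Full demarcation pipeline: homology graph -> PCs -> signatures ->
    CGJ distances -> UPGMA families -> shared-fraction genera."""
    if len(genomes) < 2:
        raise ValueError("classification requires at least 2 genomes")
    thresholds = thresholds or Thresholds()
    try:
        proteomes = {g.id: extract_proteome(g) for g in genomes}
        for gid, prots in proteomes.items():
            if not prots:
                raise ValueError(f"genome {gid} has no annotated proteins")
        graph = gene_sharing.all_vs_all(proteomes, thresholds, params, prefilter=prefilter)
    except ValueError as exc:
        raise ValueError(f"[all_vs_all] {exc}") from exc
    clusters = gene_sharing.protein_clusters(graph)
    sigs = gene_sharing.signatures(genomes, clusters, graph)
    pc_ids = [pc.pc_id for pc in clusters]
    dist, jc, jo = cgj_distance_matrix(sigs, pc_ids)
    newick, merges = upgma(dist)
    labels = list(dist.index)
    fam_idx = cut_families(merges, labels, family_cut)
    ids = [g.id for g in genomes]
    shared_dir = gene_sharing.shared_fraction_matrix(ids, graph, symmetric=False)
    shared_sym = (shared_dir + shared_dir.T) / 2.0
    genus_idx = assign_genera(fam_idx, shared_sym, genus_min_shared)

    families = {g: f"F{idx}" for g, idx in fam_idx.items()}
    genera = {g: f"G{idx}" for g, idx in genus_idx.items()}
    return TaxonomyAssignment(
        families=families,
        genera=genera,
        parameters={
            "min_identity_pct": thresholds.min_identity_pct,
            "max_evalue": thresholds.max_evalue,
            "family_cut": family_cut,
            "genus_min_shared": genus_min_shared,
            "linkage": "UPGMA",
            "cgj_composition": "1 - sqrt(J_content * J_org)",
        },
        distance=dist,
        j_content=jc,
        j_org=jo,
        shared_directed=shared_dir,
        shared_symmetric=shared_sym,
        newick=newick,
        clusters=clusters,
        graph=graph,
    )
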