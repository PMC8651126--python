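"""Thresholded protein homology graph, protein clusters and genome signatures.

Two proteins are connected when their best local alignment clears the
identity and E-value thresholds (defaults: >30% identity, E < 1e-25).
Protein clusters (PCs) are the connected components of that graph;
per-genome signatures hold the PC content (best bitscore against the PC
representative) and the PC order along the genome.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .align import (
    KarlinAltschulParams,
    alignment_score,
    bitscore,
    local_align,
    min_score_for_evalue,
)
from .genome_io import Genome, extract_proteome

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 30.0
DEFAULT_MAX_EVALUE = 1e-25

_PREFILTER_K = 4
_PREFILTER_MIN_SHARED = 3


@dataclass(frozen=True)
class Thresholds:
    min_identity_pct: float = DEFAULT_MIN_IDENTITY
    max_evalue: float = DEFAULT_MAX_EVALUE


@dataclass
class HomologyGraph:
    """Undirected protein homology graph over one or more proteomes."""

    proteins: dict[str, str]  # protein id -> sequence
    genome_of: dict[str, str]  # protein id -> genome id
    edges: dict[frozenset, tuple[float, float, float]]  # pair -> (bitscore, identity, evalue)
    thresholds: Thresholds
    adjacency: dict[str, set] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.adjacency:
            adj: dict[str, set] = {p: set() for p in self.proteins}
            for pair in self.edges:
                p1, p2 = tuple(pair)
                adj[p1].add(p2)
                adj[p2].add(p1)
            self.adjacency = adj

    def genome_proteins(self, genome_id: str) -> list[str]:
        if not hasattr(self, "_by_genome"):
            by_genome: dict[str, list[str]] = {}
            for p, g in self.genome_of.items():
                by_genome.setdefault(g, []).append(p)
            self._by_genome = by_genome
        return self._by_genome.get(genome_id, [])


@dataclass
class ProteinCluster:
    pc_id: str
    members: frozenset
    representative: str  # longest member (ties by id)


def _kmer_candidates(ids: list[str], seqs: list[str],
                     min_shared: int = _PREFILTER_MIN_SHARED) -> set[tuple[int, int]]:
    """Pairs of protein indices sharing >= min_shared distinct k-mers."""
    index: dict[str, list[int]] = defaultdict(list)
    for i, seq in enumerate(seqs):
        for kmer in {seq[j : j + _PREFILTER_K] for j in range(len(seq) - _PREFILTER_K + 1)}:
            index[kmer].append(i)
    counts: Counter = Counter()
    for bucket in index.values():
        if len(bucket) < 2:
            continue
        for a, b in itertools.combinations(bucket, 2):
            counts[(a, b)] += 1
    return {pair for pair, c in counts.items() if c >= min_shared}


def all_vs_all(proteomes: dict[str, list[tuple[str, str]]],
               thresholds: Thresholds | None = None,
               params: KarlinAltschulParams | None = None,
               prefilter: bool = True) -> HomologyGraph:
    """Build the homology graph over every protein of every proteome.

    Each unordered pair is aligned once (symmetric scoring scheme).  With
    ``prefilter`` enabled, pairs sharing fewer than two 4-mers are skipped;
    this is a sensitivity heuristic that is safe far above the default
    thresholds but can be disabled for exhaustive comparison.

    E-values use the database search-space policy: m times the summed
    length of all proteins.
    """
    if not proteomes:
        raise ValueError("at least one proteome required")
    thresholds = thresholds or Thresholds()
    params = params or KarlinAltschulParams(search_space_policy="database_mN")
    proteins: dict[str, str] = {}
    genome_of: dict[str, str] = {}
    for gid, prots in proteomes.items():
        for pid, seq in prots:
            if pid in proteins:
                raise ValueError(f"duplicate protein id {pid!r}")
            proteins[pid] = seq
            genome_of[pid] = gid
    ids = sorted(proteins)
    seqs = [proteins[p] for p in ids]
    total_residues = sum(len(s) for s in seqs)

    if prefilter:
        pairs = sorted(_kmer_candidates(ids, seqs))
    else:
        pairs = list(itertools.combinations(range(len(ids)), 2))

    edges: dict[frozenset, tuple[float, float, float]] = {}
    for i, j in pairs:
        q, s = seqs[i], seqs[j]
        score = alignment_score(q, s, mode="local")
        n_space = total_residues
        if score < min_score_for_evalue(thresholds.max_evalue, len(q), n_space, params):
            continue
        res = local_align(q, s, ids[i], ids[j], params=params,
                         search_space=(len(q), n_space), precomputed_score=score)
        if res.identity_pct > thresholds.min_identity_pct and res.evalue < thresholds.max_evalue:
            edges[frozenset((ids[i], ids[j]))] = (res.bitscore, res.identity_pct, res.evalue)
    return HomologyGraph(proteins, genome_of, edges, thresholds)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def protein_clusters(graph: HomologyGraph) -> list[ProteinCluster]:
    """Single-linkage PCs: connected components of the homology graph.

    Deterministic ids: components ordered by their lexicographically
    smallest member.  Singletons are clusters too.
    """
    uf = _UnionFind(graph.proteins)
    for pair in graph.edges:
        p1, p2 = tuple(pair)
        uf.union(p1, p2)
    comps: dict[str, set] = defaultdict(set)
    for p in graph.proteins:
        comps[uf.find(p)].add(p)
    ordered = sorted(comps.values(), key=lambda c: min(c))
    clusters = []
    width = max(4, len(str(len(ordered))))
    for i, members in enumerate(ordered, start=1):
        rep = max(members, key=lambda p: (len(graph.proteins[p]), p))
        clusters.append(ProteinCluster(f"PC{i:0{width}d}", frozenset(members), rep))
    return clusters


def shared_fraction(genome_a: str, genome_b: str, graph: HomologyGraph) -> float:
    """Directed shared-gene percentage: fraction of A's proteins with at
    least one homolog in B (a protein counts once however many hits)."""
    if genome_a == genome_b:
        return 100.0
    prots_a = graph.genome_proteins(genome_a)
    prots_b = set(graph.genome_proteins(genome_b))
    if not prots_a or not prots_b:
        raise ValueError("shared_fraction requires non-empty proteomes")
    hit = sum(1 for p in prots_a if graph.adjacency[p] & prots_b)
    return 100.0 * hit / len(prots_a)


def symmetric_shared_fraction(genome_a: str, genome_b: str, graph: HomologyGraph) -> float:
    return 0.5 * (shared_fraction(genome_a, genome_b, graph)
                  + shared_fraction(genome_b, genome_a, graph))


def shared_fraction_matrix(genome_ids: list[str], graph: HomologyGraph,
                           symmetric: bool = False) -> "pandas.DataFrame":
    import pandas as pd

    n = len(genome_ids)
    mat = np.full((n, n), 100.0)
    for i, a in enumerate(genome_ids):
        for j, b in enumerate(genome_ids):
            if i < j:
                if symmetric:
                    mat[i, j] = mat[j, i] = symmetric_shared_fraction(a, b, graph)
                else:
                    mat[i, j] = shared_fraction(a, b, graph)
                    mat[j, i] = shared_fraction(b, a, graph)
    return pd.DataFrame(mat, index=genome_ids, columns=genome_ids)


@dataclass
class GenomeSignature:
    """PC content (bitscore vs representative) and PC order of a genome."""

    genome_id: str
    content: dict[str, float]  # pc_id -> best bitscore to PC representative
    order: list[str]  # pc ids in genome coordinate order
    circular: bool = False


def signatures(genomes: list[Genome], clusters: list[ProteinCluster],
               graph: HomologyGraph,
               params: KarlinAltschulParams | None = None) -> list[GenomeSignature]:
    """Per-genome PC signatures.

    Content scores are the bitscore of the protein's alignment against its
    PC representative (self-score for the representative itself); a PC
    absent from the genome contributes 0.
    """
    params = params or KarlinAltschulParams()
    pc_of: dict[str, str] = {}
    rep_of: dict[str, str] = {}
    for pc in clusters:
        for m in pc.members:
            pc_of[m] = pc.pc_id
        rep_of[pc.pc_id] = pc.representative
    sigs = []
    for genome in genomes:
        content: dict[str, float] = {}
        order: list[str] = []
        for pid, seq in extract_proteome(genome):
            pc_id = pc_of.get(pid)
            if pc_id is None:
                continue
            rep = graph.proteins[rep_of[pc_id]]
            score = alignment_score(seq, rep, mode="local")
            bs = bitscore(max(score, 0.0), params)
            if bs > content.get(pc_id, 0.0):
                content[pc_id] = bs
            order.append(pc_id)
        sigs.append(GenomeSignature(genome.id, content, order,
                                    circular=genome.topology == "circular"))
    return sigs


def write_pc_table(clusters: list[ProteinCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("pc_id\tsize\trepresentative\tmembers\n")
        for pc in clusters:
            fh.write(f"{pc.pc_id}\t{len(pc.members)}\t{pc.representative}\t"
                     + ",".join(sorted(pc.members)) + "\n")
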