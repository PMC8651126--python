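"""Integrated provirus detection in host replicons.

Host ORFs are aligned against reference virus proteomes (protein-protein
local alignment after naive ORF calling); significant hits are chained
along the contig into candidate provirus regions, which are then searched
for flanking attachment-site direct repeats and assigned to a reference
family by shared-gene fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from . import gene_sharing
from .align import KarlinAltschulParams, alignment_score, local_align, min_score_for_evalue
from .gene_sharing import Thresholds
from .genome_io import Genome, GeneRecord, call_orfs, extract_proteome

logger = logging.getLogger(__name__)

DEFAULT_HIT_EVALUE = 1e-5
DEFAULT_MIN_HITS = 10
DEFAULT_MAX_GAP = 15_000
DEFAULT_ATT_MIN_LEN = 12
DEFAULT_ATT_MAX_MISMATCH = 1
DEFAULT_ATT_WINDOW = 2_000
DEFAULT_MIN_REGION = 5_000


@dataclass
class AttSite:
    sequence: str  # sequence of the left copy
    left_start: int
    right_start: int
    length: int
    mismatches: int


@dataclass
class ProvirusCall:
    host_contig_id: str
    start: int
    end: int
    n_virus_hits: int
    reference_virus: str
    att: AttSite | None = None
    family_assignment: str = "unassigned"
    integration_target: str = "unknown"


@dataclass
class _Hit:
    orf: GeneRecord
    reference_virus: str
    evalue: float


def _orf_hits(host: Genome, virus_proteomes: dict[str, list[tuple[str, str]]],
              max_evalue: float, min_orf_aa: int,
              params: KarlinAltschulParams) -> list[_Hit]:
    orfs = call_orfs(host.sequence, min_aa=min_orf_aa, genome_id=host.id)
    db_len = sum(len(s) for prots in virus_proteomes.values() for _, s in prots)
    # reuse the homology-graph k-mer prefilter for speed
    ref_ids, ref_seqs, ref_virus = [], [], []
    for vid, prots in sorted(virus_proteomes.items()):
        for pid, seq in prots:
            ref_ids.append(pid)
            ref_seqs.append(seq)
            ref_virus.append(vid)
    hits: list[_Hit] = []
    all_ids = [f"orf:{i}" for i in range(len(orfs))] + ref_ids
    all_seqs = [o.protein for o in orfs] + ref_seqs
    candidates = gene_sharing._kmer_candidates(all_ids, all_seqs)
    n_orfs = len(orfs)
    by_orf: dict[int, list[int]] = {}
    for a, b in candidates:
        if a < n_orfs <= b:
            by_orf.setdefault(a, []).append(b - n_orfs)
    for oi, refs in by_orf.items():
        orf = orfs[oi]
        best_e, best_v = None, None
        cutoff = min_score_for_evalue(max_evalue, len(orf.protein), db_len, params)
        for ri in refs:
            score = alignment_score(orf.protein, ref_seqs[ri], mode="local")
            if score < cutoff:
                continue
            res = local_align(orf.protein, ref_seqs[ri], params=params,
                             search_space=(len(orf.protein), db_len))
            if res.evalue < max_evalue and (best_e is None or res.evalue < best_e):
                best_e, best_v = res.evalue, ref_virus[ri]
        if best_v is not None:
            hits.append(_Hit(orf, best_v, best_e))
    hits.sort(key=lambda h: (h.orf.start, h.orf.end))
    return hits


def find_provirus_regions(host: Genome,
                          virus_proteomes: dict[str, list[tuple[str, str]]],
                          min_hits: int = DEFAULT_MIN_HITS,
                          max_gap: int = DEFAULT_MAX_GAP,
                          max_evalue: float = DEFAULT_HIT_EVALUE,
                          min_orf_aa: int = 50,
                          params: KarlinAltschulParams | None = None
                          ) -> list[ProvirusCall]:
    """Chain virus-protein hits along the contig into candidate regions.

    Maximal runs of hits with inter-hit gaps <= max_gap and at least
    min_hits hits become candidate provirus regions; the reference virus
    is the one contributing most hits to the chain.
    """
    params = params or KarlinAltschulParams(search_space_policy="database_mN")
    hits = _orf_hits(host, virus_proteomes, max_evalue, min_orf_aa, params)
    regions: list[ProvirusCall] = []
    chain: list[_Hit] = []

    def flush() -> None:
        if len(chain) >= min_hits:
            votes: dict[str, int] = {}
            for h in chain:
                votes[h.reference_virus] = votes.get(h.reference_virus, 0) + 1
            ref = max(sorted(votes), key=lambda v: votes[v])
            regions.append(ProvirusCall(
                host_contig_id=host.id,
                start=chain[0].orf.start,
                end=chain[-1].orf.end,
                n_virus_hits=len(chain),
                reference_virus=ref,
            ))

    for hit in hits:
        if chain and hit.orf.start - chain[-1].orf.end > max_gap:
            flush()
            chain = []
        chain.append(hit)
    flush()
    return regions


# ---------------------------------------------------------------------------
# Attachment-site direct repeats


def _extend_seed(a: str, b: str, i: int, j: int, seed_len: int,
                 max_mismatch: int) -> tuple[int, int, int, int]:
    """Greedy bidirectional extension of an exact seed a[i:i+seed_len] ==
    b[j:j+seed_len]; returns (start_a, start_b, length, mismatches).
    Mismatches are never left at the repeat boundaries."""
    off = j - i
    budget = max_mismatch
    # extend right
    ra = i + seed_len
    mm_right: list[int] = []
    while ra < len(a) and ra + off < len(b):
        if a[ra] != b[ra + off]:
            if budget == 0:
                break
            budget -= 1
            mm_right.append(ra)
        ra += 1
    while mm_right and ra - 1 == mm_right[-1]:
        mm_right.pop()
        ra -= 1
        budget += 1
    # extend left with the remaining budget
    la = i - 1
    mm_left: list[int] = []
    while la >= 0 and la + off >= 0:
        if a[la] != b[la + off]:
            if budget == 0:
                break
            budget -= 1
            mm_left.append(la)
        la -= 1
    start = la + 1
    while mm_left and start == mm_left[-1]:
        mm_left.pop()
        start += 1
    return start, start + off, ra - start, len(mm_left) + len(mm_right)


def find_att_repeats(host: Genome, start: int, end: int,
                     min_len: int = DEFAULT_ATT_MIN_LEN,
                     max_mismatch: int = DEFAULT_ATT_MAX_MISMATCH,
                     window: int = DEFAULT_ATT_WINDOW) -> AttSite | None:
    """Longest same-orientation direct repeat with one copy near each
    region edge (within +-window), length >= min_len and at most
    max_mismatch mismatches.  Ties break toward the copies closest to the
    region edges.  Absence is a valid result.
    """
    seq = host.sequence
    lw_start = max(0, start - window)
    lw_end = min(len(seq), start + window)
    rw_start = max(0, end - window)
    rw_end = min(len(seq), end + window)
    left = seq[lw_start:lw_end]
    right = seq[rw_start:rw_end]
    if not left or not right:
        return None
    seed_len = max(4, min_len // (max_mismatch + 1))
    index: dict[str, list[int]] = {}
    for i in range(len(left) - seed_len + 1):
        index.setdefault(left[i : i + seed_len], []).append(i)
    best: AttSite | None = None
    seen: set[tuple[int, int]] = set()
    for j in range(len(right) - seed_len + 1):
        seed = right[j : j + seed_len]
        for i in index.get(seed, ()):
            sa, sb, length, mism = _extend_seed(left, right, i, j, seed_len, max_mismatch)
            if length < min_len:
                continue
            abs_left = lw_start + sa
            abs_right = rw_start + sb
            if abs_right <= abs_left + length:
                continue  # copies overlap or out of order
            key = (abs_left, abs_right)
            if key in seen:
                continue
            seen.add(key)
            # tie-break: longer, then fewer mismatches, then closest to edges
            prox = abs(abs_left + length - start) + abs(abs_right - end)
            cand = AttSite(seq[abs_left : abs_left + length], abs_left, abs_right,
                           length, mism)
            if best is None or (length, -mism, -prox) > (
                    best.length, -best.mismatches,
                    -(abs(best.left_start + best.length - start) + abs(best.right_start - end))):
                best = cand
    return best


def validate_att(att: AttSite, host: Genome, min_len: int, max_mismatch: int) -> bool:
    """Re-validation pass: the reported copies satisfy the length and
    mismatch contract."""
    a = host.sequence[att.left_start : att.left_start + att.length]
    b = host.sequence[att.right_start : att.right_start + att.length]
    mism = sum(1 for x, y in zip(a, b) if x != y)
    return len(a) == att.length >= min_len and mism == att.mismatches <= max_mismatch


# ---------------------------------------------------------------------------
# Family assignment


def assign_provirus_family(region_proteome: list[tuple[str, str]],
                           family_representatives: dict[str, list[tuple[str, str]]],
                           min_shared: float = 20.0,
                           thresholds: Thresholds | None = None) -> str:
    """Label of the family whose representative proteome shares the highest
    symmetric gene fraction with the region proteome (>= min_shared
    percent), else "unassigned".  Ties break lexicographically."""
    if not region_proteome:
        raise ValueError("empty region proteome")
    best_label, best_frac = "unassigned", min_shared
    for label in sorted(family_representatives):
        rep = family_representatives[label]
        graph = gene_sharing.all_vs_all(
            {"region": region_proteome, "ref": rep}, thresholds)
        frac = gene_sharing.symmetric_shared_fraction("region", "ref", graph)
        if frac > best_frac or (frac == best_frac and best_label == "unassigned" and frac >= min_shared):
            if frac >= min_shared:
                best_label, best_frac = label, frac
    return best_label


def classify_integration_target(att: AttSite | None, host: Genome) -> str:
    """Overlap of the left att copy with host annotations, when present."""
    if att is None or not host.genes:
        return "unknown"
    for gene in host.genes:
        if gene.start < att.left_start + att.length and att.left_start < gene.end:
            product = (gene.product or "").lower()
            if "trna" in product:
                return "tRNA"
            return "CDS"
    return "intergenic"


def scan_host(host: Genome, virus_proteomes: dict[str, list[tuple[str, str]]],
              family_representatives: dict[str, list[tuple[str, str]]] | None = None,
              min_hits: int = DEFAULT_MIN_HITS, max_gap: int = DEFAULT_MAX_GAP,
              max_evalue: float = DEFAULT_HIT_EVALUE,
              att_min_len: int = DEFAULT_ATT_MIN_LEN,
              att_max_mismatch: int = DEFAULT_ATT_MAX_MISMATCH,
              att_window: int = DEFAULT_ATT_WINDOW) -> list[ProvirusCall]:
    """End-to-end provirus scan of one host replicon."""
    calls = find_provirus_regions(host, virus_proteomes, min_hits, max_gap, max_evalue)
    for call in calls:
        call.att = find_att_repeats(host, call.start, call.end,
                                    att_min_len, att_max_mismatch, att_window)
        if call.att is not None and not validate_att(call.att, host, att_min_len,
                                                     att_max_mismatch):
            logger.warning("att site for %s:%d-%d failed re-validation; dropped",
                           call.host_contig_id, call.start, call.end)
            call.att = None
        if call.att is not None:
            # tighten region to the att-delimited span
            call.start = call.att.left_start + call.att.length
            call.end = call.att.right_start
        if family_representatives:
            orfs = call_orfs(host.sequence[call.start:call.end], min_aa=50)
            region_prot = [(f"region|{o.gene_id}", o.protein) for o in orfs]
            if region_prot:
                call.family_assignment = assign_provirus_family(
                    region_prot, family_representatives)
        call.integration_target = classify_integration_target(call.att, host)
    return calls
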