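"""Protein pairwise alignment and whole-genome substitution counting.

Local (Smith-Waterman) and global (Needleman-Wunsch) affine-gap protein
alignment with BLAST-style defaults (BLOSUM62, gap open 11, extend 1) and
Karlin-Altschul expectation statistics, plus an anchored comparison mode
for counting nucleotide substitutions between near-identical genomes.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from math import exp, log

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

# gapped BLOSUM62 Karlin-Altschul parameters (BLAST defaults)
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041

DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1


@dataclass(frozen=True)
class KarlinAltschulParams:
    lam: float = DEFAULT_LAMBDA
    K: float = DEFAULT_K
    search_space_policy: str = "pairwise_mn"  # or "database_mN"

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


@dataclass
class AlignmentResult:
    query_id: str
    subject_id: str
    score: float
    bitscore: float
    evalue: float
    identity_pct: float
    aln_len: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    mismatches: int = 0
    gap_opens: int = 0


def bitscore(score: float, params: KarlinAltschulParams | None = None) -> float:
    params = params or KarlinAltschulParams()
    return (params.lam * score - log(params.K)) / log(2)


def evalue(score: float, m: int, n: int, params: KarlinAltschulParams | None = None) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    if m < 1 or n < 1:
        raise ValueError("search space dimensions must be >= 1")
    params = params or KarlinAltschulParams()
    return params.K * m * n * exp(-params.lam * score)


def min_score_for_evalue(emax: float, m: int, n: int,
                         params: KarlinAltschulParams | None = None) -> float:
    """Smallest raw score whose E-value is below ``emax``."""
    params = params or KarlinAltschulParams()
    return log(params.K * m * n / emax) / params.lam


@functools.lru_cache(maxsize=None)
def _matrix(name: str = "BLOSUM62"):
    mat = substitution_matrices.load(name)
    mat = mat.copy()
    # X (and other ambiguity codes) tolerated, scored 0
    for aa in mat.alphabet:
        if aa not in PROTEIN_ALPHABET:
            for bb in mat.alphabet:
                mat[aa, bb] = 0.0
                mat[bb, aa] = 0.0
    return mat


def _check_protein(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name}: empty protein sequence")
    seq = seq.upper()
    bad = set(seq) - PROTEIN_ALPHABET - {"X"}
    if bad:
        raise ValueError(f"{name}: unknown residues {sorted(bad)} (only X is tolerated)")
    return seq


@functools.lru_cache(maxsize=8)
def _aligner(mode: str, matrix_name: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _matrix(matrix_name)
    # gap of length k costs gap_open + k * gap_extend (BLAST convention)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def alignment_score(query: str, subject: str, mode: str = "local",
                    matrix: str = "BLOSUM62", gap_open: int = DEFAULT_GAP_OPEN,
                    gap_extend: int = DEFAULT_GAP_EXTEND) -> float:
    """Score-only alignment (fast path; no traceback)."""
    return _aligner(mode, matrix, gap_open, gap_extend).score(
        _check_protein(query, "query"), _check_protein(subject, "subject")
    )


def _column_stats(aln) -> tuple[int, int, int, int]:
    """(identities, columns, mismatches, gap_opens) over the aligned region."""
    q, s = aln.sequences
    identities = mismatches = columns = gap_opens = 0
    blocks_q, blocks_s = aln.aligned
    prev_qe = prev_se = None
    for (qs, qe), (ss, se) in zip(blocks_q, blocks_s):
        if prev_qe is not None:
            gq = qs - prev_qe
            gs = ss - prev_se
            if gq:
                columns += gq
                gap_opens += 1
            if gs:
                columns += gs
                gap_opens += 1
        for i in range(qe - qs):
            columns += 1
            if q[qs + i] == s[ss + i]:
                identities += 1
            else:
                mismatches += 1
        prev_qe, prev_se = qe, se
    return identities, columns, mismatches, gap_opens


def local_align(query: str, subject: str, query_id: str = "query",
                subject_id: str = "subject", matrix: str = "BLOSUM62",
                gap_open: int = DEFAULT_GAP_OPEN, gap_extend: int = DEFAULT_GAP_EXTEND,
                params: KarlinAltschulParams | None = None,
                search_space: tuple[int, int] | None = None,
                precomputed_score: float | None = None) -> AlignmentResult:
    """Optimal affine-gap Smith-Waterman alignment of two proteins.

    Identity is computed over alignment columns with gaps included in the
    denominator (BLAST convention).  E-value uses the pairwise m*n search
    space unless ``search_space`` overrides it.
    """
    query = _check_protein(query, "query")
    subject = _check_protein(subject, "subject")
    params = params or KarlinAltschulParams()
    aligner = _aligner("local", matrix, gap_open, gap_extend)
    score = precomputed_score if precomputed_score is not None else aligner.score(query, subject)
    m, n = search_space or (len(query), len(subject))
    if score <= 0:
        return AlignmentResult(query_id, subject_id, 0.0, bitscore(0.0, params),
                               evalue(0.0, m, n, params), 0.0, 0, 0, 0, 0, 0)
    aln = aligner.align(query, subject)[0]
    identities, columns, mismatches, gap_opens = _column_stats(aln)
    blocks_q, blocks_s = aln.aligned
    return AlignmentResult(
        query_id=query_id,
        subject_id=subject_id,
        score=score,
        bitscore=bitscore(score, params),
        evalue=evalue(score, m, n, params),
        identity_pct=100.0 * identities / columns,
        aln_len=columns,
        q_start=int(blocks_q[0][0]),
        q_end=int(blocks_q[-1][1]),
        s_start=int(blocks_s[0][0]),
        s_end=int(blocks_s[-1][1]),
        mismatches=mismatches,
        gap_opens=gap_opens,
    )


def global_identity(a: str, b: str, matrix: str = "BLOSUM62",
                    gap_open: int = DEFAULT_GAP_OPEN,
                    gap_extend: int = DEFAULT_GAP_EXTEND) -> float:
    """Percent identity of the global (Needleman-Wunsch) alignment.

    Denominator is the number of alignment columns, gaps included.
    """
    a = _check_protein(a, "a")
    b = _check_protein(b, "b")
    aligner = _aligner("global", matrix, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    identities = 0
    columns = 0
    blocks_a, blocks_b = aln.aligned
    prev_ae = prev_be = 0
    for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
        columns += max(as_ - prev_ae, 0) + max(bs - prev_be, 0)
        for i in range(ae - as_):
            columns += 1
            if a[as_ + i] == b[bs + i]:
                identities += 1
        prev_ae, prev_be = ae, be
    columns += (len(a) - prev_ae) + (len(b) - prev_be)
    return 100.0 * identities / columns if columns else 0.0


def write_tabular(results, path) -> None:
    """BLAST outfmt-6 style 12-column TSV (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for r in results:
            fh.write(
                "\t".join([
                    r.query_id, r.subject_id, f"{r.identity_pct:.2f}", str(r.aln_len),
                    str(r.mismatches), str(r.gap_opens),
                    str(r.q_start + 1), str(r.q_end), str(r.s_start + 1), str(r.s_end),
                    f"{r.evalue:.2e}", f"{r.bitscore:.1f}",
                ]) + "\n"
            )


# ---------------------------------------------------------------------------
# Whole-genome substitution counting


class AnchorError(ValueError):
    """Genomes too divergent for anchored comparison; use full alignment."""


@dataclass
class SubstitutionReport:
    n_substitutions: int
    positions: list[int]  # coordinates in genome A
    n_indel_events: int


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer in dup:
            continue
        if kmer in seen:
            del seen[kmer]
            dup.add(kmer)
        else:
            seen[kmer] = i
    return seen


def _lis_chain(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain of anchors increasing in both coordinates."""
    if not anchors:
        return []
    anchors = sorted(anchors)
    import bisect

    tails: list[int] = []  # b-positions of chain tails
    tails_idx: list[int] = []
    parent = [-1] * len(anchors)
    for i, (_, b) in enumerate(anchors):
        j = bisect.bisect_left(tails, b)
        if j > 0:
            parent[i] = tails_idx[j - 1]
        if j == len(tails):
            tails.append(b)
            tails_idx.append(i)
        else:
            tails[j] = b
            tails_idx[j] = i
    chain = []
    i = tails_idx[-1]
    while i != -1:
        chain.append(anchors[i])
        i = parent[i]
    return chain[::-1]


def _segment_diff(a: str, b: str, offset_a: int) -> tuple[list[int], int]:
    """Substitution positions (A coordinates) and indel events between two
    short unanchored segments, by unit-cost edit-distance traceback."""
    if a == b:
        return [], 0
    if len(a) == len(b):
        return [offset_a + i for i in range(len(a)) if a[i] != b[i]], 0
    if not a or not b:
        return [], 1
    la, lb = len(a), len(b)
    if la * lb > 25_000_000:
        raise AnchorError("unanchored segment too large for alignment")
    dp = np.zeros((la + 1, lb + 1), dtype=np.int32)
    dp[:, 0] = np.arange(la + 1)
    dp[0, :] = np.arange(lb + 1)
    bn = np.frombuffer(b.encode(), dtype=np.uint8)
    an = np.frombuffer(a.encode(), dtype=np.uint8)
    for i in range(1, la + 1):
        sub = dp[i - 1, :-1] + (an[i - 1] != bn)
        row = dp[i]
        prev = dp[i - 1]
        row[1:] = np.minimum(sub, prev[1:] + 1)
        # gap-in-b transitions need a sequential pass
        for j in range(1, lb + 1):
            if row[j - 1] + 1 < row[j]:
                row[j] = row[j - 1] + 1
    # traceback
    subs: list[int] = []
    events = 0
    i, j = la, lb
    in_gap = False
    while i > 0 or j > 0:
        if i > 0 and j > 0 and dp[i, j] == dp[i - 1, j - 1] + (a[i - 1] != b[j - 1]):
            if a[i - 1] != b[j - 1]:
                subs.append(offset_a + i - 1)
            i -= 1
            j -= 1
            in_gap = False
        elif i > 0 and dp[i, j] == dp[i - 1, j] + 1:
            if not in_gap:
                events += 1
                in_gap = True
            i -= 1
        else:
            if not in_gap:
                events += 1
                in_gap = True
            j -= 1
    subs.reverse()
    return subs, events


def count_substitutions(genome_a: str, genome_b: str, k: int = 21,
                        min_coverage: float = 0.5) -> SubstitutionReport:
    """Count nucleotide substitutions between two near-identical genomes.

    Shared k-mers unique in both sequences are chained (longest colinear
    chain); the gaps between consecutive anchors are aligned exactly.
    Indels are reported as events, not substitutions.
    """
    a = genome_a.upper()
    b = genome_b.upper()
    if a == b:
        return SubstitutionReport(0, [], 0)
    if not (0.9 <= len(a) / len(b) <= 1.1):
        raise AnchorError("genome lengths differ by more than 10%; use full alignment")
    ka = _unique_kmers(a, k)
    kb = _unique_kmers(b, k)
    anchors = [(ka[m], kb[m]) for m in ka.keys() & kb.keys()]
    chain = _lis_chain(anchors)
    if not chain:
        raise AnchorError("no shared unique anchors; genomes too divergent")
    # merge chained anchors into non-overlapping colinear blocks
    blocks: list[list[int]] = []  # [a_start, a_end, b_start, b_end]
    for pa, pb in chain:
        if blocks and pa - pb == blocks[-1][0] - blocks[-1][2] and pa <= blocks[-1][1]:
            blocks[-1][1] = max(blocks[-1][1], pa + k)
            blocks[-1][3] = max(blocks[-1][3], pb + k)
        elif blocks and (pa < blocks[-1][1] or pb < blocks[-1][3]):
            continue  # overlapping anchor with different offset; drop
        else:
            blocks.append([pa, pa + k, pb, pb + k])
    covered = sum(e - s for s, e, _, _ in blocks)
    if covered < min_coverage * len(a):
        raise AnchorError(
            f"chained anchors cover only {100 * covered / len(a):.1f}% of genome A "
            "(<50%); genomes too divergent for anchored mode"
        )
    positions: list[int] = []
    events = 0
    prev_a = prev_b = 0
    for a_s, a_e, b_s, b_e in blocks + [[len(a), len(a), len(b), len(b)]]:
        subs, ev = _segment_diff(a[prev_a:a_s], b[prev_b:b_s], prev_a)
        positions.extend(subs)
        events += ev
        prev_a, prev_b = a_e, b_e
    return SubstitutionReport(len(positions), positions, events)
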