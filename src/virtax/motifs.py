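"""Restriction-motif counting and depletion analysis.

Counts overlapping IUPAC motif occurrences (palindromes once per site,
non-palindromes on both strands), computes expected counts under a Markov
null fitted to the sequence, and compares motif frequencies between
genome groups with an in-repo Mann-Whitney U test.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass
from math import comb, erfc, sqrt

import numpy as np

from .genome_io import revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _validate_motif(motif: str) -> str:
    motif = motif.upper()
    if not motif or any(c not in IUPAC for c in motif):
        raise ValueError(f"invalid IUPAC motif {motif!r}")
    return motif


def motif_revcomp(motif: str) -> str:
    return motif.translate(_IUPAC_COMPLEMENT)[::-1]


def is_palindromic(motif: str) -> bool:
    return motif == motif_revcomp(motif)


def _motif_regex(motif: str) -> re.Pattern:
    # N never matches N in the sequence: restrict classes to ACGT literals
    return re.compile("(?=" + "".join(f"[{IUPAC[c]}]" for c in motif) + ")")


def _count_strand(sequence: str, motif: str, topology: str) -> int:
    pat = _motif_regex(motif)
    if topology == "circular" and len(sequence) > 1:
        ext = sequence + sequence[: len(motif) - 1]
        return sum(1 for m in pat.finditer(ext) if m.start() < len(sequence))
    return sum(1 for _ in pat.finditer(sequence))


def count_motif(sequence: str, motif: str, topology: str = "linear") -> int:
    """Overlapping motif occurrences; palindromic motifs are counted on the
    forward strand only, others on both strands.  Circular topology counts
    origin-spanning matches once."""
    motif = _validate_motif(motif)
    sequence = sequence.upper()
    count = _count_strand(sequence, motif, topology)
    if not is_palindromic(motif):
        count += _count_strand(sequence, motif_revcomp(motif), topology)
    return count


def freq_per_kbp(count: int, length: int) -> float:
    if length <= 0:
        raise ValueError("length must be positive")
    return count / (length / 1000.0)


# ---------------------------------------------------------------------------
# Markov null


def _expand_motif(motif: str, limit: int = 65536) -> list[str]:
    sizes = 1
    for c in motif:
        sizes *= len(IUPAC[c])
        if sizes > limit:
            raise ValueError(f"motif {motif!r} expands to too many words")
    return ["".join(w) for w in itertools.product(*(IUPAC[c] for c in motif))]


def fit_markov(sequence: str, order: int) -> tuple[dict, dict]:
    """(initial context probabilities, transition probabilities) from the
    forward strand of the sequence.  Positions containing N are skipped."""
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    seq = sequence.upper()
    if order == 0:
        counts = {b: seq.count(b) for b in "ACGT"}
        total = sum(counts.values())
        if total == 0:
            raise ValueError("sequence has no unambiguous bases")
        probs = {b: c / total for b, c in counts.items()}
        return {"": 1.0}, {("", b): probs[b] for b in "ACGT"}
    ctx_counts: dict[str, int] = {}
    trans_counts: dict[tuple[str, str], int] = {}
    for i in range(len(seq) - order):
        ctx = seq[i : i + order]
        nxt = seq[i + order]
        if "N" in ctx or nxt == "N":
            continue
        ctx_counts[ctx] = ctx_counts.get(ctx, 0) + 1
        trans_counts[(ctx, nxt)] = trans_counts.get((ctx, nxt), 0) + 1
    total_ctx = sum(ctx_counts.values())
    if total_ctx == 0:
        raise ValueError("sequence too short to fit the requested order")
    initial = {ctx: c / total_ctx for ctx, c in ctx_counts.items()}
    transition = {
        (ctx, b): trans_counts.get((ctx, b), 0) / ctx_counts[ctx]
        for ctx in ctx_counts for b in "ACGT"
    }
    return initial, transition


def _word_probability(word: str, order: int, initial: dict, transition: dict) -> float:
    if order == 0:
        p = 1.0
        for b in word:
            p *= transition.get(("", b), 0.0)
        return p
    ctx = word[:order]
    p = initial.get(ctx, 0.0)
    for i in range(order, len(word)):
        p *= transition.get((word[i - order : i], word[i]), 0.0)
        if p == 0.0:
            return 0.0
    return p


def expected_count_markov(sequence: str, motif: str, order: int = 1,
                          topology: str = "linear") -> float:
    """Expected overlapping occurrences of the motif under a Markov chain
    of the given order fitted to the sequence itself.

    Counting conventions match :func:`count_motif` (palindrome single
    strand, otherwise both strands).  A motif requiring a transition never
    observed in the sequence yields expectation 0 with a warning.
    """
    motif = _validate_motif(motif)
    seq = sequence.upper()
    initial, transition = fit_markov(seq, order)
    positions = len(seq) if topology == "circular" else len(seq) - len(motif) + 1
    if positions <= 0:
        return 0.0

    def strand_expect(m: str) -> float:
        p = sum(_word_probability(w, order, initial, transition) for w in _expand_motif(m))
        return p * positions

    expected = strand_expect(motif)
    if not is_palindromic(motif):
        expected += strand_expect(motif_revcomp(motif))
    if expected == 0.0:
        warnings.warn(f"motif {motif} requires transitions absent from the sequence; "
                      "expected count is 0")
    return expected


@dataclass
class MotifReport:
    genome_id: str
    motif: str
    count: int
    length_bp: int
    freq_per_kbp: float
    expected: float
    oe_ratio: float
    mtase_status: str = "unknown"  # encodes | lacks | unknown


def motif_report(genome_id: str, sequence: str, motif: str,
                 topology: str = "linear", order: int = 1,
                 mtase_status: str = "unknown") -> MotifReport:
    count = count_motif(sequence, motif, topology)
    expected = expected_count_markov(sequence, motif, order, topology)
    return MotifReport(
        genome_id=genome_id,
        motif=motif.upper(),
        count=count,
        length_bp=len(sequence),
        freq_per_kbp=freq_per_kbp(count, len(sequence)),
        expected=expected,
        oe_ratio=count / expected if expected > 0 else float("inf") if count else 0.0,
        mtase_status=mtase_status,
    )


def write_motif_reports(reports: list[MotifReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tmotif\tcount\tlength_bp\tfreq_per_kbp\texpected\t"
                 "oe_ratio\tmtase_status\n")
        for r in reports:
            fh.write(f"{r.genome_id}\t{r.motif}\t{r.count}\t{r.length_bp}\t"
                     f"{r.freq_per_kbp:.4f}\t{r.expected:.4f}\t{r.oe_ratio:.4f}\t"
                     f"{r.mtase_status}\n")


# ---------------------------------------------------------------------------
# Group comparison (Mann-Whitney U, in-repo implementation)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x: number of (x_i, y_j) pairs with x_i > y_j, ties 0.5."""
    gt = (x[:, None] > y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(ties)


def mann_whitney_u(x, y, alternative: str = "two-sided",
                   exact_max_n: int = 8) -> tuple[float, float]:
    """Mann-Whitney U test.

    Exact p-value by enumeration of all label assignments when both groups
    have at most ``exact_max_n`` observations; otherwise the normal
    approximation with tie correction.  ``alternative`` refers to the first
    sample: "less" tests whether x is stochastically smaller than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError("alternative must be two-sided, less or greater")
    u_obs = _u_statistic(x, y)
    n1, n2 = x.size, y.size
    if n1 <= exact_max_n and n2 <= exact_max_n:
        pooled = np.concatenate([x, y])
        idx = range(n1 + n2)
        us = np.array([
            _u_statistic(pooled[list(chosen)],
                         pooled[[i for i in idx if i not in set(chosen)]])
            for chosen in itertools.combinations(idx, n1)
        ])
        total = comb(n1 + n2, n1)
        eps = 1e-9
        p_less = np.sum(us <= u_obs + eps) / total
        p_greater = np.sum(us >= u_obs - eps) / total
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        pooled = np.concatenate([x, y])
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = (counts ** 3 - counts).sum() / (n * (n - 1))
        sigma = sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
        if sigma == 0:
            p_less = p_greater = 1.0
        else:
            z_less = (u_obs - mu + 0.5) / sigma
            z_greater = (u_obs - mu - 0.5) / sigma
            p_less = 0.5 * erfc(-z_less / sqrt(2))
            p_greater = 0.5 * erfc(z_greater / sqrt(2))
    if alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    else:
        p = min(1.0, 2 * min(p_less, p_greater))
    return u_obs, float(p)


def compare_mtase_groups(reports: list[MotifReport],
                         alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U on freq_per_kbp between MTase-encoding and
    MTase-lacking genomes."""
    encodes = [r.freq_per_kbp for r in reports if r.mtase_status == "encodes"]
    lacks = [r.freq_per_kbp for r in reports if r.mtase_status == "lacks"]
    if len(encodes) < 2 or len(lacks) < 2:
        raise ValueError("need at least 2 genomes per MTase group")
    return mann_whitney_u(encodes, lacks, alternative=alternative)
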