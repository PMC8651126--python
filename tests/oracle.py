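"""Independent brute-force oracles used only by the test suite."""

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_score_oracle(q: str, s: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Affine-gap Smith-Waterman score by straightforward Gotoh dynamic
    programming (a gap of length k costs gap_open + k * gap_extend).
    Independent of the production alignment path."""
    n, m = len(q), len(s)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in s
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in q
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = _BLOSUM62[q[i - 1], s[j - 1]]
            M[i][j] = max(0.0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + sub
            X[i][j] = max(M[i - 1][j] - gap_open - gap_extend, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open - gap_extend, Y[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return best
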