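"""Independent brute-force oracles used by the test suite.

These implementations are deliberately simple (quadratic dynamic programming
with explicit three-state affine recurrences) and share no code with the
package; they exist to cross-check the package's alignment engines.
Gap convention everywhere: a gap of length k costs open + k * extend.
"""

from __future__ import annotations

NEG = float("-inf")


def affine_dp(a: str, b: str, score_fn, gap_open: float, gap_extend: float,
              local: bool) -> float:
    """Optimal affine-gap alignment score of a vs b by explicit DP.

    ``local=True`` gives the Smith-Waterman score (floor 0), otherwise the
    Needleman-Wunsch score with end gaps penalized.
    """
    n, m = len(a), len(b)
    first = gap_open + gap_extend  # cost of the first gapped position

    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (b consumed)

    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + gap_extend * i)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + gap_extend * j)

    best_local = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            if local:
                prev = max(prev, 0.0)
            M[i][j] = prev + score_fn(a[i - 1], b[j - 1])
            X[i][j] = max(M[i - 1][j] - first, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - first, Y[i][j - 1] - gap_extend)
            if local and M[i][j] > best_local:
                best_local = M[i][j]
    if local:
        return best_local
    return max(M[n][m], X[n][m], Y[n][m])


def blosum62_score_fn():
    from Bio.Align import substitution_matrices

    base = substitution_matrices.load("BLOSUM62")

    def score(x: str, y: str) -> float:
        if x == "*" or y == "*":
            return -10000.0
        if x == "X" or y == "X":
            return -1.0
        return float(base[x, y])

    return score


def nt_score_fn(match: float, mismatch: float):
    def score(x: str, y: str) -> float:
        if x == "N" or y == "N":
            return mismatch
        return match if x == y else mismatch

    return score


def sw_protein_score(a: str, b: str) -> float:
    """Brute-force Smith-Waterman under BLOSUM62 / gap 11+k."""
    return affine_dp(a, b, blosum62_score_fn(), 11, 1, local=True)


def global_msa_score(a: str, b: str) -> float:
    """Brute-force global score under the center-star parameters (+2/-2, 6+k)."""
    return affine_dp(a, b, nt_score_fn(2, -2), 6, 1, local=False)
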