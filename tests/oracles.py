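"""Independent brute-force oracles, implemented without the package's
alignment machinery, for cross-checking scores and statistics."""

from __future__ import annotations

import math

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG = -math.inf


def _s(a: str, b: str) -> float:
    return float(_BLOSUM62[a, b])


def global_affine_score(a: str, b: str, gap_open: float, gap_extend: float) -> float:
    """Gotoh three-state global DP; a gap of length L costs open + L*extend."""
    first = gap_open + gap_extend
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a residue vs gap)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = -first - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0][j] = -first - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best_prev = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = best_prev + _s(a[i - 1], b[j - 1])
            Ix[i][j] = max(M[i - 1][j] - first, Ix[i - 1][j] - gap_extend,
                           Iy[i - 1][j] - first)
            Iy[i][j] = max(M[i][j - 1] - first, Iy[i][j - 1] - gap_extend,
                           Ix[i][j - 1] - first)
    return max(M[n][m], Ix[n][m], Iy[n][m])


def local_affine_score(a: str, b: str, gap_open: float, gap_extend: float) -> float:
    """Smith–Waterman with affine gaps; score floored at zero."""
    first = gap_open + gap_extend
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            H[i][j] = max(0.0, H[i - 1][j - 1] + _s(a[i - 1], b[j - 1]),
                          E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Closed-form Pearson statistic N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
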