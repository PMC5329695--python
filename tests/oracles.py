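"""Independent brute-force oracles used to cross-check the production code.

Everything here is written from first principles (its own IUPAC table,
plain-Python DP) and never calls into the package's alignment or
matching paths.
"""

from __future__ import annotations

NEG_INF = float("-inf")

# independent IUPAC expansion table
_EXP = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def compatible(a: str, b: str) -> bool:
    return bool(set(_EXP[a]) & set(_EXP[b]))


def all_placements(probe: str, seq: str) -> list[tuple[int, int]]:
    """Every gap-free placement of probe on seq: (0-based start, mismatches)."""
    out = []
    for start in range(len(seq) - len(probe) + 1):
        mm = 0
        for i, p in enumerate(probe):
            if not compatible(p, seq[start + i]):
                mm += 1
        out.append((start, mm))
    return out


def best_terminal_placement(probe: str, seq: str, window: int,
                            terminus: str) -> tuple[int, int]:
    """Minimum-mismatch placement within a terminal window; ties go to
    the terminus. Returns (start, mismatches)."""
    placements = all_placements(probe, seq)
    last = len(seq) - len(probe)
    if terminus == "5p":
        cand = [p for p in placements if p[0] < window]
        cand.sort(key=lambda p: (p[1], p[0]))
    else:
        cand = [p for p in placements if p[0] >= max(0, last - window + 1)]
        cand.sort(key=lambda p: (p[1], -p[0]))
    return cand[0]


def overlap_align_score(ref: str, seq: str,
                        match: float = 2.0, mismatch: float = -3.0,
                        gap_open: float = -5.0, gap_extend: float = -2.0) -> float:
    """Affine-gap overlap (free-end-gap) alignment score by Gotoh DP.

    A gap of length L costs gap_open + (L-1) * gap_extend. End gaps on
    either sequence are free.
    """
    n, m = len(ref), len(seq)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in seq (ref consumed)
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in ref (seq consumed)

    def free_start(i, j):
        return 0.0 if (i == 0 or j == 0) else NEG_INF

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if compatible(ref[i - 1], seq[j - 1]) else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1],
                              Y[i - 1][j - 1], free_start(i - 1, j - 1))
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)

    best = 0.0  # empty overlap allowed
    for i in range(1, n + 1):
        best = max(best, M[i][m], X[i][m], Y[i][m])
    for j in range(1, m + 1):
        best = max(best, M[n][j], X[n][j], Y[n][j])
    return best
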