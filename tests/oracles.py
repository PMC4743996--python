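"""Independent brute-force oracles used to check the implementation.

These deliberately share no code with the package: the alignment oracle is a
plain Gotoh three-matrix dynamic program, and the locus oracle checks every
pair of R genes directly against the intervening-gene rule.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def score_pair(a: str, b: str, alphabet: str) -> float:
    if alphabet == "protein":
        try:
            return float(_BLOSUM62[a, b])
        except KeyError:
            return 0.0
    if a == "N" or b == "N":
        return 0.0
    return 2.0 if a == b else -3.0


def smith_waterman_affine(a: str, b: str, alphabet: str,
                          gap_open: float, gap_extend: float) -> float:
    """Optimal local alignment score; gap of length L costs open + L*extend."""
    m, n = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]   # gap in a (horizontal)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]   # gap in b (vertical)
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + score_pair(a[i - 1], b[j - 1], alphabet)
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def brute_force_loci(r_flags: Sequence[bool], max_gap: int = 8) -> List[List[int]]:
    """Partition R-gene positions into loci by directly counting intervening
    non-R genes between every pair of consecutive R genes."""
    r_positions = [i for i, f in enumerate(r_flags) if f]
    loci: List[List[int]] = []
    for pos in r_positions:
        if loci:
            prev = loci[-1][-1]
            intervening = sum(1 for k in range(prev + 1, pos) if not r_flags[k])
            if intervening <= max_gap:
                loci[-1].append(pos)
                continue
        loci.append([pos])
    return loci
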