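"""Independent brute-force oracles used by the tests.

These stay deliberately separate from the package code paths they check:
the alignment oracle is a plain full-matrix dynamic program, and translation
checks go through Biopython's translator.
"""

from Bio.Seq import Seq

NEG = -(2**30)


def dp_score_two_piece(
    q: str,
    r: str,
    match: int = 8,
    mismatch: int = -16,
    go1: int = -16,
    ge1: int = -8,
    go2: int = -80,
    ge2: int = -1,
) -> int:
    """Exhaustive full-matrix local DP score with a two-piece gap cost.

    Default scores are the package defaults in scaled integer units
    (user units x4). Written row by row with explicit state matrices,
    independent of the banded implementation.
    """
    m, n = len(q), len(r)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E1 = [[NEG] * (n + 1) for _ in range(m + 1)]
    E2 = [[NEG] * (n + 1) for _ in range(m + 1)]
    F1 = [[NEG] * (n + 1) for _ in range(m + 1)]
    F2 = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e1 = max(E1[i][j - 1] + ge1, H[i][j - 1] + go1 + ge1)
            e2 = max(E2[i][j - 1] + ge2, H[i][j - 1] + go2 + ge2)
            f1 = max(F1[i - 1][j] + ge1, H[i - 1][j] + go1 + ge1)
            f2 = max(F2[i - 1][j] + ge2, H[i - 1][j] + go2 + ge2)
            s = match if q[i - 1] == r[j - 1] else mismatch
            h = max(0, H[i - 1][j - 1] + s, e1, e2, f1, f2)
            E1[i][j], E2[i][j], F1[i][j], F2[i][j], H[i][j] = e1, e2, f1, f2, h
            if h > best:
                best = h
    return best


def translate(seq: str) -> str:
    return str(Seq(seq).translate())


def find_all(haystack: str, needle: str) -> list[int]:
    """All occurrence offsets (exhaustive string-search oracle)."""
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out
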