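"""Independent brute-force oracles used by the test suite.

These are deliberately naive reference implementations (full dynamic
programming, direct enumeration, closed forms) kept separate from the
package so they can arbitrate its results.
"""

from __future__ import annotations

NEG = float("-inf")


def sw_score(a: str, b: str, score_fn, gap_open: float, gap_extend: float) -> float:
    """Optimal local alignment score, affine gaps (first gap base costs
    ``gap_open``, each further base ``gap_extend``).  Full Smith-Waterman."""
    n, m = len(a), len(b)
    best = 0.0
    h_prev = [0.0] * (m + 1)
    f = [NEG] * (m + 1)
    for i in range(1, n + 1):
        ai = a[i - 1]
        h_row = [0.0] * (m + 1)
        e = NEG
        for j in range(1, m + 1):
            e = max(e + gap_extend, h_row[j - 1] + gap_open)
            f[j] = max(f[j] + gap_extend, h_prev[j] + gap_open)
            h = max(0.0, h_prev[j - 1] + score_fn(ai, b[j - 1]), e, f[j])
            h_row[j] = h
            if h > best:
                best = h
        h_prev = h_row
    return best


def sw_align(a: str, b: str, score_fn, gap_open: float, gap_extend: float):
    """Full Smith-Waterman with traceback.

    Returns (score, matches, gap_columns, alignment_columns) of one optimal
    local alignment (ties resolved diagonal-first).
    """
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + gap_open)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + gap_open)
            h = max(0.0, H[i - 1][j - 1] + score_fn(a[i - 1], b[j - 1]), E[i][j], F[i][j])
            H[i][j] = h
            if h > best:
                best, bi, bj = h, i, j
    # traceback from (bi, bj) until a zero cell
    i, j = bi, bj
    matches = gaps = cols = 0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i][j]
            if h == 0.0:
                break
            if h == H[i - 1][j - 1] + score_fn(a[i - 1], b[j - 1]):
                cols += 1
                if a[i - 1] == b[j - 1] and a[i - 1] not in "NX":
                    matches += 1
                i, j = i - 1, j - 1
            elif h == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols += 1
            gaps += 1
            if E[i][j] == H[i][j - 1] + gap_open:
                state = "H"
            j -= 1
        else:
            cols += 1
            gaps += 1
            if F[i][j] == H[i - 1][j] + gap_open:
                state = "H"
            i -= 1
    return best, matches, gaps, cols


def nt_score_fn(match: float = 1.0, mismatch: float = -2.0):
    def fn(x, y):
        return match if (x == y and x != "N") else mismatch
    return fn


def blosum62_score_fn():
    from Bio.Align import substitution_matrices

    b62 = substitution_matrices.load("BLOSUM62")

    def fn(x, y):
        if x in "X*" or y in "X*":
            return -4.0
        return float(b62[x, y])

    return fn


def shared_word(a: str, b: str, w: int = 11) -> bool:
    """Exact shared w-mer (N-free) between two strings — seed existence."""
    words = {
        a[i : i + w]
        for i in range(len(a) - w + 1)
        if "N" not in a[i : i + w]
    }
    return any(b[i : i + w] in words for i in range(len(b) - w + 1))


def occupancy_mean_var(n_refs: int, n_reads: int) -> tuple[float, float]:
    """Mean and variance of the number of occupied boxes when ``n_reads``
    balls fall iid-uniformly into ``n_refs`` boxes (classical occupancy)."""
    r, n = n_refs, n_reads
    q1 = (1.0 - 1.0 / r) ** n
    q2 = (1.0 - 2.0 / r) ** n
    mean = r * (1.0 - q1)
    ex2 = r * (1.0 - q1) + r * (r - 1) * (1.0 - 2.0 * q1 + q2)
    return mean, ex2 - mean * mean


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
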