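"""Independent alignment-score oracles for testing.

Two implementations of optimal global alignment score with affine gaps
(gap run of length L costs open + (L - 1) * extend, terminal gaps
included), written without reference to the package's alignment module:

* ``enumerate_score`` — literal enumeration of every global alignment
  (exponential; only for very short sequences), used to validate the DP.
* ``gotoh_score`` — plain three-state dynamic program.
"""

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def _sub(a: str, b: str) -> float:
    return float(_BLOSUM62[a][b])


def enumerate_score(a: str, b: str, open_: float = 11.0, extend: float = 1.0) -> float:
    """Max score over all global alignments, by brute-force recursion.

    State tracks the previous column type so gap runs are charged
    open/extend correctly; columns with gaps in both rows are not allowed.
    """

    def rec(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = NEG
        if i < len(a) and j < len(b):
            best = max(best, _sub(a[i], b[j]) + rec(i + 1, j + 1, "m"))
        if i < len(a):  # a[i] against a gap
            cost = extend if prev == "x" else open_
            best = max(best, -cost + rec(i + 1, j, "x"))
        if j < len(b):  # b[j] against a gap
            cost = extend if prev == "y" else open_
            best = max(best, -cost + rec(i, j + 1, "y"))
        return best

    return rec(0, 0, "m")


def gotoh_score(a: str, b: str, open_: float = 11.0, extend: float = 1.0) -> float:
    """Three-state affine-gap DP (match / gap-in-b / gap-in-a)."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # a_i over gap
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap over b_j
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(open_ + (i - 1) * extend)
    for j in range(1, m + 1):
        Y[0][j] = -(open_ + (j - 1) * extend)
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                M[i][j] = _sub(a[i - 1], b[j - 1]) + max(
                    M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]
                )
            if i > 0 and (j > 0 or i > 1):
                X[i][j] = max(
                    X[i][j],
                    M[i - 1][j] - open_,
                    X[i - 1][j] - extend,
                    Y[i - 1][j] - open_,
                )
            if j > 0 and (i > 0 or j > 1):
                Y[i][j] = max(
                    Y[i][j],
                    M[i][j - 1] - open_,
                    Y[i][j - 1] - extend,
                    X[i][j - 1] - open_,
                )
    return max(M[n][m], X[n][m], Y[n][m])
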