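"""Independent textbook Smith-Waterman oracle (pure Python, quadratic).

Implements the documented alignment contract from scratch — BLOSUM62,
affine gaps where a gap of length k costs ``open + k * extend``, local
(H clipped at 0), with the fixed tie-breaks: diagonal > vertical gap >
horizontal gap > stop, gap extension preferred over re-opening, and the
maximal cell with the smallest row then column as the alignment end.
Used only to cross-check the package aligner; shares no code with it.
"""

from Bio.Align import substitution_matrices

_M = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def _score(x: str, y: str) -> float:
    x = "X" if x in "UO" else x
    y = "X" if y in "UO" else y
    return float(_M[x, y])


def sw_align(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0):
    """Returns (score, n_columns, n_identical, a_span, b_span).

    Spans are 1-based inclusive (start, end) of the aligned envelope;
    (0, 0, 0, None, None) when no positive-scoring alignment exists.
    """
    go = gap_open + gap_extend
    ge = gap_extend
    m, n = len(a), len(b)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    Hp = [[0] * (n + 1) for _ in range(m + 1)]
    Ep = [[0] * (n + 1) for _ in range(m + 1)]
    Fp = [[0] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e_open, e_ext = H[i][j - 1] - go, E[i][j - 1] - ge
            if e_ext >= e_open:
                E[i][j], Ep[i][j] = e_ext, 1
            else:
                E[i][j], Ep[i][j] = e_open, 0
            f_open, f_ext = H[i - 1][j] - go, F[i - 1][j] - ge
            if f_ext >= f_open:
                F[i][j], Fp[i][j] = f_ext, 1
            else:
                F[i][j], Fp[i][j] = f_open, 0
            diag = H[i - 1][j - 1] + _score(a[i - 1], b[j - 1])
            h, ptr = diag, 1
            if F[i][j] > h:
                h, ptr = F[i][j], 2
            if E[i][j] > h:
                h, ptr = E[i][j], 3
            if h <= 0.0:
                h, ptr = 0.0, 0
            H[i][j], Hp[i][j] = h, ptr
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0.0:
        return 0.0, 0, 0, None, None
    i, j = bi, bj
    ncols = nident = 0
    state = 0  # 0=H 1=E 2=F
    while True:
        if state == 0:
            p = Hp[i][j]
            if p == 0:
                break
            if p == 1:
                ncols += 1
                ax = "X" if a[i - 1] in "UO" else a[i - 1]
                bx = "X" if b[j - 1] in "UO" else b[j - 1]
                if ax == bx:
                    nident += 1
                i, j = i - 1, j - 1
            elif p == 2:
                state = 2
            else:
                state = 1
        elif state == 2:
            p = Fp[i][j]
            ncols += 1
            i -= 1
            state = 0 if p == 0 else 2
        else:
            p = Ep[i][j]
            ncols += 1
            j -= 1
            state = 0 if p == 0 else 1
    return best, ncols, nident, (i + 1, bi), (j + 1, bj)
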