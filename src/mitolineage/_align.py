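"""Banded global alignment with affine gap penalties.

Near-identical mitogenome pairs only ever need a narrow band around the
main diagonal, so the DP is restricted to a configurable band that is
widened and retried whenever the optimal path touches a band edge.
Scoring follows the match/mismatch/open/extend convention where a gap of
length k costs ``open + (k - 1) * extend`` (both entered as penalties).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# traceback codes
_FROM_M, _FROM_X, _FROM_Y, _NONE = 0, 1, 2, 3
_NEG = -(10 ** 9)


def _encode(s: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else (IUPAC ambiguity) -> 4."""
    lut = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _band_dp(r, q, dlo, dhi, match, mismatch, gap_open, gap_extend):
    n, m = len(r), len(q)
    W = dhi - dlo + 1
    M = np.full((n + 1, W), _NEG, dtype=np.int64)
    X = np.full((n + 1, W), _NEG, dtype=np.int64)  # gap in query (deletion)
    Y = np.full((n + 1, W), _NEG, dtype=np.int64)  # gap in reference (insertion)
    TM = np.full((n + 1, W), _NONE, dtype=np.uint8)
    TX = np.full((n + 1, W), _NONE, dtype=np.uint8)
    TY = np.full((n + 1, W), _NONE, dtype=np.uint8)

    if 0 - dlo >= 0 and 0 - dlo < W:
        M[0, 0 - dlo] = 0
    # leading gaps
    for j in range(1, m + 1):
        k = j - 0 - dlo
        if 0 <= k < W:
            Y[0, k] = -(gap_open + (j - 1) * gap_extend)
            TY[0, k] = _FROM_Y if j > 1 else _FROM_M
    for i in range(1, n + 1):
        k = 0 - i - dlo
        if 0 <= k < W:
            X[i, k] = -(gap_open + (i - 1) * gap_extend)
            TX[i, k] = _FROM_X if i > 1 else _FROM_M

    for i in range(1, n + 1):
        jlo = max(1, i + dlo)
        jhi = min(m, i + dhi)
        for j in range(jlo, jhi + 1):
            k = j - i - dlo
            # match/mismatch from (i-1, j-1) -> same band offset k
            a, b = r[i - 1], q[j - 1]
            if a == 4 or b == 4:
                s = 0
            elif a == b:
                s = match
            else:
                s = -mismatch
            best = M[i - 1, k] + s
            frm = _FROM_M
            if X[i - 1, k] + s > best:
                best = X[i - 1, k] + s
                frm = _FROM_X
            if Y[i - 1, k] + s > best:
                best = Y[i - 1, k] + s
                frm = _FROM_Y
            M[i, k] = best
            TM[i, k] = frm
            # deletion: from (i-1, j) -> offset k+1
            if k + 1 < W:
                o = M[i - 1, k + 1] - gap_open
                e = X[i - 1, k + 1] - gap_extend
                if e > o:
                    X[i, k] = e
                    TX[i, k] = _FROM_X
                else:
                    X[i, k] = o
                    TX[i, k] = _FROM_M
            # insertion: from (i, j-1) -> offset k-1
            if k - 1 >= 0:
                o = M[i, k - 1] - gap_open
                e = Y[i, k - 1] - gap_extend
                if e > o:
                    Y[i, k] = e
                    TY[i, k] = _FROM_Y
                else:
                    Y[i, k] = o
                    TY[i, k] = _FROM_M
    return M, X, Y, TM, TX, TY


def _traceback(r_len, q_len, dlo, M, X, Y, TM, TX, TY):
    k = q_len - r_len - dlo
    scores = (M[r_len, k], X[r_len, k], Y[r_len, k])
    state = int(np.argmax(scores))
    score = scores[state]
    ops = []
    i, j = r_len, q_len
    touched_edge = False
    W = M.shape[1]
    while i > 0 or j > 0:
        k = j - i - dlo
        if k <= 0 or k >= W - 1:
            touched_edge = True
        if state == 0:
            prev = TM[i, k]
            ops.append("M")
            i -= 1
            j -= 1
        elif state == 1:
            prev = TX[i, k]
            ops.append("D")
            i -= 1
        else:
            prev = TY[i, k]
            ops.append("I")
            j -= 1
        state = int(prev) if prev != _NONE else 0
    ops.reverse()
    return score, "".join(ops), touched_edge


def banded_global_align(ref: str, query: str, match: int = 1, mismatch: int = 1,
                        gap_open: int = 8, gap_extend: int = 1,
                        band: int = 32) -> tuple[int, str]:
    """Globally align ``query`` to ``ref``; return (score, ops string).

    Ops: M consumes one base of each, D one reference base (deletion in the
    query), I one query base (insertion relative to the reference).  The band
    is doubled and the DP re-run while the optimal path touches a band edge.
    """
    r = _encode(ref)
    q = _encode(query)
    shift = len(query) - len(ref)
    while True:
        dlo = min(0, shift) - band
        dhi = max(0, shift) + band
        M, X, Y, TM, TX, TY = _band_dp(r, q, dlo, dhi, match, mismatch,
                                       gap_open, gap_extend)
        score, ops, touched = _traceback(len(ref), len(query), dlo, M, X, Y,
                                         TM, TX, TY)
        if not touched or band >= max(len(ref), len(query)):
            return int(score), ops
        band *= 2


def left_normalize(ref_gapped: list[str], qry_gapped: list[str]) -> None:
    """Shift gap runs leftmost in place (score-neutral repositioning).

    A deletion run may move one column left when the reference base entering
    the run equals the one leaving it, and symmetrically for insertions —
    the VCF-style normalization convention.
    """
    changed = True
    while changed:
        changed = False
        for target, other in ((qry_gapped, ref_gapped), (ref_gapped, qry_gapped)):
            n = len(target)
            i = 0
            while i < n:
                if target[i] != "-":
                    i += 1
                    continue
                a = i
                b = i
                while b + 1 < n and target[b + 1] == "-":
                    b += 1
                # shift run [a, b] left while legal
                while a > 0 and target[a - 1] != "-" and other[a - 1] != "-" \
                        and other[a - 1] == other[b]:
                    # move the non-gap column at a-1 to position b
                    target[b] = target[a - 1]
                    target[a - 1] = "-"
                    a -= 1
                    b -= 1
                    changed = True
                i = b + 1
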