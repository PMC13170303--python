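"""Numba-jitted dynamic-programming kernels.

The Smith–Waterman/Gotoh kernel is the package's exact local-alignment oracle.
It stores one packed pointer byte per DP cell (row score vectors are rolled),
so memory is O(m*n) bytes, and traces back from every tied maximal end cell
(capped) to honour a fixed tie-break rule.

Conventions baked in here:

* codes: A=0, C=1, G=2, T=3, N=4; N never matches anything (including N).
* affine gaps: a gap of length L costs gap_open + (L-1)*gap_extend, both
  penalties being negative additive terms.
* tie-break among equal-scoring local alignments: smallest subject start,
  then smallest query start, then fewest alignment columns.
"""

from __future__ import annotations

import numba as nb
import numpy as np

# pointer byte layout: bits 0-1 = H source (0 stop, 1 diag, 2 from E, 3 from F)
#                      bit 2   = E extended from E (else opened from H)
#                      bit 3   = F extended from F (else opened from H)

_MAX_TIED_ENDS = 64


@nb.njit(cache=True)
def sw_align(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover - jitted
    """Optimal local alignment of query ``a`` vs subject ``b``.

    Returns (score, q_start, q_end, s_start, s_end, matches, aligned_cols);
    all coordinates 0-based half-open. score == 0 means no alignment.
    """
    m = a.shape[0]
    n = b.shape[0]
    NEG = np.int32(-(10 ** 9))
    ptr = np.zeros((m + 1, n + 1), dtype=np.uint8)
    h_prev = np.zeros(n + 1, dtype=np.int32)
    h_cur = np.zeros(n + 1, dtype=np.int32)
    f_col = np.full(n + 1, NEG, dtype=np.int32)

    best = np.int32(0)
    ends_i = np.zeros(_MAX_TIED_ENDS, dtype=np.int64)
    ends_j = np.zeros(_MAX_TIED_ENDS, dtype=np.int64)
    n_ends = 0

    for i in range(1, m + 1):
        e = NEG
        h_cur[0] = 0
        ai = a[i - 1]
        for j in range(1, n + 1):
            # E: gap in query (consumes subject base), horizontal move
            e_open = h_cur[j - 1] + gap_open
            e_ext = e + gap_extend
            if e_ext > e_open:
                e = e_ext
                e_bit = np.uint8(4)
            else:
                e = e_open
                e_bit = np.uint8(0)
            # F: gap in subject (consumes query base), vertical move
            f_open = h_prev[j] + gap_open
            f_ext = f_col[j] + gap_extend
            if f_ext > f_open:
                f_col[j] = f_ext
                f_bit = np.uint8(8)
            else:
                f_col[j] = f_open
                f_bit = np.uint8(0)
            bj = b[j - 1]
            if ai == bj and ai < 4:
                diag = h_prev[j - 1] + match
            else:
                diag = h_prev[j - 1] + mismatch
            # preference on ties: diag > E > F > stop
            h = np.int32(0)
            src = np.uint8(0)
            if diag >= h and diag > 0:
                h = diag
                src = np.uint8(1)
            if e > h:
                h = e
                src = np.uint8(2)
            if f_col[j] > h:
                h = f_col[j]
                src = np.uint8(3)
            h_cur[j] = h
            ptr[i, j] = src | e_bit | f_bit
            if h > best:
                best = h
                n_ends = 0
            if h == best and best > 0 and n_ends < _MAX_TIED_ENDS:
                ends_i[n_ends] = i
                ends_j[n_ends] = j
                n_ends += 1
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp

    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0

    # trace back from every tied end; pick by (s_start, q_start, cols)
    sel_qs = -1
    sel_qe = -1
    sel_ss = -1
    sel_se = -1
    sel_match = -1
    sel_cols = -1
    for t in range(n_ends):
        i = ends_i[t]
        j = ends_j[t]
        qe = i
        se = j
        matches = 0
        cols = 0
        state = 0  # 0 = H, 1 = E, 2 = F
        while True:
            p = ptr[i, j]
            if state == 0:
                src = p & np.uint8(3)
                if src == 0:
                    break
                if src == 1:
                    cols += 1
                    if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                        matches += 1
                    i -= 1
                    j -= 1
                elif src == 2:
                    state = 1
                else:
                    state = 2
            elif state == 1:
                cols += 1
                if p & np.uint8(4) == 0:
                    state = 0
                j -= 1
            else:
                cols += 1
                if p & np.uint8(8) == 0:
                    state = 0
                i -= 1
        qs = i
        ss = j
        better = False
        if sel_qs < 0:
            better = True
        elif ss < sel_ss:
            better = True
        elif ss == sel_ss:
            if qs < sel_qs:
                better = True
            elif qs == sel_qs and cols < sel_cols:
                better = True
        if better:
            sel_qs = qs
            sel_qe = qe
            sel_ss = ss
            sel_se = se
            sel_match = matches
            sel_cols = cols

    return int(best), sel_qs, sel_qe, sel_ss, sel_se, sel_match, sel_cols
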