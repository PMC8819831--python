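"""Global-alignment sequence identity for redundancy clustering.

The identity used for CD-HIT-style clustering is ``matches / columns`` of an
optimal global (Needleman-Wunsch) alignment scored with match=1, mismatch=0
and a linear gap penalty of -1.  Among co-optimal alignments the one with
the most matches is taken; given the optimal score ``S`` and match count
``M``, the number of alignment columns is ``(len(a) + len(b) + M - S) / 2``
(each gap column costs one score unit, so ``gaps = M - S``), which makes the
identity a well-defined function of ``(S, M)``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_NT_CODE = {c: i for i, c in enumerate("ACGUN")}


@njit(cache=True)
def _nw_score_matches(a, b):  # pragma: no cover - numba-compiled
    """Return (best score, matches in the max-match co-optimal alignment)."""
    la, lb = a.shape[0], b.shape[0]
    # DP over (score, matches) with lexicographic maximisation
    s_prev = np.empty(lb + 1, dtype=np.int64)
    m_prev = np.empty(lb + 1, dtype=np.int64)
    s_cur = np.empty(lb + 1, dtype=np.int64)
    m_cur = np.empty(lb + 1, dtype=np.int64)
    for j in range(lb + 1):
        s_prev[j] = -j
        m_prev[j] = 0
    for i in range(1, la + 1):
        s_cur[0] = -i
        m_cur[0] = 0
        ai = a[i - 1]
        for j in range(1, lb + 1):
            hit = 1 if (ai == b[j - 1] and ai != 4) else 0  # N never matches
            ds = s_prev[j - 1] + hit
            dm = m_prev[j - 1] + hit
            us = s_prev[j] - 1
            um = m_prev[j]
            ls = s_cur[j - 1] - 1
            lm = m_cur[j - 1]
            bs, bm = ds, dm
            if us > bs or (us == bs and um > bm):
                bs, bm = us, um
            if ls > bs or (ls == bs and lm > bm):
                bs, bm = ls, lm
            s_cur[j] = bs
            m_cur[j] = bm
        s_prev, s_cur = s_cur, s_prev
        m_prev, m_cur = m_cur, m_prev
    return s_prev[lb], m_prev[lb]


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_NT_CODE[c] for c in seq.upper().replace("T", "U")], dtype=np.int8)
    except KeyError as e:
        raise ValueError(f"non-nucleotide character {e.args[0]!r} in sequence") from None


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching columns in an optimal global alignment of *a*, *b*.

    Symmetric, in ``[0, 1]``; 1.0 for identical sequences, 0.0 when no
    residues can be matched.  Raises :class:`ValueError` on empty input.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if a == b and "N" not in a.upper():
        return 1.0
    ea, eb = _encode(a), _encode(b)
    score, matches = _nw_score_matches(ea, eb)
    columns = (len(a) + len(b) + matches - score) / 2.0
    return matches / columns
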