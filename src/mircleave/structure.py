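"""Secondary-structure annotation: folding, pair tables, structure arrays.

The per-position structure array extends the dot-bracket with loop context:

====  =========================================================
char  meaning
====  =========================================================
L     paired, 5' (left) partner of a base pair
R     paired, 3' (right) partner
H     hairpin loop (unpaired run with no enclosed helix)
B     bulge (unpaired run on one strand between stacked helices)
I     internal loop (unpaired runs on both strands)
M     multiloop (loop enclosing two or more branch helices)
E     exterior (unpaired, not enclosed by any pair)
====  =========================================================

Extended sequences carry long single-stranded flanks, which necessarily fall
outside every base pair; those positions are labeled ``E`` (the character is
an addition to the L/R/H/B/I/M loop alphabet, which has no code for them).

Folding goes through an adapter so that a thermodynamic engine (ViennaRNA's
``RNA`` module) is used when importable while precomputed dot-brackets remain
first-class input.  The built-in fallback is a deterministic maximum
weighted-pairing dynamic program (GC=3, AU=2, GU=1, minimum hairpin 3) --
adequate for the strongly paired hairpins this package works with, not a
substitute for a nearest-neighbor energy model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

MIN_HAIRPIN = 3

_PAIR_SCORES = {"GC": 3, "CG": 3, "AU": 2, "UA": 2, "GU": 1, "UG": 1}


class FoldingEngineError(RuntimeError):
    """Raised when the requested folding engine is unavailable."""


@dataclass(frozen=True)
class StructureAnnotation:
    """Dot-bracket plus enhanced structure array for one sequence."""

    dot_bracket: str
    structure_array: str
    pair_table: dict[int, int]

    def __post_init__(self) -> None:
        if len(self.dot_bracket) != len(self.structure_array):
            raise ValueError("dot_bracket and structure_array lengths differ")


def parse_pairs(dot_bracket: str) -> dict[int, int]:
    """Stack-match a dot-bracket string into a symmetric pair table.

    Only ``(``, ``)`` and ``.`` are accepted (the MFE engines used here emit
    no pseudoknots).  Raises :class:`ValueError` with the offending position
    on unbalanced or foreign characters.
    """
    stack: list[int] = []
    table: dict[int, int] = {}
    for pos, ch in enumerate(dot_bracket):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {pos}")
            i = stack.pop()
            table[i] = pos
            table[pos] = i
        elif ch != ".":
            raise ValueError(f"unsupported structure character {ch!r} at position {pos}")
    if stack:
        raise ValueError(f"unmatched '(' at position {stack[-1]}")
    return table


def _runs_and_children(pt: dict[int, int], lo: int, hi: int):
    """Top-level unpaired runs and child pairs in the open interval [lo, hi]."""
    runs, children = [], []
    p = lo
    run_start = None
    while p <= hi:
        if p in pt:
            if run_start is not None:
                runs.append((run_start, p - 1))
                run_start = None
            children.append((p, pt[p]))
            p = pt[p] + 1
        else:
            if run_start is None:
                run_start = p
            p += 1
    if run_start is not None:
        runs.append((run_start, hi))
    return runs, children


def build_structure_array(sequence: str, dot_bracket: str) -> StructureAnnotation:
    """Classify every position of ``dot_bracket`` into the L/R/H/B/I/M/E alphabet."""
    if len(sequence) != len(dot_bracket):
        raise ValueError(
            f"sequence length {len(sequence)} != structure length {len(dot_bracket)}"
        )
    pt = parse_pairs(dot_bracket)
    arr = [""] * len(dot_bracket)
    for i, j in pt.items():
        arr[i] = "L" if j > i else "R"

    # (lo, hi, closed) regions to decompose, starting from the exterior
    regions = [(0, len(dot_bracket) - 1, False)]
    while regions:
        lo, hi, closed = regions.pop()
        if lo > hi:
            continue
        runs, children = _runs_and_children(pt, lo, hi)
        if not closed:
            label = "E"
        elif not children:
            label = "H"
        elif len(children) == 1:
            label = "I" if len(runs) == 2 else "B"
        else:
            label = "M"
        for a, b in runs:
            for p in range(a, b + 1):
                arr[p] = label
        for a, b in children:
            regions.append((a + 1, b - 1, True))
    return StructureAnnotation(dot_bracket, "".join(arr), pt)


# ---------------------------------------------------------------------------
# folding engines


def _builtin_fold(seq: str) -> str:
    """Maximum weighted pairing DP (Nussinov-style) with deterministic traceback."""
    n = len(seq)
    if n == 0:
        raise ValueError("cannot fold an empty sequence")
    seq = seq.upper().replace("T", "U")
    pair = np.zeros((n, n), dtype=np.int32)
    for i in range(n):
        for j in range(i + MIN_HAIRPIN + 1, n):
            pair[i, j] = _PAIR_SCORES.get(seq[i] + seq[j], 0)

    # W stored per diagonal: diag[d][i] = W[i, i + d]
    diag = [np.zeros(n - d, dtype=np.int32) for d in range(n)]
    for d in range(1, n):
        m = n - d
        i = np.arange(m)
        best = np.maximum(diag[d - 1][1:], diag[d - 1][:m])  # i unpaired / j unpaired
        if d >= MIN_HAIRPIN + 1:
            inner = diag[d - 2][1 : 1 + m] if d >= 2 else np.zeros(m, dtype=np.int32)
            paired = inner + pair[i, i + d]
            paired[pair[i, i + d] == 0] = -1
            best = np.maximum(best, paired)
        for t in range(1, d - 1):
            best = np.maximum(best, diag[t][:m] + diag[d - t - 1][i + t + 1])
        diag[d] = best

    def W(i: int, j: int) -> int:
        return 0 if j <= i else int(diag[j - i][i])

    out = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < 1 or W(i, j) == 0:
            continue
        if pair[i, j] and W(i, j) == W(i + 1, j - 1) + pair[i, j]:
            out[i], out[j] = "(", ")"
            stack.append((i + 1, j - 1))
        elif W(i, j) == W(i + 1, j):
            stack.append((i + 1, j))
        elif W(i, j) == W(i, j - 1):
            stack.append((i, j - 1))
        else:
            for k in range(i + 1, j):
                if W(i, j) == W(i, k) + W(k + 1, j):
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
    return _drop_lonely_pairs("".join(out))


def _drop_lonely_pairs(db: str) -> str:
    """Remove isolated (unstacked) pairs, like RNAfold's --noLP option."""
    pt = parse_pairs(db)
    changed = True
    while changed:
        changed = False
        for i, j in list(pt.items()):
            if i > j or i not in pt:
                continue
            stacked = (pt.get(i + 1) == j - 1) or (pt.get(i - 1) == j + 1)
            if not stacked:
                del pt[i], pt[j]
                changed = True
    out = ["."] * len(db)
    for i, j in pt.items():
        out[i] = "(" if j > i else ")"
    return "".join(out)


def _vienna_fold(seq: str) -> str:
    try:
        import RNA  # type: ignore
    except ImportError as e:  # pragma: no cover - ViennaRNA not in test env
        raise FoldingEngineError(
            "ViennaRNA python bindings are not installed; fold with "
            "engine='builtin' or supply a precomputed dot-bracket structure"
        ) from e
    return RNA.fold(seq)[0]  # pragma: no cover


def fold(sequence: str, engine: "str | Callable[[str], str]" = "auto") -> str:
    """Predict the MFE dot-bracket of ``sequence`` with the configured engine.

    ``engine`` is ``"auto"`` (ViennaRNA if importable, else the built-in DP),
    ``"vienna"``, ``"builtin"``, or any callable ``seq -> dot_bracket``.
    Deterministic for a fixed engine.
    """
    if not sequence:
        raise ValueError("cannot fold an empty sequence")
    if callable(engine):
        return engine(sequence)
    if engine == "vienna":
        return _vienna_fold(sequence)
    if engine == "builtin":
        return _builtin_fold(sequence)
    if engine == "auto":
        try:
            return _vienna_fold(sequence)
        except FoldingEngineError:
            return _builtin_fold(sequence)
    raise ValueError(f"unknown folding engine {engine!r}")


def annotate(
    sequence: str,
    dot_bracket: Optional[str] = None,
    engine: "str | Callable[[str], str]" = "auto",
) -> StructureAnnotation:
    """Fold (unless a dot-bracket is supplied) and build the structure array."""
    if dot_bracket is None:
        dot_bracket = fold(sequence, engine=engine)
    return build_structure_array(sequence, dot_bracket)


def hairpin_loops(dot_bracket: str) -> list[tuple[int, int]]:
    """Half-open spans of hairpin loops (unpaired runs enclosed with no branch)."""
    ann = build_structure_array(dot_bracket and "N" * len(dot_bracket), dot_bracket)
    spans = []
    start = None
    for p, ch in enumerate(ann.structure_array + "$"):
        if ch == "H":
            if start is None:
                start = p
        elif start is not None:
            spans.append((start, p))
            start = None
    return spans
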