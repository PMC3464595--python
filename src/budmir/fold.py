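"""Minimum-free-energy RNA secondary structure prediction.

A self-contained, reduced nearest-neighbor energy model: stacking free
energies for the 21 distinct stack types (Watson-Crick and G:U wobble pairs,
Freier/Turner-style values, kcal/mol), linear hairpin / bulge / internal-loop
penalties, and an affine multiloop cost.  The optimum over all pseudoknot-free
structures is found with a Zuker-style dynamic program; the fill is
numba-compiled so ~300 nt precursor windows fold in well under a second.

Two entry points matter to callers:

``fold(seq)``
    returns the MFE structure (dot-bracket) and its energy.  Deterministic:
    ties are broken by a fixed traceback order (hairpin, then interior loops
    by closing pair, then multiloop splits left to right).

``structure_energy(seq, structure)``
    evaluates an arbitrary nested structure under the same model by explicit
    loop decomposition.  It shares only the parameter tables with the DP, so
    exhaustive enumeration over ``structure_energy`` serves as an independent
    oracle for the optimizer on short sequences.

Energies are handled internally as integer centi-kcal/mol so the DP is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ._util import to_rna

MIN_LEN = 15
MAX_LEN = 400

#: minimum unpaired nucleotides enclosed by a hairpin-closing pair
MIN_HAIRPIN_LOOP = 3

#: interior/bulge loops larger than this many unpaired nt are not searched
MAX_INTERIOR_LOOP = 30

_INF = int(1 << 28)

_BASES = {"A": 0, "C": 1, "G": 2, "U": 3}

# pair type indices; table order matters only for the stack lookup
PAIR_TYPES = ("CG", "GC", "GU", "UG", "AU", "UA")
_PAIR_INDEX = {p: i for i, p in enumerate(PAIR_TYPES)}

# Stacking free energies (kcal/mol) for the helix  5'-X W-3' / 3'-Y Z-5'
# indexed [outer pair XY][inner pair WZ].  Freier/Turner-style values with
# G:U wobble; the matrix satisfies the duplex rotation symmetry
# E[p][q] == E[flip(q)][flip(p)] where flip reverses a pair (tested).
_STACK_KCAL: dict[str, dict[str, float]] = {
    #            AU    CG    GC    UA    GU    UG
    "AU": dict(AU=-0.9, CG=-2.1, GC=-1.7, UA=-0.9, GU=-0.5, UG=-1.0),
    "CG": dict(AU=-1.8, CG=-2.9, GC=-2.0, UA=-1.7, GU=-1.2, UG=-1.9),
    "GC": dict(AU=-2.3, CG=-3.4, GC=-2.9, UA=-2.1, GU=-1.4, UG=-2.1),
    "UA": dict(AU=-1.1, CG=-2.3, GC=-1.8, UA=-0.9, GU=-0.8, UG=-1.1),
    "GU": dict(AU=-1.1, CG=-2.1, GC=-1.9, UA=-1.0, GU=-0.4, UG=-1.5),
    "UG": dict(AU=-0.8, CG=-1.4, GC=-1.2, UA=-0.5, GU=-0.2, UG=-0.4),
}

# loop penalties, centi-kcal/mol; all linear in loop size per the model
_HAIRPIN_INIT = 500      # loop of 3 nt
_HAIRPIN_PER_NT = 15     # each additional unpaired nt
_BULGE_INIT = 360
_BULGE_PER_NT = 30
_INTERNAL_INIT = 210
_INTERNAL_PER_NT = 40
_INTERNAL_ASYM = 30      # per nt of |n1 - n2|
_ML_CLOSE = 340          # multiloop initiation
_ML_BRANCH = 40          # per branch, closing pair included
_ML_UNPAIRED = 10        # per unpaired nt inside a multiloop


def _stack_table() -> np.ndarray:
    t = np.full((6, 6), _INF, dtype=np.int64)
    for p, row in _STACK_KCAL.items():
        for q, e in row.items():
            t[_PAIR_INDEX[p], _PAIR_INDEX[q]] = round(e * 100)
    return t


_STACK = _stack_table()


def _pair_matrix(allow_gu: bool) -> np.ndarray:
    """4x4 base -> base pair-type matrix, -1 where no pair is allowed."""
    m = np.full((4, 4), -1, dtype=np.int64)
    for p, idx in _PAIR_INDEX.items():
        if not allow_gu and p in ("GU", "UG"):
            continue
        m[_BASES[p[0]], _BASES[p[1]]] = idx
    return m


_PAIRMAT_GU = _pair_matrix(True)
_PAIRMAT_WC = _pair_matrix(False)


def hairpin_energy(size: int) -> int:
    """Centi-kcal penalty of a hairpin loop with ``size`` unpaired nt."""
    if size < MIN_HAIRPIN_LOOP:
        return _INF
    return _HAIRPIN_INIT + _HAIRPIN_PER_NT * (size - MIN_HAIRPIN_LOOP)


def interior_energy(pout: int, pin: int, n1: int, n2: int) -> int:
    """Centi-kcal cost of the interior loop (or stack) between two pairs.

    ``n1``/``n2`` are the unpaired counts on the 5' and 3' sides; 0/0 is a
    stacked pair and scores from the stacking table.
    """
    if n1 == 0 and n2 == 0:
        return int(_STACK[pout, pin])
    total = n1 + n2
    if n1 == 0 or n2 == 0:
        return _BULGE_INIT + _BULGE_PER_NT * total
    return _INTERNAL_INIT + _INTERNAL_PER_NT * total + _INTERNAL_ASYM * abs(n1 - n2)


@njit(cache=True)
def _fill(enc, pairmat, stack, minloop, maxint,
          hp_init, hp_nt, bu_init, bu_nt, il_init, il_nt, il_asym,
          ml_a, ml_b, ml_c, inf):  # pragma: no cover - exercised via fold()
    n = enc.size
    V = np.full((n, n), inf, dtype=np.int64)
    WM = np.full((n, n), inf, dtype=np.int64)
    for d in range(1, n):
        for i in range(n - d):
            j = i + d
            p = pairmat[enc[i], enc[j]]
            if p >= 0 and d > minloop:
                # hairpin loop
                best = hp_init + hp_nt * (d - 1 - minloop)
                # stack / bulge / internal loop
                for k in range(i + 1, j):
                    n1 = k - i - 1
                    if n1 > maxint:
                        break
                    for l in range(j - 1, k, -1):
                        n2 = j - 1 - l
                        if n1 + n2 > maxint:
                            break
                        q = pairmat[enc[k], enc[l]]
                        if q < 0 or V[k, l] >= inf:
                            continue
                        if n1 == 0 and n2 == 0:
                            e = stack[p, q]
                        elif n1 == 0 or n2 == 0:
                            e = bu_init + bu_nt * (n1 + n2)
                        else:
                            e = il_init + il_nt * (n1 + n2) + il_asym * abs(n1 - n2)
                        cand = V[k, l] + e
                        if cand < best:
                            best = cand
                # multiloop closure: at least two branches inside
                for k in range(i + 2, j - 1):
                    a = WM[i + 1, k]
                    b = WM[k + 1, j - 1]
                    if a < inf and b < inf:
                        cand = ml_a + ml_b + a + b
                        if cand < best:
                            best = cand
                V[i, j] = best
            # WM: segment of a multiloop holding >= 1 branch
            wm = inf
            if V[i, j] < inf:
                wm = V[i, j] + ml_b
            if WM[i, j - 1] < inf and WM[i, j - 1] + ml_c < wm:
                wm = WM[i, j - 1] + ml_c
            if i + 1 <= j and WM[i + 1, j] < inf and WM[i + 1, j] + ml_c < wm:
                wm = WM[i + 1, j] + ml_c
            for k in range(i + 1, j):
                a = WM[i, k]
                b = WM[k + 1, j]
                if a < inf and b < inf and a + b < wm:
                    wm = a + b
            WM[i, j] = wm
    W = np.zeros(n + 1, dtype=np.int64)  # W[j]: best energy of prefix [0, j)
    for j in range(1, n + 1):
        best = W[j - 1]
        for i in range(j - 1):
            if V[i, j - 1] < inf:
                cand = W[i] + V[i, j - 1]
                if cand < best:
                    best = cand
        W[j] = best
    return V, WM, W


@dataclass(frozen=True)
class FoldResult:
    """MFE fold of one sequence: dot-bracket string and energy in kcal/mol."""

    structure: str
    mfe: float
    pairs: tuple[int, ...]  # partner index per position, -1 if unpaired

    def pair_map(self) -> dict[int, int]:
        return {i: j for i, j in enumerate(self.pairs) if j >= 0}


def _encode(seq: str) -> np.ndarray:
    rna = to_rna(seq)
    try:
        return np.array([_BASES[b] for b in rna], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"sequence contains a non-ACGU(T) base: {exc}") from None


def fold(seq: str, *, allow_gu: bool = True) -> FoldResult:
    """Fold ``seq`` (RNA or DNA alphabet) to its minimum-free-energy structure.

    Parameters
    ----------
    seq:
        15-400 nt over ACGU/ACGT.
    allow_gu:
        permit G:U wobble pairs (default).  Disabling restricts the model to
        Watson-Crick pairs.

    Returns
    -------
    FoldResult with a balanced dot-bracket structure of the same length and
    ``mfe <= 0`` kcal/mol (the open chain scores exactly 0).
    """
    n = len(seq)
    if not MIN_LEN <= n <= MAX_LEN:
        raise ValueError(f"sequence length {n} outside [{MIN_LEN}, {MAX_LEN}]")
    enc = _encode(seq)
    pairmat = _PAIRMAT_GU if allow_gu else _PAIRMAT_WC
    V, WM, W = _fill(
        enc, pairmat, _STACK, MIN_HAIRPIN_LOOP, MAX_INTERIOR_LOOP,
        _HAIRPIN_INIT, _HAIRPIN_PER_NT, _BULGE_INIT, _BULGE_PER_NT,
        _INTERNAL_INIT, _INTERNAL_PER_NT, _INTERNAL_ASYM,
        _ML_CLOSE, _ML_BRANCH, _ML_UNPAIRED, _INF,
    )
    pairs = [-1] * n
    _trace_external(enc, pairmat, V, WM, W, n, pairs)
    struct = "".join(
        "." if p < 0 else ("(" if p > i else ")") for i, p in enumerate(pairs)
    )
    return FoldResult(structure=struct, mfe=int(W[n]) / 100.0, pairs=tuple(pairs))


# ---------------------------------------------------------------------------
# traceback (pure python; reads the filled matrices, mirrors the fill order)

def _trace_external(enc, pairmat, V, WM, W, j, pairs) -> None:
    while j > 0:
        if W[j] == W[j - 1]:
            j -= 1
            continue
        for i in range(j - 1):
            if V[i, j - 1] < _INF and W[j] == W[i] + V[i, j - 1]:
                _trace_V(enc, pairmat, V, WM, i, j - 1, pairs)
                j = i
                break
        else:  # numerical impossibility guard
            raise AssertionError("external traceback failed")


def _trace_V(enc, pairmat, V, WM, i, j, pairs) -> None:
    pairs[i], pairs[j] = j, i
    e = V[i, j]
    p = pairmat[enc[i], enc[j]]
    if e == hairpin_energy(j - i - 1):
        return
    for k in range(i + 1, j):
        n1 = k - i - 1
        if n1 > MAX_INTERIOR_LOOP:
            break
        for l in range(j - 1, k, -1):
            n2 = j - 1 - l
            if n1 + n2 > MAX_INTERIOR_LOOP:
                break
            q = pairmat[enc[k], enc[l]]
            if q < 0 or V[k, l] >= _INF:
                continue
            if e == V[k, l] + interior_energy(p, q, n1, n2):
                _trace_V(enc, pairmat, V, WM, k, l, pairs)
                return
    for k in range(i + 2, j - 1):
        if WM[i + 1, k] < _INF and WM[k + 1, j - 1] < _INF and \
                e == _ML_CLOSE + _ML_BRANCH + WM[i + 1, k] + WM[k + 1, j - 1]:
            _trace_WM(enc, pairmat, V, WM, i + 1, k, pairs)
            _trace_WM(enc, pairmat, V, WM, k + 1, j - 1, pairs)
            return
    raise AssertionError("paired traceback failed")


def _trace_WM(enc, pairmat, V, WM, i, j, pairs) -> None:
    e = WM[i, j]
    if V[i, j] < _INF and e == V[i, j] + _ML_BRANCH:
        _trace_V(enc, pairmat, V, WM, i, j, pairs)
        return
    if j - 1 >= i and WM[i, j - 1] < _INF and e == WM[i, j - 1] + _ML_UNPAIRED:
        _trace_WM(enc, pairmat, V, WM, i, j - 1, pairs)
        return
    if i + 1 <= j and WM[i + 1, j] < _INF and e == WM[i + 1, j] + _ML_UNPAIRED:
        _trace_WM(enc, pairmat, V, WM, i + 1, j, pairs)
        return
    for k in range(i + 1, j):
        if WM[i, k] < _INF and WM[k + 1, j] < _INF and e == WM[i, k] + WM[k + 1, j]:
            _trace_WM(enc, pairmat, V, WM, i, k, pairs)
            _trace_WM(enc, pairmat, V, WM, k + 1, j, pairs)
            return
    raise AssertionError("multiloop traceback failed")


# ---------------------------------------------------------------------------
# independent structure evaluation (loop decomposition)

def pairs_from_dotbracket(structure: str) -> list[int]:
    """Partner index per position (-1 unpaired); raises on unbalanced input."""
    stack: list[int] = []
    pairs = [-1] * len(structure)
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            pairs[i], pairs[j] = j, i
        elif c != ".":
            raise ValueError(f"bad dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pairs


def structure_energy(seq: str, structure: str | list[int] | tuple[int, ...],
                     *, allow_gu: bool = True) -> float:
    """Energy (kcal/mol) of a given nested structure under the model.

    Accepts a dot-bracket string or a partner list.  Every annotated pair
    must be Watson-Crick (or G:U when ``allow_gu``); hairpin loops must hold
    at least 3 unpaired nt.  Computed by loop decomposition, without any
    optimization machinery, so it can audit the DP.
    """
    enc = _encode(seq)
    pairs = pairs_from_dotbracket(structure) if isinstance(structure, str) \
        else list(structure)
    if len(pairs) != len(seq):
        raise ValueError("structure length != sequence length")
    pairmat = _PAIRMAT_GU if allow_gu else _PAIRMAT_WC
    for i, j in enumerate(pairs):
        if j < 0:
            continue
        if pairs[j] != i:
            raise ValueError("inconsistent pair list")
        if i < j:
            if pairmat[enc[i], enc[j]] < 0:
                raise ValueError(f"bases {i},{j} cannot pair")
            if j - i - 1 < MIN_HAIRPIN_LOOP and not any(
                    pairs[k] >= 0 for k in range(i + 1, j)):
                raise ValueError("hairpin loop shorter than 3 nt")
    total = 0
    for i, j in enumerate(pairs):
        if 0 <= j and i < j:
            total += _loop_energy(enc, pairmat, pairs, i, j)
    return total / 100.0


def _children(pairs: list[int], i: int, j: int) -> list[tuple[int, int]]:
    """Pairs immediately interior to (i, j)."""
    out = []
    k = i + 1
    while k < j:
        if pairs[k] > k:
            out.append((k, pairs[k]))
            k = pairs[k] + 1
        else:
            k += 1
    return out

def _loop_energy(enc, pairmat, pairs: list[int], i: int, j: int) -> int:
    kids = _children(pairs, i, j)
    p = pairmat[enc[i], enc[j]]
    if not kids:
        return hairpin_energy(j - i - 1)
    if len(kids) == 1:
        (k, l), = kids
        q = pairmat[enc[k], enc[l]]
        return interior_energy(p, q, k - i - 1, j - l - 1)
    unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
    return (_ML_CLOSE + _ML_BRANCH * (1 + len(kids))
            + _ML_UNPAIRED * unpaired)
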