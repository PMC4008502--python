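"""Minimum-free-energy RNA secondary structure prediction.

A self-contained nearest-neighbor folding engine tailored to miRNA
precursor stem-loops.  The model scores

* helix stacks between directly adjacent base pairs (Watson-Crick and
  G-U wobble pairs) with a stacking free-energy table,
* hairpin loops, bulges and internal loops with length-dependent
  destabilizing penalties (Jacobson-Stockmayer extrapolation beyond the
  tabulated sizes),

over the space of pseudoknot-free structures without multiloops: every
helix is a chain of nested pairs interrupted only by bulges/internal
loops, and several independent stem-loops may sit side by side on the
exterior loop.  This is exactly the architecture of a pre-miRNA, and it
keeps the structure space small enough that an exhaustive enumeration
over the same energy model is feasible for short sequences, which is how
the engine is validated.

Energies are in kcal/mol at 37 degrees C.  Absolute values track the
Turner rules only approximately (G-U stacks use a flat average); the
stability threshold applied downstream refers to this model.

A different folding backend (for example an external thermodynamic
package) can be plugged in wherever a ``fold_fn`` argument is accepted;
any callable ``seq -> FoldResult`` qualifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "FoldResult",
    "fold_mfe",
    "structure_energy",
    "pairs_to_dotbracket",
    "dotbracket_to_pairs",
    "can_pair",
]

_RT37 = 0.616  # kcal/mol, for loop-size extrapolation

_VALID = set("ACGU")

# Watson-Crick and wobble pairs
_PAIRS = {
    ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "U"), ("U", "G"),
}

_WOBBLE = {("G", "U"), ("U", "G")}

# Stacking free energies, kcal/mol.  Key: (outer 5' base, outer 3' base,
# inner 5' base, inner 3' base) for the stack
#   5'-X W-3'
#   3'-Y Z-5'
# keyed as (X, Y, W, Z).  Watson-Crick x Watson-Crick values follow the
# standard nearest-neighbor table; stacks involving a wobble pair use a
# flat average (-1.0, or -0.5 for wobble-on-wobble).
_WC_STACK = {
    ("A", "U", "A", "U"): -0.93,
    ("A", "U", "U", "A"): -1.10,
    ("A", "U", "C", "G"): -2.24,
    ("A", "U", "G", "C"): -2.08,
    ("U", "A", "A", "U"): -1.33,
    ("U", "A", "U", "A"): -0.93,
    ("U", "A", "C", "G"): -2.35,
    ("U", "A", "G", "C"): -2.11,
    ("C", "G", "A", "U"): -2.11,
    ("C", "G", "U", "A"): -2.08,
    ("C", "G", "C", "G"): -3.26,
    ("C", "G", "G", "C"): -2.36,
    ("G", "C", "A", "U"): -2.35,
    ("G", "C", "U", "A"): -2.24,
    ("G", "C", "C", "G"): -3.42,
    ("G", "C", "G", "C"): -3.26,
}

_GU_STACK = -1.0
_GU_GU_STACK = -0.5

# Destabilizing loop penalties by number of unpaired nucleotides.
_HAIRPIN_PEN = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE_PEN = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL_PEN = {2: 1.7, 3: 1.8, 4: 2.0, 5: 2.2, 6: 2.5}
_ASYM_PEN = 0.5    # per nt of internal-loop asymmetry
_ASYM_CAP = 3.0

# Interior-loop size caps (per side / total unpaired between consecutive
# pairs of a helix).  Keeps both the DP and the enumeration oracle small.
MAX_GAP_SIDE = 6
MAX_GAP_TOTAL = 8

MIN_HAIRPIN_LOOP = 3

_INF = float("inf")


def can_pair(a: str, b: str) -> bool:
    """True if bases a,b form a Watson-Crick or G-U wobble pair."""
    return (a, b) in _PAIRS


def _extrapolate(base: float, base_n: int, n: int) -> float:
    return base + 1.75 * _RT37 * math.log(n / base_n)


def hairpin_penalty(n: int) -> float:
    """Free-energy cost of a hairpin loop of n unpaired nucleotides."""
    if n < MIN_HAIRPIN_LOOP:
        return _INF
    if n in _HAIRPIN_PEN:
        return _HAIRPIN_PEN[n]
    return _extrapolate(_HAIRPIN_PEN[9], 9, n)


def interior_penalty(d1: int, d2: int) -> float:
    """Cost of the gap between consecutive helix pairs.

    d1/d2 are the unpaired counts on the 5' and 3' side.  (0,0) is a
    stack and costs nothing here (the stacking bonus is added
    separately); one-sided gaps are bulges, two-sided gaps internal
    loops with an asymmetry penalty.
    """
    if d1 == 0 and d2 == 0:
        return 0.0
    if d1 > MAX_GAP_SIDE or d2 > MAX_GAP_SIDE or d1 + d2 > MAX_GAP_TOTAL:
        return _INF
    n = d1 + d2
    if d1 == 0 or d2 == 0:
        if n in _BULGE_PEN:
            return _BULGE_PEN[n]
        return _extrapolate(_BULGE_PEN[6], 6, n)
    pen = _INTERNAL_PEN.get(n, _extrapolate(_INTERNAL_PEN[6], 6, n))
    return pen + min(_ASYM_CAP, _ASYM_PEN * abs(d1 - d2))


def stack_energy(x: str, y: str, w: str, z: str) -> float:
    """Stacking energy of inner pair (w,z) on outer pair (x,y)."""
    key = (x, y, w, z)
    if key in _WC_STACK:
        return _WC_STACK[key]
    if (x, y) in _PAIRS and (w, z) in _PAIRS:
        if (x, y) in _WOBBLE and (w, z) in _WOBBLE:
            return _GU_GU_STACK
        return _GU_STACK
    raise ValueError(f"not a stack of valid pairs: {key}")


@dataclass(frozen=True)
class FoldResult:
    """An MFE structure: sequence, dot-bracket string, energy in kcal/mol."""

    sequence: str
    structure: str
    mfe: float

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return dotbracket_to_pairs(self.structure)


def pairs_to_dotbracket(n: int, pairs: list[tuple[int, int]]) -> str:
    s = ["."] * n
    for i, j in pairs:
        s[i] = "("
        s[j] = ")"
    return "".join(s)


def dotbracket_to_pairs(structure: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    out = []
    for k, c in enumerate(structure):
        if c == "(":
            stack.append(k)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            out.append((stack.pop(), k))
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return sorted(out)


def _normalize(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"invalid RNA characters: {sorted(bad)}")
    return s


def structure_energy(seq: str, pairs: list[tuple[int, int]]) -> float:
    """Energy of an explicit structure under the model.

    ``pairs`` must describe a pseudoknot-free, multiloop-free structure
    (each helix a nested chain).  Used both by the folding engine's
    consistency checks and by the enumeration oracle in the test suite.
    """
    seq = _normalize(seq)
    if not pairs:
        return 0.0
    pairs = sorted(pairs)
    # group pairs into helix chains: children strictly nested, no branching
    # build nesting forest
    energy = 0.0
    # identify, for each pair, its immediately enclosing pair
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    stack: list[tuple[int, int]] = []
    for p in pairs:
        i, j = p
        if not can_pair(seq[i], seq[j]):
            raise ValueError(f"unpairable bases at {p}")
        while stack and stack[-1][1] < j:
            stack.pop()
        parent[p] = stack[-1] if stack else None
        if stack and not (stack[-1][0] < i and j < stack[-1][1]):
            raise ValueError("pseudoknotted structure")
        stack.append(p)
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {}
    for p, par in parent.items():
        children.setdefault(par, []).append(p)
    for par, kids in children.items():
        if par is not None and len(kids) > 1:
            raise ValueError("multiloop structures are outside the model")
    for p in pairs:
        i, j = p
        kids = children.get(p, [])
        if not kids:
            energy += hairpin_penalty(j - i - 1)
        else:
            k, l = kids[0]
            d1, d2 = k - i - 1, j - l - 1
            gap = interior_penalty(d1, d2)
            if gap == _INF:
                raise ValueError("interior loop exceeds model size caps")
            energy += gap
            if d1 == 0 and d2 == 0:
                energy += stack_energy(seq[i], seq[j], seq[k], seq[l])
    return energy


def _gap_offsets() -> list[tuple[int, int]]:
    out = []
    for d1 in range(MAX_GAP_SIDE + 1):
        for d2 in range(MAX_GAP_SIDE + 1):
            if d1 + d2 <= MAX_GAP_TOTAL:
                out.append((d1, d2))
    return out

_GAPS = _gap_offsets()


def fold_mfe(sequence: str) -> FoldResult:
    """Fold a sequence into its MFE stem-loop structure.

    Dynamic program over helix chains: V[i][j] is the best energy of a
    stem whose outermost pair is (i, j); the exterior loop combines
    non-overlapping stems additively.  The all-unpaired structure has
    energy 0, so the reported MFE is never positive.
    """
    seq = _normalize(sequence)
    n = len(seq)
    if n == 0:
        return FoldResult(seq, "", 0.0)

    pairable = [[can_pair(seq[i], seq[j]) for j in range(n)] for i in range(n)]
    V = [[_INF] * n for _ in range(n)]
    # choice[i][j]: None = not computed/unpairable, (-1,-1) = hairpin,
    # (d1,d2) = inner pair at (i+1+d1, j-1-d2)
    choice: list[list[tuple[int, int] | None]] = [[None] * n for _ in range(n)]

    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            if not pairable[i][j]:
                continue
            best = hairpin_penalty(j - i - 1)
            best_choice = (-1, -1)
            for d1, d2 in _GAPS:
                k = i + 1 + d1
                l = j - 1 - d2
                if k + MIN_HAIRPIN_LOOP >= l:
                    continue
                inner = V[k][l]
                if inner == _INF:
                    continue
                if d1 == 0 and d2 == 0:
                    cand = inner + stack_energy(seq[i], seq[j], seq[k], seq[l])
                else:
                    cand = inner + interior_penalty(d1, d2)
                if cand < best:
                    best = cand
                    best_choice = (d1, d2)
            V[i][j] = best
            choice[i][j] = best_choice

    # exterior loop: W[j] = best energy of prefix seq[0..j]
    W = [0.0] * (n + 1)
    wchoice: list[tuple[int, int] | None] = [None] * (n + 1)  # stem (i,j) ending at j
    for j in range(1, n + 1):
        W[j] = W[j - 1]
        wchoice[j] = None
        for i in range(j - 1):
            v = V[i][j - 1]
            if v < _INF and W[i] + v < W[j]:
                W[j] = W[i] + v
                wchoice[j] = (i, j - 1)
    mfe = W[n]

    pairs: list[tuple[int, int]] = []

    def trace_stem(i: int, j: int) -> None:
        while True:
            pairs.append((i, j))
            ch = choice[i][j]
            if ch == (-1, -1) or ch is None:
                return
            d1, d2 = ch
            i, j = i + 1 + d1, j - 1 - d2

    j = n
    while j > 0:
        ch = wchoice[j]
        if ch is None:
            j -= 1
        else:
            i, jj = ch
            trace_stem(i, jj)
            j = i

    if mfe >= 0.0:
        mfe, pairs = 0.0, []
    structure = pairs_to_dotbracket(n, sorted(pairs))
    return FoldResult(seq, structure, round(mfe, 10))
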