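"""Independent brute-force oracles used across the test suite.

Each oracle recomputes a quantity by a route deliberately different
from the library implementation: exact rational arithmetic for the
count-model tail sums, explicit structure enumeration (or memoized
exhaustive search) for folding, literal offset/strand scans for
alignment, and direct re-derivation of duplex stack sums.
"""

from __future__ import annotations

import functools
from fractions import Fraction

from smirna.fold import (
    MAX_GAP_SIDE,
    MAX_GAP_TOTAL,
    MIN_HAIRPIN_LOOP,
    can_pair,
    hairpin_penalty,
    interior_penalty,
    stack_energy,
    structure_energy,
)

_GAPS = [
    (d1, d2)
    for d1 in range(MAX_GAP_SIDE + 1)
    for d2 in range(MAX_GAP_SIDE + 1)
    if d1 + d2 <= MAX_GAP_TOTAL
]

_INF = float("inf")


# ---------------------------------------------------------------- counts

def ac_tails_exact(x: int, y: int, N1: int, N2: int) -> tuple[Fraction, Fraction]:
    """Exact (lower, upper) tail probabilities of the two-library count model.

    p(k | x) = (N2/N1)^k (x+k)! / (x! k! (1+N2/N1)^(x+k+1)), summed with
    exact rational arithmetic; upper = P(K >= y) = 1 - P(K <= y-1).
    """
    r = Fraction(N2, N1)
    p = Fraction(1) / (1 + r) ** (x + 1)   # p(0|x)
    lower = Fraction(0)
    p_at_y = p
    for k in range(y + 1):
        lower += p
        if k == y:
            p_at_y = p
        p = p * r * (x + k + 1) / ((k + 1) * (1 + r))
    upper = 1 - (lower - p_at_y)
    return lower, upper


def ac_pvalue_exact(x: int, y: int, N1: int, N2: int) -> float:
    lower, upper = ac_tails_exact(x, y, N1, N2)
    return float(min(Fraction(1), 2 * min(lower, upper)))


def ac_pvalue_grid_exact(x: int, ymax: int, N1: int, N2: int) -> list[float]:
    """ac_pvalue_exact(x, y) for all y in 0..ymax, in one rational sweep."""
    r = Fraction(N2, N1)
    p = Fraction(1) / (1 + r) ** (x + 1)
    lower = Fraction(0)
    out = []
    for k in range(ymax + 1):
        lower += p
        upper = 1 - (lower - p)
        out.append(float(min(Fraction(1), 2 * min(lower, upper))))
        p = p * r * (x + k + 1) / ((k + 1) * (1 + r))
    return out


# --------------------------------------------------------------- folding

def enumerate_structures(seq: str):
    """Yield every structure in the model's space as a list of pairs.

    Helix chains (nested pairs with bounded interior gaps) placed
    side by side on the exterior loop; the empty structure included.
    Exponential in length - intended for sequences up to ~26 nt.
    """
    seq = seq.upper().replace("T", "U")
    n = len(seq)

    def stems_from(i: int, j: int):
        if not can_pair(seq[i], seq[j]):
            return
        if j - i - 1 >= MIN_HAIRPIN_LOOP:
            yield [(i, j)]
        for d1, d2 in _GAPS:
            k, l = i + 1 + d1, j - 1 - d2
            if k + MIN_HAIRPIN_LOOP < l:
                for inner in stems_from(k, l):
                    yield [(i, j)] + inner

    def exterior(start: int):
        yield []
        for i in range(start, n):
            for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
                for stem in stems_from(i, j):
                    for rest in exterior(j + 1):
                        yield stem + rest

    yield from exterior(0)


def mfe_enumerated(seq: str) -> float:
    """MFE by scoring every enumerated structure (sequences <= ~26 nt)."""
    best = 0.0
    for pairs in enumerate_structures(seq):
        e = structure_energy(seq, pairs)
        if e < best:
            best = e
    return best


def mfe_exhaustive_search(seq: str) -> float:
    """MFE by memoized top-down exhaustive search over the same space."""
    seq = seq.upper().replace("T", "U")
    n = len(seq)

    @functools.lru_cache(maxsize=None)
    def stem(i: int, j: int) -> float:
        if not can_pair(seq[i], seq[j]):
            return _INF
        best = hairpin_penalty(j - i - 1)
        for d1, d2 in _GAPS:
            k, l = i + 1 + d1, j - 1 - d2
            if k + MIN_HAIRPIN_LOOP < l:
                s = stem(k, l)
                if s < _INF:
                    if d1 == 0 and d2 == 0:
                        cost = stack_energy(seq[i], seq[j], seq[k], seq[l])
                    else:
                        cost = interior_penalty(d1, d2)
                    best = min(best, s + cost)
        return best

    @functools.lru_cache(maxsize=None)
    def exterior(i: int) -> float:
        if i >= n:
            return 0.0
        best = exterior(i + 1)
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
            s = stem(i, j)
            if s < _INF:
                best = min(best, s + exterior(j + 1))
        return best

    return min(0.0, exterior(0))


# ------------------------------------------------------------- alignment

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp_brute(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def align_brute(
    tag: str, ref: str, max_mismatch: int, both_strands: bool
) -> set[tuple[int, str, int]]:
    """Every (start, strand, mismatches) placement by literal scanning."""
    tag = tag.upper().replace("U", "T")
    ref = ref.upper().replace("U", "T")
    m = len(tag)
    out = set()
    for start in range(len(ref) - m + 1):
        mm = sum(1 for k in range(m) if ref[start + k] != tag[k])
        if mm <= max_mismatch:
            out.add((start, "+", mm))
    if both_strands:
        rc = revcomp_brute(ref)
        for start in range(len(rc) - m + 1):
            mm = sum(1 for k in range(m) if rc[start + k] != tag[k])
            if mm <= max_mismatch:
                out.add((len(ref) - start - m, "-", mm))
    return out


# ----------------------------------------------------------------- duplex

_RNA_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def duplex_energy_brute(mirna: str, site: str) -> float:
    """Stack-sum duplex energy recomputed from the raw sequences.

    Re-derives which positions pair (WC or G-U against the antiparallel
    site) and sums stacking terms over adjacent paired positions.
    """
    mirna = mirna.upper().replace("T", "U")
    site = site.upper().replace("T", "U")
    L = len(mirna)
    partner: list[str | None] = []
    for k in range(L):
        idx = len(site) - 1 - k
        if 0 <= idx < len(site):
            b = site[idx]
            paired = _RNA_COMP[mirna[k]] == b or {mirna[k], b} == {"G", "U"}
            partner.append(b if paired else None)
        else:
            partner.append(None)
    e = 0.0
    for k in range(L - 1):
        if partner[k] is not None and partner[k + 1] is not None:
            e += stack_energy(mirna[k], partner[k], mirna[k + 1], partner[k + 1])
    return e
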