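"""Rule-based miRNA target prediction on 3'UTR sequences.

A site is predicted when it is found by *both* of two independent
screens, mirroring the common practice of intersecting a seed-match
scanner with a thermodynamic duplex filter:

1. a seed scan that requires complementarity of the UTR site to miRNA
   positions 2-8 (classes 8mer, 7mer-m8, 7mer-A1), and
2. a six-rule filter on the position-wise miRNA:target duplex:
   (i)   no more than 4 weighted mismatches (G-U wobbles count 0.5),
   (ii)  no run of more than two adjacent mismatches anywhere,
   (iii) no adjacent mismatches in positions 2-12,
   (iv)  no mismatch at positions 10-11,
   (v)   no more than 2.5 weighted mismatches in positions 1-12,
   (vi)  duplex MFE at least 75% of the MFE of the miRNA bound to its
         perfect complement.

Positions are numbered 1..L from the miRNA 5' end.  G-U wobbles count
as half a mismatch for the weighted totals (i, v) and as *paired* for
the adjacency rules (ii-iv).  The duplex is gap-free (position-wise
antiparallel); bulged sites are out of scope.  Duplex energies sum the
nearest-neighbor stacking terms over runs of consecutive paired
positions, sharing the energy table of the folding engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from . import fold

__all__ = [
    "PairState",
    "DuplexAlignment",
    "TargetSite",
    "duplex_align",
    "count_mismatches",
    "mfe_ratio",
    "apply_rules",
    "seed_match_scan",
    "predict_targets",
    "RULE_NAMES",
]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

RULE_NAMES = (
    "max_weighted_mismatches",
    "no_three_adjacent_mismatches",
    "no_adjacent_mismatches_2_12",
    "no_mismatch_10_11",
    "max_weighted_mismatches_1_12",
    "mfe_ratio_ge_0.75",
)


class PairState(str, Enum):
    WC = "WC"
    GU = "GU"
    MISMATCH = "MM"


@dataclass(frozen=True)
class DuplexAlignment:
    """Gap-free antiparallel miRNA:site duplex.

    ``states[k]`` is the pairing state of miRNA position k+1 (1-based
    position k+1 counts from the miRNA 5' end).  ``mfe`` is the duplex
    energy; ``perfect_mfe`` the energy of the miRNA bound to its exact
    complement.
    """

    mirna: str
    site: str
    states: tuple[PairState, ...]
    mfe: float
    perfect_mfe: float


@dataclass(frozen=True)
class TargetSite:
    utr_name: str
    start: int            # 0-based half-open on the UTR
    end: int
    mirna_name: str
    seed_class: str       # 8mer | 7mer-m8 | 7mer-A1 | none
    duplex: DuplexAlignment
    weighted_mismatches: float
    rule_verdicts: tuple[bool, ...] = field(default=())

    @property
    def predicted(self) -> bool:
        return self.seed_class != "none" and all(self.rule_verdicts)


def _norm_rna(s: str) -> str:
    return s.upper().replace("T", "U")


def _pair_state(a: str, b: str) -> PairState:
    if _COMPLEMENT.get(a) == b:
        return PairState.WC
    if (a, b) in ((("G"), ("U")), (("U"), ("G"))):
        return PairState.GU
    return PairState.MISMATCH


def _duplex_energy(mirna: str, partners: list[str | None]) -> float:
    """Sum stacking terms over consecutive paired positions.

    partners[k] is the site base opposite miRNA position k+1, or None
    where unpaired/mismatched.  Only stacks between two adjacent paired
    positions contribute; isolated pairs and loops contribute nothing.
    """
    e = 0.0
    for k in range(len(mirna) - 1):
        b1, b2 = partners[k], partners[k + 1]
        if b1 is None or b2 is None:
            continue
        # stack geometry: miRNA runs 5'->3', site antiparallel
        e += fold.stack_energy(mirna[k], b1, mirna[k + 1], b2)
    return e


def duplex_align(mirna: str, site: str) -> DuplexAlignment:
    """Align a miRNA against a candidate site, position by position.

    The site is given 5'->3' on the UTR; miRNA position k pairs with
    site position (len(site) - k), i.e. the miRNA 5' end faces the site
    3' end.  Site length must be within +-4 of the miRNA length; any
    miRNA position with no opposing site base scores as a mismatch.
    """
    mirna = _norm_rna(mirna)
    site = _norm_rna(site)
    L = len(mirna)
    if abs(len(site) - L) > 4:
        raise ValueError(
            f"site length {len(site)} differs from miRNA length {L} by more "
            "than 4; bulged-site alignment is not supported"
        )
    states = []
    partners: list[str | None] = []
    for k in range(L):
        site_idx = len(site) - 1 - k
        if 0 <= site_idx < len(site):
            st = _pair_state(mirna[k], site[site_idx])
            states.append(st)
            partners.append(site[site_idx] if st != PairState.MISMATCH else None)
        else:
            states.append(PairState.MISMATCH)
            partners.append(None)
    mfe = _duplex_energy(mirna, partners)
    perfect = [_COMPLEMENT[b] for b in mirna]
    perfect_mfe = _duplex_energy(mirna, perfect)
    return DuplexAlignment(mirna, site, tuple(states), mfe, perfect_mfe)


def count_mismatches(duplex: DuplexAlignment) -> float:
    """Weighted mismatch count: mismatch = 1.0, G-U wobble = 0.5."""
    return sum(
        1.0 if s == PairState.MISMATCH else 0.5 if s == PairState.GU else 0.0
        for s in duplex.states
    )


def mfe_ratio(duplex: DuplexAlignment) -> float:
    """Duplex MFE as a fraction of the perfect-complement MFE."""
    if duplex.perfect_mfe >= 0.0:
        raise ValueError("perfect-complement MFE must be negative")
    return max(0.0, duplex.mfe / duplex.perfect_mfe)


def apply_rules(
    duplex: DuplexAlignment,
    *,
    max_weighted_mismatches: float = 4.0,
    max_weighted_mismatches_1_12: float = 2.5,
    min_mfe_ratio: float = 0.75,
) -> tuple[tuple[bool, ...], bool]:
    """Evaluate the six duplex rules; returns (verdicts, overall)."""
    states = duplex.states
    mm = [s == PairState.MISMATCH for s in states]
    w = count_mismatches(duplex)

    r1 = w <= max_weighted_mismatches

    longest_run = run = 0
    for m in mm:
        run = run + 1 if m else 0
        longest_run = max(longest_run, run)
    r2 = longest_run <= 2

    # positions 2-12, 1-based -> indices 1..11
    r3 = not any(mm[k] and mm[k + 1] for k in range(1, min(11, len(mm) - 1)))

    r4 = not any(mm[k] for k in (9, 10) if k < len(mm))

    w12 = sum(
        1.0 if s == PairState.MISMATCH else 0.5 if s == PairState.GU else 0.0
        for s in states[:12]
    )
    r5 = w12 <= max_weighted_mismatches_1_12

    r6 = mfe_ratio(duplex) >= min_mfe_ratio

    verdicts = (r1, r2, r3, r4, r5, r6)
    return verdicts, all(verdicts)


def seed_match_scan(mirna: str, utr: str) -> list[tuple[int, int, str]]:
    """Find canonical seed-match sites on a UTR.

    Returns (start, end, seed_class) with half-open UTR coordinates of
    the seed-paired region (plus the position-1 'A' where applicable).
    Classes: 8mer (positions 2-8 paired + A opposite position 1),
    7mer-m8 (positions 2-8 paired), 7mer-A1 (positions 2-7 paired + A).
    """
    mirna = _norm_rna(mirna)
    utr = _norm_rna(utr)
    if len(utr) < 8 or len(mirna) < 8:
        return []
    # UTR site read 5'->3' is the reverse complement of the seed
    seed27 = mirna[1:7]
    seed28 = mirna[1:8]
    rc27 = "".join(_COMPLEMENT[b] for b in reversed(seed27))
    rc28 = "".join(_COMPLEMENT[b] for b in reversed(seed28))
    hits = []
    for s in range(len(utr) - 5):
        if utr[s : s + 7] == rc28:
            has_a1 = s + 7 < len(utr) and utr[s + 7] == "A"
            if has_a1:
                hits.append((s, s + 8, "8mer"))
            else:
                hits.append((s, s + 7, "7mer-m8"))
        elif utr[s : s + 6] == rc27 and s + 6 < len(utr) and utr[s + 6] == "A":
            hits.append((s, s + 7, "7mer-A1"))
    return hits


def predict_targets(
    mirnas: dict[str, str],
    utrs: dict[str, str],
    *,
    max_weighted_mismatches: float = 4.0,
    max_weighted_mismatches_1_12: float = 2.5,
    min_mfe_ratio: float = 0.75,
) -> list[TargetSite]:
    """Scan every miRNA against every UTR and apply the full filter.

    A site is ``predicted`` iff it carries a canonical seed class AND
    passes all six duplex rules.  Sites are returned for every seed hit
    (pass or fail) ordered by UTR name, coordinate, then miRNA name.
    """
    out: list[TargetSite] = []
    for utr_name in sorted(utrs):
        utr = _norm_rna(utrs[utr_name])
        for mir_name in sorted(mirnas):
            mirna = _norm_rna(mirnas[mir_name])
            L = len(mirna)
            for s, e, seed_class in seed_match_scan(mirna, utr):
                # the seed's m8-facing end is at UTR position s; miRNA
                # position 8 pairs there, so the full site spans
                # [site_end - L, site_end) with site_end = s + 8.
                site_end = s + 8
                site_start = site_end - L
                if site_start < 0 or site_end > len(utr):
                    continue
                site = utr[site_start:site_end]
                duplex = duplex_align(mirna, site)
                verdicts, _ = apply_rules(
                    duplex,
                    max_weighted_mismatches=max_weighted_mismatches,
                    max_weighted_mismatches_1_12=max_weighted_mismatches_1_12,
                    min_mfe_ratio=min_mfe_ratio,
                )
                out.append(
                    TargetSite(
                        utr_name=utr_name,
                        start=site_start,
                        end=site_end,
                        mirna_name=mir_name,
                        seed_class=seed_class,
                        duplex=duplex,
                        weighted_mismatches=count_mismatches(duplex),
                        rule_verdicts=verdicts,
                    )
                )
    out.sort(key=lambda t: (t.utr_name, t.start, t.mirna_name))
    return out
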