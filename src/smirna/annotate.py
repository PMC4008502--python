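"""Tag alignment, priority annotation, and known-miRNA quantification.

Unique tags are aligned against class-labeled reference FASTA sets
(ncRNA decoys, mature miRNAs, genome) allowing at most one substitution
and no indels, then assigned a single class by a fixed priority:

    rRNA > tRNA > snRNA > snoRNA > repeat > miRNA > genome > unannotated

so that degradation fragments of structural RNAs are filtered out
before anything is credited to a miRNA, and only tags matching nothing
but the genome go on to novel-miRNA discovery.

Alignment is an exhaustive sliding-window scan (vectorized with numpy),
searching both strands for genome-class references and the forward
strand only for the short annotation references.  Mature-miRNA matching
additionally tolerates +-2 nt terminal offsets (isomiRs): the tag may
start up to 2 nt before the annotated mature 5' end and overhang the 3'
end, with overhanging positions excluded from the mismatch count but at
least 18 nt of overlap required.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .preprocess import UniqueTag

__all__ = [
    "AlignmentHit",
    "NamedSeq",
    "CLASS_PRIORITY",
    "align_tag",
    "align_tag_isomir",
    "classify",
    "quantify_mirnas",
    "top_k_report",
    "revcomp",
]

CLASS_PRIORITY = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "miRNA", "genome")

_COMP = str.maketrans("ACGTUN", "TGCAAN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


@dataclass(frozen=True)
class NamedSeq:
    name: str
    sequence: str


@dataclass(frozen=True)
class AlignmentHit:
    tag: str
    reference: str
    ref_class: str
    start: int      # 0-based on the reference, half-open end = start + len(tag)
    strand: str     # '+' | '-'
    mismatches: int


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _scan(tag_arr: np.ndarray, ref_arr: np.ndarray, max_mismatch: int) -> list[tuple[int, int]]:
    """All placements of tag in ref with <= max_mismatch substitutions."""
    m, n = len(tag_arr), len(ref_arr)
    if m > n:
        return []
    mism = np.zeros(n - m + 1, dtype=np.int32)
    for k in range(m):
        mism += ref_arr[k : n - m + 1 + k] != tag_arr[k]
        # early exit cannot help vectorized form; m is ~22
    idx = np.nonzero(mism <= max_mismatch)[0]
    return [(int(i), int(mism[i])) for i in idx]


def align_tag(
    tag: str,
    references: Sequence[NamedSeq],
    ref_class: str,
    max_mismatch: int = 1,
    both_strands: bool = False,
) -> list[AlignmentHit]:
    """Exhaustively align a tag against a reference set.

    Returns every placement with at most ``max_mismatch`` substitutions,
    on the forward strand (and the reverse strand when ``both_strands``,
    with ``start`` given on the forward reference coordinates).
    """
    if not references:
        raise ValueError("reference set must be non-empty")
    tag_arr = _encode(tag.replace("U", "T"))
    hits: list[AlignmentHit] = []
    for ref in references:
        ref_seq = ref.sequence.upper().replace("U", "T")
        ref_arr = _encode(ref_seq)
        for start, mm in _scan(tag_arr, ref_arr, max_mismatch):
            hits.append(AlignmentHit(tag, ref.name, ref_class, start, "+", mm))
        if both_strands:
            rc_arr = _encode(revcomp(ref_seq))
            n, m = len(ref_arr), len(tag_arr)
            for start_rc, mm in _scan(tag_arr, rc_arr, max_mismatch):
                fwd_start = n - start_rc - m
                hits.append(AlignmentHit(tag, ref.name, ref_class, fwd_start, "-", mm))
    return hits


def align_tag_isomir(
    tag: str,
    matures: Sequence[NamedSeq],
    max_mismatch: int = 1,
    max_offset: int = 2,
    min_overlap: int = 18,
) -> list[tuple[AlignmentHit, int]]:
    """Match a tag against mature miRNAs allowing terminal offsets.

    The tag start may sit at offsets -max_offset..+max_offset relative
    to the mature 5' end; positions outside the mature are not
    compared.  Returns (hit, offset) with mismatches counted over the
    overlap only.  Hits are ordered by (mismatches, |offset|, reference
    order) so the first element is the best assignment.
    """
    tag_d = tag.upper().replace("U", "T")
    results: list[tuple[AlignmentHit, int, int]] = []
    for ref_idx, ref in enumerate(matures):
        mat = ref.sequence.upper().replace("U", "T")
        for off in range(-max_offset, max_offset + 1):
            # tag position k sits at mature position k + off
            lo = max(0, -off)               # first compared tag index
            hi = min(len(tag_d), len(mat) - off)
            overlap = hi - lo
            if overlap < min_overlap:
                continue
            # overhang beyond either mature end capped at max_offset
            if (len(tag_d) - hi) > max_offset or lo > max_offset:
                continue
            mm = sum(
                1 for k in range(lo, hi) if tag_d[k] != mat[k + off]
            )
            if mm <= max_mismatch:
                start = max(0, off)
                results.append(
                    (
                        AlignmentHit(tag, ref.name, "miRNA", start, "+", mm),
                        off,
                        ref_idx,
                    )
                )
    results.sort(key=lambda r: (r[0].mismatches, abs(r[1]), r[2]))
    return [(hit, off) for hit, off, _ in results]


def classify(
    tag: str,
    references: dict[str, Sequence[NamedSeq]],
    max_mismatch: int = 1,
    isomir: bool = True,
) -> str:
    """Assign a tag to the first reference class with a hit.

    ``references`` maps class names (subset of CLASS_PRIORITY) to
    sequence sets; the genome class is searched on both strands.
    Returns 'unannotated' when nothing matches.
    """
    for ref_class in CLASS_PRIORITY:
        refs = references.get(ref_class)
        if not refs:
            continue
        if ref_class == "miRNA" and isomir:
            if align_tag_isomir(tag, refs, max_mismatch):
                return ref_class
        else:
            both = ref_class == "genome"
            if align_tag(tag, refs, ref_class, max_mismatch, both_strands=both):
                return ref_class
    return "unannotated"


def quantify_mirnas(
    tags: Iterable[UniqueTag],
    matures: Sequence[NamedSeq],
    max_mismatch: int = 1,
    isomir: bool = True,
) -> dict[str, int]:
    """Per-miRNA raw counts from a library's unique tags.

    Each tag is credited in full to its single best-matching mature
    (fewest mismatches, then smallest terminal offset, then reference
    order).  miRNAs without any matching tag report zero.
    """
    counts = {m.name: 0 for m in matures}
    for tag in tags:
        if isomir:
            hits = align_tag_isomir(tag.sequence, matures, max_mismatch)
            if hits:
                counts[hits[0][0].reference] += tag.count
        else:
            hits = align_tag(tag.sequence, matures, "miRNA", max_mismatch)
            if hits:
                hits.sort(key=lambda h: (h.mismatches, h.reference))
                counts[hits[0].reference] += tag.count
    return counts


def top_k_report(counts: dict[str, int], k: int = 10) -> list[tuple[str, int, float]]:
    """Top-k miRNAs as (name, count, percent of miRNA-mapped reads)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    total = sum(counts.values())
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    out = []
    for name, c in ranked[:k]:
        pct = 100.0 * c / total if total else 0.0
        out.append((name, c, pct))
    return out
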