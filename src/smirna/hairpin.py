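"""Novel-miRNA discovery from unannotated tags via hairpin criteria.

Tags that match nothing but the genome are candidate mature miRNAs.
For each genomic placement, windows are excised that could hold a
stem-loop precursor with the tag on either arm, folded with the
nearest-neighbor engine, and screened against ten structural and
read-support criteria (the MIREAP-style rule set):

 1. candidate small-RNA length 18-26 nt,
 2. inferred mature length 20-24 nt,
 3. read depth >= 3 at the Drosha/Dicer cut site (reads whose 5' ends
    coincide with the mature 5' end, +-1 nt),
 4. genome copy number of the tag <= 20,
 5. precursor folding free energy <= -18 kcal/mol,
 6. loop spacing between mature and star <= 35 nt,
 7. >= 14 base pairs within the mature/star duplex,
 8. largest bulge (longest unpaired run on either duplex arm) <= 4 nt,
 9. duplex asymmetry (|unpaired on arm 1 - unpaired on arm 2|) <= 5 nt,
10. precursor excised with exactly 10 nt of flanking sequence.

The star span is inferred from the structure assuming the canonical
2-nt 3' overhangs of a Dicer duplex.  A candidate passes overall iff
all ten verdicts hold.  Criteria 8 and 9 are not given formal
definitions in the MIREAP rule list; the operationalizations above are
recorded in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from . import fold
from .annotate import AlignmentHit, NamedSeq, align_tag, revcomp
from .preprocess import UniqueTag

__all__ = [
    "HairpinThresholds",
    "CandidateWindow",
    "HairpinMeasurements",
    "HairpinCandidate",
    "CRITERION_NAMES",
    "fold_mfe",
    "excise_candidates",
    "measure_hairpin",
    "apply_criteria",
    "evaluate_hairpin",
    "discover_novel",
]

fold_mfe = fold.fold_mfe

CRITERION_NAMES = (
    "tag_length_18_26",
    "mature_length_20_24",
    "cut_site_depth_ge_3",
    "copy_number_le_20",
    "mfe_le_-18",
    "loop_spacing_le_35",
    "duplex_pairs_ge_14",
    "bulge_le_4",
    "asymmetry_le_5",
    "flank_eq_10",
)


@dataclass(frozen=True)
class HairpinThresholds:
    """The ten screening thresholds (defaults are the standard rule set)."""

    tag_len_min: int = 18
    tag_len_max: int = 26
    mature_len_min: int = 20
    mature_len_max: int = 24
    min_cut_depth: int = 3
    max_copy_number: int = 20
    max_mfe: float = -18.0          # kcal/mol
    max_spacing: int = 35
    min_duplex_pairs: int = 14
    max_bulge: int = 4
    max_asymmetry: int = 5
    flank: int = 10


@dataclass(frozen=True)
class CandidateWindow:
    """An excised genomic window that may hold a precursor.

    Coordinates are 0-based half-open on the forward genome strand;
    ``sequence`` is the window read 5'->3' on ``strand``.  ``mature_span``
    locates the seeding tag inside the window (window-local,
    orientation-local coordinates).
    """

    genome_name: str
    start: int
    end: int
    strand: str
    sequence: str
    mature_span: tuple[int, int]
    flank: int


@dataclass(frozen=True)
class HairpinMeasurements:
    """Raw quantities the ten criteria are checked against."""

    tag_length: int
    mature_length: int
    cut_site_depth: int
    copy_number: int
    mfe: float
    loop_spacing: int
    duplex_pairs: int
    bulge: int
    asymmetry: int
    flank: int


@dataclass(frozen=True)
class HairpinCandidate:
    window: CandidateWindow
    fold_result: fold.FoldResult
    mature_span: tuple[int, int]
    star_span: tuple[int, int] | None
    measurements: HairpinMeasurements
    verdicts: tuple[bool, ...] = field(default=())

    @property
    def passes(self) -> bool:
        return bool(self.verdicts) and all(self.verdicts)


def apply_criteria(
    m: HairpinMeasurements, thresholds: HairpinThresholds = HairpinThresholds()
) -> tuple[bool, ...]:
    """Check the ten criteria; order matches CRITERION_NAMES."""
    t = thresholds
    return (
        t.tag_len_min <= m.tag_length <= t.tag_len_max,
        t.mature_len_min <= m.mature_length <= t.mature_len_max,
        m.cut_site_depth >= t.min_cut_depth,
        m.copy_number <= t.max_copy_number,
        m.mfe <= t.max_mfe,
        m.loop_spacing <= t.max_spacing,
        m.duplex_pairs >= t.min_duplex_pairs,
        m.bulge <= t.max_bulge,
        m.asymmetry <= t.max_asymmetry,
        m.flank == t.flank,
    )


def excise_candidates(
    tag: str,
    hits: Sequence[AlignmentHit],
    genome: dict[str, str],
    thresholds: HairpinThresholds = HairpinThresholds(),
) -> list[CandidateWindow]:
    """Excise precursor-sized windows around each genomic placement.

    For every hit two windows are produced - one with the tag on the 5'
    arm, one with it on the 3' arm - each extending far enough to hold
    the opposite arm at the maximum loop spacing, plus the fixed flank.
    Tags with more than the allowed genome copy number yield nothing.
    """
    if len(hits) > thresholds.max_copy_number or not hits:
        return []
    L = len(tag)
    reach = L + thresholds.max_spacing  # room for star arm + loop
    windows = []
    for hit in hits:
        chrom = genome[hit.reference]
        glen = len(chrom)
        # forward-coordinate extent of the tag; for minus-strand hits the
        # window sequence is reverse-complemented below and both arm
        # orientations are generated, so the extents are strand-agnostic
        t5, t3 = hit.start, hit.start + L
        for arm in ("5p", "3p"):
            if arm == "5p":
                w_start = t5 - thresholds.flank
                w_end = t3 + reach + thresholds.flank
            else:
                w_start = t5 - reach - thresholds.flank
                w_end = t3 + thresholds.flank
            w_start, w_end = max(0, w_start), min(glen, w_end)
            if w_end - w_start < L + 2 * thresholds.flank:
                continue
            seq_fwd = chrom[w_start:w_end]
            if hit.strand == "+":
                seq = seq_fwd
                m0 = t5 - w_start
            else:
                seq = revcomp(seq_fwd)
                m0 = (w_end - t3)
            windows.append(
                CandidateWindow(
                    genome_name=hit.reference,
                    start=w_start,
                    end=w_end,
                    strand=hit.strand,
                    sequence=seq,
                    mature_span=(m0, m0 + L),
                    flank=thresholds.flank,
                )
            )
    return windows


def _nearest_paired(pos: int, pairmap: dict[int, int], lo: int, hi: int) -> int | None:
    """Nearest paired position to ``pos`` within [lo, hi)."""
    for d in range(hi - lo):
        for cand in (pos + d, pos - d):
            if lo <= cand < hi and cand in pairmap:
                return cand
    return None


def _star_span(
    pairmap: dict[int, int], mature: tuple[int, int], n: int
) -> tuple[int, int] | None:
    """Star arm from the structure with the canonical 2-nt 3' overhang.

    The partners of the mature's outermost paired bases delimit the
    star; the star's 3' end (always the right window coordinate, since
    both arms read 5'->3' left to right) extends 2 nt beyond its last
    paired base.  Returns None when the mature is unpaired or its
    partners straddle the mature itself (no clean two-arm duplex).
    """
    m5, m3 = mature
    a = _nearest_paired(m5, pairmap, m5, m3)
    b = _nearest_paired(m3 - 3, pairmap, m5, m3)
    if a is None or b is None:
        return None
    pa, pb = pairmap[a], pairmap[b]
    lo, hi = min(pa, pb), max(pa, pb)
    if not (hi < m5 or lo >= m3):
        return None
    star_start = lo
    star_end = hi + 1 + 2
    if hi < m5:
        # star is the 5' arm; its 3' overhang reaches toward the loop
        star_end = min(star_end, m5)
    return (max(0, star_start), min(n, star_end))


def _duplex_stats(
    pairmap: dict[int, int],
    mature: tuple[int, int],
    star: tuple[int, int],
) -> tuple[int, int, int, int]:
    """(pairs, bulge, asymmetry, loop_spacing) of the mature/star duplex."""
    m5, m3 = mature
    s5, s3 = star
    pairs = 0
    unpaired_m: list[bool] = []
    unpaired_s: list[bool] = []
    for i in range(m5, m3):
        j = pairmap.get(i)
        if j is not None and s5 <= j < s3:
            pairs += 1
            unpaired_m.append(False)
        else:
            unpaired_m.append(True)
    for i in range(s5, s3):
        j = pairmap.get(i)
        if j is not None and m5 <= j < m3:
            unpaired_s.append(False)
        else:
            unpaired_s.append(True)

    def longest_run(flags: list[bool]) -> int:
        best = run = 0
        for f in flags:
            run = run + 1 if f else 0
            best = max(best, run)
        return best

    # trim terminal overhangs: bulges are internal to the duplex
    def trim(flags: list[bool]) -> list[bool]:
        lo = 0
        hi = len(flags)
        while lo < hi and flags[lo]:
            lo += 1
        while hi > lo and flags[hi - 1]:
            hi -= 1
        return flags[lo:hi]

    bulge = max(longest_run(trim(unpaired_m)), longest_run(trim(unpaired_s)))
    asym = abs(sum(trim(unpaired_m)) - sum(trim(unpaired_s)))
    if m3 <= s5:
        spacing = s5 - m3
    else:
        spacing = m5 - s3
    return pairs, bulge, asym, max(0, spacing)


def measure_hairpin(
    window: CandidateWindow,
    read_stack: Sequence[tuple[int, int, int]],
    copy_number: int,
    fold_fn: Callable[[str], fold.FoldResult] = fold.fold_mfe,
) -> tuple[fold.FoldResult, tuple[int, int] | None, HairpinMeasurements]:
    """Fold a window and measure all criterion quantities.

    ``read_stack`` holds (start_offset, length, count) of the reads
    mapping inside the window, in window-local coordinates; cut-site
    depth counts reads whose 5' ends fall within +-1 nt of the mature
    5' end.
    """
    m5, m3 = window.mature_span
    if not (0 <= m5 < m3 <= len(window.sequence)):
        raise ValueError("mature span outside the window")
    result = fold_fn(window.sequence)
    pairmap: dict[int, int] = {}
    for i, j in result.pairs:
        pairmap[i] = j
        pairmap[j] = i
    star = _star_span(pairmap, window.mature_span, len(window.sequence))
    if star is not None:
        pairs, bulge, asym, spacing = _duplex_stats(pairmap, window.mature_span, star)
    else:
        pairs, bulge, asym, spacing = 0, len(window.sequence), 10**6, 10**6
    depth = sum(c for s, _l, c in read_stack if abs(s - m5) <= 1)
    meas = HairpinMeasurements(
        tag_length=m3 - m5,
        mature_length=m3 - m5,
        cut_site_depth=depth,
        copy_number=copy_number,
        mfe=result.mfe,
        loop_spacing=spacing,
        duplex_pairs=pairs,
        bulge=bulge,
        asymmetry=asym,
        flank=window.flank,
    )
    return result, star, meas


def evaluate_hairpin(
    window: CandidateWindow,
    read_stack: Sequence[tuple[int, int, int]],
    copy_number: int = 1,
    thresholds: HairpinThresholds = HairpinThresholds(),
    fold_fn: Callable[[str], fold.FoldResult] = fold.fold_mfe,
) -> HairpinCandidate:
    """Fold, measure and screen one candidate window."""
    if window.mature_span[1] - window.mature_span[0] > len(window.sequence):
        raise ValueError("window shorter than the tag")
    result, star, meas = measure_hairpin(window, read_stack, copy_number, fold_fn)
    verdicts = apply_criteria(meas, thresholds)
    return HairpinCandidate(
        window=window,
        fold_result=result,
        mature_span=window.mature_span,
        star_span=star,
        measurements=meas,
        verdicts=verdicts,
    )


def discover_novel(
    unannotated_tags: Iterable[UniqueTag],
    genome: dict[str, str],
    min_reads: int = 5,
    thresholds: HairpinThresholds = HairpinThresholds(),
    fold_fn: Callable[[str], fold.FoldResult] = fold.fold_mfe,
    max_mismatch: int = 0,
) -> list[HairpinCandidate]:
    """Screen unannotated tags for novel miRNA precursors.

    Tags below ``min_reads`` are skipped as sequencing noise (they still
    contribute to cut-site read depth).  One candidate is kept per
    genomic locus - the best (lowest) MFE among overlapping passing
    windows on the same strand - and candidates are returned ordered by
    genome name then start coordinate.
    """
    tags = sorted(unannotated_tags, key=lambda t: (-t.count, t.sequence))
    genome_refs = [NamedSeq(name, seq) for name, seq in genome.items()]

    # genome placements for every tag (exact by default): used both to
    # seed candidates and to build per-window read stacks for depth
    placements: dict[str, list[AlignmentHit]] = {}
    for tag in tags:
        placements[tag.sequence] = align_tag(
            tag.sequence, genome_refs, "genome", max_mismatch, both_strands=True
        )

    passing: list[HairpinCandidate] = []
    for tag in tags:
        if tag.count < min_reads:
            continue
        hits = placements[tag.sequence]
        windows = excise_candidates(tag.sequence, hits, genome, thresholds)
        for window in windows:
            stack = _window_read_stack(window, tags, placements)
            cand = evaluate_hairpin(
                window, stack, copy_number=len(hits), thresholds=thresholds,
                fold_fn=fold_fn,
            )
            if cand.passes:
                passing.append(cand)

    return _dedupe_loci(passing)


def _window_read_stack(
    window: CandidateWindow,
    tags: Sequence[UniqueTag],
    placements: dict[str, list[AlignmentHit]],
) -> list[tuple[int, int, int]]:
    stack = []
    for tag in tags:
        L = len(tag.sequence)
        for hit in placements[tag.sequence]:
            if hit.reference != window.genome_name or hit.strand != window.strand:
                continue
            if hit.start < window.start or hit.start + L > window.end:
                continue
            if window.strand == "+":
                off = hit.start - window.start
            else:
                off = window.end - (hit.start + L)
            stack.append((off, L, tag.count))
    return stack


def _dedupe_loci(candidates: list[HairpinCandidate]) -> list[HairpinCandidate]:
    """Keep the best-MFE candidate per overlapping genomic locus.

    Overlap is judged on forward genome coordinates regardless of
    strand: a perfect inverted repeat folds on both strands but is one
    locus.
    """
    ordered = sorted(
        candidates,
        key=lambda c: (c.window.genome_name, c.window.start, c.window.strand),
    )
    kept: list[HairpinCandidate] = []
    for cand in ordered:
        merged = False
        for i, prev in enumerate(kept):
            if (
                prev.window.genome_name == cand.window.genome_name
                and cand.window.start < prev.window.end
                and prev.window.start < cand.window.end
            ):
                if cand.fold_result.mfe < prev.fold_result.mfe:
                    kept[i] = cand
                merged = True
                break
        if not merged:
            kept.append(cand)
    kept.sort(key=lambda c: (c.window.genome_name, c.window.start, c.window.strand))
    return kept
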