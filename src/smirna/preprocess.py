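"""Raw small-RNA read cleaning and tag collapsing.

Cleaning removes, in order: reads whose 3' adaptor cannot be located
(including reads that begin inside the adaptor, i.e. 5' adaptor
contaminants with an empty insert), poor-quality inserts (mean Phred
below a threshold or any uncalled base), and inserts outside the
accepted size window (default 18-30 nt; sub-18-nt products of adaptor
dimers and degradation are the main casualties).  Surviving inserts are
collapsed to unique tags carrying read counts.

Adaptor location is exact-match: the leftmost occurrence of the full
adaptor, or of an adaptor prefix of at least ``min_overlap`` nt ending
flush with the read 3' end.  Mismatch-tolerant trimming is out of
scope.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, TextIO

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "TrimStatus",
    "TrimResult",
    "CleanStats",
    "UniqueTag",
    "trim_adaptor",
    "filter_reads",
    "collapse",
    "length_distribution",
    "parse_fastq",
    "write_tags_fasta",
]


class TrimStatus(str, Enum):
    TRIMMED = "trimmed"
    NO_ADAPTOR = "no_adaptor"
    ADAPTOR_ONLY = "adaptor_only"   # read begins inside the adaptor


@dataclass(frozen=True)
class TrimResult:
    status: TrimStatus
    insert: str
    quality: str


@dataclass
class CleanStats:
    """Read accounting through the cleaning filters.

    Invariant: raw_reads = clean_reads + discarded_quality +
    discarded_adaptor + discarded_short; the length histogram counts
    exactly the clean reads.
    """

    raw_reads: int = 0
    discarded_quality: int = 0
    discarded_adaptor: int = 0
    discarded_short: int = 0
    clean_reads: int = 0
    length_histogram: dict[int, int] = field(default_factory=dict)

    def check(self) -> None:
        total = (
            self.clean_reads
            + self.discarded_quality
            + self.discarded_adaptor
            + self.discarded_short
        )
        if total != self.raw_reads:
            raise AssertionError("read accounting does not balance")
        if sum(self.length_histogram.values()) != self.clean_reads:
            raise AssertionError("length histogram does not sum to clean reads")


@dataclass(frozen=True)
class UniqueTag:
    sequence: str
    count: int


def trim_adaptor(
    sequence: str, quality: str, adaptor3: str, min_overlap: int = 6
) -> TrimResult:
    """Locate the 3' adaptor and return the insert preceding it.

    Searches for the leftmost exact occurrence of the full adaptor; if
    absent, for the longest adaptor prefix (>= min_overlap nt) that is
    a suffix of the read.  A match at position 0 means the read begins
    inside the adaptor and is flagged ADAPTOR_ONLY.
    """
    if not adaptor3:
        raise ValueError("adaptor3 must be non-empty")
    seq = sequence.upper()
    adaptor = adaptor3.upper()
    pos = seq.find(adaptor)
    if pos < 0:
        # adaptor prefix running off the read 3' end
        max_partial = min(len(adaptor) - 1, len(seq))
        for k in range(max_partial, min_overlap - 1, -1):
            if seq.endswith(adaptor[:k]):
                pos = len(seq) - k
                break
    if pos < 0:
        return TrimResult(TrimStatus.NO_ADAPTOR, seq, quality)
    if pos == 0:
        return TrimResult(TrimStatus.ADAPTOR_ONLY, "", "")
    return TrimResult(TrimStatus.TRIMMED, seq[:pos], quality[:pos])


def parse_fastq(handle: TextIO) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) from a Phred+33 FASTQ stream."""
    yield from FastqGeneralIterator(handle)


def _mean_phred(quality: str) -> float:
    if not quality:
        return 0.0
    return sum(ord(c) - 33 for c in quality) / len(quality)


def filter_reads(
    reads: Iterable[tuple[str, str, str]],
    adaptor3: str,
    min_len: int = 18,
    max_len: int = 30,
    min_mean_quality: float = 20.0,
    min_overlap: int = 6,
) -> tuple[list[str], CleanStats]:
    """Trim and filter raw reads; returns clean inserts plus accounting.

    Filter order per read: adaptor status, then insert quality (mean
    Phred and uncalled bases), then the size window.
    """
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    stats = CleanStats()
    clean: list[str] = []
    for _rid, seq, qual in reads:
        stats.raw_reads += 1
        trimmed = trim_adaptor(seq, qual, adaptor3, min_overlap)
        if trimmed.status == TrimStatus.NO_ADAPTOR:
            stats.discarded_adaptor += 1
            continue
        if trimmed.status == TrimStatus.ADAPTOR_ONLY:
            # zero-length insert: counted with the sub-threshold reads
            stats.discarded_short += 1
            continue
        insert, iqual = trimmed.insert, trimmed.quality
        if "N" in insert or _mean_phred(iqual) < min_mean_quality:
            stats.discarded_quality += 1
            continue
        if not (min_len <= len(insert) <= max_len):
            stats.discarded_short += 1
            continue
        stats.clean_reads += 1
        stats.length_histogram[len(insert)] = (
            stats.length_histogram.get(len(insert), 0) + 1
        )
        clean.append(insert)
    stats.check()
    return clean, stats


def collapse(clean_reads: Iterable[str]) -> list[UniqueTag]:
    """Collapse reads to unique tags, ordered by count desc then sequence."""
    counts = Counter(clean_reads)
    return [
        UniqueTag(seq, n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def length_distribution(tags: Iterable[UniqueTag]) -> dict[int, tuple[int, int]]:
    """Per-length (read count, unique tag count) marginals."""
    reads: Counter[int] = Counter()
    uniq: Counter[int] = Counter()
    for tag in tags:
        reads[len(tag.sequence)] += tag.count
        uniq[len(tag.sequence)] += 1
    return {n: (reads[n], uniq[n]) for n in sorted(reads)}


def write_tags_fasta(tags: Iterable[UniqueTag], handle: TextIO) -> None:
    """Write collapsed tags as FASTA with headers tag<N>_x<count>."""
    for i, tag in enumerate(tags, start=1):
        handle.write(f">tag{i}_x{tag.count}\n{tag.sequence}\n")
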