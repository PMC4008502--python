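"""Seeded synthetic references and two-condition small-RNA libraries.

Everything downstream of the sequencer is testable against this module:
it fabricates a reference bundle (mature miRNAs, stem-loop precursors,
ncRNA decoy fragments, a toy genome with planted precursors, 3'UTRs
with planted target sites) and simulates Illumina-style small-RNA
libraries from it, recording complete per-read ground truth.

What the generator emulates, following the profile of a liver small-RNA
library: inserts of 18-26 nt with a dominant 22-nt mode (roughly 60-65%
of reads), one highly dominant miRNA (the miR-122 pattern, ~65% of
miRNA reads, configurable), a long-tailed abundance distribution for
the remainder, a small percentage of structural-ncRNA degradation
fragments, 3' adaptor sequence on every read, and uniform per-base
substitution error.  It does not model ligation bias, PCR duplicates,
indels, or quality decay (a constant high-quality string is written
unless a degradation mode is enabled).

Precursors are built construction-then-verify: a near-perfect stem
(mature paired to its reverse complement with a couple of G-U wobbles)
around a short loop, plus 10-nt flanks, refolded and screened against
the full hairpin criteria; failing draws are regenerated (bounded
retries), so planted precursors pass by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

import numpy as np

from . import hairpin
from .annotate import NamedSeq, revcomp

__all__ = [
    "ReferenceBundle",
    "TruthTable",
    "SimulatedRead",
    "generate_reference_bundle",
    "simulate_library",
    "make_condition_pair",
    "simulate_count_pair",
    "default_abundances",
    "write_fasta",
    "write_fastq",
    "DEFAULT_ADAPTOR3",
]

# Illumina TruSeq small-RNA 3' adaptor (first 20 nt)
DEFAULT_ADAPTOR3 = "TGGAATTCTCGGGTGCCAAG"

_MATURE_LEN_DIST = {20: 0.04, 21: 0.12, 22: 0.68, 23: 0.12, 24: 0.04}
_DECOY_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA")
_DNA = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedSite:
    utr_name: str
    mirna_name: str
    start: int
    end: int


@dataclass
class ReferenceBundle:
    """Synthetic reference sets with full provenance.

    Sequences are DNA-alphabet strings.  ``genome_coords`` records
    where each precursor (known and novel) was planted, as
    (genome name, start, end, strand), 0-based half-open.
    """

    matures: dict[str, str]
    precursors: dict[str, str]
    novel_matures: dict[str, str]
    novel_precursors: dict[str, str]
    decoys: dict[str, str]
    decoy_classes: dict[str, str]
    genome: dict[str, str]
    genome_coords: dict[str, tuple[str, int, int, str]]
    utrs: dict[str, str]
    planted_sites: list[PlantedSite]
    seed: int

    def mature_refs(self) -> list[NamedSeq]:
        return [NamedSeq(n, s) for n, s in self.matures.items()]

    def decoy_refs_by_class(self) -> dict[str, list[NamedSeq]]:
        out: dict[str, list[NamedSeq]] = {}
        for name, seq in self.decoys.items():
            out.setdefault(self.decoy_classes[name], []).append(NamedSeq(name, seq))
        return out

    def all_sources(self) -> dict[str, str]:
        """Every name a library read can be drawn from, with its insert pool."""
        srcs = dict(self.matures)
        srcs.update(self.novel_matures)
        srcs.update(self.decoys)
        return srcs


@dataclass
class TruthTable:
    """Ground truth of one simulated two-condition experiment."""

    abundance_cond1: dict[str, float]
    abundance_cond2: dict[str, float]
    de_mirnas: dict[str, float]          # name -> true fold change (cond2/cond1)
    novel_names: list[str]
    novel_coords: dict[str, tuple[str, int, int, str]]
    planted_sites: list[PlantedSite]
    seed: int

    def to_frame(self):
        import pandas as pd

        names = sorted(set(self.abundance_cond1) | set(self.abundance_cond2))
        return pd.DataFrame(
            {
                "name": names,
                "abundance_cond1": [self.abundance_cond1.get(n, 0.0) for n in names],
                "abundance_cond2": [self.abundance_cond2.get(n, 0.0) for n in names],
                "true_fold_change": [self.de_mirnas.get(n, 1.0) for n in names],
                "is_de": [n in self.de_mirnas for n in names],
                "is_novel": [n in set(self.novel_names) for n in names],
            }
        )


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    quality: str
    source: str      # name of the mature/novel/decoy the insert came from
    insert: str      # pre-error insert sequence


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _build_precursor(
    rng: np.random.Generator, mature: str, flank: int = 10, max_tries: int = 50
) -> str | None:
    """Construct a stem-loop precursor containing ``mature`` on its 5' arm.

    star = reverse complement of the mature with up to two C->T edits
    (turning G-C pairs into G-U wobbles), a 6-12 nt loop, and
    ``flank``-nt random flanks.  Each draw is refolded and screened
    against the full criterion set (with a nominal read stack); the
    first passing draw is returned.
    """
    for _ in range(max_tries):
        loop = _random_seq(rng, int(rng.integers(6, 13)))
        star = revcomp(mature)
        star_list = list(star)
        wobble_idx = [i for i, b in enumerate(star_list) if b == "C"]
        # always wobble at least one pair: keeps the stem realistic and
        # the star distinct from the mature's exact reverse complement
        n_wob = int(rng.integers(1, 3))
        if wobble_idx and n_wob:
            for i in rng.choice(wobble_idx, size=min(n_wob, len(wobble_idx)), replace=False):
                star_list[i] = "T"   # C->U: G-C pair becomes G-U wobble
        star = "".join(star_list)
        flank5 = _random_seq(rng, flank)
        flank3 = _random_seq(rng, flank)
        pre = flank5 + mature + loop + star + flank3
        window = hairpin.CandidateWindow(
            genome_name="construct",
            start=0,
            end=len(pre),
            strand="+",
            sequence=pre,
            mature_span=(flank, flank + len(mature)),
            flank=flank,
        )
        cand = hairpin.evaluate_hairpin(window, [(flank, len(mature), 5)], copy_number=1)
        if cand.passes:
            return pre
    return None


def generate_reference_bundle(
    n_mirnas: int,
    n_decoys: int,
    n_novel: int,
    seed: int,
    *,
    n_utrs: int | None = None,
    genome_spacer: int = 150,
    flank: int = 10,
) -> ReferenceBundle:
    """Generate a fully cross-consistent synthetic reference set.

    The genome carries every precursor (known and novel) at recorded
    coordinates, separated by random spacer sequence; UTRs (one per
    miRNA, up to ``n_utrs``) carry one perfect-complement target site
    each at a recorded position.  Deterministic given ``seed``.
    """
    if n_mirnas < 1:
        raise ValueError("n_mirnas must be >= 1")
    if n_decoys < 0 or n_novel < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)

    lengths = list(_MATURE_LEN_DIST)
    probs = np.array([_MATURE_LEN_DIST[k] for k in lengths])

    def draw_mature() -> str:
        L = int(rng.choice(lengths, p=probs))
        return _random_seq(rng, L)

    matures: dict[str, str] = {}
    precursors: dict[str, str] = {}
    for i in range(1, n_mirnas + 1):
        name = f"mir-{i:03d}"
        for _ in range(20):
            mat = draw_mature()
            pre = _build_precursor(rng, mat, flank=flank)
            if pre is not None:
                matures[name] = mat
                precursors[f"pre-{name}"] = pre
                break
        else:
            raise RuntimeError(f"could not construct a valid precursor for {name}")

    novel_matures: dict[str, str] = {}
    novel_precursors: dict[str, str] = {}
    for i in range(1, n_novel + 1):
        name = f"novel-{i}"
        for _ in range(20):
            mat = draw_mature()
            pre = _build_precursor(rng, mat, flank=flank)
            if pre is not None:
                novel_matures[name] = mat
                novel_precursors[f"pre-{name}"] = pre
                break
        else:
            raise RuntimeError(f"could not construct a valid precursor for {name}")

    decoys: dict[str, str] = {}
    decoy_classes: dict[str, str] = {}
    for i in range(n_decoys):
        cls = _DECOY_CLASSES[i % len(_DECOY_CLASSES)]
        name = f"{cls}-{i // len(_DECOY_CLASSES) + 1}"
        decoys[name] = _random_seq(rng, int(rng.integers(80, 161)))
        decoy_classes[name] = cls

    # toy genome: spacers interleaved with every precursor, forward strand
    parts: list[str] = []
    coords: dict[str, tuple[str, int, int, str]] = {}
    pos = 0
    all_pre = {**precursors, **novel_precursors}
    for name, pre in all_pre.items():
        spacer = _random_seq(rng, genome_spacer)
        parts.append(spacer)
        pos += len(spacer)
        parts.append(pre)
        coords[name] = ("chr1", pos, pos + len(pre), "+")
        pos += len(pre)
    parts.append(_random_seq(rng, genome_spacer))
    genome = {"chr1": "".join(parts)}

    # 3'UTRs with one planted perfect-complement site per miRNA
    if n_utrs is None:
        n_utrs = min(n_mirnas, 5)
    utrs: dict[str, str] = {}
    planted: list[PlantedSite] = []
    mir_names = list(matures)
    for i in range(n_utrs):
        mir = mir_names[i % len(mir_names)]
        site = revcomp(matures[mir])
        left = _random_seq(rng, int(rng.integers(60, 121)))
        right = _random_seq(rng, int(rng.integers(60, 121)))
        name = f"utr-{i + 1:03d}"
        utrs[name] = left + site + right
        planted.append(PlantedSite(name, mir, len(left), len(left) + len(site)))

    return ReferenceBundle(
        matures=matures,
        precursors=precursors,
        novel_matures=novel_matures,
        novel_precursors=novel_precursors,
        decoys=decoys,
        decoy_classes=decoy_classes,
        genome=genome,
        genome_coords=coords,
        utrs=utrs,
        planted_sites=planted,
        seed=seed,
    )


def default_abundances(
    bundle: ReferenceBundle,
    seed: int,
    dominant_share: float = 0.65,
    decoy_fraction: float = 0.01,
    novel_fraction: float = 0.02,
) -> dict[str, float]:
    """Study-like expected read shares for every source in the bundle.

    The first miRNA takes ``dominant_share`` of the miRNA reads (the
    miR-122 pattern); the rest follow a log-normal tail.  Decoy
    degradation fragments take ``decoy_fraction`` of all reads
    (splitting the 0.5-2% range observed for structural ncRNA), novel
    matures ``novel_fraction``.
    """
    rng = np.random.default_rng(seed)
    mir_names = list(bundle.matures)
    mir_share = 1.0 - decoy_fraction - novel_fraction * bool(bundle.novel_matures)
    weights: dict[str, float] = {}
    if len(mir_names) == 1:
        weights[mir_names[0]] = mir_share
    else:
        tail = rng.lognormal(mean=0.0, sigma=1.5, size=len(mir_names) - 1)
        tail = tail / tail.sum() * (1.0 - dominant_share) * mir_share
        weights[mir_names[0]] = dominant_share * mir_share
        for name, w in zip(mir_names[1:], tail):
            weights[name] = float(w)
    if bundle.novel_matures:
        per = novel_fraction / len(bundle.novel_matures)
        for name in bundle.novel_matures:
            weights[name] = per
    if bundle.decoys:
        per = decoy_fraction / len(bundle.decoys)
        for name in bundle.decoys:
            weights[name] = per
    return weights


def simulate_library(
    bundle: ReferenceBundle,
    abundances: dict[str, float],
    depth: int,
    error_rate: float,
    adaptor3: str = DEFAULT_ADAPTOR3,
    seed: int = 0,
    *,
    isomir_rate: float = 0.1,
    library_id: str = "lib",
) -> list[SimulatedRead]:
    """Simulate one library of ``depth`` reads with per-read truth labels.

    Sources are drawn multinomially from ``abundances`` (weights need
    not sum to 1).  miRNA/novel inserts are the mature sequence, with a
    1-nt 3' trim or precursor-templated extension at ``isomir_rate``;
    decoy inserts are random 18-26 nt degradation fragments.  Each read
    is insert + 3' adaptor with substitution errors at ``error_rate``
    and a constant high-quality string.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    sources = bundle.all_sources()
    unknown = set(abundances) - set(sources)
    if unknown:
        raise ValueError(f"unknown abundance keys: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    names = sorted(abundances)
    w = np.array([abundances[n] for n in names], dtype=float)
    if (w < 0).any():
        raise ValueError("abundances must be non-negative")
    if depth == 0 or w.sum() == 0:
        return []
    counts = rng.multinomial(depth, w / w.sum())

    pre_by_mature: dict[str, str] = {}
    for name, mat in {**bundle.matures, **bundle.novel_matures}.items():
        pname = f"pre-{name}"
        pre = bundle.precursors.get(pname) or bundle.novel_precursors.get(pname)
        if pre:
            pre_by_mature[name] = pre

    inserts: list[tuple[str, str]] = []   # (source, insert)
    for name, c in zip(names, counts):
        if c == 0:
            continue
        seq = sources[name]
        is_decoy = name in bundle.decoys
        for _ in range(int(c)):
            if is_decoy:
                L = int(rng.integers(18, 27))
                if L >= len(seq):
                    frag = seq
                else:
                    s = int(rng.integers(0, len(seq) - L + 1))
                    frag = seq[s : s + L]
                inserts.append((name, frag))
            else:
                ins = seq
                if isomir_rate > 0 and rng.random() < isomir_rate:
                    pre = pre_by_mature.get(name)
                    if rng.random() < 0.5 and len(ins) > 18:
                        ins = ins[:-1]
                    elif pre is not None:
                        p = pre.find(ins)
                        if p >= 0 and p + len(ins) < len(pre):
                            ins = pre[p : p + len(ins) + 1]
                inserts.append((name, ins))

    order = rng.permutation(len(inserts))
    reads: list[SimulatedRead] = []
    lens = np.array([len(ins) + len(adaptor3) for _, ins in inserts])
    n_err = rng.binomial(lens[order], error_rate) if error_rate > 0 else np.zeros(
        len(order), dtype=int
    )
    for k, idx in enumerate(order):
        source, insert = inserts[idx]
        read = insert + adaptor3
        if n_err[k]:
            arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
            pos = rng.choice(len(arr), size=int(n_err[k]), replace=False)
            for p in pos:
                choices = _DNA[_DNA != arr[p]]
                arr[p] = rng.choice(choices)
            read = arr.tobytes().decode()
        reads.append(
            SimulatedRead(
                read_id=f"{library_id}:{k + 1}",
                sequence=read,
                quality="I" * len(read),
                source=source,
                insert=insert,
            )
        )
    return reads


def make_condition_pair(
    bundle: ReferenceBundle,
    base_abundances: dict[str, float],
    de_spec: dict[str, float],
    depths: tuple[int, int],
    error_rate: float,
    adaptor3: str = DEFAULT_ADAPTOR3,
    seed: int = 0,
) -> tuple[list[SimulatedRead], list[SimulatedRead], TruthTable]:
    """Simulate the two-condition experiment (condition 1 vs condition 2).

    Condition-2 expected abundance is base x fold-change for miRNAs in
    ``de_spec`` and base otherwise.  Returns both read sets plus the
    complete TruthTable.
    """
    unknown = set(de_spec) - set(base_abundances)
    if unknown:
        raise ValueError(f"de_spec names not in base_abundances: {sorted(unknown)}")
    for name, fc in de_spec.items():
        if fc <= 0:
            raise ValueError(f"fold change for {name} must be positive")
    abund2 = {
        name: w * de_spec.get(name, 1.0) for name, w in base_abundances.items()
    }
    rng = np.random.default_rng(seed)
    s1, s2 = (int(x) for x in rng.integers(0, 2**31 - 1, size=2))
    reads1 = simulate_library(
        bundle, base_abundances, depths[0], error_rate, adaptor3, s1,
        library_id="cond1",
    )
    reads2 = simulate_library(
        bundle, abund2, depths[1], error_rate, adaptor3, s2, library_id="cond2"
    )
    truth = TruthTable(
        abundance_cond1=dict(base_abundances),
        abundance_cond2=abund2,
        de_mirnas=dict(de_spec),
        novel_names=list(bundle.novel_matures),
        novel_coords={
            name: bundle.genome_coords[f"pre-{name}"]
            for name in bundle.novel_matures
        },
        planted_sites=list(bundle.planted_sites),
        seed=seed,
    )
    return reads1, reads2, truth


def simulate_count_pair(
    names: Sequence[str],
    base_abundances: dict[str, float],
    de_spec: dict[str, float],
    depths: tuple[int, int],
    seed: int,
) -> tuple[dict[str, int], dict[str, int]]:
    """Count-level shortcut: multinomial per-miRNA counts for two libraries.

    Marginally equivalent to simulating error-free reads and counting
    them back; used for large differential-expression calibration runs
    where per-read simulation adds nothing.
    """
    for name, fc in de_spec.items():
        if fc <= 0:
            raise ValueError(f"fold change for {name} must be positive")
    rng = np.random.default_rng(seed)
    w1 = np.array([base_abundances[n] for n in names], dtype=float)
    w2 = np.array(
        [base_abundances[n] * de_spec.get(n, 1.0) for n in names], dtype=float
    )
    c1 = rng.multinomial(depths[0], w1 / w1.sum())
    c2 = rng.multinomial(depths[1], w2 / w2.sum())
    return (
        {n: int(c) for n, c in zip(names, c1)},
        {n: int(c) for n, c in zip(names, c2)},
    )


def write_fasta(records: Iterable[tuple[str, str]], handle: TextIO) -> None:
    for name, seq in records:
        handle.write(f">{name}\n{seq}\n")


def write_fastq(reads: Iterable[SimulatedRead], handle: TextIO) -> None:
    for r in reads:
        handle.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")
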