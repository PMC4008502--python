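# Methods

`smirna` re-creates, as a tested library, the computational path of a
two-condition small-RNA sequencing experiment: two liver libraries (a
normal-fat-diet and a high-fat-diet condition) are cleaned, collapsed,
annotated, quantified, compared, and mined for novel miRNA precursors
and candidate target sites.  Because the original deep-sequencing
libraries and a reference genome are not inputs to this package, every
stage is exercised on synthetic libraries with planted ground truth;
this note records the models, the thresholds, and the design choices
made where the procedure left them open.

## Read cleaning and tag collapsing

Raw reads are `insert + 3' adaptor`.  Cleaning removes, per read and in
this order: reads whose 3' adaptor cannot be located (including reads
that begin inside the adaptor — 5' adaptor contaminants, whose insert
is empty), inserts of poor quality, and inserts outside the size
window.  Accounting is exact: `raw = clean + discarded_quality +
discarded_adaptor + discarded_short` is asserted on every run.

Open choices, fixed as follows:

* **Poor quality** is undefined upstream; here it means mean Phred
  quality < 20 (Phred+33) or any uncalled base (`N`).  Configurable
  (`preprocess.min_mean_quality`).
* **Adaptor detection** is exact-match: the leftmost occurrence of the
  full adaptor, or an adaptor prefix of ≥ 6 nt flush with the read 3'
  end (`preprocess.min_overlap`).  Mismatch-tolerant trimming is out of
  scope; at the simulated error rates the loss is ≈ the per-read error
  probability inside the first adaptor bases.
* **Size window** 18–30 nt (`min_len`/`max_len`).  The wet-lab gel cut
  is 16–30 nt, but reads shorter than 18 nt are discarded in silico.

Clean inserts are collapsed to unique tags (sequence, count), ordered
by count descending then lexicographically, so all downstream work is
per-tag and deterministic.

## Annotation priority and quantification

Tags are aligned with at most **one substitution and no indels**
against class-labeled FASTA sets and assigned the first matching class
in the fixed priority

    rRNA > tRNA > snRNA > snoRNA > repeat > known miRNA > genome > unannotated

so structural-RNA degradation fragments can never be credited to a
miRNA, and only genome-only tags feed novel-miRNA discovery.  Genome
references are searched on both strands; annotation references forward
only.  The aligner is an exhaustive sliding-window scan (complete by
construction) and is property-tested against a literal offset/strand
oracle.

Database lookups of the original procedure (Rfam / GenBank / miRBase)
are replaced by user-supplied class-labeled FASTA files — same logic,
no network dependency.

Open choices:

* **isomiRs**: a tag may sit at ±2 nt terminal offset relative to an
  annotated mature (overhanging bases uncompared, ≥ 18 nt overlap) and
  still count toward that miRNA.  Default on (`annotate.isomir`).
* **Multi-mapping**: a tag hitting several matures is credited in full
  to the best match — fewest mismatches, then smallest terminal offset,
  then reference order.  Deterministic by construction.

## Differential expression

Counts are normalized to reads per million (`count / clean_total ×
10^6`).  A normalized value of zero is replaced by the sentinel
**0.01** so fold changes stay finite; fold change is reported as
log2(HFD/NFD).  Two reporting filters: miRNAs with normalized
expression < 1 in **both** libraries are excluded, and miRNAs with
fewer than 5 reads summed over both libraries are excluded as noise.

Significance uses the Audic–Claverie two-library model.  With x counts
among N1 clean reads and y among N2,

    p(y | x) = (N2/N1)^y · (x+y)! / ( x! · y! · (1 + N2/N1)^(x+y+1) )

which is negative-binomial in y with x+1 successes and success
probability N1/(N1+N2).  Tails are therefore computed through the
regularized incomplete beta function (scipy's `nbinom`), giving ≲ 1e-13
relative accuracy against an exact rational-arithmetic oracle over the
whole x, y ≤ 200 grid — no term-by-term summation and no overflow for
counts in the tens of thousands.  The two-sided p doubles the smaller
tail and caps at 1 (`diffexpr.pvalue_method = "doubled"`; a
sum-of-both-tails variant is selectable).

Numerical notes:

* The model takes **integer raw counts**; the library-size imbalance
  enters through the N2/N1 ratio rather than through normalized values
  (a count model cannot take non-integer input).
* The doubled-tail p-value is **not exactly invariant** under swapping
  the libraries: the point masses transform with a factor N2/N1, so the
  two orientations agree on the log scale only within
  ln(1 + max(N1/N2, N2/N1)) — a factor ≤ 2 for equal library sizes,
  reached far out in the tails (p ~ 1e-80).  log2 fold change is
  exactly antisymmetric.  The property tests assert exactly this.
* Defaults for "differentially expressed": `alpha = 0.01` and
  `|log2fc| ≥ 1`, both configurable and recorded in the output.  An
  optional Benjamini–Hochberg column exists but is off by default to
  mirror the single-pair reporting style; no replicate dispersion model
  is attempted (there are no replicates in this design).

qPCR confirmation uses the comparative-CT method: per sample
ΔCT = CT(target) − CT(reference gene); between groups
ΔΔCT = mean ΔCT(HFD) − mean ΔCT(NFD), relative fold 2^(−ΔΔCT), and a
Welch t-test on per-sample ΔCT (flagged unavailable for groups of one).

## RNA folding model

Novel-miRNA discovery needs a self-contained, deterministic folding
engine whose search space can be enumerated for validation.  The model
scores pseudoknot-free structures **without multiloops**: every helix
is a chain of nested pairs interrupted by bulges/internal loops
(per-side gap ≤ 6 nt, total ≤ 8 nt), several stem-loops may sit on the
exterior loop, and hairpin loops have ≥ 3 unpaired nt.  Energies
(kcal/mol, 37 °C): a Watson–Crick stacking table with standard
nearest-neighbor values; stacks involving G-U pairs use a flat −1.0
(−0.5 for G-U on G-U); hairpin/bulge/internal-loop penalties by length
with Jacobson–Stockmayer extrapolation and a capped internal-loop
asymmetry penalty.

This is exactly the architecture of a pre-miRNA, which is the only
thing the engine is asked to fold.  Absolute energies track published
thermodynamic engines only approximately; the −18 kcal/mol stability
threshold refers to whichever backend is configured (any callable
`seq -> FoldResult` can be plugged in via the `fold_fn` arguments).

Validation is dual-route: the MFE dynamic program is compared against
(a) literal enumeration of every structure in the space with
independent re-scoring (feasible to ~26 nt; the space holds ~10^5
structures at that length) and (b) a memoized top-down exhaustive
search for longer sequences, plus the invariant that the traceback
structure re-scores to exactly the reported MFE.

## Novel-miRNA discovery

Genome-only tags with ≥ 5 reads (the noise filter; lower-count tags
still contribute read depth) seed candidate windows: for each genomic
placement, two windows per strand orientation put the tag on the 5' or
3' arm, extending `tag + 35 nt + flank` toward the opposite arm with
exactly 10 nt of flank.  Each window is folded and screened against the
ten criteria:

|  # | criterion | threshold |
|----|-----------|-----------|
| 1  | candidate small-RNA length | 18–26 nt |
| 2  | mature length | 20–24 nt |
| 3  | read depth at the Drosha/Dicer cut site | ≥ 3 |
| 4  | genome copy number of the tag | ≤ 20 |
| 5  | precursor folding free energy | ≤ −18 kcal/mol |
| 6  | mature/star loop spacing | ≤ 35 nt |
| 7  | mature/star duplex base pairs | ≥ 14 |
| 8  | duplex bulge | ≤ 4 nt |
| 9  | duplex asymmetry | ≤ 5 nt |
| 10 | excision flank | = 10 nt |

A candidate passes iff all ten verdicts hold (the conjunction is a
structural identity in the code).  The rule set names but does not
define criteria 8 and 9; operationalizations, recorded in output
metadata: **bulge** = longest run of unpaired nucleotides on either
duplex arm (terminal overhangs trimmed); **asymmetry** = |unpaired nt
on arm 1 − unpaired nt on arm 2| within the duplex.  **Cut-site depth**
= summed counts of reads whose 5' ends fall within ±1 nt of the mature
5' end.  The **star span** is derived from the structure with the
canonical 2-nt 3' overhangs of a Dicer duplex.

One candidate is kept per genomic locus (overlapping forward-coordinate
windows, regardless of strand — a perfect inverted repeat folds on both
strands but is one locus), preferring the lowest MFE; output order is
by genome name and start coordinate.

## Target prediction

A site on a 3'UTR is predicted iff it is found by **both** of two
screens — the package's analogue of intersecting a seed-based scanner
with a thermodynamic duplex filter:

1. **Seed scan**: complementarity to miRNA positions 2–8, classes 8mer,
   7mer-m8, 7mer-A1 (site-level; a gene-level intersection option is a
   simple aggregation of the site table by UTR).
2. **Six duplex rules**, on a gap-free antiparallel alignment of the
   full miRNA against the site (positions numbered 1..L from the miRNA
   5' end; G-U wobbles weigh 0.5 toward the counts and are *paired* for
   the adjacency rules): (i) weighted mismatches ≤ 4; (ii) no run of
   three adjacent mismatches; (iii) no adjacent mismatches in positions
   2–12; (iv) no mismatch at positions 10–11; (v) weighted mismatches
   in positions 1–12 ≤ 2.5; (vi) duplex MFE ≥ 75% of the MFE of the
   miRNA bound to its perfect complement.

All bounds are inclusive: exactly 4.0, exactly 2.5, and a ratio of
exactly 0.75 pass.  Duplex energies sum the stacking terms over runs of
consecutive paired positions, sharing the folding engine's energy
table; under this model adding a mismatch can only raise (weaken) the
duplex energy, so the MFE ratio is monotone in the mismatch set.
Position-wise alignment was chosen because all six rules are phrased
positionally; bulged target sites are out of scope.  The requirement
that targets be present in an expressed-transcriptome set is replaced
by the user's choice of UTR input (an allow-list by construction).

## Synthetic data: what it emulates, what it does not

The generator fabricates a reference bundle — mature miRNAs (20–24 nt,
22 nt with probability 0.68), stem-loop precursors, ncRNA decoy
fragments (rRNA/tRNA/snRNA/snoRNA), a toy genome with every precursor
planted at recorded coordinates, and 3'UTRs with planted
perfect-complement sites — and simulates libraries by multinomial
sampling over source abundances: insert + 3' adaptor, uniform per-base
substitution errors, constant high-quality strings, and a 10% isomiR
rate (1-nt 3' trim or precursor-templated extension).

Default study-like conditions: one dominant miRNA carries 65% of the
miRNA-mapped reads (the miR-122 pattern) with a log-normal tail for the
rest; decoy degradation fragments take 1% of reads (within the 0.5–2%
range typical of such libraries); planted novel matures 2%; demo
library depth 2×10^4 reads per condition (the statistical calibration
runs use 10^5; real libraries run 10^4–10^7 and every stage is linear
in depth).  The planted differential-expression spec is a map
name → fold change applied to condition 2's expected abundance; note
that multinomial renormalization means the *realized* count ratio of a
planted miRNA is attenuated when the planted set carries substantial
mass (e.g. equal-weight 10-of-100 at fold 4 yields an observed ratio of
≈ 3.1, log2 ≈ 1.6).

Precursors are built construction-then-verify: mature + 6–12-nt loop +
reverse-complement star with 1–2 G-U wobbles + 10-nt flanks, refolded
and screened against all ten criteria, regenerating on failure (bounded
retries).  Planted precursors therefore pass by construction, which is
what makes recall-of-planted a meaningful end-to-end check.

Not modeled: ligation/sequence bias, PCR duplication, indel errors,
quality decay along the read, multi-locus miRNA families, and
expression correlation between miRNAs.  Consequently, passing tests
demonstrate the correctness of the computational pipeline under an
idealized error model — they do not certify performance on real
libraries with adapter-ligation bias or heteroscedastic quality.

The per-read length distribution of a simulated library is dominated by
the planted abundance weights (a 65%-dominant 22-mer pushes the 22-nt
read share to ~65–85%); the 18–26-nt window and 22-nt mode match the
size profile such libraries show.

## Determinism

All randomness flows from a single integer seed through
`numpy.random.default_rng`; child seeds are drawn below 2^31.  Pipeline
outputs contain no timestamps, so two runs of `smirna all` with the
same config are byte-identical (hash-checked in the test suite).  Stage
timers go to stderr only.

## Command-line interface

`smirna` exposes subcommands `simulate`, `preprocess`, `annotate`,
`de`, `novel`, `targets`, `qpcr`, and `all`, each a thin wrapper over
one library stage so real data can be pushed through any stage in
isolation; `all` drives the full simulate-then-analyze pipeline from a
single YAML config validated up front (unknown keys rejected, every
threshold range-checked).
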