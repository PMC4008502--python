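"""Two-library count-based differential expression and qPCR analysis.

Counts from two un-replicated sequencing libraries (here: normal-fat
diet, NFD, vs high-fat diet, HFD) are compared with the Audic-Claverie
model.  Given a miRNA observed x times among N1 clean reads in library
1, the probability of observing y counts among N2 reads in library 2 is

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )

which is a negative-binomial distribution in y with x+1 successes and
success probability N1/(N1+N2); tail sums are therefore evaluated with
the regularized incomplete beta function (via scipy) rather than term
by term, giving full double precision for counts into the tens of
thousands.  The two-sided p-value doubles the smaller tail and caps at
1 (a sum-of-both-tails construction is selectable).

Expression is normalized to reads per million; a normalized value of
zero is replaced by the sentinel 0.01 so that fold changes remain
finite.  Reporting conventions: miRNAs with normalized expression < 1
in both libraries are excluded, as are miRNAs with fewer than five
reads total across the two libraries; fold change is log2(HFD/NFD).

The qPCR half implements the comparative CT method: per-sample
dCT = CT(target) - CT(reference), group shift ddCT, relative fold
2^-ddCT, and a Welch t-test on the per-sample dCT values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionRecord",
    "DETestResult",
    "QpcrRecord",
    "QpcrComparison",
    "normalize",
    "log2_fold_change",
    "ac_pvalue",
    "de_table",
    "de_results_frame",
    "delta_ct",
    "compare_ct_groups",
]

ZERO_SENTINEL = 0.01


@dataclass(frozen=True)
class ExpressionRecord:
    """Raw and normalized expression of one miRNA in the two libraries."""

    name: str
    count_hfd: int   # x
    count_nfd: int   # y
    norm_hfd: float
    norm_nfd: float


@dataclass(frozen=True)
class DETestResult:
    name: str
    x: int
    y: int
    N1: int
    N2: int
    norm_hfd: float
    norm_nfd: float
    log2fc: float
    p_two_sided: float
    excluded_low_expression: bool
    excluded_low_depth: bool
    significant: bool


def normalize(count: int, total: int) -> float:
    """Reads-per-million normalization with the 0.01 zero sentinel."""
    if total <= 0:
        raise ValueError("library total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    value = count / total * 1e6
    return value if value > 0 else ZERO_SENTINEL


def log2_fold_change(norm_hfd: float, norm_nfd: float) -> float:
    """log2(HFD/NFD) on normalized (sentinel-applied) expression."""
    if norm_hfd <= 0 or norm_nfd <= 0:
        raise ValueError("normalized expressions must be positive")
    return math.log2(norm_hfd / norm_nfd)


def ac_pvalue(
    x: int, y: int, N1: int | float, N2: int | float, *, method: str = "doubled"
) -> float:
    """Audic-Claverie two-library p-value for counts x (N1) vs y (N2).

    method='doubled' (default): p = min(1, 2 * min(lower, upper)) where
    lower = P(Y <= y | x) and upper = P(Y >= y | x).  method='sum'
    returns min(1, lower + upper) - the sum-of-tails alternative (note
    both tails include the observed y).
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library totals must be positive")
    # y | x ~ NegBin(r = x+1, p_success = N1/(N1+N2))
    p_success = N1 / (N1 + N2)
    lower = stats.nbinom.cdf(y, x + 1, p_success)
    upper = stats.nbinom.sf(y - 1, x + 1, p_success)
    if method == "doubled":
        return float(min(1.0, 2.0 * min(lower, upper)))
    if method == "sum":
        return float(min(1.0, lower + upper))
    raise ValueError(f"unknown method {method!r}")


def de_table(
    records: list[ExpressionRecord],
    N1: int,
    N2: int,
    alpha: float = 0.01,
    min_abs_log2fc: float = 1.0,
    min_total_count: int = 5,
    *,
    pvalue_method: str = "doubled",
    bh_column: bool = False,
) -> list[DETestResult]:
    """Full differential-expression table with the reporting filters.

    A miRNA is flagged significant iff it survives both filters (norm
    expression >= 1 in at least one library; x + y >= min_total_count),
    p <= alpha, and |log2fc| >= min_abs_log2fc.  Excluded records carry
    significant=False regardless of p.
    """
    results = []
    for rec in records:
        lfc = log2_fold_change(rec.norm_hfd, rec.norm_nfd)
        p = ac_pvalue(rec.count_hfd, rec.count_nfd, N1, N2, method=pvalue_method)
        low_expr = rec.norm_hfd < 1.0 and rec.norm_nfd < 1.0
        low_depth = rec.count_hfd + rec.count_nfd < min_total_count
        sig = (
            not low_expr
            and not low_depth
            and p <= alpha
            and abs(lfc) >= min_abs_log2fc
        )
        results.append(
            DETestResult(
                name=rec.name,
                x=rec.count_hfd,
                y=rec.count_nfd,
                N1=N1,
                N2=N2,
                norm_hfd=rec.norm_hfd,
                norm_nfd=rec.norm_nfd,
                log2fc=lfc,
                p_two_sided=p,
                excluded_low_expression=low_expr,
                excluded_low_depth=low_depth,
                significant=sig,
            )
        )
    if bh_column:
        # attach BH-adjusted p over the tested (non-excluded) records
        tested = [
            r for r in results if not (r.excluded_low_expression or r.excluded_low_depth)
        ]
        if tested:
            ps = np.array([r.p_two_sided for r in tested])
            order = np.argsort(ps)
            m = len(ps)
            adj = np.empty(m)
            prev = 1.0
            for rank_idx in range(m - 1, -1, -1):
                i = order[rank_idx]
                prev = min(prev, ps[i] * m / (rank_idx + 1))
                adj[i] = prev
            for r, q in zip(tested, adj):
                object.__setattr__(r, "p_adjusted", float(q))
    return results


def de_results_frame(results: list[DETestResult]) -> pd.DataFrame:
    """DE results as a DataFrame in the output-table column order."""
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "x": r.x,
                "y": r.y,
                "N1": r.N1,
                "N2": r.N2,
                "norm_nfd": r.norm_nfd,
                "norm_hfd": r.norm_hfd,
                "log2fc": r.log2fc,
                "p": r.p_two_sided,
                "excluded_low_expression": r.excluded_low_expression,
                "excluded_low_depth": r.excluded_low_depth,
                "significant": r.significant,
            }
            for r in results
        ]
    )


@dataclass(frozen=True)
class QpcrRecord:
    """One qPCR sample: comparative-CT input and its dCT."""

    sample: str
    group: str          # "NFD" | "HFD"
    ct_target: float
    ct_reference: float

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclass(frozen=True)
class QpcrComparison:
    ddct: float          # mean dCT(HFD) - mean dCT(NFD)
    fold: float          # 2^-ddct, HFD relative to NFD
    t_statistic: float
    p_value: float
    n_nfd: int
    n_hfd: int
    test_available: bool


def delta_ct(ct_target: float, ct_reference: float) -> float:
    """dCT = CT(target) - CT(reference gene)."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("CT values must be finite")
    return ct_target - ct_reference


def compare_ct_groups(records: list[QpcrRecord]) -> QpcrComparison:
    """Comparative-CT group analysis: ddCT, fold change, Welch t-test."""
    nfd = [r.delta_ct for r in records if r.group == "NFD"]
    hfd = [r.delta_ct for r in records if r.group == "HFD"]
    if not nfd or not hfd:
        raise ValueError("both NFD and HFD samples are required")
    ddct = float(np.mean(hfd) - np.mean(nfd))
    fold = float(2.0 ** (-ddct))
    if len(nfd) >= 2 and len(hfd) >= 2:
        t, p = stats.ttest_ind(hfd, nfd, equal_var=False)
        return QpcrComparison(ddct, fold, float(t), float(p), len(nfd), len(hfd), True)
    return QpcrComparison(ddct, fold, float("nan"), float("nan"), len(nfd), len(hfd), False)
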