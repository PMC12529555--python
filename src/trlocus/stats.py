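"""Locus-level statistics: inventories, F/P ratios, spans, V-intron
lengths, Wilcoxon rank-sum and Fisher exact analyses.

Reporting conventions follow the ones evident in published inventory
tables of adaptive-immune loci: F/P ratios are truncated (not rounded)
at two decimals by default, and the Fisher exact test reports the
two-sided probability-mass p, the conditional maximum-likelihood odds
ratio, and the exact 95% CI obtained by inverting the one-sided
conditional tests — the convention of R's ``fisher.test``, which
differs from other implementations at boundary tables (a zero cell
yields OR 0 or infinity with a finite opposite confidence bound).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq
from scipy.stats import nchypergeom_fisher

from .models import LocusAnnotation

__all__ = [
    "StatsConfig",
    "SummaryTable",
    "ContingencyTable",
    "WilcoxonResult",
    "FisherResult",
    "summarize_locus",
    "locus_span",
    "intron_lengths",
    "wilcoxon_rank_sum",
    "fisher_exact",
    "long_intron_table",
]


@dataclass(frozen=True)
class StatsConfig:
    long_intron_threshold: int = 650
    percent_decimals: int = 2
    ratio_rounding: str = "truncate_2dp"  # or round_2dp
    wilcoxon_exact_max_n: int = 30

    def __post_init__(self) -> None:
        if self.long_intron_threshold <= 0:
            raise ValueError("long_intron_threshold must be > 0")
        if self.ratio_rounding not in ("truncate_2dp", "round_2dp"):
            raise ValueError(f"unknown ratio_rounding {self.ratio_rounding!r}")


@dataclass
class SummaryTable:
    """Per-type functional/pseudogene inventory.

    ``table`` rows are indexed by ``<locus_label><segment_type>`` (e.g.
    TRAV) with columns n_functional, n_pseudogene, n_total,
    pct_functional, pct_pseudogene, fp_ratio (NaN where undefined).
    """

    table: pd.DataFrame

    def row(self, key: str) -> pd.Series:
        return self.table.loc[key]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; rows functional/pseudogene, columns long/short intron."""

    counts: tuple[tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        if any(c < 0 for row in self.counts for c in row):
            raise ValueError("counts must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)

    def swapped_rows(self) -> "ContingencyTable":
        return ContingencyTable((self.counts[1], self.counts[0]))


@dataclass(frozen=True)
class WilcoxonResult:
    p_value: float
    statistic: float
    method: str  # exact | asymptotic_tie_corrected


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float  # conditional MLE
    ci_low: float
    ci_high: float
    conf_level: float = 0.95


def _fmt_ratio(n_f: int, n_p: int, mode: str) -> float:
    if n_p == 0:
        return float("nan")
    r = n_f / n_p
    if mode == "truncate_2dp":
        return math.floor(r * 100) / 100
    return round(r, 2)


def summarize_locus(ann: LocusAnnotation, cfg: StatsConfig = StatsConfig()) -> SummaryTable:
    """Counts, percentages and F/P ratio per segment type."""
    rows = {}
    order = []
    for seg in ann.records:
        if seg.functionality not in ("F", "P"):
            raise ValueError(f"{seg.gene_id} is unclassified")
        key = f"{seg.locus_label}{seg.segment_type}"
        if key not in rows:
            rows[key] = [0, 0]
            order.append(key)
        rows[key][0 if seg.functionality == "F" else 1] += 1
    data = []
    for key in order:
        n_f, n_p = rows[key]
        n = n_f + n_p
        data.append(
            {
                "n_functional": n_f,
                "n_pseudogene": n_p,
                "n_total": n,
                "pct_functional": round(100.0 * n_f / n, cfg.percent_decimals),
                "pct_pseudogene": round(100.0 * n_p / n, cfg.percent_decimals),
                "fp_ratio": _fmt_ratio(n_f, n_p, cfg.ratio_rounding),
            }
        )
    return SummaryTable(pd.DataFrame(data, index=pd.Index(order, name="gene_type")))


def locus_span(start: float, end: float, units: str = "Mbp") -> float:
    """Length of a locus interval, units preserved (end >= start)."""
    if end < start:
        raise ValueError(f"end {end} < start {start}")
    return end - start


def intron_lengths(ann: LocusAnnotation) -> pd.Series:
    """V-intron length per gene (bp): distance between the leader and
    the V exon in 1-based inclusive coordinates. Single-exon V genes
    (no leader) carry no intron and are excluded."""
    out = {}
    for seg in ann.of_type("V"):
        l1, v = seg.exon("L1"), seg.exon("V_EXON")
        if l1 is None or v is None:
            continue
        left, right = sorted((l1, v), key=lambda e: e.start)
        out[seg.gene_id] = right.start - left.end - 1
    return pd.Series(out, dtype=float, name="v_intron_bp")


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float], cfg: StatsConfig = StatsConfig()
) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when the combined sample is small
    (<= ``wilcoxon_exact_max_n``) and tie-free; otherwise the normal
    approximation with tie and continuity corrections. The method used
    is recorded in the result.
    """
    a, b = list(a), list(b)
    if not a or not b:
        raise ValueError("both groups must be nonempty")
    ties = len(set(a) | set(b)) < len(a) + len(b)
    exact = (len(a) + len(b) <= cfg.wilcoxon_exact_max_n) and not ties
    res = sps.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return WilcoxonResult(
        p_value=float(min(res.pvalue, 1.0)),
        statistic=float(res.statistic),
        method="exact" if exact else "asymptotic_tie_corrected",
    )


# ---------------------------------------------------------------------------
# Fisher exact test, R convention


def _nch(psi: float, N: int, K: int, n: int):
    """Fisher noncentral hypergeometric for cell (1,1) given margins."""
    return nchypergeom_fisher(N, K, n, psi)


def fisher_exact(
    table: "ContingencyTable | Sequence[Sequence[int]]",
    conf_level: float = 0.95,
) -> FisherResult:
    """Two-sided Fisher exact test with conditional-MLE odds ratio and
    exact confidence interval.

    p is the sum of probabilities of all tables with the observed
    margins whose hypergeometric probability does not exceed the
    observed one. The odds ratio maximizes the conditional likelihood,
    and the CI inverts the one-sided exact conditional tests; both
    follow R's ``fisher.test``.
    """
    if isinstance(table, ContingencyTable):
        t = table.as_array()
    else:
        t = ContingencyTable(tuple(map(tuple, table))).as_array()
    x = int(t[0, 0])
    K = int(t[0, 0] + t[0, 1])  # row-1 margin
    n = int(t[0, 0] + t[1, 0])  # column-1 margin
    N = int(t.sum())
    p = float(sps.fisher_exact(t, alternative="two-sided")[1])

    lo = max(0, K + n - N)
    hi = min(K, n)
    if lo == hi:  # degenerate margins: a single possible table
        return FisherResult(1.0, float("nan"), 0.0, float("inf"), conf_level)

    odds = _conditional_mle(x, N, K, n, lo, hi)
    alpha2 = (1.0 - conf_level) / 2.0
    ci_low = 0.0 if x == lo else _solve_psi(
        lambda psi: _nch(psi, N, K, n).sf(x - 1) - alpha2
    )
    ci_high = float("inf") if x == hi else _solve_psi(
        lambda psi: alpha2 - _nch(psi, N, K, n).cdf(x)
    )
    return FisherResult(p, odds, ci_low, ci_high, conf_level)


def _conditional_mle(x, N, K, n, lo, hi) -> float:
    if x == lo:
        return 0.0
    if x == hi:
        return float("inf")
    f = lambda logpsi: _nch(math.exp(logpsi), N, K, n).mean() - x
    return math.exp(brentq(f, -36.0, 36.0, xtol=1e-12))


def _solve_psi(g) -> float:
    """Root of a monotone function of the odds ratio on (0, inf)."""
    f = lambda logpsi: g(math.exp(logpsi))
    a, b = -36.0, 36.0
    fa, fb = f(a), f(b)
    if fa == 0.0:
        return math.exp(a)
    if fa * fb > 0:
        return 0.0 if fa < 0 and fb < 0 else float("inf")
    return math.exp(brentq(f, a, b, xtol=1e-10))


def long_intron_table(
    ann: LocusAnnotation, cfg: StatsConfig = StatsConfig()
) -> ContingencyTable:
    """Cross-classify V genes: functional/pseudogene x long/short
    V-intron (long means strictly above the threshold, default 650 bp).
    Genes without a measurable intron are excluded."""
    lens = intron_lengths(ann)
    counts = [[0, 0], [0, 0]]
    for seg in ann.of_type("V"):
        if seg.gene_id not in lens.index:
            continue
        if seg.functionality not in ("F", "P"):
            raise ValueError(f"{seg.gene_id} is unclassified")
        i = 0 if seg.functionality == "F" else 1
        j = 0 if lens[seg.gene_id] > cfg.long_intron_threshold else 1
        counts[i][j] += 1
    return ContingencyTable((tuple(counts[0]), tuple(counts[1])))
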