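"""Co-localization statistics: log-space enrichment tests, percentages,
emergent-region logic, signal profiles/heat maps, and rank-sum comparisons.

Two regions co-localize when they overlap by at least 1 bp.  Enrichment
tests (hypergeometric and binomial upper tails) are computed by log-gamma
summation so probabilities far below the double underflow limit (the
analyses here report values like 1e-300) remain representable as log10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

from .genome_core import GenomicInterval, TagLibrary, check_disjoint, _IntervalIndex
from .island_caller import Island

__all__ = [
    "ProfileParams",
    "log10_hypergeom_tail",
    "log10_binomial_tail",
    "percent",
    "emergent_regions",
    "top_n",
    "average_profile",
    "profile_matrix",
    "heatmap_matrix",
    "wilcoxon_rank_sum",
    "RankSumResult",
]

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class ProfileParams:
    """Binning geometry for average profiles and heat maps around element
    centers: 5-bp bins to +/-10 kb for profiles, 50-bp bins for heat maps,
    with rows ranked by signal in the central 400-bp window."""

    halfwidth: int = 10_000
    bin_size: int = 5
    heatmap_resolution: int = 50
    rank_window: int = 400

    def __post_init__(self) -> None:
        if self.halfwidth % self.bin_size != 0:
            raise ValueError("bin_size must divide halfwidth")
        if self.rank_window % self.heatmap_resolution != 0:
            raise ValueError("rank_window must be a multiple of heatmap_resolution")


# ---------------------------------------------------------------------------
# log-space enrichment tests
# ---------------------------------------------------------------------------

def _log_hypergeom_pmf(N: int, K: int, n: int, ks: np.ndarray) -> np.ndarray:
    return (gammaln(K + 1) - gammaln(ks + 1) - gammaln(K - ks + 1)
            + gammaln(N - K + 1) - gammaln(n - ks + 1) - gammaln(N - K - n + ks + 1)
            - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1)))


def log10_hypergeom_tail(N: int, K: int, n: int, k: int,
                         strict: bool = False) -> float:
    """log10 of the hypergeometric upper tail.

    By default the inclusive tail P(X >= k) of drawing ``k`` marked items
    in a sample of ``n`` from a population of ``N`` with ``K`` marked.
    ``strict=True`` gives P(X > k), the convention of R's
    ``phyper(..., lower.tail=FALSE)`` and of some published analyses.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= n and k <= K):
        raise ValueError(f"invalid hypergeometric input N={N} K={K} n={n} k={k}")
    lo = k + 1 if strict else k
    hi = min(n, K)
    if lo <= 0:
        return 0.0
    if lo > hi:
        return -math.inf
    ks = np.arange(lo, hi + 1)
    return float(logsumexp(_log_hypergeom_pmf(N, K, n, ks)) / _LN10)


def log10_binomial_tail(n: int, k: int, p0: float,
                        strict: bool = False) -> float:
    """log10 of the binomial upper tail P(X >= k) (or P(X > k) with
    ``strict=True``) for ``n`` trials at success probability ``p0``."""
    if not (0 <= k <= n):
        raise ValueError(f"invalid binomial input n={n} k={k}")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0, 1)")
    lo = k + 1 if strict else k
    if lo <= 0:
        return 0.0
    if lo > n:
        return -math.inf
    ks = np.arange(lo, n + 1)
    logpmf = (gammaln(n + 1) - gammaln(ks + 1) - gammaln(n - ks + 1)
              + ks * math.log(p0) + (n - ks) * math.log1p(-p0))
    return float(logsumexp(logpmf) / _LN10)


def percent(k: int, n: int) -> float:
    """100*k/n rounded half-away-from-zero to one decimal place."""
    if n == 0:
        raise ValueError("denominator must be nonzero")
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    return float((Decimal(100) * Decimal(k) / Decimal(n))
                 .quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# emergent regions over a time course
# ---------------------------------------------------------------------------

def emergent_regions(
    ordered_sets: Sequence[Sequence[Island]],
) -> List[List[Island]]:
    """Per-time-point emergent islands.

    An island is emergent at time t if it overlaps (>= 1 bp) no island of
    any earlier time point.  The first set is emergent in full.
    """
    for s in ordered_sets:
        check_disjoint([i.interval for i in s], "island set")
    out: List[List[Island]] = []
    earlier: List[GenomicInterval] = []
    for t, current in enumerate(ordered_sets):
        if t == 0:
            out.append(list(current))
        else:
            index = _IntervalIndex(earlier)
            out.append([isl for isl in current if not index.query(isl.interval)])
        earlier.extend(i.interval for i in current)
    return out


def top_n(islands: Sequence[Island], n: int) -> List[Island]:
    """Top-n islands ranked by ascending FDR, ties broken by descending
    score, then genomic coordinate."""
    ranked = sorted(
        islands,
        key=lambda i: (i.log10_fdr, -i.score, i.interval.sort_key()),
    )
    return ranked[:n]


# ---------------------------------------------------------------------------
# profiles and heat maps
# ---------------------------------------------------------------------------

def profile_matrix(
    tags: TagLibrary,
    centers: Sequence[Tuple[str, int]],
    halfwidth: int,
    bin_size: int,
) -> np.ndarray:
    """Matrix of reads-per-million per bin around each center.

    Rows follow the input center order; columns run left to right in
    genome coordinates over [center - halfwidth, center + halfwidth).
    """
    if not centers:
        raise ValueError("need at least one center")
    n_bins = 2 * halfwidth // bin_size
    scale = 1e6 / tags.total_count if tags.total_count else 0.0
    mat = np.zeros((len(centers), n_bins))
    edges = np.arange(n_bins + 1) * bin_size
    for row, (chrom, c) in enumerate(centers):
        arr = tags.positions.get(chrom)
        if arr is None:
            continue
        left = c - halfwidth
        lo = np.searchsorted(arr, left)
        hi = np.searchsorted(arr, c + halfwidth)
        if hi > lo:
            rel = arr[lo:hi] - left
            mat[row] = np.histogram(rel, bins=edges)[0] * scale
    return mat


def average_profile(
    tags: TagLibrary,
    centers: Sequence[Tuple[str, int]],
    params: ProfileParams = ProfileParams(),
) -> np.ndarray:
    """Column means of the per-center profile matrix (depth-normalized
    tag counts per bin, averaged over centers)."""
    mat = profile_matrix(tags, centers, params.halfwidth, params.bin_size)
    return mat.mean(axis=0)


def heatmap_matrix(
    tags: TagLibrary,
    centers: Sequence[Tuple[str, int]],
    params: ProfileParams = ProfileParams(),
    ranking_tags: Optional[TagLibrary] = None,
) -> Tuple[np.ndarray, List[int]]:
    """Heat-map matrix around centers with rows ranked by central signal.

    Rows (one per center) are sorted by descending signal of
    ``ranking_tags`` (default: ``tags`` itself) within the central
    ``rank_window``; columns are ``heatmap_resolution`` bins spanning
    +/- halfwidth.  Returns the sorted matrix and the row order as indices
    into the input center list.
    """
    mat = profile_matrix(tags, centers, params.halfwidth,
                         params.heatmap_resolution)
    ranker = ranking_tags if ranking_tags is not None else tags
    half_rank = params.rank_window // 2
    signal = np.array([
        ranker.count_in(chrom, c - half_rank, c + half_rank)
        for chrom, c in centers
    ])
    order = sorted(range(len(centers)),
                   key=lambda i: (-signal[i], centers[i][0], centers[i][1]))
    return mat[order], order


# ---------------------------------------------------------------------------
# rank-sum comparison
# ---------------------------------------------------------------------------

class RankSumResult(NamedTuple):
    two_sided: float
    less: float
    greater: float


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> RankSumResult:
    """Wilcoxon rank-sum (Mann-Whitney) test of two samples.

    Exact enumeration when the smaller group has <= 8 members and the data
    are tie-free; otherwise the normal approximation with midrank tie
    correction (no continuity correction).  Returns two-sided and both
    one-sided p-values ('less' tests a shifted below b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return RankSumResult(1.0, 1.0, 1.0)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    ps = {}
    for alt in ("two-sided", "less", "greater"):
        res = stats.mannwhitneyu(a, b, alternative=alt, method=method,
                                 use_continuity=False)
        ps[alt] = min(1.0, float(res.pvalue))
    return RankSumResult(ps["two-sided"], ps["less"], ps["greater"])
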