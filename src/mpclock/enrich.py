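"""Hypergeometric over/underrepresentation of locus sets.

Two flavours: interval-based (do clock loci fall in genomic features
more or less often than their selection background, optionally after
expanding each query position by a proximity window), and set-based
(the representation factor of the overlap of two locus sets drawn from
a common universe).  P-values come from the hypergeometric law of the
2x2 margins; odds-ratio confidence intervals use the Woolf log-odds
approximation with a Haldane-Anscombe correction for empty cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .containers import EnrichmentResult
from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass
class IntervalSet:
    """Named collection of 0-based half-open genomic intervals."""

    name: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise InputError(
                    f"{self.name}: interval must satisfy start < end, got {chrom}:{start}-{end}"
                )

    @classmethod
    def from_dataframe(cls, name: str, df) -> "IntervalSet":
        return cls(name, [(str(r.chrom), int(r.start), int(r.end)) for r in df.itertuples()])

    @classmethod
    def from_positions(cls, name: str, positions) -> "IntervalSet":
        """1-bp intervals from (chrom, pos) locus keys (array-probe style)."""
        return cls(name, [(str(c), int(p), int(p) + 1) for c, p in positions])

    def merged(self) -> "IntervalSet":
        """Sort and merge overlapping or adjacent intervals per chromosome."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.intervals:
            by_chrom.setdefault(chrom, []).append((start, end))
        merged = []
        for chrom in sorted(by_chrom):
            ivs = sorted(by_chrom[chrom])
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    merged.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((chrom, cur_s, cur_e))
        return IntervalSet(self.name, merged)

    def trees(self) -> dict[str, IntervalTree]:
        out: dict[str, IntervalTree] = {}
        for chrom, start, end in self.merged().intervals:
            out.setdefault(chrom, IntervalTree()).addi(start, end)
        return out


def overlap_counts(
    query: IntervalSet,
    background: IntervalSet,
    features: IntervalSet,
    window: int = 0,
) -> tuple[int, int, int, int]:
    """Contingency margins (k, n, K, N) for query vs background hits.

    A locus hits a feature iff its interval, expanded by ``window``
    bases on each side, intersects any (merged) feature interval.
    Query loci absent from the background are inconsistent with the
    sampling model and are dropped with a log entry.
    """
    if window < 0:
        raise InputError("window must be >= 0")
    bg = set(background.intervals)
    q = [iv for iv in query.intervals if iv in bg]
    dropped = len(query.intervals) - len(q)
    if dropped:
        logger.warning("dropped %d query loci not present in the background", dropped)
    trees = features.trees()

    def hit(iv: tuple[str, int, int]) -> bool:
        chrom, start, end = iv
        tree = trees.get(chrom)
        return bool(tree and tree.overlap(max(0, start - window), end + window))

    k = sum(hit(iv) for iv in q)
    K = sum(hit(iv) for iv in bg)
    return k, len(q), K, len(bg)


def _two_sided_hypergeom_p(k: int, n: int, K: int, N: int, method: str) -> float:
    """Two-sided p for observing k hits drawing n from N with K marked."""
    rv = stats.hypergeom(N, K, n)
    lo, hi = max(0, n + K - N), min(n, K)
    if method == "min-likelihood":
        # Fisher-style: total probability of outcomes no more likely
        # than the observed one
        support = np.arange(lo, hi + 1)
        pmf = rv.pmf(support)
        p = float(pmf[pmf <= rv.pmf(k) * (1 + 1e-9)].sum())
    elif method == "doubled":
        lower = float(rv.cdf(k))
        upper = float(rv.sf(k - 1))
        p = 2.0 * min(lower, upper)
    else:
        raise InputError(f"unknown method {method!r}")
    return min(1.0, p)


def hypergeom_test(
    k: int, n: int, K: int, N: int, feature: str = "", window: int = 0,
    method: str = "min-likelihood",
) -> EnrichmentResult:
    """Hypergeometric 2x2 over/underrepresentation test.

    The table is (k, n-k, K-k, N-n-K+k); the odds ratio is its
    cross-product ratio with a Woolf 95% CI on the log scale
    (Haldane-Anscombe 0.5 added to every cell, and flagged, when any
    cell is zero); ``representation_factor`` is observed/expected hits,
    k / (nK/N).
    """
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise InputError(f"inconsistent margins k={k} n={n} K={K} N={N}")
    if n == 0 or N == 0:
        raise InputError("query and background must be non-empty")
    p = _two_sided_hypergeom_p(k, n, K, N, method)

    a, b, c, d = k, n - k, K - k, N - n - K + k
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = float(np.exp(np.log(odds) - 1.96 * se))
    ci_high = float(np.exp(np.log(odds) + 1.96 * se))
    expected = n * K / N
    rf = k / expected if expected > 0 else float("nan")
    return EnrichmentResult(
        feature=feature, k=k, n=n, K=K, N=N,
        odds_ratio=float(odds), ci_low=ci_low, ci_high=ci_high,
        p=p, representation_factor=float(rf), window=window, corrected=corrected,
    )


def interval_enrichment(
    query: IntervalSet,
    background: IntervalSet,
    features: IntervalSet,
    windows: tuple[int, ...] = (0, 25),
    method: str = "min-likelihood",
) -> list[EnrichmentResult]:
    """Run the overlap test for each proximity window (direct + nearby)."""
    out = []
    for window in windows:
        k, n, K, N = overlap_counts(query, background, features, window)
        out.append(hypergeom_test(k, n, K, N, feature=features.name, window=window, method=method))
    return out


def set_overlap_rf(setA: set, setB: set, universe: set) -> tuple[float, float]:
    """Representation factor and p of the overlap of two locus sets.

    rf = |A & B| * |U| / (|A| * |B|), i.e. observed over expected
    overlap under independent draws from the universe; p is the
    two-sided hypergeometric tail (doubled smaller tail, capped at 1).
    """
    if not setA or not setB:
        raise InputError("setA and setB must be non-empty")
    if not (setA <= universe and setB <= universe):
        raise InputError("both sets must be subsets of the universe")
    k = len(setA & setB)
    n, K, N = len(setA), len(setB), len(universe)
    rf = k * N / (n * K)
    p = _two_sided_hypergeom_p(k, n, K, N, method="doubled")
    return float(rf), float(p)
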