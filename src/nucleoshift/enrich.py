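"""Hypergeometric network scoring and transcript-set Venn bookkeeping.

The network score of a gene network is the negative base-10 logarithm of a
right-tailed Fisher's exact (hypergeometric) p-value for the overlap
between a differential data set and the network: with ``N`` molecules in
total, ``K`` of them in the network, a data set of size ``n`` and ``k``
network-eligible molecules in the data set,

    p = P(X >= k),  X ~ Hypergeometric(N, K, n),    score = -log10(p).

Scores in the 40s correspond to p ~ 1e-41, far below double-precision
comfort for naive summation of products, so the tail is accumulated in log
space from gamma-function evaluations of the pmf.

Differential-transcript lists from two conditions are summarized as a
three-way Venn partition (A-only, B-only, shared) of opaque transcript IDs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "EnrichmentInput",
    "ScoreResult",
    "VennPartition",
    "hypergeom_right_tail",
    "log10_right_tail",
    "network_score",
    "enrichment_score",
    "venn_partition",
]


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts entering the hypergeometric network score.

    universe_size ``N``: molecules considered in total; network_size ``K``:
    molecules in the network; dataset_size ``n``: molecules in the data set;
    overlap ``k``: network-eligible molecules in the data set.
    """

    universe_size: int
    network_size: int
    dataset_size: int
    overlap: int

    def __post_init__(self) -> None:
        N, K, n, k = (
            self.universe_size,
            self.network_size,
            self.dataset_size,
            self.overlap,
        )
        if N < 0:
            raise ValueError(f"universe_size must be >= 0, got {N}")
        if not 0 <= K <= N:
            raise ValueError(f"network_size must satisfy 0 <= K <= N: K={K}, N={N}")
        if not 0 <= n <= N:
            raise ValueError(f"dataset_size must satisfy 0 <= n <= N: n={n}, N={N}")
        if not 0 <= k <= min(K, n):
            raise ValueError(
                f"overlap must satisfy 0 <= k <= min(K, n): k={k}, K={K}, n={n}"
            )
        if k < n + K - N:
            raise ValueError(
                f"overlap below the hypergeometric support: k={k} < n+K-N={n + K - N}"
            )


@dataclass(frozen=True)
class ScoreResult:
    """A p-value and its network score, ``score = -log10(p)``."""

    p_value: float
    score: float


@dataclass(frozen=True)
class VennPartition:
    """Three-way partition of two ID sets: exclusive and shared counts."""

    only_a: int
    only_b: int
    shared: int

    @property
    def size_a(self) -> int:
        return self.only_a + self.shared

    @property
    def size_b(self) -> int:
        return self.only_b + self.shared


def _log_pmf(N: int, K: int, n: int, ks: np.ndarray) -> np.ndarray:
    # log C(K, k) + log C(N-K, n-k) - log C(N, n), via gammaln
    def logcomb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return logcomb(K, ks) + logcomb(N - K, n - ks) - logcomb(N, n)


def log10_right_tail(inp: EnrichmentInput) -> float:
    """log10 of the inclusive right tail P(X >= k), computed in log space."""
    N, K, n, k = inp.universe_size, inp.network_size, inp.dataset_size, inp.overlap
    if k <= max(0, n + K - N):
        return 0.0  # tail covers the whole support
    ks = np.arange(k, min(K, n) + 1)
    log_p = logsumexp(_log_pmf(N, K, n, ks))
    return float(min(log_p, 0.0) / np.log(10.0))


def hypergeom_right_tail(inp: EnrichmentInput) -> float:
    """Right-tailed Fisher's exact p-value, P(X >= k), inclusive of k."""
    return float(10.0 ** log10_right_tail(inp))


def network_score(p: float) -> float:
    """Network score of a p-value: ``-log10(p)`` for p in (0, 1]."""
    if not 0 < p <= 1:
        raise ValueError(f"p-value must be in (0, 1], got {p}")
    return float(-np.log10(p))


def enrichment_score(inp: EnrichmentInput) -> ScoreResult:
    """p-value and network score for one enrichment input, end-to-end in log
    space so that scores of 40+ (p ~ 1e-41 and below) stay exact."""
    log10_p = log10_right_tail(inp)
    return ScoreResult(p_value=float(10.0 ** log10_p), score=-log10_p)


def venn_partition(set_a: Iterable[str], set_b: Iterable[str]) -> VennPartition:
    """Exact three-way partition of two transcript-ID sets.

    IDs are opaque strings; counts reconstruct the input cardinalities
    (``only_a + shared = |A|`` etc.).
    """
    a, b = set(set_a), set(set_b)
    shared = a & b
    return VennPartition(
        only_a=len(a - shared), only_b=len(b - shared), shared=len(shared)
    )
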