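"""Gene-set over-representation analysis by the hypergeometric upper tail.

Tests whether a differential-expression gene list contains more members of
a gene-ontology-style category than expected by chance, against a
background of expressed genes. The statistic is the exact one-sided
hypergeometric tail P(X >= k) for drawing ``n`` genes from a background of
``N`` of which ``K`` belong to the set, computed by exact integer
summation. Significance is flagged on the raw p-value (default alpha
0.01); Benjamini-Hochberg adjusted values are reported alongside but do
not drive the flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .io import GeneSet

logger = logging.getLogger(__name__)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact P(X >= k) for hypergeometric X with parameters (N, K, n).

    Integer summation over the support: sum_i C(K,i) C(N-K, n-i) / C(N,n)
    for i from k to min(K, n); exact up to the final float division.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K <= N and 0 <= n <= N, got N={N} K={K} n={n}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"need 0 <= k <= min(K, n), got k={k}, min={min(K, n)}")
    if k == 0:
        return 1.0
    lo = max(k, n - (N - K))
    numer = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(lo, min(K, n) + 1))
    return numer / math.comb(N, n)


@dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation record for one gene set.

    ``N`` background size, ``K`` background genes in the set, ``n`` DE-list
    size (restricted to background), ``k`` overlap.
    """

    set_id: str
    description: str
    N: int
    K: int
    n: int
    k: int
    p_hyper: float
    p_adj: float
    significant: bool
    overlap_genes: tuple[str, ...] = ()


def run_overrepresentation(
    de_genes: Iterable[str],
    background: Iterable[str],
    gene_sets: Sequence[GeneSet],
    alpha_enrich: float = 0.01,
) -> list[EnrichmentResult]:
    """Test each gene set for over-representation in the DE list.

    Symbols are matched case-insensitively. DE genes absent from the
    background are dropped with a warning. Sets with no background member
    are skipped. Results are sorted by increasing raw p-value.
    """
    bg = {g.upper() for g in background}
    if not bg:
        raise ValueError("background is empty")
    de_raw = [g.upper() for g in de_genes]
    de = set(de_raw) & bg
    dropped = set(de_raw) - bg
    if dropped:
        logger.warning(
            "%d DE gene(s) absent from background dropped: %s",
            len(dropped), ", ".join(sorted(dropped)[:10]),
        )
    N, n = len(bg), len(de)
    rows: list[tuple[GeneSet, int, int, tuple[str, ...], float]] = []
    for gs in gene_sets:
        members = {m.upper() for m in gs.members} & bg
        K = len(members)
        if K == 0:
            continue
        overlap = tuple(sorted(members & de))
        k = len(overlap)
        rows.append((gs, K, k, overlap, hypergeom_upper_tail(N, K, n, k)))
    if not rows:
        return []
    pvals = [r[4] for r in rows]
    padj = stats.false_discovery_control(pvals, method="bh")
    results = [
        EnrichmentResult(
            set_id=gs.set_id,
            description=gs.description,
            N=N, K=K, n=n, k=k,
            p_hyper=p,
            p_adj=float(pa),
            significant=p < alpha_enrich,
            overlap_genes=overlap,
        )
        for (gs, K, k, overlap, p), pa in zip(rows, padj)
    ]
    results.sort(key=lambda r: (r.p_hyper, r.set_id))
    return results
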