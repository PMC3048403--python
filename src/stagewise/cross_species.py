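"""Cross-species concordance of a DE gene list against reference platforms.

Given a list of differentially expressed genes from the mouse model and a
reference (e.g. human tumour-vs-normal) platform table of per-gene
p-values and fold changes, each gene is scored by its percentile rank when
the platform is sorted by increasing p-value. A gene is *significant* on
the platform when its rank is at or below ``rank_threshold`` percent, and
*concordant* when it is significant (and, optionally, changes in the same
direction as the mouse call). Genes absent from the platform, or below
its detection limit, are printed ``x``: they count in ``n`` but never in
``k``.

The overlap statistic is the upper-tail cumulative binomial
P(X >= k | n, p_null) with a per-gene null success probability that
defaults to ``rank_threshold / 100`` — under the null, a random gene lands
in the top r% of the p-value ranking with probability r/100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_RANK_THRESHOLD = 10.0

# bundled reference comparison of down-regulated cytoskeletal / focal
# adhesion genes across two archived human ovarian-cancer platforms
REFERENCE_COMPARISON_RESOURCE = "ovarian_platform_comparison.tsv"


def percentile_rank(p_values: Mapping[str, float] | pd.Series, query_gene: str) -> float:
    """Percentile position of one gene when sorting by increasing p-value.

    1-based average rank (ties get their mean rank) divided by the
    platform size, times 100. The query gene must be present.
    """
    s = pd.Series(p_values, dtype=float)
    if query_gene not in s.index:
        raise KeyError(f"gene {query_gene!r} not on platform")
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("platform p-values must be finite")
    ranks = stats.rankdata(s.to_numpy(), method="average")
    pos = s.index.get_loc(query_gene)
    return float(ranks[pos] / len(s) * 100.0)


def binomial_upper_tail(n: int, k: int, p_null: float) -> float:
    """Exact cumulative binomial P(X >= k) = sum_{i=k}^{n} C(n,i) p^i (1-p)^(n-i)."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0 < p_null < 1:
        raise ValueError(f"p_null must be in (0, 1), got {p_null}")
    if k == 0:
        return 1.0
    return float(
        sum(
            math.comb(n, i) * p_null**i * (1 - p_null) ** (n - i)
            for i in range(k, n + 1)
        )
    )


@dataclass(frozen=True)
class OverlapSummary:
    """Concordance count and its cumulative-binomial tail probability."""

    n: int
    k: int
    p_null: float
    binom_p: float


def summarize_overlap(
    gene_list: Sequence[str],
    platform_table: pd.DataFrame,
    rank_threshold: float = DEFAULT_RANK_THRESHOLD,
    direction_map: Mapping[str, int] | None = None,
    p_null: float | None = None,
    check_direction: bool = False,
) -> tuple[OverlapSummary, pd.DataFrame]:
    """Score a mouse DE gene list against one reference platform.

    ``platform_table`` needs a ``gene`` column plus either a
    ``percentile_rank`` column (precomputed ranks, as published comparison
    tables print them) or a ``p_value`` column from which ranks are
    computed over the whole table; a signed ``fold_change`` column is
    required when ``check_direction`` is on. Matching is
    case-insensitive. Returns the overlap summary and a per-gene table
    mirroring the published layout (rank/fold/p, or ``x`` for genes absent
    or below detection).
    """
    if len(gene_list) == 0:
        raise ValueError("empty gene list")
    if "gene" not in platform_table.columns:
        raise ValueError("platform table needs a 'gene' column")
    table = platform_table.copy()
    table["_key"] = table["gene"].astype(str).str.upper()
    if table["_key"].duplicated().any():
        raise ValueError("platform table has duplicate gene symbols")
    if "percentile_rank" not in table.columns:
        if "p_value" not in table.columns:
            raise ValueError("platform table needs 'percentile_rank' or 'p_value'")
        pv = table["p_value"].astype(float)
        table["percentile_rank"] = stats.rankdata(pv, method="average") / len(pv) * 100.0
    lookup = table.set_index("_key")
    if p_null is None:
        p_null = rank_threshold / 100.0

    rows = []
    k = 0
    for gene in gene_list:
        key = gene.upper()
        if key not in lookup.index or not np.isfinite(
            float(lookup.loc[key, "percentile_rank"])
        ):
            rows.append(
                {"gene": gene, "rank_pct": None, "fold_change": None,
                 "p_value": None, "significant": False, "concordant": False}
            )
            continue
        rec = lookup.loc[key]
        rank = float(rec["percentile_rank"])
        fold = float(rec["fold_change"]) if "fold_change" in rec and pd.notna(rec.get("fold_change")) else None
        pval = float(rec["p_value"]) if "p_value" in rec and pd.notna(rec.get("p_value")) else None
        significant = rank <= rank_threshold
        concordant = significant
        if check_direction and significant:
            if direction_map is None:
                raise ValueError("check_direction requires a direction_map")
            mouse_dir = direction_map.get(gene, direction_map.get(key))
            if mouse_dir is None:
                raise ValueError(f"no mouse direction for {gene!r}")
            if fold is None:
                raise ValueError(f"no platform fold change for {gene!r}")
            concordant = np.sign(fold) == np.sign(mouse_dir)
        k += int(concordant)
        rows.append(
            {"gene": gene, "rank_pct": rank, "fold_change": fold,
             "p_value": pval, "significant": significant, "concordant": concordant}
        )
    n = len(gene_list)
    summary = OverlapSummary(
        n=n, k=k, p_null=p_null, binom_p=binomial_upper_tail(n, k, p_null)
    )
    return summary, pd.DataFrame(rows)


def format_overlap_table(per_gene: pd.DataFrame) -> pd.DataFrame:
    """Render the per-gene table with ``x`` for absent/undetected genes."""
    out = per_gene.copy()
    for col, fmt in (("rank_pct", "{:.1f}%"), ("fold_change", "{:.1f}"),
                     ("p_value", "{:.2e}")):
        out[col] = [
            fmt.format(v) if v is not None and pd.notna(v) else "x"
            for v in out[col]
        ]
    return out[["gene", "rank_pct", "fold_change", "p_value", "concordant"]]


def load_reference_comparison(path: str | Path | None = None) -> pd.DataFrame:
    """Load the bundled two-platform comparison of cytoskeletal genes.

    Columns: ``gene`` plus ``<platform>_rank`` (percent), ``<platform>_fold``
    and ``<platform>_p`` for the illumina and affymetrix platforms; empty
    cells mark genes not significant or below detection on that platform.
    """
    if path is None:
        src = resources.files("stagewise").joinpath(
            f"data/{REFERENCE_COMPARISON_RESOURCE}"
        )
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return df


def platform_columns(comparison: pd.DataFrame, platform: str) -> pd.DataFrame:
    """Extract one platform from the comparison table as a platform table.

    Rows with no rank on that platform are dropped (they render as ``x``
    in :func:`summarize_overlap`, which matches on the remaining genes).
    """
    cols = {f"{platform}_rank": "percentile_rank",
            f"{platform}_fold": "fold_change",
            f"{platform}_p": "p_value"}
    missing = [c for c in cols if c not in comparison.columns]
    if missing:
        raise ValueError(f"comparison table lacks columns {missing}")
    out = comparison[["gene", *cols]].rename(columns=cols)
    out = out[pd.notna(out["percentile_rank"])].reset_index(drop=True)
    return out
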