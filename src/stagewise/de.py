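"""Trimmed-mean array scaling, pairwise stage statistics, and the DE filter.

Each array (column) is scaled so that its trimmed mean equals a fixed
target (500 fluorescence units by default), which puts chips on a common
scale without changing within-array structure. Per probe, signed fold
changes and two-sample t-test p-values are computed for the three pairwise
stage comparisons on the linear intensity scale, and a probe is called
differentially expressed when it is expressed above the intensity floor,
changes at least ``fold_threshold``-fold between the early and late stages,
and that change is significant at ``alpha``. No multiple-testing
correction is applied to the per-probe p-values.

Signed fold changes follow the table convention: magnitude always >= 1,
with the sign carrying direction (-2.0 means 2-fold lower).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, ProbeGeneMap, STAGES

logger = logging.getLogger(__name__)

TTestVariant = Literal["pooled", "welch"]

CONTRAST_COLUMNS = [
    "fc_ie", "p_ie", "fc_le", "p_le", "fc_il", "p_il", "max_intensity",
]


@dataclass(frozen=True)
class NormalizationConfig:
    """Per-array trimmed-mean scaling parameters.

    ``trim_fraction`` is the proportion discarded from *each* tail before
    averaging; 0.02 is the conventional trimmed mean for this platform.
    """

    target_trimmed_mean: float = 500.0
    trim_fraction: float = 0.02

    def __post_init__(self) -> None:
        if self.target_trimmed_mean <= 0:
            raise ValueError("target_trimmed_mean must be > 0")
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")


@dataclass(frozen=True)
class FilterConfig:
    """Differential-expression filter thresholds (all inclusive)."""

    intensity_floor: float = 500.0
    fold_threshold: float = 2.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.intensity_floor <= 0 or self.fold_threshold <= 0 or self.alpha <= 0:
            raise ValueError("filter thresholds must be strictly positive")
        if self.alpha > 1:
            raise ValueError("alpha must be <= 1")


@dataclass(frozen=True)
class StageContrast:
    """Per-probe statistics for the three pairwise stage comparisons."""

    probe_id: str
    fc_ie: float
    p_ie: float
    fc_le: float
    p_le: float
    fc_il: float
    p_il: float
    max_intensity: float


def trimmed_mean(values: np.ndarray, trim_fraction: float) -> float:
    """Mean after discarding floor(trim_fraction * n) values from each tail."""
    v = np.sort(np.asarray(values, dtype=float))
    k = math.floor(trim_fraction * v.size)
    kept = v[k : v.size - k] if k > 0 else v
    if kept.size == 0:
        raise ValueError("no values left after trimming")
    return float(kept.mean())


def scale_trimmed_mean(
    matrix: ExpressionMatrix, config: NormalizationConfig | None = None
) -> ExpressionMatrix:
    """Scale each column so its trimmed mean equals the target.

    Columns are scaled independently; a column whose trimmed mean is zero
    (all-zero array) cannot be scaled and is a hard error.
    """
    config = config or NormalizationConfig()
    scaled = matrix.values.copy()
    for col in scaled.columns:
        tm = trimmed_mean(scaled[col].to_numpy(), config.trim_fraction)
        if tm <= 0:
            raise ValueError(f"degenerate array {col!r}: trimmed mean is zero")
        scaled[col] = scaled[col] * (config.target_trimmed_mean / tm)
    return matrix.with_values(scaled)


def signed_fold_change(mean_test: float, mean_ref: float) -> float:
    """Ratio with magnitude >= 1 and a sign for direction."""
    if mean_test <= 0 or mean_ref <= 0:
        raise ValueError("signed fold change requires positive means")
    r = mean_test / mean_ref
    return r if r >= 1 else -1.0 / r


def ttest_two_sample(
    group_a: Sequence[float],
    group_b: Sequence[float],
    variant: TTestVariant = "pooled",
) -> float:
    """Two-sided two-sample t-test p-value.

    ``pooled`` is the homoscedastic (spreadsheet-style) test; ``welch``
    drops the equal-variance assumption. When the pooled variance is zero
    the p-value is 1 for equal means and 0 otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(res.pvalue)


def _vector_ttest(
    a: np.ndarray, b: np.ndarray, variant: TTestVariant
) -> np.ndarray:
    """Row-wise two-sample t-test over probes x replicates arrays."""
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant rows trip scipy's precision-loss warning; they are
        # handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(a, b, axis=1, equal_var=(variant == "pooled")).pvalue
    p = np.asarray(p, dtype=float)
    # zero pooled variance: both groups constant
    degenerate = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    if degenerate.any():
        equal = a.mean(axis=1) == b.mean(axis=1)
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    return p


def _vector_signed_fc(mean_test: np.ndarray, mean_ref: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        r = mean_test / mean_ref
        out = np.where(r >= 1, r, -1.0 / r)
    out[(mean_test <= 0) | (mean_ref <= 0)] = np.nan
    return out


def contrast_stats(
    matrix: ExpressionMatrix, ttest_variant: TTestVariant = "pooled"
) -> pd.DataFrame:
    """Per-probe fold changes and p-values for I vs E, L vs E, and L vs I.

    Returns a DataFrame indexed by probe id with columns
    ``fc_ie, p_ie, fc_le, p_le, fc_il, p_il, max_intensity``. Statistics
    are computed on linear-scale replicate values; ``max_intensity`` is the
    maximum over all samples. Probes with a non-positive stage mean get
    NaN fold changes (and are later excluded by the DE filter).
    """
    groups = {}
    for stage in STAGES:
        cols = matrix.stage_columns(stage)
        if len(cols) < 2:
            raise ValueError(f"stage {stage!r} needs >= 2 replicates, has {len(cols)}")
        groups[stage] = matrix.stage_values(stage)
    e, i, l = groups["E"], groups["I"], groups["L"]
    me, mi, ml = e.mean(axis=1), i.mean(axis=1), l.mean(axis=1)
    df = pd.DataFrame(
        {
            "fc_ie": _vector_signed_fc(mi, me),
            "p_ie": _vector_ttest(i, e, ttest_variant),
            "fc_le": _vector_signed_fc(ml, me),
            "p_le": _vector_ttest(l, e, ttest_variant),
            "fc_il": _vector_signed_fc(ml, mi),
            "p_il": _vector_ttest(l, i, ttest_variant),
            "max_intensity": matrix.values.max(axis=1).to_numpy(),
        },
        index=matrix.values.index,
    )
    df.index.name = "probe_id"
    return df


def iter_contrasts(contrasts: pd.DataFrame) -> Iterator[StageContrast]:
    for probe_id, row in contrasts.iterrows():
        yield StageContrast(
            probe_id=str(probe_id),
            fc_ie=row["fc_ie"], p_ie=row["p_ie"],
            fc_le=row["fc_le"], p_le=row["p_le"],
            fc_il=row["fc_il"], p_il=row["p_il"],
            max_intensity=row["max_intensity"],
        )


@dataclass
class DeFilterResult:
    """Exhaustive, disjoint partition of probes by the DE filter."""

    up: pd.DataFrame
    down: pd.DataFrame
    excluded: pd.DataFrame

    @property
    def n_total(self) -> int:
        return len(self.up) + len(self.down) + len(self.excluded)


def passes_de_filter(
    contrast: StageContrast | pd.Series, config: FilterConfig | None = None
) -> bool:
    """Whether one probe passes the expression/fold/significance filter."""
    config = config or FilterConfig()
    fc, p, mx = contrast.fc_le, contrast.p_le, contrast.max_intensity
    if not (np.isfinite(fc) and np.isfinite(p)):
        return False
    return (
        mx > config.intensity_floor
        and abs(fc) >= config.fold_threshold
        and p <= config.alpha
    )


def de_filter(
    contrasts: pd.DataFrame, config: FilterConfig | None = None
) -> DeFilterResult:
    """Partition probes into up-regulated, down-regulated, and excluded.

    A probe is retained iff its maximum intensity exceeds the floor, the
    L-vs-E fold-change magnitude meets the threshold, and the L-vs-E
    p-value is at most alpha (fold and p thresholds inclusive). Retained
    probes are split by the sign of the L-vs-E fold change.
    """
    config = config or FilterConfig()
    fc = contrasts["fc_le"]
    keep = (
        (contrasts["max_intensity"] > config.intensity_floor)
        & (fc.abs() >= config.fold_threshold)
        & (contrasts["p_le"] <= config.alpha)
    ).fillna(False)
    up = contrasts[keep & (fc > 0)]
    down = contrasts[keep & (fc < 0)]
    excluded = contrasts[~keep]
    return DeFilterResult(up=up, down=down, excluded=excluded)


@dataclass
class GeneCollapse:
    """Direction-wise gene lists after collapsing probes to symbols."""

    up: list[str]
    down: list[str]
    both_directions: list[str]
    n_unannotated: int


def collapse_to_genes(
    de_probes: Mapping[str, Iterable[str]], probe_gene_map: ProbeGeneMap
) -> GeneCollapse:
    """Collapse DE probe lists to unique gene symbols per direction.

    ``de_probes`` maps ``"up"``/``"down"`` to probe-id lists. Unmapped
    probes are counted but excluded; a gene with probes in both directions
    appears in both lists and is logged.
    """
    n_unannotated = 0
    per_dir: dict[str, list[str]] = {}
    for direction in ("up", "down"):
        seen: set[str] = set()
        genes: list[str] = []
        for probe in de_probes.get(direction, []):
            gene = probe_gene_map.get(probe)
            if gene is None:
                n_unannotated += 1
                continue
            if gene not in seen:
                seen.add(gene)
                genes.append(gene)
        per_dir[direction] = genes
    both = sorted(set(per_dir["up"]) & set(per_dir["down"]))
    if both:
        logger.warning(
            "%d gene(s) have probes in both directions: %s", len(both), ", ".join(both)
        )
    return GeneCollapse(
        up=per_dir["up"],
        down=per_dir["down"],
        both_directions=both,
        n_unannotated=n_unannotated,
    )
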