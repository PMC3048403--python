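"""Statistics for the bench validation assays.

Three small, exactly specified computations:

* **ΔΔCt relative quantification** for qRT-PCR: ΔCt = Ct(target) -
  Ct(reference) per sample, ΔΔCt = mean ΔCt(test) - mean ΔCt(control),
  fold = 2^(−ΔΔCt); significance by a two-sided two-sample t-test on the
  ΔCt values (the standard Livak practice).
* **Densitometry percent-of-control** for western blots: band intensity
  normalized to its loading control, expressed as percent of the
  control-group mean ratio.
* **F-actin fluorescence per cell** with quotient propagation of error:
  z̄ = x̄/ȳ and σ_z = z̄ · sqrt((σ_x/x̄)² + (σ_y/ȳ)²), where x is
  fluorescence (RFU), y is cell count, and σ is the sample (n−1)
  standard deviation.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats


def delta_ct(ct_target: Sequence[float], ct_reference: Sequence[float]) -> np.ndarray:
    """Per-sample ΔCt = Ct(target) − Ct(reference)."""
    t = np.asarray(ct_target, dtype=float)
    r = np.asarray(ct_reference, dtype=float)
    if t.shape != r.shape:
        raise ValueError("target and reference Ct arrays must align")
    if not (np.isfinite(t).all() and np.isfinite(r).all()):
        raise ValueError("Ct values must be finite")
    if (t <= 0).any() or (r <= 0).any():
        raise ValueError("Ct values must be positive")
    return t - r


def ddct_fold(
    test_dcts: Sequence[float], control_dcts: Sequence[float]
) -> tuple[float, float | None]:
    """Relative expression fold of test vs control, with a t-test p-value.

    fold = 2^(−ΔΔCt) with ΔΔCt = mean(test ΔCt) − mean(control ΔCt).
    The p-value is computed on the ΔCt values and is ``None`` when either
    group has fewer than 2 replicates.
    """
    t = np.asarray(test_dcts, dtype=float)
    c = np.asarray(control_dcts, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("each group needs at least one ΔCt value")
    ddct = t.mean() - c.mean()
    fold = float(2.0 ** (-ddct))
    p: float | None = None
    if t.size >= 2 and c.size >= 2:
        if t.var(ddof=1) == 0 and c.var(ddof=1) == 0:
            p = 1.0 if t.mean() == c.mean() else 0.0
        else:
            p = float(stats.ttest_ind(t, c, equal_var=True).pvalue)
    return fold, p


def densitometry_percent(
    bands: Sequence[float],
    loading: Sequence[float],
    is_control: Sequence[bool],
) -> np.ndarray:
    """Band/loading ratios expressed as percent of the control-group mean.

    ``is_control`` flags the control-group lanes; their mean percent is
    exactly 100 by construction.
    """
    b = np.asarray(bands, dtype=float)
    l = np.asarray(loading, dtype=float)
    mask = np.asarray(is_control, dtype=bool)
    if b.shape != l.shape or b.shape != mask.shape:
        raise ValueError("bands, loading, and is_control must align")
    if (l <= 0).any():
        raise ValueError("loading-control intensities must be positive")
    if not mask.any():
        raise ValueError("control group is empty")
    ratio = b / l
    return 100.0 * ratio / ratio[mask].mean()


def factin_per_cell(
    fluor_values: Sequence[float], cell_counts: Sequence[float]
) -> tuple[float, float]:
    """Mean fluorescence per cell and its propagated standard deviation.

    Returns (z̄, σ_z) with z̄ = x̄/ȳ and
    σ_z = z̄ · sqrt((σ_x/x̄)² + (σ_y/ȳ)²); σ is the sample standard
    deviation (ddof=1). Requires at least two replicates of each input
    and strictly positive cell counts.
    """
    x = np.asarray(fluor_values, dtype=float)
    y = np.asarray(cell_counts, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 replicates per input")
    if (y <= 0).any():
        raise ValueError("cell counts must be positive")
    xbar, ybar = x.mean(), y.mean()
    if xbar <= 0:
        raise ValueError("mean fluorescence must be positive")
    zbar = xbar / ybar
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    sz = zbar * math.sqrt((sx / xbar) ** 2 + (sy / ybar) ** 2)
    return float(zbar), float(sz)
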