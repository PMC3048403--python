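"""Expression-trajectory pattern classification for three-stage designs.

A differentially expressed probe is assigned one of the stage-progression
patterns observed across the early (E), intermediate (I), and late (L)
stages:

* **late** — no significant change E -> I, significant change I -> L: the
  change happens after the intermediate stage.
* **early** — the I/E ratio already sits within ``early_window`` of the
  L/E ratio (same direction, significant at I): the change is complete by
  the intermediate stage.
* **progressive** — significant, same-direction change on both legs: a
  stepwise change across the whole progression.
* **other** — none of the above.

Rules are evaluated in fixed precedence late -> early -> progressive ->
other. Plateau (early) probes generally fail the I -> L significance leg,
so precedence only resolves boundary ties; placing early before
progressive keeps the exclusive early set small, as observed. The
``early_window`` comparison is inclusive and measured on the signed
fold-change scale of the printed ratio columns.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .de import FilterConfig, StageContrast, iter_contrasts, passes_de_filter

CLASSES = (
    "late_up",
    "late_down",
    "progressive_up",
    "progressive_down",
    "early",
    "other",
)

# coarse groups used for summary fractions
CLASS_GROUPS = {
    "late_up": "late",
    "late_down": "late",
    "progressive_up": "progressive",
    "progressive_down": "progressive",
    "early": "early",
    "other": "other",
}


@dataclass(frozen=True)
class TrajectoryParams:
    """``alpha`` gates the per-leg significance tests; ``early_window`` is
    the maximum |I/E - L/E| distance (signed fold-change units) for an
    early call."""

    alpha: float = 0.05
    early_window: float = 0.4

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.early_window < 0:
            raise ValueError("early_window must be >= 0")


@dataclass(frozen=True)
class TrajectoryCall:
    probe_id: str
    pattern: str
    contrast: StageContrast

    def __post_init__(self) -> None:
        if self.pattern not in CLASSES:
            raise ValueError(f"unknown pattern {self.pattern!r}")


def _sign(x: float) -> int:
    return 1 if x > 0 else (-1 if x < 0 else 0)


def classify_probe(
    contrast: StageContrast,
    params: TrajectoryParams | None = None,
    filter_config: FilterConfig | None = None,
) -> TrajectoryCall:
    """Assign one trajectory pattern to a DE probe.

    Precedence: late (p_IE > alpha, p_IL <= alpha, direction from the
    sign of the L/E change), then early (|fc_IE - fc_LE| <= window, same
    sign, p_IE <= alpha), then progressive (both legs significant, all
    signs agree), then other. A missing (NaN) leg p-value simply fails
    its significance condition.
    """
    params = params or TrajectoryParams()
    if not passes_de_filter(contrast, filter_config):
        raise ValueError(
            f"classify only filtered probes: {contrast.probe_id!r} is not DE"
        )
    a = params.alpha
    c = contrast
    if c.p_ie > a and (np.isfinite(c.p_il) and c.p_il <= a):
        pattern = "late_up" if c.fc_le > 0 else "late_down"
    elif (
        abs(c.fc_ie - c.fc_le) <= params.early_window
        and _sign(c.fc_ie) == _sign(c.fc_le)
        and c.p_ie <= a
    ):
        pattern = "early"
    elif (
        c.p_ie <= a
        and (np.isfinite(c.p_il) and c.p_il <= a)
        and _sign(c.fc_ie) == _sign(c.fc_il) == _sign(c.fc_le)
    ):
        pattern = "progressive_up" if c.fc_le > 0 else "progressive_down"
    else:
        pattern = "other"
    return TrajectoryCall(probe_id=c.probe_id, pattern=pattern, contrast=c)


def classify_probes(
    contrasts: pd.DataFrame,
    params: TrajectoryParams | None = None,
    filter_config: FilterConfig | None = None,
) -> list[TrajectoryCall]:
    """Classify every probe in a DE contrast table (rows must all be DE)."""
    return [
        classify_probe(c, params, filter_config) for c in iter_contrasts(contrasts)
    ]


@dataclass
class TrajectorySummary:
    """Counts and percent fractions per pattern, over all DE probes."""

    counts: dict[str, int]
    fractions_pct: dict[str, float]
    group_counts: dict[str, int]
    group_fractions_pct: dict[str, float]
    n_total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "count": pd.Series(self.counts),
                "fraction_pct": pd.Series(self.fractions_pct),
            }
        )


def summarize(calls: Sequence[TrajectoryCall] | Iterable[TrajectoryCall]) -> TrajectorySummary:
    """Tally pattern counts and fractions (percent of all DE probes)."""
    calls = list(calls)
    n = len(calls)
    counts = Counter(call.pattern for call in calls)
    full = {cls: counts.get(cls, 0) for cls in CLASSES}
    frac = {cls: (100.0 * v / n if n else 0.0) for cls, v in full.items()}
    gcounts: Counter[str] = Counter()
    for cls, v in full.items():
        gcounts[CLASS_GROUPS[cls]] += v
    groups = ("late", "progressive", "early", "other")
    gfull = {g: gcounts.get(g, 0) for g in groups}
    gfrac = {g: (100.0 * v / n if n else 0.0) for g, v in gfull.items()}
    return TrajectorySummary(
        counts=full,
        fractions_pct=frac,
        group_counts=gfull,
        group_fractions_pct=gfrac,
        n_total=n,
    )


def calls_to_frame(calls: Sequence[TrajectoryCall]) -> pd.DataFrame:
    """Per-probe call table: contrast statistics plus the assigned pattern."""
    rows = []
    for call in calls:
        c = call.contrast
        rows.append(
            {
                "probe_id": call.probe_id,
                "fc_ie": c.fc_ie, "p_ie": c.p_ie,
                "fc_le": c.fc_le, "p_le": c.p_le,
                "fc_il": c.fc_il, "p_il": c.p_il,
                "max_intensity": c.max_intensity,
                "pattern": call.pattern,
            }
        )
    return pd.DataFrame(rows).set_index("probe_id") if rows else pd.DataFrame(
        columns=["fc_ie", "p_ie", "fc_le", "p_le", "fc_il", "p_il",
                 "max_intensity", "pattern"]
    )
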