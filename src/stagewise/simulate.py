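"""Synthetic-data generators with known ground truth for every stage.

The expression simulator emulates the three-stage, three-replicate array
design: probe baselines are drawn log-normally, each probe is planted with
one trajectory class, and replicate noise is multiplicative log-normal
parameterized by its coefficient of variation (CV), so intensities stay
positive fluorescence-like units and the linear-scale t-test is exercised
the way the pipeline runs it.

Planted class semantics (log2 offsets relative to the early-stage
baseline, with effect e = ±log2(effect_fold)):

* ``early``        — (0, e, e): change complete by the intermediate stage
* ``progressive``  — (0, e/2, e): stepwise, half the log effect at I
* ``late``         — (0, 0, e): change only after the intermediate stage
* ``null``         — (0, 0, 0)

Companion generators produce gene sets with one planted enriched set, a
reference platform with a planted concordant gene subset, and qPCR Ct
tables with planted fold changes. All draws flow from a mandatory seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, Sample

PATTERN_CLASSES = ("early", "progressive", "late", "null")

DEFAULT_PROPORTIONS = {"early": 0.05, "progressive": 0.3, "late": 0.6, "null": 0.05}


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic generators.

    Defaults mirror the array design being emulated: 3 biological
    replicates per stage, a 4-fold planted effect, and trajectory-class
    proportions dominated by late-stage changes.
    """

    seed: int
    n_probes: int = 2000
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    effect_fold: float = 4.0
    p_up: float = 0.5
    baseline_log2_mean: float = 9.0
    baseline_log2_sd: float = 1.2
    cv: float = 0.05
    replicates: int = 3
    # probability of a gene having 1, 2, ... probes
    probes_per_gene: Sequence[float] = (0.7, 0.2, 0.1)
    n_gene_sets: int = 20
    gene_set_size: int = 40
    enrichment_factor: float = 5.0
    platform_size: int = 5000
    concordant_fraction: float = 0.6
    rank_threshold: float = 10.0
    qpcr_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if set(self.class_proportions) != set(PATTERN_CLASSES):
            raise ValueError(f"class_proportions must cover {PATTERN_CLASSES}")
        total = sum(self.class_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"class proportions must sum to 1, got {total}")
        if any(v < 0 for v in self.class_proportions.values()):
            raise ValueError("class proportions must be non-negative")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per stage")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _allocate_counts(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder allocation so counts match proportions within rounding."""
    keys = list(PATTERN_CLASSES)
    raw = {k: n * proportions[k] for k in keys}
    counts = {k: int(math.floor(raw[k])) for k in keys}
    short = n - sum(counts.values())
    for k in sorted(keys, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def _stage_log2_offsets(cls: str, e: float) -> tuple[float, float, float]:
    if cls == "early":
        return (0.0, e, e)
    if cls == "progressive":
        return (0.0, e / 2.0, e)
    if cls == "late":
        return (0.0, 0.0, e)
    return (0.0, 0.0, 0.0)


def simulate_expression(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate an expression matrix and its per-probe truth table.

    The truth table is indexed by probe id with columns ``gene``,
    ``pattern_class``, ``direction`` (+1/-1, meaningless for null),
    ``fold_i`` and ``fold_l`` (true signed fold changes at the
    intermediate and late stages). Multi-probe genes share one planted
    class and direction so probe- and gene-level truths agree.
    """
    rng = rng if rng is not None else config.rng()
    counts = _allocate_counts(config.n_probes, config.class_proportions)

    probe_rows: list[dict] = []
    gene_no = 0
    ppg = np.asarray(config.probes_per_gene, dtype=float)
    ppg = ppg / ppg.sum()
    for cls in PATTERN_CLASSES:
        remaining = counts[cls]
        while remaining > 0:
            size = min(int(rng.choice(len(ppg), p=ppg)) + 1, remaining)
            gene_no += 1
            gene = f"GENE{gene_no:05d}"
            direction = 1 if rng.random() < config.p_up else -1
            for _ in range(size):
                probe_rows.append(
                    {"gene": gene, "pattern_class": cls, "direction": direction}
                )
            remaining -= size
    truth = pd.DataFrame(probe_rows)
    truth.index = [f"probe_{i + 1:06d}" for i in range(len(truth))]
    truth.index.name = "probe_id"

    n = len(truth)
    e_abs = math.log2(config.effect_fold)
    offsets = np.zeros((n, 3))
    for row_i, (cls, d) in enumerate(zip(truth["pattern_class"], truth["direction"])):
        offsets[row_i] = _stage_log2_offsets(cls, d * e_abs)
    truth["fold_i"] = [_signed_from_log2(o) for o in offsets[:, 1]]
    truth["fold_l"] = [_signed_from_log2(o) for o in offsets[:, 2]]

    baseline = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    stage_means = baseline[:, None] * 2.0 ** offsets  # probes x 3 stages

    r = config.replicates
    sigma = math.sqrt(math.log1p(config.cv**2))
    # E[exp(N(-sigma^2/2, sigma))] = 1, so replicate means stay unbiased
    noise = np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=(n, 3, r)))
    data = stage_means[:, :, None] * noise

    samples = [
        Sample(f"{stage}_{rep + 1}", stage, rep + 1)
        for stage in "EIL"
        for rep in range(r)
    ]
    values = pd.DataFrame(
        data.reshape(n, 3 * r),
        index=truth.index,
        columns=[s.sample_id for s in samples],
    )
    return ExpressionMatrix(values, samples), truth


def _signed_from_log2(offset: float) -> float:
    """Signed fold-change convention for a log2 offset (0 -> +1.0)."""
    r = 2.0**offset
    return r if r >= 1 else -1.0 / r


def probe_gene_map(truth: pd.DataFrame) -> dict[str, str]:
    return dict(zip(truth.index, truth["gene"]))


def simulate_gene_sets(
    background_genes: Sequence[str],
    de_genes: Sequence[str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[GeneSet], str]:
    """Gene sets with one planted enriched set; returns (sets, planted id).

    The planted set draws ``enrichment_factor`` times the background DE
    fraction of its members from the DE list; the remaining sets are
    uniform draws from the background.
    """
    rng = rng if rng is not None else config.rng()
    bg = list(dict.fromkeys(background_genes))
    de = [g for g in dict.fromkeys(de_genes) if g in set(bg)]
    if not bg or not de:
        raise ValueError("background and DE gene lists must be non-empty")
    size = min(config.gene_set_size, len(bg))
    de_frac = min(1.0, config.enrichment_factor * len(de) / len(bg))
    n_de = min(int(round(de_frac * size)), len(de))
    non_de = [g for g in bg if g not in set(de)]
    planted_members = list(rng.choice(de, size=n_de, replace=False)) + list(
        rng.choice(non_de, size=min(size - n_de, len(non_de)), replace=False)
    )
    sets = [
        GeneSet("SET_PLANTED", "planted enriched set", frozenset(planted_members))
    ]
    for j in range(config.n_gene_sets - 1):
        members = rng.choice(bg, size=size, replace=False)
        sets.append(GeneSet(f"SET{j + 1:03d}", "random set", frozenset(members)))
    return sets, "SET_PLANTED"


def simulate_platform(
    mouse_genes: Sequence[str],
    directions: Mapping[str, int],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Reference-platform p/fold table with a planted concordant subset.

    Planted concordant genes draw p-values from the low tail (safely
    inside the top ``rank_threshold`` percent of a uniform background) and
    a fold change matching the mouse direction; everything else draws
    uniform p-values and random directions. Returns the platform table
    (columns gene, p_value, fold_change) and the per-mouse-gene truth
    flags, indexed like ``mouse_genes``.
    """
    rng = rng if rng is not None else config.rng()
    genes = [g.upper() for g in mouse_genes]
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate mouse gene symbols")
    n_fill = max(config.platform_size - len(genes), 0)
    fillers = [f"BG{j + 1:06d}" for j in range(n_fill)]

    concordant = pd.Series(
        rng.random(len(genes)) < config.concordant_fraction, index=mouse_genes
    )
    rows = []
    low_cap = 0.5 * config.rank_threshold / 100.0
    for g, orig in zip(genes, mouse_genes):
        if concordant[orig]:
            p = rng.uniform(0.0, low_cap)
            sign = np.sign(directions.get(orig, directions.get(g, 1))) or 1
        else:
            p = rng.uniform(0.0, 1.0)
            sign = 1 if rng.random() < 0.5 else -1
        mag = 2.0 ** rng.uniform(0.5, 3.5)
        rows.append({"gene": g, "p_value": p, "fold_change": sign * mag})
    for g in fillers:
        sign = 1 if rng.random() < 0.5 else -1
        rows.append(
            {
                "gene": g,
                "p_value": rng.uniform(0.0, 1.0),
                "fold_change": sign * 2.0 ** rng.uniform(0.0, 2.0),
            }
        )
    return pd.DataFrame(rows), concordant


def simulate_qpcr(
    planted_folds: Mapping[str, float],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_replicates: int | None = None,
) -> pd.DataFrame:
    """Ct table with planted fold changes, columns
    ``sample, group, gene, ct_target, ct_reference``.

    Control-group target Ct sits at 24 cycles against an 18-cycle
    reference; the test group's target Ct is shifted by −log2(fold) so
    ΔΔCt quantification recovers the planted fold in expectation.
    Gaussian noise of ``qpcr_noise_sd`` cycles is added to every Ct.
    """
    rng = rng if rng is not None else config.rng()
    reps = n_replicates if n_replicates is not None else config.replicates
    sd = config.qpcr_noise_sd
    rows = []
    for gene, fold in planted_folds.items():
        if fold <= 0:
            raise ValueError(f"planted fold for {gene!r} must be positive")
        for group, target_base in (("control", 24.0), ("test", 24.0 - math.log2(fold))):
            for rep in range(reps):
                rows.append(
                    {
                        "sample": f"{group}_{rep + 1}",
                        "group": group,
                        "gene": gene,
                        "ct_target": target_base + rng.normal(0.0, sd),
                        "ct_reference": 18.0 + rng.normal(0.0, sd),
                    }
                )
    return pd.DataFrame(rows)
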