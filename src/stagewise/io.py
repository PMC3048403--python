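"""Readers and writers for the tables the pipeline consumes and produces.

Supported formats: plain tab-delimited expression matrices (probes x
samples), a minimal GEO Series Matrix dialect (``!``-prefixed metadata with
a delimited data table between begin/end markers), GMT gene-set files, and
the tab-delimited per-gene result tables the pipeline emits.

Stage labels are the three progression stages of the cell model:
``E`` (early / benign), ``I`` (intermediate), ``L`` (late / malignant).
Stage assignment is always explicit — sample titles are never parsed
heuristically. Intensities stay on the linear fluorescence-unit scale as
read; no log transform is applied.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGES = ("E", "I", "L")

SERIES_TABLE_BEGIN = "!series_matrix_table_begin"
SERIES_TABLE_END = "!series_matrix_table_end"


@dataclass(frozen=True)
class Sample:
    """One array: its column id, progression stage, and replicate index."""

    sample_id: str
    stage: str
    replicate: int

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(
                f"sample {self.sample_id!r}: stage must be one of {STAGES}, got {self.stage!r}"
            )


class ExpressionMatrix:
    """Probe-set intensities with stage/replicate sample labels.

    ``values`` is a probes x samples DataFrame of finite non-negative
    intensities on the linear scale; ``samples`` carries one
    :class:`Sample` per column, in column order.
    """

    def __init__(self, values: pd.DataFrame, samples: Sequence[Sample]):
        samples = list(samples)
        if values.shape[1] != len(samples):
            raise ValueError(
                f"{values.shape[1]} columns but {len(samples)} sample records"
            )
        if list(values.columns) != [s.sample_id for s in samples]:
            raise ValueError("column order must match sample record order")
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate probe id {dup!r}")
        pairs = [(s.stage, s.replicate) for s in samples]
        if len(set(pairs)) != len(pairs):
            raise ValueError("(stage, replicate) pairs must be unique")
        arr = values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if (arr < 0).any():
            raise ValueError("intensities must be non-negative")
        self.values = values.astype(float)
        self.samples = samples

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    def stage_columns(self, stage: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.stage == stage]

    def stage_values(self, stage: str) -> np.ndarray:
        """Probes x replicates array for one stage."""
        cols = self.stage_columns(stage)
        if not cols:
            raise ValueError(f"no samples for stage {stage!r}")
        return self.values[cols].to_numpy(dtype=float)

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.samples)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionMatrix({self.n_probes} probes x {len(self.samples)} samples)"


# probe -> gene symbol; many-to-one allowed, unmapped probes simply absent
ProbeGeneMap = Mapping[str, str]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols (one GMT line)."""

    set_id: str
    description: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")
        if any(not m for m in self.members):
            raise ValueError(f"gene set {self.set_id!r} has an empty member symbol")


def _matrix_from_rows(
    header: list[str],
    rows: list[list[str]],
    stage_assignment: Mapping[str, tuple[str, int]],
    source: str,
) -> ExpressionMatrix:
    sample_ids = header[1:]
    for sid in sample_ids:
        if sid not in stage_assignment:
            raise ValueError(f"{source}: sample {sid!r} has no stage assignment")
    samples = [
        Sample(sid, stage_assignment[sid][0], stage_assignment[sid][1])
        for sid in sample_ids
    ]
    probe_ids: list[str] = []
    data = np.empty((len(rows), len(sample_ids)), dtype=float)
    seen: set[str] = set()
    for i, row in enumerate(rows):
        if len(row) != len(header):
            raise ValueError(
                f"{source}: row {i + 2} has {len(row)} fields, expected {len(header)}"
            )
        probe = row[0]
        if probe in seen:
            raise ValueError(f"{source}: duplicate probe id {probe!r}")
        seen.add(probe)
        probe_ids.append(probe)
        for j, cell in enumerate(row[1:]):
            try:
                data[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{source}: non-numeric value {cell!r} at row {i + 2}, "
                    f"column {sample_ids[j]!r}"
                ) from None
    values = pd.DataFrame(data, index=probe_ids, columns=sample_ids)
    return ExpressionMatrix(values, samples)


def _split_lines(text: str) -> list[str]:
    # accept LF or CRLF, drop trailing blank lines
    lines = text.replace("\r\n", "\n").split("\n")
    while lines and lines[-1] == "":
        lines.pop()
    return lines


def read_expression_table(
    path: str | Path, stage_assignment: Mapping[str, tuple[str, int]]
) -> ExpressionMatrix:
    """Read a tab-delimited expression table.

    First column holds probe ids, the header row holds sample ids;
    ``stage_assignment`` maps each sample id to ``(stage, replicate)``.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = _split_lines(text)
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    rows = [line.split("\t") for line in lines[1:]]
    return _matrix_from_rows(header, rows, stage_assignment, str(path))


def read_series_matrix(
    path: str | Path, stage_assignment: Mapping[str, tuple[str, int]]
) -> ExpressionMatrix:
    """Read the data table of a GEO Series Matrix file.

    Lines beginning with ``!`` are metadata and are ignored except for the
    table-begin/-end markers that bracket the data table. Double quotes
    around identifiers are stripped.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = _split_lines(text)
    in_table = False
    table_lines: list[str] = []
    found_begin = False
    for line in lines:
        low = line.strip().lower()
        if low.startswith(SERIES_TABLE_BEGIN):
            in_table = True
            found_begin = True
            continue
        if low.startswith(SERIES_TABLE_END):
            in_table = False
            continue
        if line.startswith("!"):
            continue
        if in_table:
            table_lines.append(line)
    if not found_begin or not table_lines:
        raise ValueError(f"{path}: no data table")
    rows = [
        [cell.strip().strip('"') for cell in line.split("\t")] for line in table_lines
    ]
    return _matrix_from_rows(rows[0], rows[1:], stage_assignment, str(path))


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix in the plain tab-delimited layout read_expression_table reads."""
    matrix.values.to_csv(path, sep="\t", index_label="probe_id")


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets in GMT format: set_id TAB description TAB member...

    Duplicate members on one line are collapsed with a logged warning.
    """
    sets: list[GeneSet] = []
    for lineno, line in enumerate(_split_lines(Path(path).read_text(encoding="utf-8")), 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}: line {lineno}: GMT line needs at least 3 fields, got {len(fields)}"
            )
        set_id, description, *members = fields
        members = [m for m in members if m]
        unique = frozenset(members)
        if len(unique) < len(members):
            logger.warning(
                "%s: line %d (%s): %d duplicate member(s) collapsed",
                path, lineno, set_id, len(members) - len(unique),
            )
        sets.append(GeneSet(set_id, description, unique))
    return sets


def write_gene_sets(gene_sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.set_id, gs.description, *sorted(gs.members)]) + "\n")


RESULT_COLUMNS = [
    "gene_symbol",
    "accession",
    "fc_ie",
    "p_ie",
    "fc_le",
    "p_le",
    "trajectory",
]


def write_results_table(records: Iterable[Mapping], path: str | Path) -> None:
    """Write the per-gene result table.

    Columns follow the published table layout: gene symbol, accession,
    signed fold change and p-value for each contrast (I vs E, then L vs E),
    and the trajectory call. Fold changes are rendered signed with one
    decimal (``-19.3`` means 19.3-fold lower), p-values with four decimals.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for rec in records:
            fh.write(
                "\t".join(
                    [
                        str(rec["gene_symbol"]),
                        str(rec.get("accession", "")),
                        f"{rec['fc_ie']:.1f}",
                        f"{rec['p_ie']:.4f}",
                        f"{rec['fc_le']:.1f}",
                        f"{rec['p_le']:.4f}",
                        str(rec.get("trajectory", "")),
                    ]
                )
                + "\n"
            )


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Parse a table written by :func:`write_results_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_symbol": str, "accession": str})
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df
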