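"""Within-cell redundancy screening and reviewed merges.

Indicator pairs sharing a cell are correlated (Pearson, which is the
phi coefficient for binary pairs); pairs above a review threshold are
flagged for human judgment, and an externally reviewed merge map can
then collapse near-duplicates into single columns.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .data_ingest import FacilityIndicatorTable
from .quality_matrix import (
    CellKey,
    IndicatorDefinition,
    QualityMatrix,
    VarType,
)

__all__ = [
    "RedundancyFlag",
    "MergeMap",
    "MergeError",
    "pairwise_cell_correlations",
    "flag_redundant",
    "apply_merge_map",
]


class MergeError(ValueError):
    pass


@dataclass(frozen=True)
class RedundancyFlag:
    cell: CellKey
    indicator_a: str
    indicator_b: str
    correlation: float  # NaN when degenerate
    degenerate: bool = False


@dataclass(frozen=True)
class MergeMap:
    """Reviewed merges: each entry absorbs columns into a survivor."""

    entries: tuple[tuple[str, tuple[str, ...], str], ...] = ()

    def __post_init__(self) -> None:
        absorbed_all: set[str] = set()
        survivors = {e[0] for e in self.entries}
        for survivor, absorbed, _label in self.entries:
            for a in absorbed:
                if a in absorbed_all:
                    raise MergeError(f"indicator {a!r} absorbed twice")
                if a in survivors:
                    raise MergeError(f"survivor {a!r} is itself absorbed")
                absorbed_all.add(a)
            if survivor in absorbed_all:
                raise MergeError(f"survivor {survivor!r} is itself absorbed")

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "MergeMap":
        entries = []
        with Path(path).open(newline="") as fh:
            for row in csv.DictReader(fh):
                absorbed = tuple(
                    a.strip() for a in row["absorbed_ids"].split(";") if a.strip()
                )
                entries.append(
                    (row["survivor_id"].strip(), absorbed, row.get("combined_label", ""))
                )
        return cls(entries=tuple(entries))


def pairwise_cell_correlations(
    table: FacilityIndicatorTable, matrix: QualityMatrix
) -> list[RedundancyFlag]:
    """Pearson correlation for every indicator pair within each cell.

    Zero-variance columns make a pair degenerate: it is reported with a
    NaN correlation and flagged rather than raising.
    """
    flags: list[RedundancyFlag] = []
    for cell in matrix.cells:
        ids = [i for i in matrix.indicators_in(cell) if i in table.values.columns]
        for pos, a in enumerate(ids):
            for b in ids[pos + 1:]:
                xa = table.values[a].to_numpy(dtype=float)
                xb = table.values[b].to_numpy(dtype=float)
                if np.std(xa) == 0.0 or np.std(xb) == 0.0:
                    flags.append(RedundancyFlag(cell, a, b, float("nan"), True))
                else:
                    r = float(np.corrcoef(xa, xb)[0, 1])
                    flags.append(RedundancyFlag(cell, a, b, r))
    return flags


def flag_redundant(
    flags: Sequence[RedundancyFlag],
    threshold: float = 0.7,
    absolute: bool = False,
) -> list[RedundancyFlag]:
    """Return pairs whose correlation strictly exceeds the threshold.

    The rule is one-sided (r > threshold) by default; ``absolute=True``
    uses |r|.  Degenerate pairs are excluded with a warning.  Nothing is
    merged automatically.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    degenerate = [f for f in flags if f.degenerate]
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} zero-variance pair(s) excluded from "
            "redundancy flagging",
            stacklevel=2,
        )
    out = []
    for f in flags:
        if f.degenerate:
            continue
        r = abs(f.correlation) if absolute else f.correlation
        if r > threshold:
            out.append(f)
    return out


def flags_to_frame(flags: Sequence[RedundancyFlag]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "dimension": f.cell.dimension.value,
                "element": f.cell.element.value,
                "indicator_a": f.indicator_a,
                "indicator_b": f.indicator_b,
                "correlation": f.correlation,
                "degenerate": f.degenerate,
            }
            for f in flags
        ]
    )


def apply_merge_map(
    table: FacilityIndicatorTable,
    matrix: QualityMatrix,
    definitions: Sequence[IndicatorDefinition],
    merges: MergeMap,
) -> tuple[FacilityIndicatorTable, QualityMatrix, list[IndicatorDefinition]]:
    """Collapse merged columns; shrink the per-cell indicator counts.

    The survivor column becomes the mean of the merged columns,
    re-binarized at >= 0.5 for binary indicators (symmetric, and the
    identity for identical columns).  Merging across cells is an error.
    An empty merge map is the identity.
    """
    if not merges.entries:
        return table, matrix, list(definitions)
    by_id = {d.indicator_id: d for d in definitions}
    values = table.values.copy()
    provenance = table.provenance.copy()
    dropped: set[str] = set()
    new_defs = {d.indicator_id: d for d in definitions}

    for survivor, absorbed, label in merges.entries:
        members = (survivor,) + tuple(absorbed)
        for m in members:
            if m not in by_id:
                raise MergeError(f"merge references unknown indicator {m!r}")
        cells = {by_id[m].cell for m in members}
        if len(cells) != 1:
            raise MergeError(
                f"merge for {survivor!r} spans cells "
                f"{sorted(str(c) for c in cells)}"
            )
        merged = values[list(members)].mean(axis=1)
        if by_id[survivor].var_type is VarType.BINARY:
            merged = (merged >= 0.5).astype(float)
        values[survivor] = merged
        if label:
            new_defs[survivor] = replace(new_defs[survivor], label=label)
        dropped |= set(absorbed)

    values = values.drop(columns=sorted(dropped))
    provenance = provenance.drop(columns=sorted(dropped))
    kept_defs = [new_defs[i] for i in values.columns if i in new_defs]
    new_by_cell = {
        cell: tuple(i for i in matrix.indicators_in(cell) if i not in dropped)
        for cell in matrix.cells
        if matrix.indicators_in(cell)
    }
    new_matrix = QualityMatrix(
        active_dimensions=matrix.active_dimensions,
        indicators_by_cell=new_by_cell,
    )
    new_matrix.validate_partition()
    return (
        FacilityIndicatorTable(values=values, provenance=provenance),
        new_matrix,
        kept_defs,
    )
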