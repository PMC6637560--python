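"""Conceptual quality matrix: dimensions x elements, and the indicator map.

The matrix cross-classifies quality-of-care dimensions (effective,
efficient, accessible/timely, patient-centered/acceptable, equitable,
safe) with the Donabedian elements (structure, process, outcome).  Each
quality indicator is assigned to exactly one cell; the assignment is
input data and is validated here, never computed.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

logger = logging.getLogger(__name__)

__all__ = [
    "Dimension",
    "Element",
    "SourceTool",
    "VarType",
    "Direction",
    "CutoffRule",
    "CellKey",
    "IndicatorDefinition",
    "QualityMatrix",
    "IndicatorMapError",
    "load_indicator_map",
    "build_matrix",
    "drop_unpopulated_dimensions",
]

INDICATOR_MAP_COLUMNS = [
    "indicator_id",
    "label",
    "dimension",
    "element",
    "source_tool",
    "var_type",
    "direction",
    "cutoff_rule",
    "proxy_id",
]


class Dimension(str, Enum):
    EFFECTIVE = "effective"
    EFFICIENT = "efficient"
    ACCESSIBLE = "accessible"
    PATIENT_CENTERED = "patient_centered"
    EQUITABLE = "equitable"
    SAFE = "safe"


class Element(str, Enum):
    STRUCTURE = "structure"
    PROCESS = "process"
    OUTCOME = "outcome"


class SourceTool(str, Enum):
    INVENTORY = "inventory"
    OBSERVATION = "observation"
    PROVIDER_INTERVIEW = "provider_interview"
    EXIT_INTERVIEW = "exit_interview"


class VarType(str, Enum):
    BINARY = "binary"
    ORDINAL = "ordinal"
    CONTINUOUS = "continuous"


class Direction(str, Enum):
    HIGHER_BETTER = "higher_better"
    LOWER_BETTER = "lower_better"


class IndicatorMapError(ValueError):
    """Raised on any schema or consistency violation in an indicator map."""


@dataclass(frozen=True)
class CutoffRule:
    """Rule turning a non-binary indicator into 0/1.

    ``kind`` is one of ``none`` (binary indicators), ``median`` (sample
    median cutoff), ``fixed`` (1 iff value >= ``value`` for
    higher-is-better indicators) or ``fixed_le`` (explicit 1 iff value
    <= ``value``).
    """

    kind: str
    value: Optional[float] = None

    _KINDS = ("none", "median", "fixed", "fixed_le")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise IndicatorMapError(f"unknown cutoff rule kind {self.kind!r}")
        if self.kind in ("fixed", "fixed_le") and self.value is None:
            raise IndicatorMapError(f"cutoff rule {self.kind!r} requires a value")
        if self.kind in ("none", "median") and self.value is not None:
            raise IndicatorMapError(f"cutoff rule {self.kind!r} takes no value")

    @classmethod
    def parse(cls, text: str) -> "CutoffRule":
        text = (text or "none").strip()
        if text in ("none", ""):
            return cls("none")
        if text == "median":
            return cls("median")
        for prefix in ("fixed_le", "fixed"):
            if text.startswith(prefix + ":"):
                raw = text[len(prefix) + 1:]
                try:
                    return cls(prefix, float(raw))
                except ValueError:
                    raise IndicatorMapError(
                        f"cutoff rule {text!r}: {raw!r} is not a number"
                    ) from None
        raise IndicatorMapError(f"cannot parse cutoff rule {text!r}")

    def serialize(self) -> str:
        if self.kind in ("none", "median"):
            return self.kind
        value = self.value
        assert value is not None
        text = f"{value:g}"
        return f"{self.kind}:{text}"


@dataclass(frozen=True, order=True)
class CellKey:
    dimension: Dimension
    element: Element

    def __str__(self) -> str:  # pragma: no cover - display only
        return f"{self.dimension.value}/{self.element.value}"


@dataclass(frozen=True)
class IndicatorDefinition:
    indicator_id: str
    label: str
    cell: CellKey
    source_tool: SourceTool
    var_type: VarType
    direction: Direction = Direction.HIGHER_BETTER
    cutoff_rule: CutoffRule = field(default_factory=lambda: CutoffRule("none"))
    proxy_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.var_type is VarType.BINARY and self.cutoff_rule.kind != "none":
            raise IndicatorMapError(
                f"indicator {self.indicator_id!r}: binary indicators take "
                f"cutoff rule 'none', got {self.cutoff_rule.serialize()!r}"
            )
        if self.var_type is not VarType.BINARY and self.cutoff_rule.kind == "none":
            # Tolerated: such an indicator can only be used under min-max
            # normalization; binarize_indicator will reject it at run time.
            pass


@dataclass(frozen=True)
class QualityMatrix:
    """The active grid of cells with their indicator assignments.

    Cells are ordered elements-major, dimensions-minor, both in
    declaration order, so every report enumerates them identically.
    """

    active_dimensions: tuple[Dimension, ...]
    indicators_by_cell: Mapping[CellKey, tuple[str, ...]]

    @property
    def cells(self) -> list[CellKey]:
        return [
            CellKey(dim, elem)
            for elem in Element
            for dim in self.active_dimensions
        ]

    @property
    def n_cells(self) -> int:
        return len(self.active_dimensions) * len(Element)

    def indicators_in(self, cell: CellKey) -> tuple[str, ...]:
        return tuple(self.indicators_by_cell.get(cell, ()))

    def all_indicator_ids(self) -> list[str]:
        out: list[str] = []
        for cell in self.cells:
            out.extend(self.indicators_in(cell))
        return out

    def cell_of(self, indicator_id: str) -> CellKey:
        for cell in self.cells:
            if indicator_id in self.indicators_in(cell):
                return cell
        raise KeyError(indicator_id)

    def validate_partition(self) -> None:
        """Every indicator lives in exactly one cell."""
        seen: set[str] = set()
        for cell in self.cells:
            for ind in self.indicators_in(cell):
                if ind in seen:
                    raise IndicatorMapError(
                        f"indicator {ind!r} appears in more than one cell"
                    )
                seen.add(ind)


def _parse_row(row: Mapping[str, str], line_no: int) -> IndicatorDefinition:
    def enum_field(enum_cls, name: str):
        raw = (row.get(name) or "").strip()
        try:
            return enum_cls(raw)
        except ValueError:
            valid = ", ".join(m.value for m in enum_cls)
            raise IndicatorMapError(
                f"row {line_no}, field {name!r}: unknown value {raw!r} "
                f"(expected one of: {valid})"
            ) from None

    indicator_id = (row.get("indicator_id") or "").strip()
    if not indicator_id:
        raise IndicatorMapError(f"row {line_no}: empty indicator_id")
    try:
        cutoff = CutoffRule.parse(row.get("cutoff_rule") or "none")
    except IndicatorMapError as exc:
        raise IndicatorMapError(f"row {line_no}, field 'cutoff_rule': {exc}") from None
    proxy = (row.get("proxy_id") or "").strip() or None
    try:
        return IndicatorDefinition(
            indicator_id=indicator_id,
            label=(row.get("label") or "").strip(),
            cell=CellKey(enum_field(Dimension, "dimension"), enum_field(Element, "element")),
            source_tool=enum_field(SourceTool, "source_tool"),
            var_type=enum_field(VarType, "var_type"),
            direction=enum_field(Direction, "direction"),
            cutoff_rule=cutoff,
            proxy_id=proxy,
        )
    except IndicatorMapError as exc:
        raise IndicatorMapError(f"row {line_no}: {exc}") from None


def build_matrix(
    definitions: Sequence[IndicatorDefinition],
    active_dimensions: Optional[Sequence[Dimension]] = None,
) -> QualityMatrix:
    """Assemble a matrix from validated definitions.

    ``active_dimensions`` defaults to all six dimensions; unpopulated
    ones can be removed afterwards with :func:`drop_unpopulated_dimensions`.
    """
    ids = [d.indicator_id for d in definitions]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise IndicatorMapError(f"duplicate indicator_id(s): {sorted(dupes)}")
    known = set(ids)
    for d in definitions:
        if d.proxy_id is not None and d.proxy_id not in known:
            raise IndicatorMapError(
                f"indicator {d.indicator_id!r}: proxy_id {d.proxy_id!r} "
                "does not reference an indicator in this map"
            )
    dims = tuple(active_dimensions) if active_dimensions is not None else tuple(Dimension)
    by_cell: dict[CellKey, list[str]] = {}
    for d in definitions:
        if d.cell.dimension not in dims:
            raise IndicatorMapError(
                f"indicator {d.indicator_id!r} assigned to inactive "
                f"dimension {d.cell.dimension.value!r}"
            )
        by_cell.setdefault(d.cell, []).append(d.indicator_id)
    matrix = QualityMatrix(
        active_dimensions=dims,
        indicators_by_cell={c: tuple(v) for c, v in by_cell.items()},
    )
    matrix.validate_partition()
    return matrix


def load_indicator_map(
    path: Union[str, Path],
) -> tuple[QualityMatrix, list[IndicatorDefinition]]:
    """Read and validate an indicator map CSV.

    The header must be exactly ``indicator_id,label,dimension,element,
    source_tool,var_type,direction,cutoff_rule,proxy_id``.  Duplicate
    ids, unknown enum values and dangling proxy references are rejected
    with an error naming the offending row and field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != INDICATOR_MAP_COLUMNS:
            raise IndicatorMapError(
                f"{path}: header must be {','.join(INDICATOR_MAP_COLUMNS)!r}, "
                f"got {','.join(reader.fieldnames or [])!r}"
            )
        definitions = [
            _parse_row(row, line_no)
            for line_no, row in enumerate(reader, start=2)
        ]
    if not definitions:
        raise IndicatorMapError(f"{path}: indicator map is empty")
    matrix = build_matrix(definitions)
    return matrix, definitions


def save_indicator_map(
    definitions: Iterable[IndicatorDefinition], path: Union[str, Path]
) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(INDICATOR_MAP_COLUMNS)
        for d in definitions:
            writer.writerow(
                [
                    d.indicator_id,
                    d.label,
                    d.cell.dimension.value,
                    d.cell.element.value,
                    d.source_tool.value,
                    d.var_type.value,
                    d.direction.value,
                    d.cutoff_rule.serialize(),
                    d.proxy_id or "",
                ]
            )


def drop_unpopulated_dimensions(matrix: QualityMatrix) -> QualityMatrix:
    """Remove dimensions with no indicator in any of the three elements.

    Idempotent.  Removal is logged; a matrix reduced to a single
    dimension triggers a warning but remains legal.
    """
    populated = []
    for dim in matrix.active_dimensions:
        count = sum(
            len(matrix.indicators_in(CellKey(dim, elem))) for elem in Element
        )
        if count > 0:
            populated.append(dim)
        else:
            logger.info("dropping unpopulated dimension %s", dim.value)
    if not populated:
        raise IndicatorMapError("no dimension has any indicator")
    if len(populated) == 1:
        warnings.warn(
            "matrix reduced to a single dimension", stacklevel=2
        )
    if tuple(populated) == matrix.active_dimensions:
        return matrix
    return replace(matrix, active_dimensions=tuple(populated))
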