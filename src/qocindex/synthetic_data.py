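"""Synthetic multi-source facility studies with known latent quality.

A purely test-harness generative model: each facility gets a latent
quality q in (0, 1); individual-level binary items succeed with
probability logistic(a_c + b*q) where a_c is a cell-specific intercept
and b the signal strength; inventory items are Bernoulli(q).  One
lower-is-better continuous waiting-time item and one ordinal
satisfaction item exercise the cutoff logic.  MCAR item gaps and
whole-tool dropout can be injected.  Everything is reproducible from
the seed.

Also packages the study's published facility score table (26
facilities x 5 scenarios) as a checksummed fixture.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_ingest import SOURCE_FILENAMES, Level, SourceRecordSet, TOOL_LEVELS
from .quality_matrix import (
    CellKey,
    CutoffRule,
    Dimension,
    Direction,
    Element,
    IndicatorDefinition,
    QualityMatrix,
    SourceTool,
    VarType,
    build_matrix,
    save_indicator_map,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "StudyData",
    "generate_study",
    "write_study",
    "load_table3_fixture",
    "TABLE3_SHA256",
]

TABLE3_SHA256 = "23eac5d5373b27a58f300caab641c258939ee1b0abf8969e88aa202afb61557e"

# 4 active dimensions x 3 elements; the study matched neither the
# efficient nor the equitable dimension with its data.
ACTIVE_DIMENSIONS = (
    Dimension.EFFECTIVE,
    Dimension.ACCESSIBLE,
    Dimension.PATIENT_CENTERED,
    Dimension.SAFE,
)

# 12 per-cell indicator counts, elements-major order, spanning 6-19 and
# summing to 85 (the inventory-heavy accessible/structure cell is the
# largest).
DEFAULT_INDICATORS_PER_CELL = (19, 6, 6, 6, 6, 6, 6, 6, 6, 6, 6, 6)

# structure cells draw on the inventory; process cells on delivery
# observations; outcome cells split between exit and provider interviews.
_ELEMENT_TOOLS = {
    Element.STRUCTURE: SourceTool.INVENTORY,
    Element.PROCESS: SourceTool.OBSERVATION,
    Element.OUTCOME: SourceTool.EXIT_INTERVIEW,
}


@dataclass(frozen=True)
class SimulationConfig:
    n_facilities: int = 26
    indicators_per_cell: tuple[int, ...] = DEFAULT_INDICATORS_PER_CELL
    records_per_facility: Mapping[str, int] = field(
        default_factory=lambda: {
            "observation": 3,
            "provider_interview": 3,
            "exit_interview": 8,
        }
    )
    quality_spread: float = 1.0   # SD of the latent quality on the logit scale
    signal: float = 4.0           # b: slope of item probability in latent quality
    item_missing_rate: float = 0.05
    tool_dropout: int = 0         # facilities losing one whole tool
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_facilities < 2:
            raise ValueError("need at least 2 facilities")
        if len(self.indicators_per_cell) != 12:
            raise ValueError("indicators_per_cell must list 12 cell counts")
        if any(c < 1 for c in self.indicators_per_cell):
            raise ValueError("every cell needs at least one indicator")
        if not 0.0 <= self.item_missing_rate <= 1.0:
            raise ValueError("item_missing_rate outside [0, 1]")
        if self.tool_dropout < 0 or self.tool_dropout > self.n_facilities:
            raise ValueError("tool_dropout outside [0, n_facilities]")
        for tool, n in self.records_per_facility.items():
            if n < 1:
                raise ValueError(f"records_per_facility[{tool}] must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    latent_quality: pd.Series   # facility -> value in (0, 1)
    true_rank: pd.Series        # descending average ranks of latent quality


@dataclass
class StudyData:
    recordsets: dict[SourceTool, SourceRecordSet]
    matrix: QualityMatrix
    definitions: list[IndicatorDefinition]
    truth: GroundTruth
    config: SimulationConfig


def _build_definitions(config: SimulationConfig) -> list[IndicatorDefinition]:
    cells = [
        CellKey(dim, elem) for elem in Element for dim in ACTIVE_DIMENSIONS
    ]
    definitions: list[IndicatorDefinition] = []
    for cell, count in zip(cells, config.indicators_per_cell):
        tool = _ELEMENT_TOOLS[cell.element]
        for j in range(count):
            ind_id = f"{cell.dimension.value[:4]}_{cell.element.value[:4]}_{j:02d}"
            var_type = VarType.BINARY
            direction = Direction.HIGHER_BETTER
            cutoff = CutoffRule("none")
            ind_tool = tool
            # A few non-binary items to exercise cutoffs, placed in fixed slots.
            if cell == CellKey(Dimension.ACCESSIBLE, Element.STRUCTURE) and j == 0:
                var_type = VarType.CONTINUOUS  # skilled birth attendants
                cutoff = CutoffRule("fixed", 3.0)
                ind_tool = SourceTool.INVENTORY
            elif cell == CellKey(Dimension.ACCESSIBLE, Element.OUTCOME) and j == 0:
                var_type = VarType.CONTINUOUS  # waiting time, minutes
                direction = Direction.LOWER_BETTER
                cutoff = CutoffRule("median")
            elif cell == CellKey(Dimension.PATIENT_CENTERED, Element.OUTCOME) and j == 0:
                var_type = VarType.ORDINAL     # satisfaction rating 1-5
                cutoff = CutoffRule("median")
            elif cell.element is Element.OUTCOME and cell.dimension is Dimension.SAFE:
                ind_tool = SourceTool.PROVIDER_INTERVIEW
            definitions.append(
                IndicatorDefinition(
                    indicator_id=ind_id,
                    label=ind_id.replace("_", " "),
                    cell=cell,
                    source_tool=ind_tool,
                    var_type=var_type,
                    direction=direction,
                    cutoff_rule=cutoff,
                )
            )
    # give the first two binary observation items proxies (each other)
    obs = [d for d in definitions if d.source_tool is SourceTool.OBSERVATION]
    if len(obs) >= 2:
        from dataclasses import replace

        a, b = obs[0], obs[1]
        for d, proxy in ((a, b.indicator_id), (b, a.indicator_id)):
            definitions[definitions.index(d)] = replace(d, proxy_id=proxy)
    return definitions


def generate_study(config: Optional[SimulationConfig] = None) -> StudyData:
    """Draw one full multi-source study from the generative model."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    definitions = _build_definitions(config)
    matrix = build_matrix(definitions, ACTIVE_DIMENSIONS)

    facilities = [f"F{i:02d}" for i in range(1, config.n_facilities + 1)]
    logit_q = rng.normal(0.0, config.quality_spread, size=config.n_facilities)
    q = expit(logit_q)
    truth = GroundTruth(
        latent_quality=pd.Series(q, index=facilities, name="latent_quality"),
        true_rank=pd.Series(
            pd.Series(-q, index=facilities).rank(method="average"),
            index=facilities,
            name="true_rank",
        ),
    )

    # cell intercepts: item difficulty varies by cell, centered so mid
    # quality facilities sit near 50-70% success
    cell_intercepts = {
        cell: rng.normal(0.3, 0.5) for cell in matrix.cells
    }

    by_tool: dict[SourceTool, list[IndicatorDefinition]] = {}
    for d in definitions:
        by_tool.setdefault(d.source_tool, []).append(d)

    frames: dict[SourceTool, pd.DataFrame] = {}
    for tool in SourceTool:
        defs = by_tool.get(tool, [])
        if not defs:
            continue
        if TOOL_LEVELS[tool] is Level.FACILITY:
            rows = []
            for fac, qf in zip(facilities, q):
                row: dict[str, object] = {"facility_id": fac}
                for d in defs:
                    row[d.indicator_id] = _draw_item(
                        d, qf, cell_intercepts, config.signal, rng
                    )
                rows.append(row)
            frames[tool] = pd.DataFrame(rows)
        else:
            n_rec = int(config.records_per_facility.get(tool.value, 3))
            rows = []
            for fac, qf in zip(facilities, q):
                for _ in range(n_rec):
                    row = {"facility_id": fac}
                    for d in defs:
                        row[d.indicator_id] = _draw_item(
                            d, qf, cell_intercepts, config.signal, rng
                        )
                    rows.append(row)
            frames[tool] = pd.DataFrame(rows)

    # MCAR item gaps (never on facility_id)
    if config.item_missing_rate > 0:
        for tool, frame in frames.items():
            cols = [c for c in frame.columns if c != "facility_id"]
            mask = rng.random((len(frame), len(cols))) < config.item_missing_rate
            values = frame[cols].to_numpy(dtype=float)
            values[mask] = np.nan
            frame[cols] = values

    # whole-tool dropout: each affected facility loses one non-inventory tool
    if config.tool_dropout > 0:
        droppable = [t for t in frames if TOOL_LEVELS[t] is Level.INDIVIDUAL]
        if not droppable:
            raise ValueError("tool dropout requested but no individual-level tool")
        victims = rng.choice(facilities, size=config.tool_dropout, replace=False)
        for fac in victims:
            tool = droppable[int(rng.integers(len(droppable)))]
            frame = frames[tool]
            frames[tool] = frame[frame["facility_id"] != fac].reset_index(drop=True)

    recordsets = {
        tool: SourceRecordSet(tool=tool, records=frame, level=TOOL_LEVELS[tool])
        for tool, frame in frames.items()
    }
    return StudyData(
        recordsets=recordsets,
        matrix=matrix,
        definitions=definitions,
        truth=truth,
        config=config,
    )


def _draw_item(
    definition: IndicatorDefinition,
    qf: float,
    cell_intercepts: Mapping[CellKey, float],
    signal: float,
    rng: np.random.Generator,
) -> float:
    if definition.var_type is VarType.BINARY:
        if definition.source_tool is SourceTool.INVENTORY:
            p = qf
        else:
            # logistic(a_c + b*(q - 1/2)): centered so b scales contrast
            p = expit(cell_intercepts[definition.cell] + signal * (qf - 0.5))
        return float(rng.random() < p)
    if definition.var_type is VarType.ORDINAL:
        # satisfaction 1-5, mean tracks quality
        return float(1 + rng.binomial(4, 0.2 + 0.6 * qf))
    # continuous
    if definition.direction is Direction.LOWER_BETTER:
        # waiting time in minutes: better facilities are faster
        return float(max(1.0, rng.normal(35.0 - 25.0 * qf, 5.0)))
    # staffing count: better facilities staff more
    return float(max(0.0, np.round(rng.normal(1.5 + 3.0 * qf, 1.0))))


def write_study(study: StudyData, directory: Union[str, Path]) -> None:
    """Write the four source CSVs, indicator map and ground truth."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for tool, rs in study.recordsets.items():
        rs.records.to_csv(directory / SOURCE_FILENAMES[tool], index=False)
    save_indicator_map(study.definitions, directory / "indicator_map.csv")
    truth = pd.DataFrame(
        {
            "latent_quality": study.truth.latent_quality,
            "true_rank": study.truth.true_rank,
        }
    )
    truth.index.name = "facility_id"
    truth.to_csv(directory / "ground_truth.csv")


def load_table3_fixture() -> pd.DataFrame:
    """The published per-facility composite scores: 26 facilities
    (A-Z, descending base score) x 5 scenario columns, exactly as
    printed.  The packaged file is checksum-verified."""
    ref = resources.files("qocindex").joinpath("data/table3_scores.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE3_SHA256:
        raise RuntimeError(
            f"table3_scores.csv checksum mismatch: {digest} != {TABLE3_SHA256}"
        )
    from io import BytesIO

    frame = pd.read_csv(BytesIO(raw), index_col="facility")
    assert list(frame.columns) == ["base", "alt_a", "alt_b", "alt_c", "alt_d"]
    assert len(frame) == 26
    return frame
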