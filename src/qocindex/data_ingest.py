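"""Reading source datasets, facility aggregation, completeness filtering
and single-value imputation.

Four source tools feed the pipeline: a facility inventory (one row per
facility) and three individual-level tools (delivery observations,
provider interviews, exit interviews; many rows per facility, keyed by
``facility_id``).  Individual records are averaged within facility,
facilities missing a whole tool are excluded rather than imputed, and
remaining item gaps are filled by simple deterministic rules (zero/one
for observation items, proxy-then-mode or mode for binary items, mean
for continuous ones) with per-entry provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .quality_matrix import (
    Direction,
    IndicatorDefinition,
    SourceTool,
    VarType,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Level",
    "SourceRecordSet",
    "FacilityIndicatorTable",
    "ImputationPolicy",
    "IngestError",
    "read_source_csv",
    "aggregate_to_facility",
    "binarize_share",
    "filter_complete_facilities",
    "assemble_facility_table",
    "impute_missing",
    "screen_indicators",
]

SOURCE_FILENAMES = {
    SourceTool.INVENTORY: "inventory.csv",
    SourceTool.OBSERVATION: "observations.csv",
    SourceTool.PROVIDER_INTERVIEW: "provider_interviews.csv",
    SourceTool.EXIT_INTERVIEW: "exit_interviews.csv",
}


class IngestError(ValueError):
    pass


class Level(str, Enum):
    FACILITY = "facility"
    INDIVIDUAL = "individual"


TOOL_LEVELS = {
    SourceTool.INVENTORY: Level.FACILITY,
    SourceTool.OBSERVATION: Level.INDIVIDUAL,
    SourceTool.PROVIDER_INTERVIEW: Level.INDIVIDUAL,
    SourceTool.EXIT_INTERVIEW: Level.INDIVIDUAL,
}


@dataclass
class SourceRecordSet:
    """Raw records from one collection tool.

    ``records`` must carry a ``facility_id`` column; all other columns
    are raw variables.  Facility-level tools allow at most one row per
    facility.
    """

    tool: SourceTool
    records: pd.DataFrame
    level: Level

    def __post_init__(self) -> None:
        if "facility_id" not in self.records.columns:
            raise IngestError(f"{self.tool.value}: missing facility_id column")
        expected = TOOL_LEVELS[self.tool]
        if self.level != expected:
            raise IngestError(
                f"{self.tool.value} is a {expected.value}-level tool, "
                f"declared {self.level.value}"
            )
        if self.level is Level.FACILITY:
            counts = self.records["facility_id"].value_counts()
            multi = counts[counts > 1]
            if not multi.empty:
                raise IngestError(
                    f"{self.tool.value}: more than one row for "
                    f"facilities {sorted(multi.index.tolist())}"
                )

    @property
    def facility_ids(self) -> list[str]:
        return sorted(self.records["facility_id"].astype(str).unique())


def read_source_csv(path: Union[str, Path], tool: SourceTool) -> SourceRecordSet:
    """Read one source CSV; empty fields become missing values."""
    frame = pd.read_csv(path, dtype={"facility_id": str})
    return SourceRecordSet(tool=tool, records=frame, level=TOOL_LEVELS[tool])


@dataclass
class FacilityIndicatorTable:
    """Facilities x indicators, with per-entry provenance.

    ``values`` is indexed by facility_id; ``provenance`` has the same
    shape and holds ``observed`` or one of the ``imputed_*`` flags.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.provenance is None:
            self.provenance = pd.DataFrame(
                "observed", index=self.values.index, columns=self.values.columns
            )
        if not self.provenance.index.equals(self.values.index) or not (
            self.provenance.columns.equals(self.values.columns)
        ):
            raise IngestError("provenance shape does not match values")

    @property
    def facility_ids(self) -> list[str]:
        return list(self.values.index)

    def copy(self) -> "FacilityIndicatorTable":
        return FacilityIndicatorTable(self.values.copy(), self.provenance.copy())


@dataclass(frozen=True)
class ImputationPolicy:
    """How to fill the gaps that survive facility aggregation.

    observation_missing: zero | one | mode  (direct-observation items)
    binary_missing:      mode | proxy_then_mode
    continuous_missing:  mean
    """

    observation_missing: str = "zero"
    binary_missing: str = "proxy_then_mode"
    continuous_missing: str = "mean"
    proxy_map: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        if self.observation_missing not in ("zero", "one", "mode"):
            raise IngestError(
                f"unknown observation_missing {self.observation_missing!r}"
            )
        if self.binary_missing not in ("mode", "proxy_then_mode"):
            raise IngestError(f"unknown binary_missing {self.binary_missing!r}")
        if self.continuous_missing != "mean":
            raise IngestError(f"unknown continuous_missing {self.continuous_missing!r}")


def aggregate_to_facility(recordset: SourceRecordSet) -> pd.DataFrame:
    """Average individual-level records within each facility.

    Missing entries are excluded from the mean, so binary items become
    proportions in [0, 1] and continuous items plain means.  Facility
    -level tools pass through unchanged (indexed by facility_id).
    """
    frame = recordset.records.copy()
    frame["facility_id"] = frame["facility_id"].astype(str)
    if recordset.level is Level.FACILITY:
        return frame.set_index("facility_id").astype(float)
    return frame.groupby("facility_id").mean()


def binarize_share(proportion: float) -> int:
    """Re-binarize an aggregated share: 1 iff the share is >= 0.5."""
    p = float(proportion)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion {p} outside [0, 1]")
    return 1 if p >= 0.5 else 0


def filter_complete_facilities(
    tables: Mapping[SourceTool, pd.DataFrame],
    required_tools: Optional[Iterable[SourceTool]] = None,
) -> list[str]:
    """Keep only facilities where every required tool was applied.

    Whole-tool absence is never imputed; such facilities are dropped and
    the reasons logged.  Raises if nothing survives.
    """
    required = set(required_tools) if required_tools is not None else set(tables)
    missing_req = required - set(tables)
    if missing_req:
        raise IngestError(
            f"required tool(s) not supplied: {sorted(t.value for t in missing_req)}"
        )
    universe: set[str] = set()
    for frame in tables.values():
        universe |= set(map(str, frame.index))
    if not universe:
        raise IngestError("no facilities in any source table")
    retained = []
    for fac in sorted(universe):
        absent = [
            tool.value
            for tool in sorted(required, key=lambda t: t.value)
            if fac not in set(map(str, tables[tool].index))
        ]
        if absent:
            logger.info("dropping facility %s: missing tool(s) %s", fac, absent)
        else:
            retained.append(fac)
    if not retained:
        raise IngestError("completeness filter retained zero facilities")
    return retained


def assemble_facility_table(
    tables: Mapping[SourceTool, pd.DataFrame],
    definitions: Sequence[IndicatorDefinition],
    facility_ids: Sequence[str],
    binarize_shares: bool = True,
) -> FacilityIndicatorTable:
    """Match aggregated source variables to indicator definitions.

    Each indicator column is pulled from its declared source tool's
    facility table.  Aggregated shares of binary source items are
    re-binarized at the 0.5 cutoff (>= 0.5 -> 1) unless disabled.
    """
    index = pd.Index([str(f) for f in facility_ids], name="facility_id")
    data: dict[str, pd.Series] = {}
    for d in definitions:
        source = tables.get(d.source_tool)
        if source is None or d.indicator_id not in source.columns:
            raise IngestError(
                f"indicator {d.indicator_id!r}: no column in the "
                f"{d.source_tool.value} table"
            )
        col = source[d.indicator_id].reindex(index).astype(float)
        if (
            binarize_shares
            and d.var_type is VarType.BINARY
            and TOOL_LEVELS[d.source_tool] is Level.INDIVIDUAL
        ):
            col = col.map(lambda p: np.nan if pd.isna(p) else binarize_share(p))
        data[d.indicator_id] = col
    values = pd.DataFrame(data, index=index)
    return FacilityIndicatorTable(values=values)


def _mode_fill(col: pd.Series, indicator_id: str) -> float:
    observed = col.dropna()
    if observed.empty:
        raise IngestError(
            f"indicator {indicator_id!r}: all values missing, mode undefined"
        )
    ones = int((observed >= 0.5).sum())
    zeros = len(observed) - ones
    # Ties resolve to 1, mirroring the >= 0.5 re-binarization convention.
    return 1.0 if ones >= zeros else 0.0


def impute_missing(
    table: FacilityIndicatorTable,
    policy: ImputationPolicy,
    definitions: Sequence[IndicatorDefinition],
) -> FacilityIndicatorTable:
    """Fill every remaining gap per the policy, recording provenance.

    Order of precedence per indicator: direct-observation items use
    ``observation_missing``; other binary items use ``binary_missing``
    (a proxy value is copied from the same facility's proxy indicator
    when available, falling back to mode); ordinal/continuous items use
    the sample mean.  A table with no gaps is returned unchanged.
    """
    out = table.copy()
    by_id = {d.indicator_id: d for d in definitions}
    proxy_map = dict(policy.proxy_map or {})
    for d in definitions:
        if d.indicator_id not in proxy_map and d.proxy_id is not None:
            proxy_map[d.indicator_id] = d.proxy_id
    for ind, proxy in proxy_map.items():
        if ind not in by_id or proxy not in by_id:
            raise IngestError(f"proxy_map entry {ind!r} -> {proxy!r} unknown")

    for ind in out.values.columns:
        col = out.values[ind]
        mask = col.isna()
        if not mask.any():
            continue
        d = by_id.get(ind)
        if d is None:
            raise IngestError(f"no definition for column {ind!r}")
        if d.source_tool is SourceTool.OBSERVATION and d.var_type is VarType.BINARY:
            if policy.observation_missing == "zero":
                fill, flag = 0.0, "imputed_zero"
            elif policy.observation_missing == "one":
                fill, flag = 1.0, "imputed_one"
            else:
                fill, flag = _mode_fill(col, ind), "imputed_mode"
            out.values.loc[mask, ind] = fill
            out.provenance.loc[mask, ind] = flag
        elif d.var_type is VarType.BINARY:
            if policy.binary_missing == "proxy_then_mode" and ind in proxy_map:
                proxy_col = out.values[proxy_map[ind]]
                use_proxy = mask & proxy_col.notna()
                out.values.loc[use_proxy, ind] = proxy_col[use_proxy]
                out.provenance.loc[use_proxy, ind] = "imputed_proxy"
                mask = out.values[ind].isna()
            if mask.any():
                out.values.loc[mask, ind] = _mode_fill(col, ind)
                out.provenance.loc[mask, ind] = "imputed_mode"
        else:
            observed = col.dropna()
            if observed.empty:
                raise IngestError(
                    f"indicator {ind!r}: all values missing, mean undefined"
                )
            out.values.loc[mask, ind] = float(observed.mean())
            out.provenance.loc[mask, ind] = "imputed_mean"
    assert not out.values.isna().any().any()
    return out


def screen_indicators(
    table: FacilityIndicatorTable,
    definitions: Sequence[IndicatorDefinition],
    pre_imputation_missing: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Descriptive screen: range, spread, missingness and outlier flags.

    Non-binary indicators are scanned for values outside
    median +/- 1.5*IQR; binary ones only report their distribution.
    Constant columns are flagged degenerate.
    """
    by_id = {d.indicator_id: d for d in definitions}
    rows = []
    for ind in table.values.columns:
        col = table.values[ind].astype(float)
        d = by_id.get(ind)
        var_type = d.var_type.value if d else "unknown"
        direction = d.direction.value if d else "unknown"
        sd = float(col.std(ddof=1)) if len(col) > 1 else 0.0
        outliers: list[str] = []
        if d is not None and d.var_type is not VarType.BINARY:
            med = float(col.median())
            q1, q3 = col.quantile([0.25, 0.75])
            iqr = float(q3 - q1)
            lo, hi = med - 1.5 * iqr, med + 1.5 * iqr
            outliers = [str(f) for f, v in col.items() if v < lo or v > hi]
        rows.append(
            {
                "indicator_id": ind,
                "var_type": var_type,
                "direction": direction,
                "min": float(col.min()),
                "max": float(col.max()),
                "mean": float(col.mean()),
                "sd": sd,
                "n_missing_pre_imputation": int(
                    (pre_imputation_missing or {}).get(ind, 0)
                ),
                "degenerate": bool(sd == 0.0),
                "outlier_facilities": ";".join(outliers),
            }
        )
    return pd.DataFrame(rows).set_index("indicator_id")


def load_study(
    directory: Union[str, Path],
    definitions: Sequence[IndicatorDefinition],
    policy: Optional[ImputationPolicy] = None,
    required_tools: Optional[Iterable[SourceTool]] = None,
) -> FacilityIndicatorTable:
    """End-to-end ingest: read the four CSVs, aggregate, filter, impute."""
    directory = Path(directory)
    policy = policy or ImputationPolicy()
    recordsets = {
        tool: read_source_csv(directory / name, tool)
        for tool, name in SOURCE_FILENAMES.items()
        if (directory / name).exists()
    }
    if not recordsets:
        raise IngestError(f"no source CSVs found in {directory}")
    aggregated = {t: aggregate_to_facility(rs) for t, rs in recordsets.items()}
    retained = filter_complete_facilities(aggregated, required_tools)
    table = assemble_facility_table(aggregated, definitions, retained)
    return impute_missing(table, policy, definitions)
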