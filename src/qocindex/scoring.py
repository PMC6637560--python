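"""Scenario-driven composite construction.

A scenario fixes four choices: how indicators are put on a common scale
(binarize at a cutoff, or min-max rescale), how they are aggregated
into a cell score (additive sum or geometric product), how cell scores
are normalized (min-max against theoretical or empirical bounds, or
z-scores) and how the normalized cells combine into the composite
(additive or geometric).  Five presets are built in:

========  =====================  ===========  ==================  ==========
name      indicator norm         ind. agg.    cell norm           cell agg.
========  =====================  ===========  ==================  ==========
base      binarize               additive     minmax_theoretical  additive
alt_a     minmax                 additive     minmax_theoretical  additive
alt_b     binarize               geometric    minmax_theoretical  additive
alt_c     binarize               additive     zscore              additive
alt_d     binarize               additive     minmax_theoretical  geometric
========  =====================  ===========  ==================  ==========

With an additive composite over min-max cells the scale is
[0, n_cells] (0-12 for the 4x3 matrix); a geometric composite lives in
[0, 1]; z-score cells make the scale unbounded.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .data_ingest import FacilityIndicatorTable
from .quality_matrix import (
    CellKey,
    Direction,
    IndicatorDefinition,
    QualityMatrix,
    VarType,
)

__all__ = [
    "ScenarioConfig",
    "CellScoreSet",
    "CompositeResult",
    "ScoringError",
    "PRESETS",
    "orient_indicator",
    "binarize_indicator",
    "minmax_rescale",
    "zscore_standardize",
    "aggregate_indicators",
    "aggregate_cells",
    "run_scenario",
    "run_base_and_alternatives",
]

INDICATOR_NORMALIZATIONS = ("binarize", "minmax")
AGGREGATIONS = ("additive", "geometric")
CELL_NORMALIZATIONS = ("minmax_theoretical", "minmax_empirical", "zscore")


class ScoringError(ValueError):
    pass


WeightSpec = Union[str, Mapping[str, float]]


@dataclass(frozen=True)
class ScenarioConfig:
    name: str
    indicator_normalization: str = "binarize"
    indicator_aggregation: str = "additive"
    cell_normalization: str = "minmax_theoretical"
    cell_aggregation: str = "additive"
    indicator_weights: WeightSpec = "equal"
    cell_weights: WeightSpec = "equal"

    def __post_init__(self) -> None:
        if self.indicator_normalization not in INDICATOR_NORMALIZATIONS:
            raise ScoringError(
                f"unknown indicator_normalization {self.indicator_normalization!r}"
            )
        if self.indicator_aggregation not in AGGREGATIONS:
            raise ScoringError(
                f"unknown indicator_aggregation {self.indicator_aggregation!r}"
            )
        if self.cell_normalization not in CELL_NORMALIZATIONS:
            raise ScoringError(
                f"unknown cell_normalization {self.cell_normalization!r}"
            )
        if self.cell_aggregation not in AGGREGATIONS:
            raise ScoringError(f"unknown cell_aggregation {self.cell_aggregation!r}")
        for spec, what in ((self.indicator_weights, "indicator"),
                           (self.cell_weights, "cell")):
            if isinstance(spec, str):
                if spec != "equal":
                    raise ScoringError(f"unknown {what}_weights {spec!r}")
            else:
                vals = list(spec.values())
                if any(w < 0 for w in vals):
                    raise ScoringError(f"{what} weights must be non-negative")
                if not any(w > 0 for w in vals):
                    raise ScoringError(f"at least one {what} weight must be positive")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ScenarioConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        )
        return cls(**data)


PRESETS: dict[str, ScenarioConfig] = {
    "base": ScenarioConfig(name="base"),
    "alt_a": ScenarioConfig(name="alt_a", indicator_normalization="minmax"),
    "alt_b": ScenarioConfig(name="alt_b", indicator_aggregation="geometric"),
    "alt_c": ScenarioConfig(name="alt_c", cell_normalization="zscore"),
    "alt_d": ScenarioConfig(name="alt_d", cell_aggregation="geometric"),
}

SCENARIO_ORDER = ["base", "alt_a", "alt_b", "alt_c", "alt_d"]


@dataclass
class CellScoreSet:
    raw: pd.DataFrame          # facility x cell, pre-normalization
    normalized: pd.DataFrame   # facility x cell, post-normalization
    cell_maxima: dict[CellKey, float]


@dataclass
class CompositeResult:
    scenario: str
    facility_scores: pd.Series
    cell_scores: CellScoreSet
    scale_range: Optional[tuple[float, float]]  # None == unbounded
    config: ScenarioConfig
    matrix: QualityMatrix

    @property
    def scale_label(self) -> str:
        if self.scale_range is None:
            return "unbounded"
        lo, hi = self.scale_range
        return f"{lo:g}-{hi:g}"


def orient_indicator(values: pd.Series, definition: IndicatorDefinition) -> pd.Series:
    """Make higher always mean better, ahead of min-max rescaling.

    Lower-is-better columns are reflected (max - x); binary
    lower-is-better columns are complemented.  Cutoff-based
    binarization handles direction itself and does not use this.
    """
    if definition.direction is Direction.HIGHER_BETTER:
        return values
    if definition.var_type is VarType.BINARY:
        return 1.0 - values
    return values.max() - values


def resolve_cutoff(values: pd.Series, definition: IndicatorDefinition) -> float:
    rule = definition.cutoff_rule
    if rule.kind in ("fixed", "fixed_le"):
        return float(rule.value)  # type: ignore[arg-type]
    if rule.kind == "median":
        observed = values.dropna()
        if observed.empty:
            raise ScoringError(
                f"indicator {definition.indicator_id!r}: median cutoff on an "
                "all-missing column"
            )
        return float(observed.median())
    raise ScoringError(
        f"indicator {definition.indicator_id!r} ({definition.var_type.value}) "
        "has no cutoff rule; use min-max normalization or declare one"
    )


def binarize_indicator(
    values: pd.Series,
    definition: IndicatorDefinition,
    cutoff_context: Optional[Mapping[str, float]] = None,
) -> pd.Series:
    """Cut a non-binary column at its rule's threshold.

    Higher-is-better: 1 iff value >= cutoff.  Lower-is-better (and the
    explicit ``fixed_le`` rule): 1 iff value <= cutoff, so a value equal
    to the median satisfies its own cutoff in both directions.
    """
    if definition.var_type is VarType.BINARY:
        raise ScoringError(
            f"indicator {definition.indicator_id!r} is already binary"
        )
    if cutoff_context and definition.indicator_id in cutoff_context:
        cutoff = float(cutoff_context[definition.indicator_id])
    else:
        cutoff = resolve_cutoff(values, definition)
    lower_is_better = (
        definition.direction is Direction.LOWER_BETTER
        or definition.cutoff_rule.kind == "fixed_le"
    )
    if lower_is_better:
        return (values <= cutoff).astype(float)
    return (values >= cutoff).astype(float)


def minmax_rescale(
    values: pd.Series,
    bounds: Union[str, tuple[float, float]] = "empirical",
) -> pd.Series:
    """Rescale to [0, 1] as (x - lo) / (hi - lo).

    ``bounds`` is either the string ``"empirical"`` (observed min/max;
    requires >= 2 values; a constant column maps to all 0.5 with a
    degeneracy warning) or a ``(lo, hi)`` pair of theoretical bounds,
    in which case any value outside them is an error.
    """
    if isinstance(bounds, str):
        if bounds != "empirical":
            raise ScoringError(f"unknown bounds {bounds!r}")
        if len(values) < 2:
            raise ScoringError("empirical min-max needs at least 2 values")
        lo, hi = float(values.min()), float(values.max())
        if lo == hi:
            warnings.warn(
                "constant column under empirical min-max; mapping to 0.5",
                stacklevel=2,
            )
            return pd.Series(0.5, index=values.index)
    else:
        lo, hi = float(bounds[0]), float(bounds[1])
        if not lo < hi:
            raise ScoringError(f"theoretical bounds ({lo}, {hi}) require lo < hi")
        if (values < lo).any() or (values > hi).any():
            raise ScoringError(
                f"value(s) outside theoretical bounds [{lo}, {hi}]"
            )
    return (values - lo) / (hi - lo)


def zscore_standardize(values: pd.Series) -> pd.Series:
    """Standardize to mean 0, sample SD 1 (n-1 denominator).

    A constant column becomes all zeros with a warning.
    """
    if len(values) < 2:
        raise ScoringError("z-score standardization needs at least 2 values")
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        warnings.warn("constant column under z-score; returning zeros", stacklevel=2)
        return pd.Series(0.0, index=values.index)
    return (values - values.mean()) / sd


def _resolve_weights(
    keys: Sequence[str], spec: WeightSpec, what: str
) -> np.ndarray:
    """Weights normalized to sum to len(keys), so equal weights are 1s
    and plain sums (and the 0-12 scale) are preserved."""
    if isinstance(spec, str):
        return np.ones(len(keys))
    try:
        w = np.array([float(spec[k]) for k in keys])
    except KeyError as exc:
        raise ScoringError(f"missing {what} weight for {exc.args[0]!r}") from None
    total = w.sum()
    if total <= 0:
        raise ScoringError(f"{what} weights sum to zero")
    return w * len(keys) / total


def aggregate_indicators(
    cell_columns: pd.DataFrame,
    method: str,
    weights: WeightSpec = "equal",
) -> pd.Series:
    """Combine the indicator columns of one cell into a raw cell score.

    Additive: weighted sum (equal weights = plain sum, so the
    theoretical maximum is the indicator count for binarized inputs).
    Geometric: plain product — any 0 among binary inputs zeroes the
    cell, and the theoretical maximum is 1.
    """
    if cell_columns.shape[1] == 0:
        raise ScoringError("cannot aggregate an empty cell")
    if method == "additive":
        w = _resolve_weights(list(cell_columns.columns), weights, "indicator")
        return cell_columns.mul(w, axis=1).sum(axis=1)
    if method == "geometric":
        if (cell_columns < 0).any().any():
            raise ScoringError("geometric aggregation requires non-negative values")
        return cell_columns.prod(axis=1)
    raise ScoringError(f"unknown aggregation {method!r}")


def aggregate_cells(
    normalized_cells: pd.DataFrame,
    method: str,
    weights: WeightSpec = "equal",
) -> pd.Series:
    """Combine normalized cell scores into the composite.

    Additive: weighted sum, range [0, n_cells] for min-max cells under
    equal weights.  Geometric: product, range [0, 1] for min-max cells;
    negative cell values (possible after z-scoring) are rejected with a
    pointer to a non-negative cell normalization.
    """
    if method == "additive":
        w = _resolve_weights(list(normalized_cells.columns), weights, "cell")
        return normalized_cells.mul(w, axis=1).sum(axis=1)
    if method == "geometric":
        if (normalized_cells < 0).any().any():
            raise ScoringError(
                "geometric cell aggregation requires non-negative cell scores; "
                "use a min-max cell normalization instead of z-scores"
            )
        return normalized_cells.prod(axis=1)
    raise ScoringError(f"unknown aggregation {method!r}")


def _normalize_indicators(
    table: FacilityIndicatorTable,
    definitions: Sequence[IndicatorDefinition],
    config: ScenarioConfig,
) -> pd.DataFrame:
    by_id = {d.indicator_id: d for d in definitions}
    out = {}
    for ind in table.values.columns:
        d = by_id.get(ind)
        if d is None:
            raise ScoringError(f"no definition for indicator {ind!r}")
        col = table.values[ind].astype(float)
        if d.var_type is VarType.BINARY:
            out[ind] = orient_indicator(col, d)
        elif config.indicator_normalization == "binarize":
            out[ind] = binarize_indicator(col, d)
        else:  # minmax
            out[ind] = minmax_rescale(orient_indicator(col, d), "empirical")
    return pd.DataFrame(out, index=table.values.index)


def run_scenario(
    table: FacilityIndicatorTable,
    matrix: QualityMatrix,
    definitions: Sequence[IndicatorDefinition],
    config: ScenarioConfig,
) -> CompositeResult:
    """Execute orient -> indicator normalization -> indicator
    aggregation -> cell normalization -> cell aggregation.

    Deterministic for fixed inputs; the scale range is recorded on the
    result (``None`` when z-score cells make it unbounded).
    """
    normalized_ind = _normalize_indicators(table, definitions, config)
    cells = [c for c in matrix.cells if matrix.indicators_in(c)]
    if not cells:
        raise ScoringError("matrix has no populated cells")

    raw = {}
    maxima: dict[CellKey, float] = {}
    for cell in cells:
        ids = list(matrix.indicators_in(cell))
        missing = [i for i in ids if i not in normalized_ind.columns]
        if missing:
            raise ScoringError(f"cell {cell}: indicator column(s) {missing} absent")
        sub = normalized_ind[ids]
        if isinstance(config.indicator_weights, Mapping):
            w_spec: WeightSpec = {
                i: config.indicator_weights.get(i, 1.0) for i in ids
            }
        else:
            w_spec = "equal"
        raw[str(cell)] = aggregate_indicators(sub, config.indicator_aggregation, w_spec)
        # Geometric cell scores live in [0, 1] whatever the indicator count.
        maxima[cell] = 1.0 if config.indicator_aggregation == "geometric" else float(
            len(ids)
        )
    raw_df = pd.DataFrame(raw, index=table.values.index)

    norm = {}
    for cell in cells:
        col = raw_df[str(cell)]
        if config.cell_normalization == "minmax_theoretical":
            norm[str(cell)] = minmax_rescale(col, (0.0, maxima[cell]))
        elif config.cell_normalization == "minmax_empirical":
            norm[str(cell)] = minmax_rescale(col, "empirical")
        else:
            norm[str(cell)] = zscore_standardize(col)
    norm_df = pd.DataFrame(norm, index=table.values.index)

    if isinstance(config.cell_weights, Mapping):
        cw: WeightSpec = {str(c): config.cell_weights.get(str(c), 1.0) for c in cells}
    else:
        cw = "equal"
    composite = aggregate_cells(norm_df, config.cell_aggregation, cw)

    if config.cell_normalization == "zscore":
        scale: Optional[tuple[float, float]] = None
    elif config.cell_aggregation == "geometric":
        scale = (0.0, 1.0)
    else:
        scale = (0.0, float(len(cells)))
    return CompositeResult(
        scenario=config.name,
        facility_scores=composite.rename(config.name),
        cell_scores=CellScoreSet(raw=raw_df, normalized=norm_df, cell_maxima=maxima),
        scale_range=scale,
        config=config,
        matrix=matrix,
    )


def run_base_and_alternatives(
    table: FacilityIndicatorTable,
    matrix: QualityMatrix,
    definitions: Sequence[IndicatorDefinition],
) -> dict[str, CompositeResult]:
    """Run the five presets; each alternative differs from base in
    exactly one configuration field."""
    return {
        name: run_scenario(table, matrix, definitions, PRESETS[name])
        for name in SCENARIO_ORDER
    }


def scores_frame(results: Mapping[str, CompositeResult]) -> pd.DataFrame:
    """Facility x scenario table of composite scores."""
    return pd.DataFrame(
        {name: res.facility_scores for name, res in results.items()}
    )
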