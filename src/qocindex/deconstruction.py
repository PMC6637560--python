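"""Deconstructing composites into cell and element sub-scores.

Cell-level means with confidence intervals across facilities, element
(structure/process/outcome) totals, and the composite summary.  Two
interval methods are supported: ``normal_se`` (mean +/- 1.96*SD/sqrt(n),
the default) and ``two_sd`` (mean +/- 2*SD); every output names the
method used.  Z-score scenarios have cell means of 0 by construction,
so their summaries carry the SD and extremes instead of an informative
mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .quality_matrix import CellKey, Element
from .scoring import CompositeResult

__all__ = [
    "CellSummary",
    "ElementTotals",
    "cell_summary",
    "element_totals",
    "facility_element_scores",
    "composite_summary",
    "indicator_contributions",
]

CI_METHODS = ("normal_se", "two_sd")
_Z95 = 1.96


def _interval(values: np.ndarray, method: str) -> tuple[float, float, float, float]:
    if method not in CI_METHODS:
        raise ValueError(f"unknown CI method {method!r}")
    n = len(values)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    half = _Z95 * sd / np.sqrt(n) if method == "normal_se" else 2.0 * sd
    return mean, mean - half, mean + half, sd


@dataclass(frozen=True)
class CellSummary:
    cell: CellKey
    scenario: str
    mean: float
    ci_low: float
    ci_high: float
    sd: float
    n: int
    ci_method: str


@dataclass(frozen=True)
class ElementTotals:
    element: Element
    scenario: str
    mean_total: float
    ci_low: float
    ci_high: float
    n_dimensions: int
    ci_method: str

    @property
    def range(self) -> tuple[float, float]:
        return (0.0, float(self.n_dimensions))


def cell_summary(
    result: CompositeResult, method: str = "normal_se"
) -> list[CellSummary]:
    """Mean and CI of every normalized cell score across facilities."""
    norm = result.cell_scores.normalized
    if len(norm) < 2:
        raise ValueError("cell summaries need at least 2 facilities")
    out = []
    for cell in result.matrix.cells:
        key = str(cell)
        if key not in norm.columns:
            continue
        mean, lo, hi, sd = _interval(norm[key].to_numpy(dtype=float), method)
        out.append(
            CellSummary(
                cell=cell,
                scenario=result.scenario,
                mean=mean,
                ci_low=lo,
                ci_high=hi,
                sd=sd,
                n=len(norm),
                ci_method=method,
            )
        )
    return out


def facility_element_scores(result: CompositeResult) -> pd.DataFrame:
    """Per-facility element sub-scores (sum of that element's cells)."""
    norm = result.cell_scores.normalized
    data = {}
    for elem in Element:
        cols = [
            str(c)
            for c in result.matrix.cells
            if c.element is elem and str(c) in norm.columns
        ]
        if cols:
            data[elem.value] = norm[cols].sum(axis=1)
    return pd.DataFrame(data, index=norm.index)


def element_totals(
    result: CompositeResult, method: str = "normal_se"
) -> list[ElementTotals]:
    """Element totals: sum of the element's cell means, with a CI from
    the per-facility element sub-scores.

    For additive scenarios the three element totals sum to the mean
    composite (linearity of the mean).
    """
    per_facility = facility_element_scores(result)
    n_dims = len(result.matrix.active_dimensions)
    out = []
    for elem in Element:
        if elem.value not in per_facility.columns:
            continue
        mean, lo, hi, _sd = _interval(
            per_facility[elem.value].to_numpy(dtype=float), method
        )
        out.append(
            ElementTotals(
                element=elem,
                scenario=result.scenario,
                mean_total=mean,
                ci_low=lo,
                ci_high=hi,
                n_dimensions=n_dims,
                ci_method=method,
            )
        )
    return out


def composite_summary(
    scores: pd.Series, method: str = "normal_se"
) -> tuple[float, float, float]:
    """Mean and CI of the composite column: (mean, ci_low, ci_high)."""
    values = np.asarray(scores, dtype=float)
    if len(values) < 2:
        raise ValueError("composite summary needs at least 2 facilities")
    mean, lo, hi, _sd = _interval(values, method)
    return mean, lo, hi


def indicator_contributions(
    result: CompositeResult,
    table_values: pd.DataFrame,
) -> pd.DataFrame:
    """Per-indicator contribution: indicator mean x its weight share of
    the cell (equal weights -> 1/cell size)."""
    rows = []
    for cell in result.matrix.cells:
        ids = result.matrix.indicators_in(cell)
        if not ids:
            continue
        for ind in ids:
            if ind not in table_values.columns:
                continue
            mean = float(table_values[ind].mean())
            rows.append(
                {
                    "scenario": result.scenario,
                    "dimension": cell.dimension.value,
                    "element": cell.element.value,
                    "indicator_id": ind,
                    "indicator_mean": mean,
                    "weight_share": 1.0 / len(ids),
                    "contribution": mean / len(ids),
                }
            )
    return pd.DataFrame(rows)


def deconstruction_frame(
    result: CompositeResult, method: str = "normal_se"
) -> pd.DataFrame:
    """CSV-ready cell summary table.

    For z-score scenarios the mean column is 0 by construction; the sd
    column is the informative one there.
    """
    return pd.DataFrame(
        [
            {
                "scenario": s.scenario,
                "cell_dimension": s.cell.dimension.value,
                "cell_element": s.cell.element.value,
                "mean": s.mean,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "sd": s.sd,
                "n": s.n,
                "ci_method": s.ci_method,
            }
            for s in cell_summary(result, method)
        ]
    )


def element_totals_frame(
    result: CompositeResult, method: str = "normal_se"
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scenario": t.scenario,
                "element": t.element.value,
                "mean_total": t.mean_total,
                "ci_low": t.ci_low,
                "ci_high": t.ci_high,
                "range_lo": t.range[0],
                "range_hi": t.range[1],
                "ci_method": t.ci_method,
            }
            for t in element_totals(result, method)
        ]
    )
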