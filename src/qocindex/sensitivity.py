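"""Ranking robustness across construction scenarios.

Facilities are ranked per scenario (rank 1 = highest score, tied scores
share the average of the spanned positions) and scenario pairs are
compared with the tie-aware Spearman coefficient — the Pearson
correlation of the two rank vectors — plus rank-shift diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "RankVector",
    "SensitivityReport",
    "rank_facilities",
    "spearman_rho",
    "compare_scenarios",
]


@dataclass(frozen=True)
class RankVector:
    facility_ids: tuple[str, ...]
    ranks: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.facility_ids)
        if len(self.ranks) != n:
            raise ValueError("facility_ids and ranks differ in length")
        if abs(sum(self.ranks) - n * (n + 1) / 2) > 1e-9:
            raise ValueError("ranks do not sum to n(n+1)/2")

    def as_series(self) -> pd.Series:
        return pd.Series(self.ranks, index=list(self.facility_ids))


def _extract_scores(obj) -> pd.Series:
    if isinstance(obj, pd.Series):
        return obj
    scores = getattr(obj, "facility_scores", None)
    if scores is not None:
        return scores
    return pd.Series(dict(obj))


def rank_facilities(scores: Union[pd.Series, Mapping[str, float]]) -> RankVector:
    """Descending ranks with average-tie handling (1 = best)."""
    s = _extract_scores(scores)
    if len(s) < 2:
        raise ValueError("ranking needs at least 2 facilities")
    ranks = rankdata(-s.to_numpy(dtype=float), method="average")
    return RankVector(
        facility_ids=tuple(str(i) for i in s.index),
        ranks=tuple(float(r) for r in ranks),
    )


def spearman_rho(x: RankVector, y: RankVector) -> float:
    """Pearson correlation of two rank vectors (tie-aware Spearman).

    Reduces to 1 - 6*sum(d^2)/(n(n^2-1)) when neither vector has ties.
    """
    if x.facility_ids != y.facility_ids:
        raise ValueError("rank vectors cover different facility sets/orders")
    rx = np.asarray(x.ranks, dtype=float)
    ry = np.asarray(y.ranks, dtype=float)
    if np.std(rx) == 0.0 or np.std(ry) == 0.0:
        raise ValueError("zero-variance rank vector (all facilities tied)")
    return float(np.corrcoef(rx, ry)[0, 1])


@dataclass(frozen=True)
class SensitivityReport:
    pairs: tuple[dict, ...]
    k: int

    def as_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(list(self.pairs))
        frame["k"] = self.k
        return frame


def compare_scenarios(
    results: Mapping[str, object],
    baseline: str = "base",
    pairs: str = "baseline",
    k: int = 5,
) -> SensitivityReport:
    """Compare scenario rankings.

    ``pairs="baseline"`` pairs every other scenario with ``baseline``;
    ``pairs="all"`` yields every unordered pair.  Each entry reports the
    tie-aware rho, the largest absolute rank shift, and the facilities
    shifting more than ``k`` positions.
    """
    names = list(results)
    if len(names) < 2:
        raise ValueError("need at least 2 scenarios")
    series = {n: _extract_scores(results[n]) for n in names}
    index = series[names[0]].index
    for n in names[1:]:
        if not series[n].index.equals(index):
            raise ValueError(f"scenario {n!r} covers a different facility set")
    rank_vectors = {n: rank_facilities(series[n]) for n in names}

    if pairs == "baseline":
        if baseline not in results:
            raise ValueError(f"baseline scenario {baseline!r} not supplied")
        pairings = [(baseline, n) for n in names if n != baseline]
    elif pairs == "all":
        pairings = [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]
    else:
        raise ValueError(f"unknown pairs mode {pairs!r}")

    entries = []
    for a, b in pairings:
        ra, rb = rank_vectors[a], rank_vectors[b]
        shifts = np.abs(np.asarray(ra.ranks) - np.asarray(rb.ranks))
        shifted = [
            fac for fac, s in zip(ra.facility_ids, shifts) if s > k
        ]
        entries.append(
            {
                "scenario_a": a,
                "scenario_b": b,
                "spearman_rho": spearman_rho(ra, rb),
                "max_abs_rank_shift": float(shifts.max()),
                "n_shifted_gt_k": len(shifted),
                "facilities_shifted_gt_k": ";".join(shifted),
            }
        )
    return SensitivityReport(pairs=tuple(entries), k=k)


def ranks_frame(results: Mapping[str, object]) -> pd.DataFrame:
    """Facility x scenario table of ranks (the rank-plot data)."""
    return pd.DataFrame(
        {n: rank_facilities(_extract_scores(r)).as_series() for n, r in results.items()}
    )
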