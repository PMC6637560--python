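import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qocindex.data_ingest import FacilityIndicatorTable
from qocindex.quality_matrix import (
    CutoffRule,
    Direction,
    Element,
    VarType,
    build_matrix,
    drop_unpopulated_dimensions,
)
from qocindex.scoring import (
    PRESETS,
    SCENARIO_ORDER,
    ScenarioConfig,
    ScoringError,
    aggregate_cells,
    aggregate_indicators,
    binarize_indicator,
    minmax_rescale,
    orient_indicator,
    run_base_and_alternatives,
    run_scenario,
    zscore_standardize,
)

from conftest import make_def


def series(values, name="x"):
    return pd.Series(values, index=[f"F{i}" for i in range(len(values))], name=name)


class TestOrientAndBinarize:
    def _wait_def(self):
        return make_def(
            "wait",
            var_type=VarType.CONTINUOUS,
            direction=Direction.LOWER_BETTER,
            cutoff=CutoffRule("fixed", 20.0),
        )

    @pytest.mark.parametrize("value,expected", [(15.0, 1.0), (25.0, 0.0), (20.0, 1.0)])
    def test_lower_better_cutoff(self, value, expected):
        col = series([value, 30.0, 10.0])
        out = binarize_indicator(col, self._wait_def())
        assert out.iloc[0] == expected

    def test_fixed_ge_cutoff(self):
        d = make_def("sba", var_type=VarType.CONTINUOUS, cutoff=CutoffRule("fixed", 3.0))
        out = binarize_indicator(series([3.0, 2.0, 5.0]), d)
        assert list(out) == [1.0, 0.0, 1.0]

    def test_median_cutoff_ordinal(self):
        # [2,3,3,4,5]: median 3 -> [0,1,1,1,1]
        d = make_def("sat", var_type=VarType.ORDINAL, cutoff=CutoffRule("median"))
        out = binarize_indicator(series([2, 3, 3, 4, 5]), d)
        assert list(out) == [0.0, 1.0, 1.0, 1.0, 1.0]

    def test_median_on_all_missing_errors(self):
        d = make_def("sat", var_type=VarType.ORDINAL, cutoff=CutoffRule("median"))
        with pytest.raises(ScoringError, match="all-missing"):
            binarize_indicator(series([np.nan, np.nan]), d)

    def test_orient_reflects_lower_better(self):
        d = self._wait_def()
        out = orient_indicator(series([10.0, 30.0, 20.0]), d)
        assert list(out) == [20.0, 0.0, 10.0]

    def test_orient_identity_higher_better(self):
        d = make_def("x", var_type=VarType.CONTINUOUS, cutoff=CutoffRule("median"))
        col = series([1.0, 2.0])
        pd.testing.assert_series_equal(orient_indicator(col, d), col)


class TestMinmaxRescale:
    def test_theoretical_formula(self):
        # raw 3 in bounds (0, 6) -> 0.5
        out = minmax_rescale(series([3.0, 0.0, 6.0]), (0.0, 6.0))
        assert list(out) == [0.5, 0.0, 1.0]

    def test_empirical_endpoints(self):
        out = minmax_rescale(series([2.0, 4.0, 6.0]), "empirical")
        assert list(out) == [0.0, 0.5, 1.0]

    def test_constant_empirical_maps_to_half(self):
        with pytest.warns(UserWarning, match="constant"):
            out = minmax_rescale(series([5.0, 5.0, 5.0]), "empirical")
        assert list(out) == [0.5, 0.5, 0.5]

    def test_out_of_bounds_errors(self):
        with pytest.raises(ScoringError, match="outside"):
            minmax_rescale(series([7.0, 1.0]), (0.0, 6.0))

    def test_bad_bounds(self):
        with pytest.raises(ScoringError):
            minmax_rescale(series([1.0, 2.0]), (5.0, 5.0))


class TestZscore:
    def test_unit_example(self):
        # [1,2,3]: mean 2, sample SD 1 -> [-1, 0, 1]
        out = zscore_standardize(series([1.0, 2.0, 3.0]))
        assert list(out) == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_returns_zeros(self):
        with pytest.warns(UserWarning, match="constant"):
            out = zscore_standardize(series([4.0, 4.0, 4.0]))
        assert list(out) == [0.0, 0.0, 0.0]

    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=20).filter(
            lambda v: max(v) - min(v) > 1e-3
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_mean_zero_sd_one(self, values):
        out = zscore_standardize(series(values))
        assert out.mean() == pytest.approx(0.0, abs=1e-9)
        assert out.std(ddof=1) == pytest.approx(1.0, rel=1e-9)


class TestAggregation:
    def test_additive_sum_and_maximum(self):
        cols = pd.DataFrame({"a": [1.0], "b": [0.0], "c": [1.0]})
        assert aggregate_indicators(cols, "additive").iloc[0] == 2.0

    def test_geometric_any_zero(self):
        cols = pd.DataFrame({"a": [1.0], "b": [0.0], "c": [1.0]})
        assert aggregate_indicators(cols, "geometric").iloc[0] == 0.0

    def test_geometric_all_ones(self):
        cols = pd.DataFrame({"a": [1.0], "b": [1.0], "c": [1.0]})
        assert aggregate_indicators(cols, "geometric").iloc[0] == 1.0

    def test_geometric_negative_rejected(self):
        cols = pd.DataFrame({"a": [-0.5], "b": [1.0]})
        with pytest.raises(ScoringError, match="non-negative"):
            aggregate_indicators(cols, "geometric")

    def test_cells_additive_maximum(self):
        cells = pd.DataFrame({f"c{i}": [1.0] for i in range(12)})
        assert aggregate_cells(cells, "additive").iloc[0] == 12.0

    def test_cells_geometric_zero_propagates(self):
        cells = pd.DataFrame({f"c{i}": [1.0] for i in range(11)} | {"c11": [0.0]})
        assert aggregate_cells(cells, "geometric").iloc[0] == 0.0

    def test_cells_geometric_product(self):
        cells = pd.DataFrame({f"c{i}": [0.9] for i in range(12)})
        assert aggregate_cells(cells, "geometric").iloc[0] == pytest.approx(0.9 ** 12)
        assert 0.9 ** 12 == pytest.approx(0.2824, abs=5e-5)

    def test_cells_geometric_negative_rejected(self):
        cells = pd.DataFrame({"c0": [-1.2], "c1": [0.5]})
        with pytest.raises(ScoringError, match="z-score"):
            aggregate_cells(cells, "geometric")

    def test_weights_normalized_to_component_count(self):
        cols = pd.DataFrame({"a": [1.0], "b": [1.0]})
        out = aggregate_indicators(cols, "additive", {"a": 10.0, "b": 10.0})
        assert out.iloc[0] == pytest.approx(2.0)  # equal weights -> plain sum

    @given(
        st.lists(st.floats(0, 1), min_size=2, max_size=8),
    )
    @settings(max_examples=100, deadline=None)
    def test_geometric_le_min_le_additive_mean(self, values):
        cols = pd.DataFrame({f"c{i}": [v] for i, v in enumerate(values)})
        geo = aggregate_cells(cols, "geometric").iloc[0]
        add_mean = aggregate_cells(cols, "additive").iloc[0] / len(values)
        assert geo <= min(values) + 1e-12
        assert min(values) <= add_mean + 1e-12


# ---------------------------------------------------------------------------
# Brute-force oracle: an independent recomputation from the formulas,
# using plain python loops over dicts, for tiny instances.
# ---------------------------------------------------------------------------

def brute_force_scenario(values, defs, config):
    """values: {facility: {indicator: value}}; defs: list of definitions."""
    facilities = sorted(values)
    by_cell = {}
    for d in defs:
        by_cell.setdefault((d.cell.dimension.value, d.cell.element.value), []).append(d)

    # indicator normalization
    norm = {f: {} for f in facilities}
    for d in defs:
        col = [values[f][d.indicator_id] for f in facilities]
        if d.var_type is VarType.BINARY:
            out = col
        elif config.indicator_normalization == "binarize":
            if d.cutoff_rule.kind == "median":
                s = sorted(col)
                n = len(s)
                cut = s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2
            else:
                cut = d.cutoff_rule.value
            if d.direction is Direction.LOWER_BETTER or d.cutoff_rule.kind == "fixed_le":
                out = [1.0 if v <= cut else 0.0 for v in col]
            else:
                out = [1.0 if v >= cut else 0.0 for v in col]
        else:
            if d.direction is Direction.LOWER_BETTER:
                col = [max(col) - v for v in col]
            lo, hi = min(col), max(col)
            out = [0.5] * len(col) if lo == hi else [(v - lo) / (hi - lo) for v in col]
        for f, v in zip(facilities, out):
            norm[f][d.indicator_id] = v

    # indicator aggregation -> raw cell scores
    raw = {f: {} for f in facilities}
    maxima = {}
    for cell, cell_defs in by_cell.items():
        for f in facilities:
            vals = [norm[f][d.indicator_id] for d in cell_defs]
            if config.indicator_aggregation == "additive":
                raw[f][cell] = sum(vals)
            else:
                raw[f][cell] = math.prod(vals)
        maxima[cell] = 1.0 if config.indicator_aggregation == "geometric" else len(cell_defs)

    # cell normalization
    cnorm = {f: {} for f in facilities}
    for cell in by_cell:
        col = [raw[f][cell] for f in facilities]
        if config.cell_normalization == "minmax_theoretical":
            out = [v / maxima[cell] for v in col]
        elif config.cell_normalization == "minmax_empirical":
            lo, hi = min(col), max(col)
            out = [0.5] * len(col) if lo == hi else [(v - lo) / (hi - lo) for v in col]
        else:
            mean = sum(col) / len(col)
            sd = math.sqrt(sum((v - mean) ** 2 for v in col) / (len(col) - 1))
            out = [0.0] * len(col) if sd == 0 else [(v - mean) / sd for v in col]
        for f, v in zip(facilities, out):
            cnorm[f][cell] = v

    # cell aggregation
    composite = {}
    for f in facilities:
        vals = list(cnorm[f].values())
        composite[f] = (
            sum(vals) if config.cell_aggregation == "additive" else math.prod(vals)
        )
    return composite


def tiny_instance(seed):
    rng = np.random.default_rng(seed)
    defs = [make_def(f"s{i}") for i in range(3)]
    defs.append(
        make_def(
            "wait",
            element=Element.PROCESS,
            var_type=VarType.CONTINUOUS,
            direction=Direction.LOWER_BETTER,
            cutoff=CutoffRule("median"),
        )
    )
    defs.append(
        make_def("sat", element=Element.PROCESS, var_type=VarType.ORDINAL,
                 cutoff=CutoffRule("median"))
    )
    defs.append(make_def("p0", element=Element.PROCESS))
    facilities = [f"F{i}" for i in range(4)]
    values = pd.DataFrame(
        {
            "s0": rng.integers(0, 2, 4).astype(float),
            "s1": rng.integers(0, 2, 4).astype(float),
            "s2": rng.integers(0, 2, 4).astype(float),
            "wait": rng.uniform(5, 60, 4).round(1),
            "sat": rng.integers(1, 6, 4).astype(float),
            "p0": rng.integers(0, 2, 4).astype(float),
        },
        index=pd.Index(facilities, name="facility_id"),
    )
    table = FacilityIndicatorTable(values=values)
    matrix = drop_unpopulated_dimensions(build_matrix(defs))
    return table, matrix, defs


class TestRunScenarioOracle:
    @pytest.mark.parametrize("scenario", SCENARIO_ORDER)
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, scenario, seed):
        table, matrix, defs = tiny_instance(seed)
        config = PRESETS[scenario]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = run_scenario(table, matrix, defs, config)
            expected = brute_force_scenario(
                {f: dict(row) for f, row in table.values.iterrows()}, defs, config
            )
        for fac in table.values.index:
            assert result.facility_scores[fac] == pytest.approx(
                expected[fac], abs=1e-10
            ), f"{scenario} seed {seed} facility {fac}"


class TestRunScenario:
    def test_base_scale_0_12(self, study, study_table):
        result = run_scenario(study_table, study.matrix, study.definitions, PRESETS["base"])
        assert result.scale_range == (0.0, 12.0)
        assert ((result.facility_scores >= 0) & (result.facility_scores <= 12)).all()

    def test_alt_d_scale_0_1(self, study, study_table):
        result = run_scenario(study_table, study.matrix, study.definitions, PRESETS["alt_d"])
        assert result.scale_range == (0.0, 1.0)
        assert ((result.facility_scores >= 0) & (result.facility_scores <= 1)).all()

    def test_alt_c_unbounded(self, study, study_table):
        result = run_scenario(study_table, study.matrix, study.definitions, PRESETS["alt_c"])
        assert result.scale_range is None
        assert result.scale_label == "unbounded"

    def test_alt_c_cells_standardized(self, study_results):
        norm = study_results["alt_c"].cell_scores.normalized
        for col in norm.columns:
            assert norm[col].mean() == pytest.approx(0.0, abs=1e-9)
            assert norm[col].std(ddof=1) == pytest.approx(1.0, rel=1e-9)

    def test_base_raw_cells_are_integers_within_maxima(self, study_results):
        res = study_results["base"]
        raw = res.cell_scores.raw
        assert np.allclose(raw, raw.round())
        for cell, mx in res.cell_scores.cell_maxima.items():
            col = raw[str(cell)]
            assert ((col >= 0) & (col <= mx)).all()

    def test_deterministic(self, study, study_table):
        a = run_scenario(study_table, study.matrix, study.definitions, PRESETS["base"])
        b = run_scenario(study_table, study.matrix, study.definitions, PRESETS["base"])
        pd.testing.assert_series_equal(a.facility_scores, b.facility_scores)

    def test_base_monotone_in_any_indicator(self):
        table, matrix, defs = tiny_instance(7)
        binary_ids = [d.indicator_id for d in defs if d.var_type is VarType.BINARY]
        base = run_scenario(table, matrix, defs, PRESETS["base"]).facility_scores
        for ind in binary_ids:
            for fac in table.values.index:
                if table.values.loc[fac, ind] == 1.0:
                    continue
                bumped = table.values.copy()
                bumped.loc[fac, ind] = 1.0
                res = run_scenario(
                    FacilityIndicatorTable(values=bumped), matrix, defs, PRESETS["base"]
                ).facility_scores
                assert (res - base >= -1e-12).all()

    def test_composite_invariant_to_cell_permutation(self, study_results):
        res = study_results["base"]
        norm = res.cell_scores.normalized
        shuffled = norm[list(norm.columns[::-1])]
        pd.testing.assert_series_equal(
            aggregate_cells(norm, "additive"),
            aggregate_cells(shuffled, "additive"),
            check_names=False,
        )


class TestRunBaseAndAlternatives:
    def test_five_results_same_facilities(self, study_results):
        assert list(study_results) == SCENARIO_ORDER
        index = study_results["base"].facility_scores.index
        for res in study_results.values():
            assert res.facility_scores.index.equals(index)

    def test_alternatives_differ_in_one_field(self):
        base = PRESETS["base"]
        fields = [
            "indicator_normalization",
            "indicator_aggregation",
            "cell_normalization",
            "cell_aggregation",
            "indicator_weights",
            "cell_weights",
        ]
        for name in ["alt_a", "alt_b", "alt_c", "alt_d"]:
            diffs = [
                f for f in fields if getattr(PRESETS[name], f) != getattr(base, f)
            ]
            assert len(diffs) == 1, name

    def test_perfect_quality_hits_scale_maxima(self, tiny_matrix, tiny_definitions):
        values = pd.DataFrame(
            1.0,
            index=pd.Index([f"F{i}" for i in range(4)], name="facility_id"),
            columns=[d.indicator_id for d in tiny_definitions],
        )
        table = FacilityIndicatorTable(values=values)
        n_cells = sum(
            1 for c in tiny_matrix.cells if tiny_matrix.indicators_in(c)
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = run_base_and_alternatives(table, tiny_matrix, tiny_definitions)
        for name in ["base", "alt_a", "alt_b"]:
            assert (results[name].facility_scores == n_cells).all(), name
        assert (results["alt_d"].facility_scores == 1.0).all()
        # alt_c is degenerate (constant cells -> zeros), scale n/a
        assert (results["alt_c"].facility_scores == 0.0).all()


class TestScenarioConfig:
    def test_unknown_enum_rejected(self):
        with pytest.raises(ScoringError):
            ScenarioConfig(name="x", cell_normalization="sigmoid")

    def test_negative_weights_rejected(self):
        with pytest.raises(ScoringError):
            ScenarioConfig(name="x", cell_weights={"c": -1.0})

    def test_from_yaml(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("name: custom\nindicator_normalization: minmax\n")
        cfg = ScenarioConfig.from_file(path)
        assert cfg.name == "custom"
        assert cfg.indicator_normalization == "minmax"

    def test_from_json(self, tmp_path):
        path = tmp_path / "cfg.json"
        path.write_text('{"name": "custom", "cell_aggregation": "geometric"}')
        assert ScenarioConfig.from_file(path).cell_aggregation == "geometric"
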