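import numpy as np
import pandas as pd
import pytest

from qocindex.data_ingest import (
    FacilityIndicatorTable,
    ImputationPolicy,
    aggregate_to_facility,
    assemble_facility_table,
    filter_complete_facilities,
    impute_missing,
)
from qocindex.quality_matrix import (
    CellKey,
    CutoffRule,
    Dimension,
    Direction,
    Element,
    IndicatorDefinition,
    SourceTool,
    VarType,
    build_matrix,
)
from qocindex.synthetic_data import SimulationConfig, generate_study


def make_def(
    ind_id,
    dimension=Dimension.EFFECTIVE,
    element=Element.STRUCTURE,
    tool=SourceTool.INVENTORY,
    var_type=VarType.BINARY,
    direction=Direction.HIGHER_BETTER,
    cutoff=None,
    proxy=None,
):
    return IndicatorDefinition(
        indicator_id=ind_id,
        label=ind_id,
        cell=CellKey(dimension, element),
        source_tool=tool,
        var_type=var_type,
        direction=direction,
        cutoff_rule=cutoff or CutoffRule("none"),
        proxy_id=proxy,
    )


@pytest.fixture
def tiny_definitions():
    """6 binary indicators over 2 cells (4 + 2), 4 facilities."""
    defs = [make_def(f"s{i}") for i in range(4)]
    defs += [
        make_def(f"p{i}", element=Element.PROCESS, tool=SourceTool.OBSERVATION)
        for i in range(2)
    ]
    return defs


@pytest.fixture
def tiny_table(tiny_definitions):
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.integers(0, 2, size=(4, 6)).astype(float),
        index=pd.Index([f"F{i}" for i in range(4)], name="facility_id"),
        columns=[d.indicator_id for d in tiny_definitions],
    )
    return FacilityIndicatorTable(values=values)


@pytest.fixture
def tiny_matrix(tiny_definitions):
    from qocindex.quality_matrix import drop_unpopulated_dimensions

    return drop_unpopulated_dimensions(build_matrix(tiny_definitions))


@pytest.fixture(scope="session")
def study():
    """One default-sized synthetic study (26 facilities, 85 indicators)."""
    return generate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def study_table(study):
    aggregated = {t: aggregate_to_facility(rs) for t, rs in study.recordsets.items()}
    retained = filter_complete_facilities(aggregated)
    table = assemble_facility_table(aggregated, study.definitions, retained)
    return impute_missing(table, ImputationPolicy(), study.definitions)


@pytest.fixture(scope="session")
def study_results(study, study_table):
    from qocindex.scoring import run_base_and_alternatives

    return run_base_and_alternatives(study_table, study.matrix, study.definitions)
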