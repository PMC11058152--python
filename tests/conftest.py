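"""Shared fixtures: small hand-built matrices and the study-shaped
synthetic matrix."""

from __future__ import annotations

import numpy as np
import pytest

from aecpg_align import (
    AECPGCatalog,
    DesireMatrix,
    DesireRecord,
    ScenarioSupply,
    SupplyMatrix,
    dutch_case_config,
    dutch_supply_matrix,
    generate_desire_matrix,
)


def make_record(scores, weights, stakeholder_id="s1", group="Citizens"):
    return DesireRecord(
        stakeholder_id=stakeholder_id,
        group=group,
        scores=np.array(scores, dtype=object),
        weights=np.array(weights, dtype=object),
    )


def make_supply(values, scenario_id="scn"):
    return ScenarioSupply(
        scenario_id=scenario_id, supply=np.array(values, dtype=object)
    )


@pytest.fixture(scope="session")
def catalog3():
    return AECPGCatalog(("biodiversity", "water_quality", "recreation"))


@pytest.fixture(scope="session")
def dutch_supply():
    return dutch_supply_matrix()


@pytest.fixture(scope="session")
def dutch_matrix():
    """Study-shaped synthetic desire matrix: 83 stakeholders, 10 groups."""
    return generate_desire_matrix(dutch_case_config(seed=123))


@pytest.fixture()
def toy_matrix(catalog3):
    """Two organisations and one citizen subgroup over a 3-good catalog."""
    records = (
        make_record([1, 0, 1], [2, 0, 1], "org_a", "NGOs"),
        make_record([0, 1, 0], [1, 1, 0], "org_b", "Banks"),
        make_record([0.5, 1, 0], [1, 1, 1], "cit_total", "Citizens"),
    )
    return DesireMatrix(catalog=catalog3, records=records)
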