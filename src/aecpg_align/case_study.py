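"""Reference tables of the Dutch national AECPG assessment.

The published Dutch case assessed nine public goods against the visions
of 83 stakeholders in ten groups and four meta-scenarios for the
agricultural sector in 2050.  This module bundles the openly printed
parts of that case:

* the four meta-scenario expected-change vectors
  (:func:`dutch_supply_matrix`),
* the citizen survey percentage table with its thirteen subgroup rows
  (:func:`dutch_citizen_survey`),
* the per-group sizes and mean desire scores of the nine organisation
  groups (:data:`DUTCH_GROUP_PROFILES`), and
* the published overall-agreement figures used by the reproduction
  harness (:data:`REFERENCE_OVERALL_AGREEMENT`).

The stakeholder-level desire matrix itself was released only as
supplementary material and is not redistributed here; the synthetic
generator's :func:`~aecpg_align.synthetic.dutch_case_config` uses the
group profiles to produce matrices with the same shape and first
moments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catalog import DEFAULT_CATALOG
from .citizen_scoring import SurveyTable
from .matrices import ScenarioSupply, SupplyMatrix

__all__ = [
    "DUTCH_SUPPLY",
    "DUTCH_CITIZEN_SURVEY",
    "DUTCH_GROUP_PROFILES",
    "REFERENCE_OVERALL_AGREEMENT",
    "dutch_supply_matrix",
    "dutch_citizen_survey",
]

# Expected change per meta-scenario, in catalog order:
# (biodiversity, aesthetic_landscape_quality, heritage, water_quality,
#  air_quality, soil_quality, product_quality, recreation,
#  climate_regulation)
DUTCH_SUPPLY: dict[str, tuple[float, ...]] = {
    "regional": (1, 1, 0.5, 1, 0.5, 1, 0.5, 1, 1),
    "productivity": (0, 0, 0, 0.5, 0.5, 0, 0, 0, 1),
    "meadow_bird": (1, 1, 1, 0.5, 0, 0.5, 0, 0.5, 0.5),
    "integral": (1, 1, 0.5, 1, 0, 1, 0.5, 0.5, 1),
}

# Citizen survey: per subgroup, % of respondents expressing desire per good.
DUTCH_CITIZEN_SURVEY: dict[str, dict[str, float]] = {
    "total":        {"biodiversity": 54, "aesthetic_landscape_quality": 30, "heritage": 42, "water_quality": 19, "air_quality": 41, "soil_quality": 12, "product_quality": 44, "recreation": 41, "climate_regulation": 62},
    "men":          {"biodiversity": 53, "aesthetic_landscape_quality": 29, "heritage": 40, "water_quality": 20, "air_quality": 39, "soil_quality": 11, "product_quality": 42, "recreation": 40, "climate_regulation": 63},
    "women":        {"biodiversity": 54, "aesthetic_landscape_quality": 30, "heritage": 43, "water_quality": 18, "air_quality": 44, "soil_quality": 13, "product_quality": 45, "recreation": 42, "climate_regulation": 61},
    "left":         {"biodiversity": 59, "aesthetic_landscape_quality": 32, "heritage": 39, "water_quality": 18, "air_quality": 45, "soil_quality": 13, "product_quality": 40, "recreation": 46, "climate_regulation": 71},
    "centre":       {"biodiversity": 51, "aesthetic_landscape_quality": 30, "heritage": 45, "water_quality": 21, "air_quality": 28, "soil_quality": 11, "product_quality": 43, "recreation": 39, "climate_regulation": 57},
    "right":        {"biodiversity": 47, "aesthetic_landscape_quality": 27, "heritage": 41, "water_quality": 17, "air_quality": 29, "soil_quality": 12, "product_quality": 50, "recreation": 36, "climate_regulation": 53},
    "age_15_24":    {"biodiversity": 47, "aesthetic_landscape_quality": 25, "heritage": 38, "water_quality": 16, "air_quality": 46, "soil_quality": 6,  "product_quality": 36, "recreation": 31, "climate_regulation": 71},
    "age_25_39":    {"biodiversity": 55, "aesthetic_landscape_quality": 38, "heritage": 32, "water_quality": 22, "air_quality": 43, "soil_quality": 11, "product_quality": 47, "recreation": 38, "climate_regulation": 59},
    "age_40_54":    {"biodiversity": 55, "aesthetic_landscape_quality": 35, "heritage": 42, "water_quality": 20, "air_quality": 28, "soil_quality": 13, "product_quality": 45, "recreation": 44, "climate_regulation": 61},
    "age_55_plus":  {"biodiversity": 54, "aesthetic_landscape_quality": 23, "heritage": 49, "water_quality": 19, "air_quality": 41, "soil_quality": 14, "product_quality": 43, "recreation": 45, "climate_regulation": 62},
    "rural":        {"biodiversity": 53, "aesthetic_landscape_quality": 21, "heritage": 42, "water_quality": 18, "air_quality": 39, "soil_quality": 11, "product_quality": 45, "recreation": 42, "climate_regulation": 59},
    "town":         {"biodiversity": 53, "aesthetic_landscape_quality": 32, "heritage": 40, "water_quality": 20, "air_quality": 40, "soil_quality": 13, "product_quality": 42, "recreation": 42, "climate_regulation": 62},
    "large_town":   {"biodiversity": 56, "aesthetic_landscape_quality": 41, "heritage": 44, "water_quality": 21, "air_quality": 48, "soil_quality": 12, "product_quality": 43, "recreation": 39, "climate_regulation": 66},
}

# Organisation groups: size and mean desire per good (citizens are the
# 13 survey subgroups above).  Means double as desire probabilities for
# the case-shaped synthetic generator.
DUTCH_GROUP_PROFILES: dict[str, tuple[int, dict[str, float]]] = {
    "Banks":                (6,  {"biodiversity": 0.83, "aesthetic_landscape_quality": 0.33, "heritage": 0.0,  "water_quality": 0.67, "air_quality": 0.33, "soil_quality": 0.83, "product_quality": 0.5,  "recreation": 0.0,  "climate_regulation": 1.0}),
    "Funds":                (5,  {"biodiversity": 1.0,  "aesthetic_landscape_quality": 1.0,  "heritage": 0.8,  "water_quality": 0.4,  "air_quality": 0.2,  "soil_quality": 0.4,  "product_quality": 0.0,  "recreation": 0.6,  "climate_regulation": 0.6}),
    "Landowners":           (6,  {"biodiversity": 1.0,  "aesthetic_landscape_quality": 0.83, "heritage": 0.5,  "water_quality": 0.67, "air_quality": 0.5,  "soil_quality": 0.83, "product_quality": 0.33, "recreation": 0.5,  "climate_regulation": 0.67}),
    "Value chain":          (18, {"biodiversity": 0.67, "aesthetic_landscape_quality": 0.06, "heritage": 0.11, "water_quality": 0.39, "air_quality": 0.17, "soil_quality": 0.39, "product_quality": 0.56, "recreation": 0.0,  "climate_regulation": 0.83}),
    "Governments":          (7,  {"biodiversity": 1.0,  "aesthetic_landscape_quality": 0.86, "heritage": 0.57, "water_quality": 1.0,  "air_quality": 0.71, "soil_quality": 0.86, "product_quality": 0.57, "recreation": 0.71, "climate_regulation": 1.0}),
    "NGOs":                 (13, {"biodiversity": 1.0,  "aesthetic_landscape_quality": 0.46, "heritage": 0.31, "water_quality": 0.69, "air_quality": 0.38, "soil_quality": 0.69, "product_quality": 0.23, "recreation": 0.31, "climate_regulation": 0.46}),
    "Labels":               (3,  {"biodiversity": 1.0,  "aesthetic_landscape_quality": 0.67, "heritage": 0.33, "water_quality": 1.0,  "air_quality": 0.67, "soil_quality": 1.0,  "product_quality": 0.67, "recreation": 0.0,  "climate_regulation": 1.0}),
    "Pension funds":        (3,  {"biodiversity": 0.33, "aesthetic_landscape_quality": 0.0,  "heritage": 0.0,  "water_quality": 0.0,  "air_quality": 0.0,  "soil_quality": 0.33, "product_quality": 0.0,  "recreation": 0.0,  "climate_regulation": 1.0}),
    "Farmer organizations": (9,  {"biodiversity": 0.8,  "aesthetic_landscape_quality": 0.75, "heritage": 0.3,  "water_quality": 0.9,  "air_quality": 0.4,  "soil_quality": 0.9,  "product_quality": 0.7,  "recreation": 0.2,  "climate_regulation": 0.9}),
}

#: Published overall agreement per scenario for the baseline analysis and
#: both sensitivity re-runs.  The meadow-bird baseline cell is reported as
#: 57 in the summary table and 58 in the running text, hence the set.
REFERENCE_OVERALL_AGREEMENT: dict[str, dict[str, set[int]]] = {
    "baseline": {
        "regional": {83},
        "productivity": {34},
        "meadow_bird": {57, 58},
        "integral": {78},
    },
    "simplified_weights": {
        "regional": {83},
        "productivity": {34},
        "meadow_bird": {57},
        "integral": {77},
    },
    "simplified_delivery": {
        "regional": {73},
        "productivity": {27},
        "meadow_bird": {38},
        "integral": {68},
    },
}


def dutch_supply_matrix() -> SupplyMatrix:
    """The four meta-scenario expected-change vectors of the Dutch case."""
    return SupplyMatrix(
        catalog=DEFAULT_CATALOG,
        scenarios=tuple(
            ScenarioSupply(scenario_id=sid, supply=np.array(vals, dtype=object))
            for sid, vals in DUTCH_SUPPLY.items()
        ),
    )


def dutch_citizen_survey() -> SurveyTable:
    """The thirteen-subgroup citizen percentage table of the Dutch case."""
    df = pd.DataFrame.from_dict(DUTCH_CITIZEN_SURVEY, orient="index")
    df = df[list(DEFAULT_CATALOG)]
    df.index.name = "subgroup"
    return SurveyTable(catalog=DEFAULT_CATALOG, data=df)
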