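"""Scoring-robustness transforms and the three-block sensitivity report.

Both the 0/1/2 weighting of vision documents and the three-level coding
of scenario supply are judgment calls, so the analysis is re-run under
two simplifications:

* **simplified weights** — every weight 2 becomes 1, removing the
  distinction between central and merely mentioned goods;
* **simplified delivery** — every supply level 0.5 becomes 0, counting
  active conservation as no enhancement.

Each transform returns a new matrix (inputs are never mutated) and is
idempotent.  :func:`run_sensitivity` bundles the baseline and both
re-runs into one report mirroring the conventional three-block summary
table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .agreement import GroupAgreementSummary, group_agreement
from .matrices import DesireMatrix, DesireRecord, ScenarioSupply, SupplyMatrix

__all__ = [
    "simplify_weights",
    "simplify_supply",
    "SensitivityReport",
    "run_sensitivity",
]


def simplify_weights(m: DesireMatrix) -> DesireMatrix:
    """Collapse central (weight 2) goods to weight 1; scores untouched."""
    records = tuple(
        DesireRecord(
            stakeholder_id=r.stakeholder_id,
            group=r.group,
            scores=r.scores,
            weights=np.minimum(r.weights, 1),
        )
        for r in m.records
    )
    return DesireMatrix(catalog=m.catalog, records=records,
                        citizen_groups=m.citizen_groups)


def simplify_supply(sm: SupplyMatrix) -> SupplyMatrix:
    """Collapse active conservation (0.5) to 0 in every scenario."""
    scenarios = tuple(
        ScenarioSupply(
            scenario_id=s.scenario_id,
            supply=np.where(s.supply == 0.5, 0.0, s.supply),
        )
        for s in sm.scenarios
    )
    return SupplyMatrix(catalog=sm.catalog, scenarios=scenarios)


@dataclass(frozen=True)
class SensitivityReport:
    """Baseline + both sensitivity re-runs, per scenario."""

    baseline: dict[str, GroupAgreementSummary]
    simplified_weights: dict[str, GroupAgreementSummary]
    simplified_delivery: dict[str, GroupAgreementSummary]

    def to_frame(self) -> pd.DataFrame:
        """Three-block long-format table: one row per (analysis, scenario)
        with overall agreement and the best/worst group."""
        rows = []
        for analysis, block in (
            ("baseline", self.baseline),
            ("simplified_weights", self.simplified_weights),
            ("simplified_delivery", self.simplified_delivery),
        ):
            for scenario_id, summary in block.items():
                g = summary.per_group
                rows.append(
                    {
                        "analysis": analysis,
                        "scenario_id": scenario_id,
                        "overall_agreement": summary.overall,
                        "max_agreement": g["mean"].max(),
                        "max_group": g["mean"].idxmax(),
                        "min_agreement": g["mean"].min(),
                        "min_group": g["mean"].idxmin(),
                    }
                )
        return pd.DataFrame(rows)


def run_sensitivity(
    m: DesireMatrix,
    sm: SupplyMatrix,
    overall_mode: str = "stakeholder_mean",
    policy: str = "agreement_closed_at_80",
) -> SensitivityReport:
    """Run the agreement analysis at baseline and under both transforms."""

    def summarise(dm: DesireMatrix, supply: SupplyMatrix):
        return {
            s.scenario_id: group_agreement(dm, s, overall_mode, policy)
            for s in supply.scenarios
        }

    return SensitivityReport(
        baseline=summarise(m, sm),
        simplified_weights=summarise(simplify_weights(m), sm),
        simplified_delivery=summarise(m, simplify_supply(sm)),
    )
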