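"""Harness comparing a computed analysis against published reference values.

The published overall-agreement figures leave two details ambiguous: how
"overall agreement" aggregates stakeholders (mean over all stakeholders
versus mean of the group means) and how the overlapping class-band edges
are closed.  Rather than guessing, the harness runs the full analysis
under every combination of overall mode and boundary policy and reports
which, if any, reproduces the reference numbers.  (Boundary policy can
never change the numbers — only the verbal labels — but it is part of
the reported combination for completeness.)
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .agreement import BOUNDARY_POLICIES, OVERALL_MODES
from .case_study import REFERENCE_OVERALL_AGREEMENT, dutch_supply_matrix
from .matrices import DesireMatrix, SupplyMatrix
from .sensitivity import run_sensitivity

__all__ = ["ReproductionAttempt", "ReproductionReport", "compare_to_reference"]


@dataclass(frozen=True)
class ReproductionAttempt:
    """One (overall_mode, boundary_policy) run against the reference."""

    overall_mode: str
    boundary_policy: str
    computed: dict[str, dict[str, int]]  # analysis -> scenario -> overall
    mismatches: tuple[str, ...]  # "analysis/scenario: got X, expected {..}"

    @property
    def matches(self) -> bool:
        return not self.mismatches


@dataclass(frozen=True)
class ReproductionReport:
    attempts: tuple[ReproductionAttempt, ...]

    @property
    def matching(self) -> tuple[ReproductionAttempt, ...]:
        return tuple(a for a in self.attempts if a.matches)

    @property
    def any_match(self) -> bool:
        return bool(self.matching)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.attempts:
            for analysis, scen in a.computed.items():
                for scenario_id, overall in scen.items():
                    rows.append(
                        {
                            "overall_mode": a.overall_mode,
                            "boundary_policy": a.boundary_policy,
                            "analysis": analysis,
                            "scenario_id": scenario_id,
                            "overall_agreement": overall,
                            "matches_reference": not any(
                                m.startswith(f"{analysis}/{scenario_id}:")
                                for m in a.mismatches
                            ),
                        }
                    )
        return pd.DataFrame(rows)


def compare_to_reference(
    m: DesireMatrix,
    sm: SupplyMatrix | None = None,
    reference: dict[str, dict[str, set[int]]] | None = None,
) -> ReproductionReport:
    """Try every overall mode × boundary policy against the reference.

    ``sm`` defaults to the published Dutch supply matrix and ``reference``
    to the published overall agreements (where the table and running text
    disagree, either value is accepted).
    """
    sm = sm if sm is not None else dutch_supply_matrix()
    reference = reference if reference is not None else REFERENCE_OVERALL_AGREEMENT
    attempts = []
    for mode in OVERALL_MODES:
        for policy in BOUNDARY_POLICIES:
            report = run_sensitivity(m, sm, overall_mode=mode, policy=policy)
            computed: dict[str, dict[str, int]] = {}
            mismatches: list[str] = []
            for analysis, block in (
                ("baseline", report.baseline),
                ("simplified_weights", report.simplified_weights),
                ("simplified_delivery", report.simplified_delivery),
            ):
                computed[analysis] = {
                    sid: summ.overall for sid, summ in block.items()
                }
                for sid, expected in reference.get(analysis, {}).items():
                    got = computed[analysis].get(sid)
                    if got not in expected:
                        mismatches.append(
                            f"{analysis}/{sid}: got {got}, expected one of "
                            f"{sorted(expected)}"
                        )
            attempts.append(
                ReproductionAttempt(
                    overall_mode=mode,
                    boundary_policy=policy,
                    computed=computed,
                    mismatches=tuple(mismatches),
                )
            )
    return ReproductionReport(attempts=tuple(attempts))
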