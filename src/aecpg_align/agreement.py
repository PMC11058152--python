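"""The supply–desire agreement statistic and its summaries.

For a scenario with expected change e_i and a stakeholder with desire
d_ij and weight w_ij over the shared catalog of goods, the statistic is
a weighted, normalised L1 distance turned into a percentage:

    DEA  = Σ_i |e_i − d_ij| · w_ij      (difference between expected and
                                         desired change)
    PA   = Σ_i w_ij                     (potential agreement: the largest
                                         DEA a stakeholder could score)
    Agreement = 100 · (PA − DEA) / PA   (per cent, in [0, 100])

Since scores and supply levels both live in [0, 1], every weighted term
of DEA is at most w_i, so 0 ≤ DEA ≤ PA and the percentage is bounded.
Agreement is 100 exactly when the scenario matches the stakeholder's
desire on every good the stakeholder weighted, and is invariant to
rescaling all of a stakeholder's weights by a positive constant.

Agreement percentages are classified into five verbal classes
(strong disagreement < 20 ≤ disagreement < 40 ≤ moderate < 60 ≤
agreement ≤ 80 < high agreement).  The printed band edges overlap at
20/40/60/80; the default policy closes the agreement band at 80 so that
"high agreement" means strictly above 80, and an alternative policy
closes every band on the left.  Classification never affects the
numbers, only the labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .errors import CatalogMismatchError, UndefinedAgreementError, ValidationError
from .matrices import DesireMatrix, DesireRecord, ScenarioSupply, SupplyMatrix

__all__ = [
    "CLASS_LABELS",
    "BOUNDARY_POLICIES",
    "OVERALL_MODES",
    "AgreementResult",
    "GroupAgreementSummary",
    "dea",
    "pa",
    "agreement_score",
    "classify",
    "score_record",
    "score_matrix",
    "group_agreement",
    "optimal_scenario",
]

CLASS_LABELS: tuple[str, ...] = (
    "strong_disagreement",
    "disagreement",
    "moderate",
    "agreement",
    "high_agreement",
)

#: "agreement_closed_at_80": [0,20) [20,40) [40,60) [60,80] (80,100]
#: "high_from_80":           [0,20) [20,40) [40,60) [60,80) [80,100]
BOUNDARY_POLICIES: tuple[str, ...] = ("agreement_closed_at_80", "high_from_80")

#: How the per-scenario overall agreement aggregates stakeholders:
#: the mean over all stakeholders, or the mean of the group means.
OVERALL_MODES: tuple[str, ...] = ("stakeholder_mean", "group_mean_of_means")


def _resolve(e, d, w):
    """Accept (ScenarioSupply, DesireRecord) or raw (e, d, w) vectors."""
    if isinstance(e, ScenarioSupply) and isinstance(d, DesireRecord):
        supply, scores, weights = e.supply, d.scores, d.weights
    else:
        supply = np.asarray(e, dtype=float)
        scores = np.asarray(d, dtype=float)
        weights = np.asarray(w, dtype=float)
    if supply.shape != scores.shape or scores.shape != weights.shape:
        raise CatalogMismatchError(
            f"supply ({supply.shape}), desire ({scores.shape}) and weights "
            f"({weights.shape}) must share one catalog"
        )
    return supply, scores, weights


def dea(e, d, w=None) -> float:
    """Weighted absolute difference between expected and desired change.

    Call as ``dea(scenario, record)`` or ``dea(e, d, w)`` with vectors.
    """
    supply, scores, weights = _resolve(e, d, w)
    return float(np.sum(np.abs(supply - scores) * weights))


def pa(r) -> float:
    """Potential agreement: the stakeholder's total weight."""
    weights = r.weights if isinstance(r, DesireRecord) else np.asarray(r, dtype=float)
    return float(np.sum(weights))


def agreement_score(e, d, w=None) -> float:
    """Agreement percentage 100·(PA − DEA)/PA, in [0, 100].

    Raises :class:`UndefinedAgreementError` when PA is 0: with no weighted
    good there is nothing to agree or disagree about, and neither 0 nor
    100 would be an honest answer.
    """
    supply, scores, weights = _resolve(e, d, w)
    total = float(np.sum(weights))
    if total <= 0:
        raise UndefinedAgreementError(
            "potential agreement is zero; agreement is undefined"
        )
    diff = float(np.sum(np.abs(supply - scores) * weights))
    return 100.0 * (total - diff) / total


def classify(a: float, policy: str = "agreement_closed_at_80") -> str:
    """Verbal five-class label for an agreement percentage."""
    if not (0 <= a <= 100):
        raise ValidationError(f"agreement {a!r} outside [0, 100]")
    if policy not in BOUNDARY_POLICIES:
        raise ValidationError(f"unknown boundary policy {policy!r}")
    if a < 20:
        return "strong_disagreement"
    if a < 40:
        return "disagreement"
    if a < 60:
        return "moderate"
    if policy == "agreement_closed_at_80":
        return "agreement" if a <= 80 else "high_agreement"
    return "agreement" if a < 80 else "high_agreement"


@dataclass(frozen=True)
class AgreementResult:
    """One stakeholder's agreement with one scenario."""

    stakeholder_id: str
    group: str
    scenario_id: str
    dea: float
    pa: float
    agreement: float
    class_label: str


def score_record(
    s: ScenarioSupply,
    r: DesireRecord,
    policy: str = "agreement_closed_at_80",
) -> AgreementResult:
    """DEA, PA, agreement and class for one (scenario, stakeholder) pair."""
    d = dea(s, r)
    p = pa(r)
    a = agreement_score(s, r)
    return AgreementResult(
        stakeholder_id=r.stakeholder_id,
        group=r.group,
        scenario_id=s.scenario_id,
        dea=d,
        pa=p,
        agreement=a,
        class_label=classify(a, policy),
    )


def score_matrix(
    m: DesireMatrix,
    s: ScenarioSupply,
    policy: str = "agreement_closed_at_80",
) -> pd.DataFrame:
    """Per-stakeholder agreement with one scenario, as a tidy frame."""
    if len(m.catalog) != s.supply.size:
        raise CatalogMismatchError(
            "desire matrix and scenario do not share one catalog"
        )
    rows = [score_record(s, r, policy) for r in m.records]
    return pd.DataFrame([vars(r) for r in rows])


@dataclass(frozen=True)
class GroupAgreementSummary:
    """Per-group and overall agreement with one scenario.

    ``per_group`` is indexed by group (first-appearance order) with
    columns n, mean, min, max — mean/min/max rounded half-up to one
    decimal for reporting.  ``overall_raw`` is unrounded; ``overall`` is
    the integer percentage conventionally printed.
    """

    scenario_id: str
    per_group: pd.DataFrame
    overall_raw: float
    overall: int
    overall_mode: str


def group_agreement(
    m: DesireMatrix,
    s: ScenarioSupply,
    overall_mode: str = "stakeholder_mean",
    policy: str = "agreement_closed_at_80",
) -> GroupAgreementSummary:
    """Summarise per-stakeholder agreement by group and overall.

    Group means are rounded half-up to one decimal for the report; the
    overall value is computed from *unrounded* per-stakeholder agreements
    — either their plain mean ("stakeholder_mean", so large groups weigh
    more) or the mean of the unrounded group means
    ("group_mean_of_means", one vote per group) — and printed as an
    integer percentage.
    """
    if overall_mode not in OVERALL_MODES:
        raise ValidationError(f"unknown overall mode {overall_mode!r}")
    detail = score_matrix(m, s, policy)
    grouped = detail.groupby("group", sort=False)["agreement"]
    per_group = pd.DataFrame(
        {
            "n": grouped.size(),
            "mean": grouped.mean().map(lambda x: round_half_up(x, 1)),
            "min": grouped.min().map(lambda x: round_half_up(x, 1)),
            "max": grouped.max().map(lambda x: round_half_up(x, 1)),
        }
    )
    if overall_mode == "stakeholder_mean":
        overall_raw = float(detail["agreement"].mean())
    else:
        overall_raw = float(grouped.mean().mean())
    return GroupAgreementSummary(
        scenario_id=s.scenario_id,
        per_group=per_group,
        overall_raw=overall_raw,
        overall=int(round_half_up(overall_raw, 0)),
        overall_mode=overall_mode,
    )


def optimal_scenario(
    sm: SupplyMatrix,
    m: DesireMatrix,
    overall_mode: str = "stakeholder_mean",
) -> str:
    """Scenario id with the highest overall agreement.

    Exact ties are broken in favour of the first scenario in input order,
    with a warning.
    """
    if len(sm) == 0:
        raise ValidationError("supply matrix contains no scenarios")
    overalls = [
        group_agreement(m, s, overall_mode).overall_raw for s in sm.scenarios
    ]
    best = max(overalls)
    winners = [s.scenario_id for s, o in zip(sm.scenarios, overalls) if o == best]
    if len(winners) > 1:
        warnings.warn(
            f"scenarios {winners} tie at overall agreement {best:.6g}; "
            f"keeping {winners[0]!r} (first in input order)",
            stacklevel=2,
        )
    return winners[0]
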