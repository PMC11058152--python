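"""Three-level scoring of citizen survey percentage tables.

Organisation stakeholders publish vision documents that can be scored
directly, but citizens' desire for public goods is observed only through
mass-survey percentages (share of respondents expressing desire for, or
concern about, a good).  This module maps such a percentage table —
one row per citizen subgroup (total, gender, political orientation, age
band, living environment), one or more survey questions per good — onto
three-level desire scores:

* below ``t_mid`` per cent → 0 (no observable desire),
* between ``t_mid`` and ``t_high`` → 0.5 (desire for active conservation
  or a minor increase),
* at or above ``t_high`` → 1 (a clearly observable desire for delivery).

When a good is covered by several questions the question-level scores are
combined by an order-independent rule (default: arithmetic mean snapped
back onto {0, 0.5, 1}, ties snapping upward).  The thresholds are
configuration, not estimates: the original survey interpretation was
qualitative, and reifying it as an explicit step function is what makes
the stage reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import DEFAULT_CATALOG, AECPGCatalog
from ._util import snap_to_levels
from .errors import SchemaError, ValidationError
from .matrices import DesireRecord

__all__ = [
    "SurveyTable",
    "CitizenScoringConfig",
    "read_survey_table",
    "score_question",
    "score_citizen_subgroups",
]


@dataclass(frozen=True)
class SurveyTable:
    """Citizen subgroup × survey-question percentage table.

    ``data`` is indexed by subgroup label; columns are either a bare good
    name (one question) or ``<good>:q<k>`` (question *k* for that good).
    All values are percentages in [0, 100].
    """

    catalog: AECPGCatalog
    data: pd.DataFrame

    def __post_init__(self) -> None:
        qmap = self.question_columns()
        missing = [name for name in self.catalog if not qmap.get(name)]
        if missing:
            raise SchemaError(
                f"survey table has no question column for good(s) {missing}"
            )
        values = self.data[[c for cols in qmap.values() for c in cols]]
        arr = values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValidationError("survey table contains missing percentages")
        if (arr < 0).any() or (arr > 100).any():
            raise ValidationError("survey percentages must lie in [0, 100]")

    def question_columns(self) -> dict[str, list[str]]:
        """Map each good to its question column(s), in column order."""
        out: dict[str, list[str]] = {name: [] for name in self.catalog}
        for col in self.data.columns:
            base = str(col).split(":", 1)[0]
            if base in out:
                out[base].append(str(col))
        return out

    @property
    def subgroups(self) -> tuple[str, ...]:
        return tuple(str(i) for i in self.data.index)


def read_survey_table(
    path: str | Path, catalog: AECPGCatalog = DEFAULT_CATALOG
) -> SurveyTable:
    """Read a survey table from CSV (first column = subgroup label)."""
    try:
        df = pd.read_csv(path, index_col=0)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    return SurveyTable(catalog=catalog, data=df)


@dataclass(frozen=True)
class CitizenScoringConfig:
    """Thresholds and combination rule for percentage-to-score mapping.

    t_mid/t_high are percent cut points (0 ≤ t_mid < t_high ≤ 100);
    ``combine`` is how multiple questions per good are fused ("mean_snap"
    is the only built-in rule); ``weight`` is the uniform vision weight
    given to citizen records (organisation-style 0/1/2 weighting has no
    survey analogue).
    """

    t_mid: float = 30.0
    t_high: float = 60.0
    combine: str = "mean_snap"
    weight: int = 1
    group_label: str = "Citizens"

    def __post_init__(self) -> None:
        if not (0 <= self.t_mid < self.t_high <= 100):
            raise ValidationError(
                f"thresholds must satisfy 0 <= t_mid < t_high <= 100, "
                f"got t_mid={self.t_mid}, t_high={self.t_high}"
            )
        if self.combine != "mean_snap":
            raise ValidationError(f"unknown combine rule {self.combine!r}")
        if self.weight not in (0, 1, 2):
            raise ValidationError("citizen weight must be 0, 1 or 2")


def score_question(pct: float, cfg: CitizenScoringConfig) -> float:
    """Map one percentage to a desire level via the two-threshold step."""
    if not (0 <= pct <= 100):
        raise ValidationError(f"percentage {pct!r} outside [0, 100]")
    if pct >= cfg.t_high:
        return 1.0
    if pct >= cfg.t_mid:
        return 0.5
    return 0.0


def score_citizen_subgroups(
    table: SurveyTable, cfg: CitizenScoringConfig | None = None
) -> list[DesireRecord]:
    """Score every subgroup row into a citizen desire record.

    Per subgroup and good, each question percentage is scored with
    :func:`score_question`; multiple question scores are averaged and
    snapped to the nearest of {0, 0.5, 1} with ties upward.  Weights are
    uniform (``cfg.weight``, default 1) for every good.
    """
    cfg = cfg or CitizenScoringConfig()
    qmap = table.question_columns()
    records = []
    for subgroup in table.subgroups:
        row = table.data.loc[subgroup]
        scores = []
        for name in table.catalog:
            qscores = [score_question(float(row[c]), cfg) for c in qmap[name]]
            scores.append(snap_to_levels(float(np.mean(qscores))))
        records.append(
            DesireRecord(
                stakeholder_id=str(subgroup),
                group=cfg.group_label,
                scores=np.array(scores, dtype=object),
                weights=np.full(len(table.catalog), cfg.weight, dtype=object),
            )
        )
    return records
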