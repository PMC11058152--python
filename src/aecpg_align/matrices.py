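"""Desire and supply matrices: domain types, validation, CSV/XLSX I/O,
and group-level descriptive summaries.

The *desire matrix* holds one record per stakeholder: a desire score
d_i per public good (0 = no desire expressed, 1 = desire expressed;
citizen subgroups additionally use 0.5 for a weaker, conservation-level
desire) and a weight w_i (0 = unmentioned, 1 = mentioned or implied,
2 = central to the stakeholder's vision).  The *supply matrix* holds one
expected-change vector e_i per scenario (0 = indifferent, 0.5 = active
conservation, 1 = demonstrable enhancement).

Invariants enforced here:

* scores come from {0, 0.5, 1} and weights from {0, 1, 2}, compared
  exactly — never with a tolerance;
* a weight of 0 forces a score of 0 (an unmentioned good carries no
  expressed desire);
* every stakeholder mentions or implies at least one good (sum of
  weights > 0 — the study inclusion criterion);
* only records in a citizen group may use the 0.5 score; organisation
  visions are scored binarily.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import DEFAULT_CATALOG, AECPGCatalog
from ._util import round_half_up
from .errors import SchemaError, ValidationError

__all__ = [
    "SCORE_ALPHABET",
    "BINARY_SCORE_ALPHABET",
    "WEIGHT_ALPHABET",
    "DesireRecord",
    "DesireMatrix",
    "ScenarioSupply",
    "SupplyMatrix",
    "GroupDesireSummary",
    "read_desire_matrix",
    "write_desire_matrix",
    "read_desire_matrix_xlsx",
    "read_supply_matrix",
    "write_supply_matrix",
    "group_desire_summary",
    "cumulative_desire_counts",
]

SCORE_ALPHABET: tuple[float, ...] = (0.0, 0.5, 1.0)
BINARY_SCORE_ALPHABET: tuple[float, ...] = (0.0, 1.0)
WEIGHT_ALPHABET: tuple[int, ...] = (0, 1, 2)

#: Group labels whose records may carry three-level (0/0.5/1) scores.
DEFAULT_CITIZEN_GROUPS: tuple[str, ...] = ("Citizens",)


def _parse_score(value: object, where: str) -> float:
    try:
        x = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{where}: score {value!r} is not numeric") from None
    if x not in SCORE_ALPHABET:
        raise ValidationError(
            f"{where}: score {value!r} not in allowed alphabet {{0, 0.5, 1}}"
        )
    return x


def _parse_weight(value: object, where: str) -> int:
    try:
        x = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{where}: weight {value!r} is not numeric") from None
    if not x.is_integer() or int(x) not in WEIGHT_ALPHABET:
        raise ValidationError(
            f"{where}: weight {value!r} not in allowed alphabet {{0, 1, 2}}"
        )
    return int(x)


@dataclass(frozen=True)
class DesireRecord:
    """One stakeholder's desire scores and weights over the catalog."""

    stakeholder_id: str
    group: str
    scores: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(
            [_parse_score(s, f"stakeholder {self.stakeholder_id!r}") for s in np.atleast_1d(self.scores)],
            dtype=float,
        )
        weights = np.asarray(
            [_parse_weight(w, f"stakeholder {self.stakeholder_id!r}") for w in np.atleast_1d(self.weights)],
            dtype=int,
        )
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "weights", weights)
        who = f"stakeholder {self.stakeholder_id!r}"
        if scores.shape != weights.shape:
            raise ValidationError(f"{who}: scores and weights differ in length")
        if np.any((weights == 0) & (scores > 0)):
            raise ValidationError(
                f"{who}: weight 0 with positive desire score — an unmentioned "
                "public good cannot carry expressed desire"
            )
        if weights.sum() <= 0:
            raise ValidationError(
                f"{who}: all weights are zero; every included vision must "
                "mention or imply at least one public good"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DesireRecord):
            return NotImplemented
        return (
            self.stakeholder_id == other.stakeholder_id
            and self.group == other.group
            and np.array_equal(self.scores, other.scores)
            and np.array_equal(self.weights, other.weights)
        )

    __hash__ = None  # type: ignore[assignment]

    @property
    def is_binary(self) -> bool:
        """True if no score uses the intermediate 0.5 level."""
        return bool(np.all(np.isin(self.scores, BINARY_SCORE_ALPHABET)))


@dataclass(frozen=True)
class DesireMatrix:
    """All stakeholder desire records over one shared catalog."""

    catalog: AECPGCatalog
    records: tuple[DesireRecord, ...]
    citizen_groups: tuple[str, ...] = DEFAULT_CITIZEN_GROUPS

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        object.__setattr__(self, "citizen_groups", tuple(self.citizen_groups))
        ids = [r.stakeholder_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate stakeholder ids: {dupes}")
        n = len(self.catalog)
        for r in self.records:
            if r.scores.size != n:
                raise ValidationError(
                    f"stakeholder {r.stakeholder_id!r}: vector length "
                    f"{r.scores.size} does not match catalog size {n}"
                )
            if r.group not in self.citizen_groups and not r.is_binary:
                raise ValidationError(
                    f"stakeholder {r.stakeholder_id!r} (group {r.group!r}): "
                    "the 0.5 desire level is reserved for citizen subgroups"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DesireMatrix):
            return NotImplemented
        return (
            self.catalog == other.catalog
            and self.records == other.records
            and self.citizen_groups == other.citizen_groups
        )

    __hash__ = None  # type: ignore[assignment]

    @property
    def groups(self) -> tuple[str, ...]:
        """Group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.group, None)
        return tuple(seen)

    def by_group(self) -> dict[str, list[DesireRecord]]:
        out: dict[str, list[DesireRecord]] = {}
        for r in self.records:
            out.setdefault(r.group, []).append(r)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tabular form with `<good>_score` / `<good>_weight` columns."""
        rows = []
        for r in self.records:
            row: dict[str, object] = {
                "stakeholder_id": r.stakeholder_id,
                "group": r.group,
            }
            for i, name in enumerate(self.catalog):
                row[f"{name}_score"] = r.scores[i]
                row[f"{name}_weight"] = int(r.weights[i])
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScenarioSupply:
    """Expected change of every public good under one scenario."""

    scenario_id: str
    supply: np.ndarray

    def __post_init__(self) -> None:
        supply = np.asarray(
            [_parse_score(s, f"scenario {self.scenario_id!r}") for s in np.atleast_1d(self.supply)],
            dtype=float,
        )
        object.__setattr__(self, "supply", supply)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScenarioSupply):
            return NotImplemented
        return self.scenario_id == other.scenario_id and np.array_equal(
            self.supply, other.supply
        )

    __hash__ = None  # type: ignore[assignment]


@dataclass(frozen=True)
class SupplyMatrix:
    """Expected-change vectors of all scenarios over one shared catalog."""

    catalog: AECPGCatalog
    scenarios: tuple[ScenarioSupply, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenarios", tuple(self.scenarios))
        ids = [s.scenario_id for s in self.scenarios]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate scenario ids")
        n = len(self.catalog)
        for s in self.scenarios:
            if s.supply.size != n:
                raise ValidationError(
                    f"scenario {s.scenario_id!r}: vector length {s.supply.size} "
                    f"does not match catalog size {n}"
                )

    def __len__(self) -> int:
        return len(self.scenarios)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SupplyMatrix):
            return NotImplemented
        return self.catalog == other.catalog and self.scenarios == other.scenarios

    __hash__ = None  # type: ignore[assignment]

    def __getitem__(self, scenario_id: str) -> ScenarioSupply:
        for s in self.scenarios:
            if s.scenario_id == scenario_id:
                return s
        raise KeyError(scenario_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.scenarios:
            row: dict[str, object] = {"scenario_id": s.scenario_id}
            row.update({name: s.supply[i] for i, name in enumerate(self.catalog)})
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def read_desire_matrix(
    path: str | Path,
    catalog: AECPGCatalog = DEFAULT_CATALOG,
    citizen_groups: Sequence[str] = DEFAULT_CITIZEN_GROUPS,
) -> DesireMatrix:
    """Read a desire matrix from CSV.

    Expected columns: ``stakeholder_id``, ``group``, then for every catalog
    entry ``<name>_score`` and ``<name>_weight``.  All alphabet and
    consistency invariants are enforced; violations raise
    :class:`~aecpg_align.errors.ValidationError` naming the offending row.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    return desire_matrix_from_frame(df, catalog, citizen_groups)


def desire_matrix_from_frame(
    df: pd.DataFrame,
    catalog: AECPGCatalog = DEFAULT_CATALOG,
    citizen_groups: Sequence[str] = DEFAULT_CITIZEN_GROUPS,
) -> DesireMatrix:
    """Validate a tabular desire matrix already loaded into a DataFrame."""
    score_cols = [f"{name}_score" for name in catalog]
    weight_cols = [f"{name}_weight" for name in catalog]
    _require_columns(df, ["stakeholder_id", "group", *score_cols, *weight_cols],
                     "desire matrix")
    records = []
    for _, row in df.iterrows():
        records.append(
            DesireRecord(
                stakeholder_id=str(row["stakeholder_id"]),
                group=str(row["group"]),
                scores=np.array([row[c] for c in score_cols], dtype=object),
                weights=np.array([row[c] for c in weight_cols], dtype=object),
            )
        )
    return DesireMatrix(catalog=catalog, records=tuple(records),
                        citizen_groups=tuple(citizen_groups))


def write_desire_matrix(m: DesireMatrix, path: str | Path) -> None:
    """Write a desire matrix as CSV (round-trips exactly)."""
    df = m.to_frame()
    # scores print as 0, 0.5, 1 — never 0.0/1.0 — so files stay diffable
    for name in m.catalog:
        df[f"{name}_score"] = df[f"{name}_score"].map(
            lambda x: f"{x:g}"
        )
    df.to_csv(path, index=False)


# Header aliases seen in hand-prepared spreadsheets of this kind; keys are
# lower-cased with punctuation collapsed to single underscores.
_XLSX_HEADER_ALIASES: Mapping[str, str] = {
    "id": "stakeholder_id",
    "stakeholder": "stakeholder_id",
    "stakeholder_name": "stakeholder_id",
    "name": "stakeholder_id",
    "stakeholder_group": "group",
    "group": "group",
    "aesthetic_landscape_quality": "aesthetic_landscape_quality",
    "landscape_quality": "aesthetic_landscape_quality",
    "natural_heritage": "heritage",
    "quality_of_products": "product_quality",
    "product_quality": "product_quality",
    "climate": "climate_regulation",
    "climate_regulation": "climate_regulation",
}


def _normalise_header(name: str) -> str:
    out = "".join(ch if ch.isalnum() else "_" for ch in str(name).strip().lower())
    while "__" in out:
        out = out.replace("__", "_")
    return out.strip("_")


def read_desire_matrix_xlsx(
    path: str | Path,
    catalog: AECPGCatalog = DEFAULT_CATALOG,
    citizen_groups: Sequence[str] = DEFAULT_CITIZEN_GROUPS,
    sheet: int | str = 0,
    column_map: Mapping[str, str] | None = None,
) -> DesireMatrix:
    """Best-effort XLSX import of an externally prepared desire matrix.

    Headers are normalised (lower-cased, punctuation collapsed) and mapped
    through a table of common aliases onto the canonical
    ``<good>_score`` / ``<good>_weight`` schema; ``column_map`` overrides
    the mapping for layouts the heuristics miss (keys are original headers,
    values canonical column names).  The resulting frame is validated
    exactly like a CSV import.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    rename: dict[str, str] = {}
    for col in df.columns:
        if column_map and col in column_map:
            rename[col] = column_map[col]
            continue
        norm = _normalise_header(col)
        base, suffix = norm, ""
        for suf in ("_score", "_weight"):
            if norm.endswith(suf):
                base, suffix = norm[: -len(suf)], suf
                break
        base = _XLSX_HEADER_ALIASES.get(base, base)
        rename[col] = base + suffix
    df = df.rename(columns=rename)
    return desire_matrix_from_frame(df, catalog, citizen_groups)


def read_supply_matrix(
    path: str | Path, catalog: AECPGCatalog = DEFAULT_CATALOG
) -> SupplyMatrix:
    """Read a supply (expected-change) matrix from CSV.

    Expected columns: ``scenario_id`` plus one column per catalog entry.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    _require_columns(df, ["scenario_id", *catalog.names], "supply matrix")
    if len(df) == 0:
        raise SchemaError(f"{path}: supply matrix contains no scenarios")
    scenarios = tuple(
        ScenarioSupply(
            scenario_id=str(row["scenario_id"]),
            supply=np.array([row[name] for name in catalog], dtype=object),
        )
        for _, row in df.iterrows()
    )
    return SupplyMatrix(catalog=catalog, scenarios=scenarios)


def write_supply_matrix(sm: SupplyMatrix, path: str | Path) -> None:
    df = sm.to_frame()
    for name in sm.catalog:
        df[name] = df[name].map(lambda x: f"{x:g}")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Descriptive summaries


@dataclass(frozen=True)
class GroupDesireSummary:
    """Per-(group, good) count, mean desire and standard error of the mean.

    ``data`` is tidy and unrounded; :meth:`table` renders the conventional
    wide report with "mean (se)" cells rounded to two decimals.
    """

    data: pd.DataFrame  # columns: group, aecpg, n, mean, se

    def table(self, ndigits: int = 2) -> pd.DataFrame:
        def cell(row: pd.Series) -> str:
            return (
                f"{round_half_up(row['mean'], ndigits):g} "
                f"({round_half_up(row['se'], ndigits):g})"
            )

        d = self.data.copy()
        d["cell"] = d.apply(cell, axis=1)
        wide = d.pivot(index="group", columns="aecpg", values="cell")
        order = list(dict.fromkeys(self.data["aecpg"]))
        n = self.data.drop_duplicates("group").set_index("group")["n"]
        wide = wide.loc[list(dict.fromkeys(self.data["group"])), order]
        wide.insert(0, "n", n)
        return wide


def group_desire_summary(m: DesireMatrix) -> GroupDesireSummary:
    """Mean desire and its standard error per stakeholder group and good.

    Weights are ignored: this summarises expressed desire only.  The SE is
    the sample standard deviation (n−1 denominator) over sqrt(n); groups of
    size one report SE 0.  Within-group SE is the homogeneity indicator:
    small SE means the group's visions agree on that good.
    """
    if len(m) == 0:
        raise ValidationError("cannot summarise an empty desire matrix")
    rows = []
    for group, records in m.by_group().items():
        scores = np.array([r.scores for r in records], dtype=float)
        n = scores.shape[0]
        means = scores.mean(axis=0)
        if n > 1:
            ses = scores.std(axis=0, ddof=1) / math.sqrt(n)
        else:
            ses = np.zeros(scores.shape[1])
        for i, name in enumerate(m.catalog):
            rows.append(
                {"group": group, "aecpg": name, "n": n,
                 "mean": means[i], "se": ses[i]}
            )
    return GroupDesireSummary(pd.DataFrame(rows))


def cumulative_desire_counts(m: DesireMatrix) -> pd.Series:
    """Number of stakeholders expressing any desire (d > 0) per good.

    The 0.5 citizen level counts as expressed desire.
    """
    if len(m) == 0:
        return pd.Series(0, index=list(m.catalog), dtype=int)
    scores = np.array([r.scores for r in m.records], dtype=float)
    counts = (scores > 0).sum(axis=0)
    return pd.Series(counts.astype(int), index=list(m.catalog), name="n_desiring")
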