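"""Meta-scenario synthesis from per-source scenario codings.

National scenario studies are first coded one by one on the shared
catalog (0 = indifferent, 0.5 = active conservation, 1 = demonstrable
enhancement of a good's supply).  Studies sharing a theme — productivity
/ sustainable intensification, integral nature-inclusive transition,
meadow-bird conservation, region-differentiated zoning — are then fused
into one meta-scenario supply vector by averaging per good and snapping
the average back onto {0, 0.5, 1}; exact midpoints snap upward by
default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import DEFAULT_CATALOG, AECPGCatalog
from ._util import snap_to_levels
from .errors import SchemaError, ValidationError
from .matrices import ScenarioSupply, _parse_score

__all__ = ["CANONICAL_THEMES", "SourceCoding", "read_source_codings", "synthesize_meta"]

#: Themes of the four meta-scenarios in the national assessment.  Library
#: use accepts arbitrary theme labels.
CANONICAL_THEMES: tuple[str, ...] = (
    "productivity",
    "integral",
    "meadow_bird",
    "regional",
)


@dataclass(frozen=True)
class SourceCoding:
    """One source study's coded supply vector under a scenario theme."""

    source_id: str
    theme: str
    supply: np.ndarray

    def __post_init__(self) -> None:
        supply = np.asarray(
            [_parse_score(s, f"source {self.source_id!r}") for s in np.atleast_1d(self.supply)],
            dtype=float,
        )
        object.__setattr__(self, "supply", supply)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SourceCoding):
            return NotImplemented
        return (
            self.source_id == other.source_id
            and self.theme == other.theme
            and np.array_equal(self.supply, other.supply)
        )

    __hash__ = None  # type: ignore[assignment]


def read_source_codings(
    path: str | Path, catalog: AECPGCatalog = DEFAULT_CATALOG
) -> list[SourceCoding]:
    """Read source codings from CSV (columns: source_id, theme, one per good)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    missing = [c for c in ("source_id", "theme", *catalog.names) if c not in df.columns]
    if missing:
        raise SchemaError(f"source codings: missing required column(s) {missing}")
    return [
        SourceCoding(
            source_id=str(row["source_id"]),
            theme=str(row["theme"]),
            supply=np.array([row[name] for name in catalog], dtype=object),
        )
        for _, row in df.iterrows()
    ]


def synthesize_meta(
    codings: Sequence[SourceCoding], tie: str = "up"
) -> ScenarioSupply:
    """Average same-theme codings per good and snap to {0, 0.5, 1}.

    The scenario id of the result is the shared theme.  Snapping ties
    (averages of exactly 0.25 or 0.75) go upward unless ``tie='down'``.
    Synthesizing a single coding returns it unchanged (idempotence), and
    the result does not depend on the order of the codings.
    """
    if len(codings) == 0:
        raise ValidationError("cannot synthesize a meta-scenario from no codings")
    themes = {c.theme for c in codings}
    if len(themes) != 1:
        raise ValidationError(
            f"codings mix themes {sorted(themes)}; synthesize one theme at a time"
        )
    sizes = {c.supply.size for c in codings}
    if len(sizes) != 1:
        raise ValidationError("codings differ in catalog size")
    means = np.mean([c.supply for c in codings], axis=0)
    snapped = [snap_to_levels(float(x), tie=tie) for x in means]
    return ScenarioSupply(
        scenario_id=codings[0].theme, supply=np.array(snapped, dtype=object)
    )
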