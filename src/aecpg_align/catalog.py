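"""The ordered catalog of agri-environmental-climate public goods (AECPGs).

AECPGs are the non-commodity, non-exclusive, non-rival benefits of
agriculture — biodiversity, clean water, an attractive landscape, and so
on.  Every desire and supply matrix in this package is expressed over one
shared, ordered catalog so that vectors are positionally comparable.  The
standard national assessment uses the nine goods in
:data:`CANONICAL_AECPGS`; smaller or different catalogs are accepted for
library use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

__all__ = ["CANONICAL_AECPGS", "AECPGCatalog", "DEFAULT_CATALOG"]

#: Canonical order of the nine assessed public goods.  Index i of every
#: score/weight/supply vector refers to this order.
CANONICAL_AECPGS: tuple[str, ...] = (
    "biodiversity",
    "aesthetic_landscape_quality",
    "heritage",
    "water_quality",
    "air_quality",
    "soil_quality",
    "product_quality",
    "recreation",
    "climate_regulation",
)


@dataclass(frozen=True)
class AECPGCatalog:
    """An ordered, duplicate-free set of public-good identifiers.

    The order is fixed and shared by every matrix built on the catalog;
    all positional vectors (desire scores, weights, expected change) are
    interpreted against it.
    """

    names: tuple[str, ...] = CANONICAL_AECPGS

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(names) == 0:
            raise ValueError("catalog must contain at least one public good")
        if len(set(names)) != len(names):
            raise ValueError("catalog names must be unique")
        if any(not isinstance(n, str) or not n for n in names):
            raise ValueError("catalog names must be non-empty strings")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)

    def __contains__(self, name: object) -> bool:
        return name in self.names

    def index(self, name: str) -> int:
        """Position of *name* in the catalog order."""
        return self.names.index(name)


#: The nine-good catalog used by the national assessment.
DEFAULT_CATALOG = AECPGCatalog()
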