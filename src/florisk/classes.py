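"""Ordinal class ontologies for the two censuses and the decline scores.

Population sizes were recorded on an ordinal scale whose vocabulary differs
between the two censuses: the first census used {1-9, 10-99, 100-999, >=1000}
and the second {extinct, 1-9, 10-49, 50-99, 100-999, 1000-9999, >=10000}.
Decline scores record the fraction of individuals surviving a decade, on the
scale {<1/100, 1/100-1/10, 1/10-1/2, 1/2-1, >1}.

Open-ended size classes carry a point value (1000 and 10 000) instead of an
interval; the open rate classes take a configurable floor/ceiling, defaulting
to 1/10 000 (the forced-extinction rate) and 2 (reciprocal symmetry with the
1/2-1 class).

Labels are matched after Unicode normalization so that en-dash ("100–999") and
"≥1000" dialects parse to the same canonical ASCII form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "FIRST_CENSUS_LABELS",
    "SECOND_CENSUS_LABELS",
    "RATE_CLASS_LABELS",
    "EXTINCT_LABEL",
    "RATE_FLOOR_DEFAULT",
    "RATE_CEILING_DEFAULT",
    "SizeClass",
    "RateClass",
    "class_bounds",
    "normalize_label",
]

EXTINCT_LABEL = "extinct"

#: canonical (ASCII) vocabularies, in increasing order of abundance
FIRST_CENSUS_LABELS = ("1-9", "10-99", "100-999", ">=1000")
SECOND_CENSUS_LABELS = (
    EXTINCT_LABEL,
    "1-9",
    "10-49",
    "50-99",
    "100-999",
    "1000-9999",
    ">=10000",
)
RATE_CLASS_LABELS = ("<1/100", "1/100-1/10", "1/10-1/2", "1/2-1", ">1")

RATE_FLOOR_DEFAULT = 1.0 / 10_000
RATE_CEILING_DEFAULT = 2.0

# interval bounds; open-ended classes are represented by their point value
_FIRST_BOUNDS = {
    "1-9": (1.0, 9.0),
    "10-99": (10.0, 99.0),
    "100-999": (100.0, 999.0),
    ">=1000": (1000.0, 1000.0),
}
_SECOND_BOUNDS = {
    "1-9": (1.0, 9.0),
    "10-49": (10.0, 49.0),
    "50-99": (50.0, 99.0),
    "100-999": (100.0, 999.0),
    "1000-9999": (1000.0, 9999.0),
    ">=10000": (10_000.0, 10_000.0),
}
_OPEN_POINT = {">=1000": 1000.0, ">=10000": 10_000.0}

_DASHES = {"–": "-", "—": "-", "−": "-"}


def normalize_label(label: str) -> str:
    """Map a class label to canonical ASCII form (en-dash -> '-', '≥' -> '>=')."""
    s = label.strip()
    for bad, good in _DASHES.items():
        s = s.replace(bad, good)
    s = s.replace("≥", ">=")
    # tolerate spaces inside numerals, e.g. ">= 10 000"
    s = s.replace(" ", "").replace(" ", "")
    return s


@dataclass(frozen=True)
class SizeClass:
    """One ordinal population-size category from either census.

    ``lower``/``upper`` bound the number of reproductive individuals; for the
    open-ended classes both equal ``point_value``.  The special second-census
    label ``extinct`` has no bounds.
    """

    label: str
    census_epoch: str  # "first" | "second"
    lower: float | None
    upper: float | None
    point_value: float | None = None

    @classmethod
    def parse(cls, label: str, census_epoch: str) -> "SizeClass":
        s = normalize_label(label)
        if census_epoch == "first":
            vocab = _FIRST_BOUNDS
        elif census_epoch == "second":
            if s == EXTINCT_LABEL:
                return cls(EXTINCT_LABEL, "second", None, None, None)
            vocab = _SECOND_BOUNDS
        else:
            raise ValueError(f"unknown census epoch {census_epoch!r}")
        if s not in vocab:
            raise ValueError(
                f"unknown {census_epoch}-census size class {label!r}"
            )
        lo, hi = vocab[s]
        return cls(s, census_epoch, lo, hi, _OPEN_POINT.get(s))

    @property
    def is_extinct(self) -> bool:
        return self.label == EXTINCT_LABEL

    @property
    def is_open(self) -> bool:
        return self.point_value is not None

    def bounds(self) -> tuple[float, float]:
        """(lower, upper); open-ended classes collapse to their point value."""
        if self.is_extinct:
            raise ValueError("the 'extinct' class has no numeric bounds")
        if self.point_value is not None:
            return (self.point_value, self.point_value)
        return (self.lower, self.upper)  # type: ignore[return-value]

    def geometric_midpoint(self) -> float:
        lo, hi = self.bounds()
        return math.sqrt(lo * hi)


@dataclass(frozen=True)
class RateClass:
    """One ordinal decadal-survival (decline score) category."""

    label: str
    lower: float
    upper: float

    @classmethod
    def parse(
        cls,
        label: str,
        floor: float = RATE_FLOOR_DEFAULT,
        ceiling: float = RATE_CEILING_DEFAULT,
    ) -> "RateClass":
        s = normalize_label(label)
        table = {
            "<1/100": (floor, 0.01),
            "1/100-1/10": (0.01, 0.1),
            "1/10-1/2": (0.1, 0.5),
            "1/2-1": (0.5, 1.0),
            ">1": (1.0, ceiling),
        }
        if s not in table:
            raise ValueError(f"unknown rate class {label!r}")
        lo, hi = table[s]
        return cls(s, lo, hi)

    @property
    def is_decline(self) -> bool:
        """True for categories lying (strictly) below 1; '>1' is an increase."""
        return self.label != ">1"

    def bounds(self) -> tuple[float, float]:
        return (self.lower, self.upper)


def class_bounds(obj: SizeClass | RateClass) -> tuple[float, float]:
    """Numeric bounds of a size or rate class (point classes collapse)."""
    return obj.bounds()
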