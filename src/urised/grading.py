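"""Semi-quantitative grading of urine sediment particle concentrations.

Automated urine sediment analyzers count formed elements (cells, casts,
crystals, microorganisms) in particles/µL and report each element on an
ordinal scale: negative (``Neg``), then ``+1`` up to ``+4``.  Rare or
all-or-nothing elements (WBC clumps, pathological casts, sperm) use a single
positive level, and bacteria use three.  The mapping from a concentration to
a category is defined by the manufacturer's fixed cutoffs, one lower bound
per positive category.

Boundary convention
-------------------
The instrument documentation prints gapped decimal ranges (e.g. RBC ``+1``
as 1.1–9.1 and ``+2`` as 9.2–34.1).  This module treats every category as a
half-open interval ``[lower_k, lower_{k+1})`` built from each category's
printed lower bound, which tiles the whole non-negative line at any input
resolution.  Where a negative upper bound and the ``+1`` lower bound
disagree by more than the printed resolution (bacteria: ``Neg < 15`` but
``+1`` starting at 16), the negative bound wins, so ``+1`` starts at 15.
Open-topped categories printed as ``> x`` start at the next representable
value at the printed resolution (RBC ``+4 > 45.5`` becomes ``[45.6, ∞)``).
Whether the instruments use inclusive or exclusive comparisons exactly at a
printed cutoff is not documented; the half-open convention is this package's
documented choice.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError, InputError

#: Ordinal category labels; the integer category value indexes this tuple.
CATEGORY_LABELS: tuple[str, ...] = ("Neg", "+1", "+2", "+3", "+4")

#: The negative category.
NEG: int = 0


def category_label(value: int) -> str:
    """Return the report literal (``Neg``, ``+1`` ...) for a category value."""
    if not 0 <= value < len(CATEGORY_LABELS):
        raise InputError(f"category value {value!r} outside 0..{len(CATEGORY_LABELS) - 1}")
    return CATEGORY_LABELS[value]


def parse_category(text: str) -> int:
    """Parse a report literal into its ordinal value.

    Literals are case-sensitive; the allowed set is ``Neg, +1, +2, +3, +4``.
    """
    try:
        return CATEGORY_LABELS.index(text)
    except ValueError:
        raise InputError(
            f"unknown category literal {text!r}; allowed: {', '.join(CATEGORY_LABELS)}"
        ) from None


@dataclass(frozen=True)
class GradingScheme:
    """Cutoffs mapping a particle concentration to an ordinal category.

    Parameters
    ----------
    parameter
        Sediment parameter identifier, e.g. ``"RBC"``.
    cutoffs
        Strictly increasing lower bounds (particles/µL) of categories
        ``+1 .. +max``; ``len(cutoffs)`` equals the highest category.
    """

    parameter: str
    cutoffs: tuple[float, ...]

    def __post_init__(self) -> None:
        cutoffs = tuple(float(c) for c in self.cutoffs)
        object.__setattr__(self, "cutoffs", cutoffs)
        if not cutoffs:
            raise ConfigError(f"{self.parameter}: at least one cutoff required")
        if any(not math.isfinite(c) or c <= 0 for c in cutoffs):
            raise ConfigError(f"{self.parameter}: cutoffs must be finite and > 0")
        if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
            raise ConfigError(f"{self.parameter}: cutoffs must be strictly increasing")
        if len(cutoffs) > len(CATEGORY_LABELS) - 1:
            raise ConfigError(f"{self.parameter}: at most {len(CATEGORY_LABELS) - 1} cutoffs")

    @property
    def max_category(self) -> int:
        """Highest reportable category (1, 3 or 4 in practice)."""
        return len(self.cutoffs)

    @property
    def n_categories(self) -> int:
        """Number of reportable levels including ``Neg``."""
        return len(self.cutoffs) + 1

    def grade(self, concentration: float) -> int:
        """Grade a concentration (particles/µL) into an ordinal category.

        Returns ``0`` (Neg) below the first cutoff, ``k`` for concentrations
        in ``[cutoffs[k-1], cutoffs[k])`` and ``max_category`` at or above
        the last cutoff.  Monotone non-decreasing in the concentration.
        """
        try:
            x = float(concentration)
        except (TypeError, ValueError):
            raise InputError(f"concentration {concentration!r} is not a number") from None
        if not math.isfinite(x) or x < 0:
            raise InputError(f"concentration must be finite and >= 0, got {concentration!r}")
        return bisect_right(self.cutoffs, x)


def grade(concentration: float, scheme: GradingScheme) -> int:
    """Functional form of :meth:`GradingScheme.grade`."""
    return scheme.grade(concentration)


# Lower bounds of +1..+max per parameter (particles/µL), under the half-open
# convention described in the module docstring.  Open-topped categories start
# one printed-resolution step above the printed "> x" bound.
MANUFACTURER_CUTOFFS: Mapping[str, tuple[float, ...]] = {
    "RBC": (1.1, 9.2, 34.2, 45.6),
    "WBC": (2.1, 11.5, 45.6, 91.0),
    "WBC_clumps": (2.1,),
    "EPI": (1.1, 5.8, 17.2, 27.4),
    "NEC": (0.1, 1.0, 1.5, 1.9),
    "hyaline_casts": (0.1, 1.0, 1.5, 1.9),
    "pathological_casts": (0.1,),
    "bacteria": (15.0, 31.0, 101.0),
    "total_crystals": (1.4, 4.2, 13.7, 30.1),
    "CaOx": (1.4, 4.2, 13.7, 30.1),
    "mucus": (30.0, 61.0, 151.0, 301.0),
    "yeasts": (0.7, 2.1, 5.1, 10.1),
    "sperm": (2.7,),
}

#: The 13 sediment parameters, in reporting order.
PARAMETERS: tuple[str, ...] = tuple(MANUFACTURER_CUTOFFS)


def default_schemes() -> dict[str, GradingScheme]:
    """Grading schemes with the manufacturer's default cutoffs."""
    return {p: GradingScheme(p, c) for p, c in MANUFACTURER_CUTOFFS.items()}


@dataclass(frozen=True)
class MergeMap:
    """Ordered partition of a parameter's categories into merged levels.

    Agreement analysis merges sparse upper categories (e.g. NEC ``+2`` to
    ``+4``) so that every level retains enough events.  Groups must cover
    every category exactly once and preserve order (no interleaving), which
    makes the merge an order-preserving surjection.
    """

    parameter: str
    groups: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        groups = tuple(tuple(int(c) for c in g) for g in self.groups)
        object.__setattr__(self, "groups", groups)
        flat = [c for g in groups for c in g]
        if not groups or any(not g for g in groups):
            raise ConfigError(f"{self.parameter}: empty merge group")
        if flat != list(range(len(flat))):
            raise ConfigError(
                f"{self.parameter}: merge groups must be contiguous, ordered and "
                f"cover categories 0..{len(flat) - 1} exactly once; got {groups}"
            )

    @classmethod
    def identity(cls, parameter: str, n_categories: int) -> "MergeMap":
        return cls(parameter, tuple((c,) for c in range(n_categories)))

    @property
    def n_levels(self) -> int:
        return len(self.groups)

    @property
    def n_categories(self) -> int:
        return sum(len(g) for g in self.groups)

    def apply(self, category: int) -> int:
        """Merged level of a raw category."""
        for level, group in enumerate(self.groups):
            if category in group:
                return level
        raise InputError(
            f"{self.parameter}: category {category} not covered by merge map"
        )

    def level_labels(self) -> tuple[str, ...]:
        """Human-readable labels, e.g. ``('Neg', '+1', '+2 to +4')``."""
        labels = []
        for group in self.groups:
            if len(group) == 1:
                labels.append(category_label(group[0]))
            else:
                labels.append(
                    f"{category_label(group[0])} to {category_label(group[-1])}"
                )
        return tuple(labels)


def merge_categories(cats: Iterable[int], merge_map: MergeMap) -> list[int]:
    """Map a sequence of raw categories onto merged ordinal levels."""
    lookup = {c: level for level, g in enumerate(merge_map.groups) for c in g}
    out = []
    for c in cats:
        if c not in lookup:
            raise InputError(
                f"{merge_map.parameter}: category {c} not covered by merge map"
            )
        out.append(lookup[c])
    return out


# Merged level structure used for agreement analysis: sparse upper categories
# collapsed so every level keeps a workable number of events.  Parameters not
# listed use the identity map.
DEFAULT_MERGE_GROUPS: Mapping[str, tuple[tuple[int, ...], ...]] = {
    "NEC": ((0,), (1,), (2, 3, 4)),
    "hyaline_casts": ((0,), (1,), (2, 3, 4)),
    "total_crystals": ((0,), (1,), (2, 3, 4)),
    "CaOx": ((0,), (1, 2, 3, 4)),
    "mucus": ((0,), (1,), (2,), (3, 4)),
    "yeasts": ((0,), (1, 2, 3, 4)),
}


def default_merge_maps(
    schemes: Mapping[str, GradingScheme] | None = None,
) -> dict[str, MergeMap]:
    """Default merge maps (identity where no merging is needed)."""
    schemes = schemes if schemes is not None else default_schemes()
    maps = {}
    for param, scheme in schemes.items():
        if param in DEFAULT_MERGE_GROUPS:
            maps[param] = MergeMap(param, DEFAULT_MERGE_GROUPS[param])
        else:
            maps[param] = MergeMap.identity(param, scheme.n_categories)
    return maps
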