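"""Disjoint-region partitioning of 2-6 named sets.

Each element of the union of the input sets belongs to exactly one
*region*, identified by its n-bit membership signature (bit i-1 set iff
the element is in set i, set 1 being the first input column).  A 6-set
comparison therefore produces the full complement of 2**6 - 1 = 63
intersection categories.  Regions are additionally classified against a
*reference* set (the non-stimulated condition of a dose-response series)
into five categories:

BLUE   unique to the reference set
RED    unique to exactly one non-reference (dose) set
GREY   shared by several dose sets, absent from the reference
BLACK  present in the reference and in some but not all dose sets
GREEN  present in every set

These codes partition the signature space for any reference choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Sequence, Tuple

logger = logging.getLogger(__name__)

MIN_SETS = 2
MAX_SETS = 6


class Category(str, Enum):
    """Five-color classification of a region relative to a reference set."""

    BLUE = "BLUE"
    RED = "RED"
    GREY = "GREY"
    BLACK = "BLACK"
    GREEN = "GREEN"


class UnsupportedSetCountError(ValueError):
    """Raised when a collection has fewer than 2 or more than 6 sets."""


@dataclass(frozen=True)
class CanonicalizationOptions:
    """How raw cell strings are turned into canonical labels.

    Comparison is case-sensitive by default: official gene/protein
    symbols are case-meaningful (e.g. human GIT1 vs murine Git1).
    """

    case_sensitive: bool = True
    strip: bool = True

    def canonical(self, text: str) -> str:
        if self.strip:
            text = text.strip()
        if not self.case_sensitive:
            text = text.casefold()
        return text


def canonicalize_entries(
    raw_cells: Iterable[str],
    options: CanonicalizationOptions | None = None,
) -> set:
    """Canonicalize a column of raw cells into a set of labels.

    Empty and whitespace-only cells are dropped; duplicates collapse
    (with a logged count); the empty set is a legal result.
    """
    options = options or CanonicalizationOptions()
    out: set = set()
    n_kept = 0
    for cell in raw_cells:
        if cell is None:
            continue
        text = options.canonical(str(cell))
        if not text.strip():
            continue
        n_kept += 1
        out.add(text)
    dups = n_kept - len(out)
    if dups:
        logger.warning("collapsed %d duplicate entr%s", dups, "y" if dups == 1 else "ies")
    return out


@dataclass(frozen=True)
class InputCollection:
    """An ordered list of 2-6 named, canonicalized label sets."""

    names: Tuple[str, ...]
    sets: Tuple[frozenset, ...]

    def __post_init__(self) -> None:
        n = len(self.sets)
        if len(self.names) != n:
            raise ValueError("names and sets must align")
        if not MIN_SETS <= n <= MAX_SETS:
            raise UnsupportedSetCountError(
                f"need between {MIN_SETS} and {MAX_SETS} sets, got {n}"
            )
        if len(set(self.names)) != n:
            raise ValueError(f"set names must be unique, got {self.names}")

    @property
    def n(self) -> int:
        return len(self.sets)

    def union(self) -> frozenset:
        return frozenset().union(*self.sets)

    @classmethod
    def from_lists(
        cls,
        columns: Sequence[Tuple[str, Sequence[str]]],
        options: CanonicalizationOptions | None = None,
    ) -> "InputCollection":
        """Build a collection from (name, raw cells) pairs."""
        names = tuple(name for name, _ in columns)
        sets = tuple(
            frozenset(canonicalize_entries(cells, options)) for _, cells in columns
        )
        return cls(names=names, sets=sets)


def signature_index(mask: int, n: int) -> int:
    """Region number of a signature: the mask value itself, set 1 = LSB.

    A deterministic bijection from the 2**n - 1 non-empty signatures
    onto 1..2**n-1, used consistently in all exports.
    """
    if not MIN_SETS <= n <= MAX_SETS:
        raise UnsupportedSetCountError(f"n={n} outside {MIN_SETS}..{MAX_SETS}")
    if not 1 <= mask < (1 << n):
        raise ValueError(f"mask {mask} invalid for n={n}")
    return mask


def signature_sets(mask: int, n: int) -> Tuple[int, ...]:
    """1-based set indices contained in a signature, ascending."""
    signature_index(mask, n)
    return tuple(i + 1 for i in range(n) if mask >> i & 1)


def signature_names(mask: int, collection: InputCollection) -> Tuple[str, ...]:
    return tuple(collection.names[i - 1] for i in signature_sets(mask, collection.n))


@dataclass
class Partition:
    """The complete disjoint partition of a collection's union.

    ``regions`` maps every one of the 2**n - 1 signatures (empty ones
    included, with empty lists) to the sorted labels lying in exactly
    the sets named by the signature.
    """

    collection: InputCollection
    regions: Dict[int, List[str]] = field(repr=False)

    @property
    def n(self) -> int:
        return self.collection.n

    def size(self, mask: int) -> int:
        return len(self.regions[mask])

    def nonempty(self) -> Dict[int, List[str]]:
        return {m: v for m, v in self.regions.items() if v}


def compute_partition(collection: InputCollection) -> Partition:
    """Assign each element of the union to its membership signature."""
    n = collection.n
    masks: Dict[str, int] = {}
    for i, members in enumerate(collection.sets):
        bit = 1 << i
        for label in members:
            masks[label] = masks.get(label, 0) | bit
    regions: Dict[int, List[str]] = {m: [] for m in range(1, 1 << n)}
    for label, mask in masks.items():
        regions[mask].append(label)
    for members in regions.values():
        members.sort()
    return Partition(collection=collection, regions=regions)


def classify_region(mask: int, reference_index: int, n: int) -> Category:
    """Five-color category of a signature relative to the reference set."""
    signature_index(mask, n)
    if not 1 <= reference_index <= n:
        raise ValueError(f"reference_index {reference_index} outside 1..{n}")
    full = (1 << n) - 1
    ref_bit = 1 << (reference_index - 1)
    in_ref = bool(mask & ref_bit)
    n_doses = bin(mask & ~ref_bit).count("1")
    if mask == full:
        return Category.GREEN
    if in_ref and n_doses == 0:
        return Category.BLUE
    if not in_ref and n_doses == 1:
        return Category.RED
    if not in_ref:  # >= 2 dose sets, reference absent
        return Category.GREY
    # reference plus some but not all dose sets
    return Category.BLACK


def category_census(n: int, reference_index: int = 1) -> Dict[Category, int]:
    """How many of the 2**n - 1 signatures fall in each category."""
    census: Dict[Category, int] = {c: 0 for c in Category}
    for mask in range(1, 1 << n):
        census[classify_region(mask, reference_index, n)] += 1
    return census


def dose_unique_members(
    partition: Partition, reference_index: int = 1
) -> Dict[str, List[str]]:
    """Members unique to each single non-reference set (its RED region)."""
    n = partition.n
    if not 1 <= reference_index <= n:
        raise ValueError(f"reference_index {reference_index} outside 1..{n}")
    out: Dict[str, List[str]] = {}
    for i in range(1, n + 1):
        if i == reference_index:
            continue
        out[partition.collection.names[i - 1]] = list(partition.regions[1 << (i - 1)])
    return out
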