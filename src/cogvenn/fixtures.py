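"""Synthetic set collections with a fully known ground-truth partition.

A :class:`PartitionPlan` prescribes how many members each of the
2**n - 1 regions should hold; :func:`generate_collection` synthesizes
fresh labels accordingly and returns both the collection and the exact
partition it must produce.  Labels are sequential ``P<seed>_000001``
strings — no attempt is made to mimic real gene symbols, since the
comparison is string-exact — so distinct seeds give label-disjoint
collections and the same seed reproduces the collection byte-for-byte.

:func:`paper_shaped_plan` builds six-set dose-response plans (reference
plus five agonist doses) whose dose-unique region counts follow printed
proportional distributions from a published muscarinic-receptor
phosphoproteomics study; the share values that study does not print are
synthetic fill chosen to sum to 100.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from .setcore import (
    MAX_SETS,
    MIN_SETS,
    Category,
    InputCollection,
    Partition,
    UnsupportedSetCountError,
    classify_region,
)

#: condition names of the six-set dose-response design
DOSE_SET_NAMES = ("NS", "10nM", "100nM", "1uM", "10uM", "100uM")

#: dose-unique percentage splits per context; starred values are printed
#: in the source study, the rest are synthetic fill summing to 100
DOSE_UNIQUE_SHARES: Dict[str, Tuple[int, ...]] = {
    "control": (15, 15, 21, 22, 27),  # all five printed
    "cmp": (7, 11, 20, 24, 38),  # 7* and 11*; high doses synthetic
    "go-control": (24, 19, 19, 19, 19),  # 24*; rest synthetic
    "go-cmp": (4, 10, 14, 18, 54),  # 4* and 54*; middle synthetic
    "pathway-control": (11, 33, 20, 18, 18),  # 11*; rest synthetic
    "pathway-cmp": (0, 15, 25, 40, 20),  # 0*; rest synthetic
}

#: overall stimulated-unique percentage (dose-unique members among the
#: stimulated-only members) per context family
STIMULATED_UNIQUE_PCT = {"control": 36, "cmp": 38}


@dataclass
class PartitionPlan:
    """Intended member count per region signature, plus label provenance."""

    n: int
    counts: Dict[int, int]
    label_prefix: str = "P"
    seed: int = 0
    set_names: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not MIN_SETS <= self.n <= MAX_SETS:
            raise UnsupportedSetCountError(f"n={self.n} outside {MIN_SETS}..{MAX_SETS}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative region count")
        if any(not 1 <= m < (1 << self.n) for m in self.counts):
            raise ValueError("signature outside 1..2^n-1")
        if not any(self.counts.values()):
            raise ValueError("plan has all-zero counts")
        if not self.set_names:
            self.set_names = tuple(f"Set{i + 1}" for i in range(self.n))
        if len(self.set_names) != self.n:
            raise ValueError("set_names length must equal n")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def generate_collection(plan: PartitionPlan) -> Tuple[InputCollection, Partition]:
    """Synthesize a collection realizing the plan, with its ground truth.

    Each label is placed into exactly the sets named by its signature;
    deterministic given the plan's seed, and label-disjoint across
    distinct seeds.
    """
    rng = random.Random(plan.seed)
    counter = 0
    members_by_set: List[List[str]] = [[] for _ in range(plan.n)]
    regions: Dict[int, List[str]] = {m: [] for m in range(1, 1 << plan.n)}
    for mask in sorted(plan.counts):
        for _ in range(plan.counts[mask]):
            counter += 1
            label = f"{plan.label_prefix}{plan.seed}_{counter:06d}"
            regions[mask].append(label)
            for i in range(plan.n):
                if mask >> i & 1:
                    members_by_set[i].append(label)
    # present each column in shuffled order, as real input would be
    for col in members_by_set:
        rng.shuffle(col)
    collection = InputCollection.from_lists(
        list(zip(plan.set_names, members_by_set))
    )
    for v in regions.values():
        v.sort()
    return collection, Partition(collection=collection, regions=regions)


def random_plan(
    n: int, seed: int, max_count: int = 8, label_prefix: str = "R"
) -> PartitionPlan:
    """A random plan for property tests: uniform counts in 0..max_count."""
    rng = random.Random(seed)
    counts = {m: rng.randint(0, max_count) for m in range(1, 1 << n)}
    if not any(counts.values()):
        counts[(1 << n) - 1] = 1
    return PartitionPlan(
        n=n, counts=counts, label_prefix=label_prefix, seed=seed
    )


def paper_shaped_plan(
    context: str = "control", scale: int = 100, seed: int = 0
) -> PartitionPlan:
    """A six-set dose-response plan calibrated to printed proportions.

    ``scale`` is the total number of dose-unique members (the study's
    proportions are integer percentages, so scale >= 100 keeps the
    per-dose counts exact multiples).  The plan places:

    * per-dose unique (RED) counts following the context's proportional
      split;
    * enough doses-only shared (GREY) mass that the dose-unique members
      make up the context's printed share of all stimulated-only
      members (36% control family, 38% CMP family);
    * reference-unique (BLUE), reference-plus-some-doses (BLACK) and
      all-sets (GREEN) mass at fixed realistic ratios — these do not
      enter the calibrated statistics.
    """
    context = context.lower()
    if context not in DOSE_UNIQUE_SHARES:
        raise ValueError(
            f"unknown context {context!r}; choose from {sorted(DOSE_UNIQUE_SHARES)}"
        )
    if scale < 100:
        raise ValueError("scale must be >= 100")
    n = 6
    shares = DOSE_UNIQUE_SHARES[context]
    stim_pct = STIMULATED_UNIQUE_PCT["cmp" if "cmp" in context else "control"]
    counts: Dict[int, int] = {}
    red_masks = [1 << i for i in range(1, n)]  # doses are sets 2..6
    for mask, share in zip(red_masks, shares):
        counts[mask] = share * scale // 100
    red_total = sum(counts[m] for m in red_masks)
    # GREY mass so red_total / (red_total + grey_total) ~= stim_pct %
    grey_total = round(red_total * (100 - stim_pct) / stim_pct)
    grey_masks = [
        m
        for m in range(1, 1 << n)
        if classify_region(m, 1, n) is Category.GREY
    ]
    base, rem = divmod(grey_total, len(grey_masks))
    for j, m in enumerate(sorted(grey_masks)):
        counts[m] = base + (1 if j < rem else 0)
    # uncalibrated background mass
    counts[1] = scale // 2  # BLUE: reference-unique
    counts[(1 << n) - 1] = scale // 5  # GREEN: present everywhere
    black_masks = [
        m
        for m in range(1, 1 << n)
        if classify_region(m, 1, n) is Category.BLACK
    ]
    black_total = scale
    base, rem = divmod(black_total, len(black_masks))
    for j, m in enumerate(sorted(black_masks)):
        counts[m] = base + (1 if j < rem else 0)
    return PartitionPlan(
        n=n,
        counts=counts,
        label_prefix=f"{context.replace('-', '')}_",
        seed=seed,
        set_names=DOSE_SET_NAMES,
    )
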