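"""Dose-response set summaries built on the region partition.

A six-condition dose-response comparison (one non-stimulated reference
set plus five agonist doses) asks three questions of the partition:
how large is each of the 63 intersection categories and how is it
classified (the category histogram); what fraction of the stimulated
response is *dose-unique*, i.e. appears at exactly one dose and not in
the reference (the dose profile); and how much do two cellular contexts
share condition-by-condition (the cross-context comparison).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

import pandas as pd

from .setcore import (
    Category,
    InputCollection,
    Partition,
    classify_region,
    signature_names,
)

#: Denominator choices for the stimulated-unique fraction.
DENOM_STIMULATED = "stimulated"  # in >=1 dose set AND absent from reference
DENOM_ALL_STIMULATED = "all-stimulated"  # in >=1 dose set, reference ignored


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (display convention)."""
    return int(math.floor(x + 0.5))


def category_histogram(
    partition: Partition, reference_index: int = 1
) -> Dict[int, Tuple[int, Category]]:
    """(size, category) per region index — the data behind the bar charts."""
    n = partition.n
    return {
        mask: (len(partition.regions[mask]), classify_region(mask, reference_index, n))
        for mask in sorted(partition.regions)
    }


@dataclass
class DoseProfile:
    """Per-dose unique counts and the dose-unique proportional split."""

    reference_name: str
    dose_names: List[str]
    unique_counts: Dict[str, int]
    unique_fractions: Dict[str, int]  # integer percent, rounded half-up
    raw_fractions: Dict[str, float]  # exact percentages
    stimulated_unique_fraction: int  # integer percent
    raw_stimulated_unique_fraction: float
    denominator: str

    @property
    def total_unique(self) -> int:
        return sum(self.unique_counts.values())


def dose_unique_profile(
    partition: Partition,
    reference_index: int = 1,
    denominator: str = DENOM_STIMULATED,
) -> DoseProfile:
    """Dose-unique counts, their proportional split, and the overall
    fraction of the stimulated response that is dose-unique.

    The default denominator counts members present in at least one dose
    set but absent from the reference set; ``all-stimulated`` instead
    counts every member of any dose set.
    """
    n = partition.n
    if n < 3:
        raise ValueError("need a reference plus at least two dose sets (n >= 3)")
    if not 1 <= reference_index <= n:
        raise ValueError(f"reference_index {reference_index} outside 1..{n}")
    if denominator not in (DENOM_STIMULATED, DENOM_ALL_STIMULATED):
        raise ValueError(f"unknown denominator {denominator!r}")
    names = partition.collection.names
    dose_indices = [i for i in range(1, n + 1) if i != reference_index]
    if all(not partition.collection.sets[i - 1] for i in dose_indices):
        raise ValueError("every dose set is empty")

    ref_bit = 1 << (reference_index - 1)
    unique_counts = {
        names[i - 1]: len(partition.regions[1 << (i - 1)]) for i in dose_indices
    }
    total_unique = sum(unique_counts.values())
    raw_fractions = {
        name: (100.0 * c / total_unique if total_unique else 0.0)
        for name, c in unique_counts.items()
    }
    denom = 0
    for mask, members in partition.regions.items():
        in_dose = bool(mask & ~ref_bit)
        if in_dose and (denominator == DENOM_ALL_STIMULATED or not mask & ref_bit):
            denom += len(members)
    raw_stim = 100.0 * total_unique / denom if denom else 0.0
    return DoseProfile(
        reference_name=names[reference_index - 1],
        dose_names=[names[i - 1] for i in dose_indices],
        unique_counts=unique_counts,
        unique_fractions={k: round_half_up(v) for k, v in raw_fractions.items()},
        raw_fractions=raw_fractions,
        stimulated_unique_fraction=round_half_up(raw_stim),
        raw_stimulated_unique_fraction=raw_stim,
        denominator=denominator,
    )


@dataclass
class CrossContextComparison:
    """Condition-by-condition set sizes and overlap across two contexts."""

    condition_names: List[str]
    size_a: Dict[str, int]
    size_b: Dict[str, int]
    intersection: Dict[str, int]


def cross_context_compare(
    collection_a: InputCollection, collection_b: InputCollection
) -> CrossContextComparison:
    """Per condition: |A|, |B| and |A ∩ B| under canonical comparison."""
    if collection_a.names != collection_b.names:
        raise ValueError(
            f"condition names differ: {collection_a.names} vs {collection_b.names}"
        )
    size_a, size_b, inter = {}, {}, {}
    for name, sa, sb in zip(collection_a.names, collection_a.sets, collection_b.sets):
        size_a[name] = len(sa)
        size_b[name] = len(sb)
        inter[name] = len(sa & sb)
    return CrossContextComparison(
        condition_names=list(collection_a.names),
        size_a=size_a,
        size_b=size_b,
        intersection=inter,
    )


# ---------------------------------------------------------------------------
# CSV serialization
# ---------------------------------------------------------------------------

def write_category_histogram(
    partition: Partition, reference_index: int, path: str | Path
) -> pd.DataFrame:
    hist = category_histogram(partition, reference_index)
    frame = pd.DataFrame(
        {
            "region_index": list(hist),
            "signature": [
                "∩".join(signature_names(m, partition.collection)) for m in hist
            ],
            "size": [s for s, _ in hist.values()],
            "category_code": [c.value for _, c in hist.values()],
        }
    )
    frame.to_csv(path, index=False)
    return frame


def write_dose_profile(profile: DoseProfile, path: str | Path) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "dose": profile.dose_names,
            "unique_count": [profile.unique_counts[d] for d in profile.dose_names],
            "unique_fraction_pct": [
                profile.unique_fractions[d] for d in profile.dose_names
            ],
            "raw_fraction_pct": [profile.raw_fractions[d] for d in profile.dose_names],
        }
    )
    frame.attrs["stimulated_unique_fraction_pct"] = profile.stimulated_unique_fraction
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# reference={profile.reference_name}")
        fh.write(f" denominator={profile.denominator}")
        fh.write(
            f" stimulated_unique_fraction_pct={profile.stimulated_unique_fraction}"
            f" raw={profile.raw_stimulated_unique_fraction:.4f}\n"
        )
        frame.to_csv(fh, index=False)
    return frame


def write_cross_context(comparison: CrossContextComparison, path: str | Path) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "condition": comparison.condition_names,
            "size_a": [comparison.size_a[c] for c in comparison.condition_names],
            "size_b": [comparison.size_b[c] for c in comparison.condition_names],
            "intersection": [
                comparison.intersection[c] for c in comparison.condition_names
            ],
        }
    )
    frame.to_csv(path, index=False)
    return frame
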