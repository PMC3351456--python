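import pytest

import cogvenn as cv


@pytest.fixture
def disjoint_pair():
    """Two disjoint singleton sets: regions 1:{a}, 2:{b}, 3:{}."""
    return cv.InputCollection.from_lists([("A", ["a"]), ("B", ["b"])])


@pytest.fixture
def hand_triple():
    """{a,b}, {b,c}, {c}: only regions 1:{a}, 3:{b}, 6:{c} non-empty."""
    return cv.InputCollection.from_lists(
        [("S1", ["a", "b"]), ("S2", ["b", "c"]), ("S3", ["c"])]
    )


@pytest.fixture
def six_identical():
    members = ["m1", "m2", "m3"]
    return cv.InputCollection.from_lists(
        [(f"D{i}", list(members)) for i in range(1, 7)]
    )


@pytest.fixture(scope="session")
def default_layouts():
    """Validated default layouts for every supported set count."""
    return {n: cv.build_layout(n) for n in range(2, 7)}


def brute_force_partition(collection: cv.InputCollection) -> dict:
    """Independent oracle: per-element membership scan over all sets."""
    regions = {m: [] for m in range(1, 1 << collection.n)}
    for label in sorted(collection.union()):
        mask = 0
        for i, members in enumerate(collection.sets):
            if label in members:
                mask |= 1 << i
        regions[mask].append(label)
    return regions
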