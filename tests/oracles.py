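"""Independent reference computations used as test oracles.

These deliberately avoid the library's own code paths: the partition
oracle is a per-element membership-bitmask brute force over plain Python
sets, and the geometry oracle goes through shapely's predicates.
"""

from __future__ import annotations

import numpy as np

LABELS = "ABCDEF"


def bitmask_partition(lists: list[list[str]]) -> dict[str, set[str]]:
    """Brute-force exclusive partition: each element of the union is keyed
    by the labels of every list that contains it."""
    sets = [set(lst) for lst in lists]
    union = set().union(*sets) if sets else set()
    regions: dict[str, set[str]] = {}
    for element in union:
        key = "".join(LABELS[i] for i, s in enumerate(sets) if element in s)
        regions.setdefault(key, set()).add(element)
    return regions


def brute_force_value_sums(
    lists: list[list[str]], values: list[list[float]]
) -> dict[str, float]:
    """Region value sums by direct enumeration over (list, element) pairs."""
    regions = bitmask_partition(lists)
    region_of = {el: key for key, els in regions.items() for el in els}
    sums: dict[str, float] = {key: 0.0 for key in regions}
    for i, (lst, vals) in enumerate(zip(lists, values)):
        for el, val in zip(lst, vals):
            sums[region_of[el]] += val
    return sums


def random_lists(
    rng: np.random.Generator, n_lists: int, max_elements: int = 200
) -> list[list[str]]:
    """Random list collection over a shared identifier pool.

    Each list draws a random-sized sample (with possible overlap between
    lists) from a pool of at most ``max_elements`` identifiers.
    """
    pool_size = int(rng.integers(1, max_elements + 1))
    pool = [f"Otu{i}" for i in range(pool_size)]
    lists = []
    for _ in range(n_lists):
        k = int(rng.integers(0, pool_size + 1))
        idx = rng.choice(pool_size, size=k, replace=False)
        lists.append([pool[i] for i in idx])
    return lists


def shapely_region_of(shapes, point) -> str | None:
    """Region key of a point via shapely containment (geometry oracle)."""
    from shapely.geometry import Point, Polygon

    labels = []
    p = Point(point)
    for shape in shapes:
        poly = Polygon(shape.rings[0], [r for r in shape.rings[1:]]).buffer(0)
        if poly.contains(p):
            labels.append(shape.label)
    return "".join(sorted(labels)) or None
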