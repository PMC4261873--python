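"""Exclusive-region partition of up to six named lists, and derived statistics.

Every identifier in the union of the input lists belongs to exactly one
*exclusive region*: the region keyed by the sorted subset of list labels
(A..F) of precisely the lists that contain it.  For ``n`` lists there are
``2**n - 1`` regions; their counts are what a Venn diagram displays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .errors import ListLimitError, QueryError, VennKitError
from .io_formats import LABELS, MAX_LISTS, IntersectionCountsDoc, VennSeries

MODE_CARDINALITY = "cardinality"
MODE_VALUE_SUM = "value_sum"
MODE_USER_SUPPLIED = "user_supplied"


def region_sort_key(key: str) -> tuple[int, str]:
    """Canonical ordering: subset size ascending, then lexicographic."""
    return (len(key), key)


def canonical_regions(labels: Sequence[str]) -> list[str]:
    """All ``2**n - 1`` region keys over ``labels``, in canonical order."""
    labs = sorted(labels)
    keys = []
    for size in range(1, len(labs) + 1):
        for combo in combinations(labs, size):
            keys.append("".join(combo))
    return keys


@dataclass(frozen=True)
class RegionTable:
    """The complete exclusive-region partition for one list collection.

    ``counts`` maps every region key to its figure: a cardinality, a sum of
    per-element values, or a user-supplied count, depending on ``mode``.
    ``elements`` holds the exclusive identifiers per region when the input
    provided them (``None`` for pure count input).
    """

    labels: tuple[str, ...]
    names: Mapping[str, str]
    counts: Mapping[str, float]
    elements: Mapping[str, tuple[str, ...]] | None
    mode: str = MODE_CARDINALITY

    @property
    def n_lists(self) -> int:
        return len(self.labels)

    def __post_init__(self) -> None:
        expected = canonical_regions(self.labels)
        if sorted(self.counts, key=region_sort_key) != expected:
            raise VennKitError(
                f"region table must hold exactly the {len(expected)} regions "
                f"over labels {''.join(self.labels)}"
            )
        if any(c < 0 for c in self.counts.values()):
            raise VennKitError("region counts must be non-negative")

    def regions(self) -> list[str]:
        return canonical_regions(self.labels)

    def union_size(self) -> int:
        """Number of distinct identifiers across all lists.

        Only meaningful when counts are cardinalities.
        """
        return int(sum(self.counts.values()))


def _check_series(series: Sequence[VennSeries]) -> Sequence[VennSeries]:
    if len(series) > MAX_LISTS:
        raise ListLimitError(
            f"{len(series)} lists supplied; at most {MAX_LISTS} are supported"
        )
    if not series:
        raise VennKitError("at least one list is required")
    return series


def assign_labels(series: Sequence[VennSeries]) -> dict[str, VennSeries]:
    """Label series A..F in input order."""
    _check_series(series)
    return {LABELS[i]: s for i, s in enumerate(series)}


def compute_partition(series: Sequence[VennSeries]) -> RegionTable:
    """Partition the union of the input lists into exclusive regions.

    Each identifier is assigned to the region keyed by the labels of every
    list containing it; region counts are cardinalities.  Element order
    within a region follows first appearance across the lists (A first).
    """
    labeled = assign_labels(series)
    labels = tuple(labeled)
    membership: dict[str, str] = {}
    for label, s in labeled.items():
        for ident in s.data:
            membership[ident] = membership.get(ident, "") + label
    elements: dict[str, list[str]] = {key: [] for key in canonical_regions(labels)}
    for ident, key in membership.items():
        elements[key].append(ident)
    return RegionTable(
        labels=labels,
        names={lab: s.name for lab, s in labeled.items()},
        counts={key: len(vals) for key, vals in elements.items()},
        elements={key: tuple(vals) for key, vals in elements.items()},
        mode=MODE_CARDINALITY,
    )


def from_intersection_counts(doc: IntersectionCountsDoc) -> RegionTable:
    """Wrap user-supplied region counts as a region table."""
    return RegionTable(
        labels=doc.labels,
        names=dict(doc.names),
        counts=dict(doc.counts),
        elements=dict(doc.elements) if doc.elements is not None else None,
        mode=MODE_USER_SUPPLIED,
    )


def aggregate_count_values(
    series: Sequence[VennSeries], partition: RegionTable
) -> RegionTable:
    """Aggregate per-element values into region value sums.

    The figure for a region is the sum, over every member list of the region
    and every exclusive element of the region, of that element's value in
    that list — so the grand total over regions equals the grand total of
    all input values (conservation).
    """
    labeled = assign_labels(series)
    if tuple(labeled) != partition.labels:
        raise VennKitError("partition was built from a different list collection")
    missing = [s.name for s in series if s.values is None]
    if missing:
        raise VennKitError(
            f"count aggregation needs values on every list; missing on: "
            f"{', '.join(missing)}"
        )
    if partition.elements is None:
        raise VennKitError("partition lacks element membership")
    value_of = {
        lab: dict(zip(s.data, s.values)) for lab, s in labeled.items()
    }
    sums: dict[str, float] = {}
    for key in partition.regions():
        total = 0.0
        for lab in key:
            lookup = value_of[lab]
            for ident in partition.elements[key]:
                total += lookup[ident]
        sums[key] = total
    return replace(partition, counts=sums, mode=MODE_VALUE_SUM)


def list_size_stats(series: Sequence[VennSeries]) -> list[int]:
    """Per-list sizes after de-duplication, in label order."""
    _check_series(series)
    return [len(s.data) for s in series]


def shared_distribution(partition: RegionTable) -> dict[int, float]:
    """How many elements are specific to one list, shared by two, three, ...

    Entry ``k`` sums the counts of all regions spanning exactly ``k`` lists;
    the entries total the union size.  Requires counts that are element
    counts (computed or user-supplied), not value sums.
    """
    if partition.mode == MODE_VALUE_SUM:
        raise VennKitError(
            "shared distribution needs element counts, not value sums"
        )
    dist = {k: 0.0 for k in range(1, partition.n_lists + 1)}
    for key, count in partition.counts.items():
        dist[len(key)] += count
    return dist


def search_identifiers(
    partition: RegionTable, query: str
) -> list[tuple[str, str]]:
    """Case-insensitive substring search over all identifiers.

    Each match is reported with the key of its (unique) exclusive region,
    ordered by canonical region order then identifier.
    """
    if not query:
        raise QueryError("search query must be non-empty")
    if partition.elements is None:
        raise VennKitError("search needs element membership")
    needle = query.lower()
    matches = []
    for key in partition.regions():
        for ident in sorted(partition.elements.get(key, ())):
            if needle in ident.lower():
                matches.append((ident, key))
    return matches
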