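"""Synthetic list collections with planted region sizes.

The generator emulates the identifier-list inputs of omics workflows
(gene or OTU lists): it plants an exact number of distinct identifiers in
every exclusive region and assigns each identifier to precisely the lists
of its region, so the true partition is known by construction.  Optional
per-element values follow a negative-binomial distribution, the standard
overdispersed model for sequencing read counts.

Everything is driven by a single seed: the same spec always yields the
same identifiers and values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import LABELS, MAX_LISTS, VennSeries, serialize_series
from .setcore import RegionTable, canonical_regions


@dataclass(frozen=True)
class SyntheticSpec:
    """Planted region sizes for one synthetic instance.

    ``region_counts`` maps region keys (over the first ``n_lists`` labels)
    to the number of identifiers planted in that exclusive region; missing
    regions default to 0.  ``value_mean``/``value_dispersion`` parameterize
    the negative-binomial read-count model used when ``with_values`` is on
    (mean ~48 reads, dispersion 2 — a typical overdispersed OTU profile).
    """

    n_lists: int
    region_counts: dict[str, int] = field(default_factory=dict)
    prefix: str = "id"
    with_values: bool = False
    value_mean: float = 48.0
    value_dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_lists <= MAX_LISTS:
            raise ValueError(f"n_lists must be 1..{MAX_LISTS}")
        valid = set(canonical_regions(LABELS[: self.n_lists]))
        for key, count in self.region_counts.items():
            if key not in valid:
                raise ValueError(f"unknown region key {key!r} for n={self.n_lists}")
            if count < 0:
                raise ValueError(f"region {key!r}: negative planted count")


def generate_series(
    spec: SyntheticSpec,
) -> tuple[list[VennSeries], RegionTable]:
    """Synthesize series realizing the planted partition, plus the truth.

    Identifiers are ``<prefix><zero-padded index>`` assigned to regions in
    canonical order, so output is reproducible and searchable.  Returns the
    series and the expected region table; ``compute_partition`` on the
    series must reproduce it exactly.
    """
    labels = tuple(LABELS[: spec.n_lists])
    regions = canonical_regions(labels)
    counts = {key: int(spec.region_counts.get(key, 0)) for key in regions}
    rng = np.random.default_rng(spec.seed)

    elements: dict[str, tuple[str, ...]] = {}
    next_index = 0
    for key in regions:
        ids = tuple(
            f"{spec.prefix}{i:06d}"
            for i in range(next_index, next_index + counts[key])
        )
        next_index += counts[key]
        elements[key] = ids

    per_list: dict[str, list[str]] = {lab: [] for lab in labels}
    for key in regions:
        for lab in key:
            per_list[lab].extend(elements[key])

    series = []
    for i, lab in enumerate(labels):
        data = tuple(per_list[lab])
        values = None
        if spec.with_values:
            p = spec.value_dispersion / (spec.value_dispersion + spec.value_mean)
            draws = rng.negative_binomial(spec.value_dispersion, p, size=len(data))
            values = tuple(float(v) for v in draws)
        series.append(VennSeries(name=f"list_{lab}", data=data, values=values))

    expected = RegionTable(
        labels=labels,
        names={lab: f"list_{lab}" for lab in labels},
        counts=counts,
        elements=elements,
        mode="cardinality",
    )
    return series, expected


def random_spec(
    n_lists: int,
    rng: np.random.Generator,
    max_region_count: int = 8,
    prefix: str = "id",
    with_values: bool = False,
) -> SyntheticSpec:
    """Draw a random planted spec (region counts uniform on 0..max)."""
    regions = canonical_regions(LABELS[:n_lists])
    counts = {
        key: int(rng.integers(0, max_region_count + 1)) for key in regions
    }
    return SyntheticSpec(
        n_lists=n_lists,
        region_counts=counts,
        prefix=prefix,
        with_values=with_values,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_document(spec: SyntheticSpec) -> dict:
    """Generate an instance and serialize it to the JSON input shape."""
    series, _ = generate_series(spec)
    return serialize_series(series)
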