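"""Input and output formats for named-list comparison.

Three JSON document shapes are accepted, mirroring the formats used by
list-comparison web tools for omics data:

``lists``
    ``{"series": [{"name": ..., "data": [id, ...]}, ...]}`` — plain
    identifier lists; intersection counts are computed.
``intersection_counts``
    ``{"series": [{"name": {"A": ...}, "data": {"A": [...], ...}}],
    "values": {"A": 3, "AB": 4, ...}}`` — the user supplies the count of
    every exclusive region directly (element lists optional).
``count_lists``
    like ``lists`` but every series carries a parallel ``values`` array of
    non-negative numbers (e.g. OTU read counts); region figures are then
    value sums rather than cardinalities.

Plain-text input (one identifier per line, one blob per list) and the
intersection-membership CSV export are handled here as well.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import (
    AmbiguousFormatError,
    DocumentError,
    EmptyInputError,
    ExportUnsupportedError,
    ListLimitError,
)

MAX_LISTS = 6
LABELS = "ABCDEF"

FORMAT_LISTS = "lists"
FORMAT_INTERSECTION_COUNTS = "intersection_counts"
FORMAT_COUNT_LISTS = "count_lists"


@dataclass(frozen=True)
class VennSeries:
    """One named input list, optionally with a per-element numeric value.

    ``data`` holds the identifiers in their original order with duplicates
    collapsed; when duplicates are collapsed in a count list, their values
    are summed so that list totals are preserved.
    """

    name: str
    data: tuple[str, ...]
    values: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise DocumentError("series name must be a non-empty string")
        if self.values is not None and len(self.values) != len(self.data):
            raise DocumentError(
                f"series {self.name!r}: {len(self.values)} values for "
                f"{len(self.data)} identifiers"
            )
        if len(set(self.data)) != len(self.data):
            raise DocumentError(
                f"series {self.name!r} contains duplicate identifiers after "
                "normalization"
            )

    @classmethod
    def from_raw(
        cls,
        name: str,
        data: Sequence[str],
        values: Sequence[float] | None = None,
    ) -> "VennSeries":
        """Build a series from raw input, trimming and de-duplicating.

        Identifiers are compared by exact string equality after stripping
        surrounding whitespace; repeated identifiers are kept once, in the
        position of their first occurrence.  When ``values`` are given, the
        values of collapsed duplicates are summed.
        """
        if not isinstance(name, str) or not name.strip():
            raise DocumentError("series name must be a non-empty string")
        if values is not None and len(values) != len(data):
            raise DocumentError(
                f"series {name!r}: {len(values)} values for {len(data)} identifiers"
            )
        seen: dict[str, int] = {}
        out_data: list[str] = []
        out_values: list[float] = []
        for i, raw in enumerate(data):
            ident = str(raw).strip()
            if not ident:
                continue
            val = None
            if values is not None:
                val = float(values[i])
                if val < 0:
                    raise DocumentError(
                        f"series {name!r}: negative value {val} for {ident!r}"
                    )
            if ident in seen:
                if val is not None:
                    out_values[seen[ident]] += val
                continue
            seen[ident] = len(out_data)
            out_data.append(ident)
            if val is not None:
                out_values.append(val)
        return cls(
            name=name.strip(),
            data=tuple(out_data),
            values=tuple(out_values) if values is not None else None,
        )


@dataclass(frozen=True)
class IntersectionCountsDoc:
    """User-supplied region counts, with optional element membership.

    ``names`` maps single-letter labels to display names; ``counts`` maps
    canonical region keys (sorted label subsets such as ``"AB"``) to
    non-negative integers.  Region keys absent from the input default to 0.
    """

    names: Mapping[str, str]
    counts: Mapping[str, int]
    elements: Mapping[str, tuple[str, ...]] | None = None
    labels: tuple[str, ...] = field(default=())

    @property
    def n_lists(self) -> int:
        return len(self.labels)


def _series_entries(document: object) -> list[dict]:
    if not isinstance(document, Mapping):
        raise DocumentError("input document must be a JSON object")
    if "series" not in document:
        raise DocumentError('input document lacks a "series" entry')
    series = document["series"]
    if not isinstance(series, Sequence) or isinstance(series, (str, bytes)):
        raise DocumentError('"series" must be an array')
    entries = list(series)
    for entry in entries:
        if not isinstance(entry, Mapping):
            raise DocumentError("every series entry must be an object")
    return entries


def detect_format(document: object) -> str:
    """Classify a parsed JSON document as one of the three input formats.

    A top-level ``values`` mapping marks ``intersection_counts``; per-series
    ``values`` arrays mark ``count_lists``; otherwise the document is plain
    ``lists``.  Mixing both signals is rejected as ambiguous.
    """
    entries = _series_entries(document)
    has_top_values = isinstance(document.get("values"), Mapping)
    has_series_values = any("values" in e for e in entries)
    if has_top_values and has_series_values:
        raise AmbiguousFormatError(
            "document mixes a top-level values mapping with per-series values"
        )
    if has_top_values:
        return FORMAT_INTERSECTION_COUNTS
    if has_series_values:
        return FORMAT_COUNT_LISTS
    return FORMAT_LISTS


def _check_series_collection(series: list[VennSeries]) -> list[VennSeries]:
    if len(series) > MAX_LISTS:
        raise ListLimitError(
            f"{len(series)} lists supplied; at most {MAX_LISTS} are supported"
        )
    names = [s.name for s in series]
    if len(set(names)) != len(names):
        raise DocumentError("series names must be unique")
    return series


def parse_lists(document: object) -> list[VennSeries]:
    """Parse a ``lists`` document into de-duplicated series."""
    if detect_format(document) != FORMAT_LISTS:
        raise DocumentError("document is not in lists format")
    entries = _series_entries(document)
    out = []
    for entry in entries:
        data = entry.get("data")
        if not isinstance(data, Sequence) or isinstance(data, (str, bytes)):
            raise DocumentError('every series needs a "data" array')
        out.append(VennSeries.from_raw(str(entry.get("name", "")), list(data)))
    return _check_series_collection(out)


def parse_count_lists(document: object) -> list[VennSeries]:
    """Parse a ``count_lists`` document; every series gets parallel values."""
    if detect_format(document) != FORMAT_COUNT_LISTS:
        raise DocumentError("document is not in count_lists format")
    entries = _series_entries(document)
    out = []
    for entry in entries:
        data = entry.get("data")
        values = entry.get("values")
        if not isinstance(data, Sequence) or isinstance(data, (str, bytes)):
            raise DocumentError('every series needs a "data" array')
        if not isinstance(values, Sequence) or isinstance(values, (str, bytes)):
            raise DocumentError(
                'count_lists series need a "values" array parallel to "data"'
            )
        out.append(
            VennSeries.from_raw(str(entry.get("name", "")), list(data), list(values))
        )
    return _check_series_collection(out)


def parse_intersection_counts(document: object) -> IntersectionCountsDoc:
    """Parse an ``intersection_counts`` document.

    Returns the label->name mapping, the (optional) element lists and the
    region count mapping.  Regions omitted from ``values`` default to 0;
    when element lists are present their lengths must match the declared
    counts.
    """
    if detect_format(document) != FORMAT_INTERSECTION_COUNTS:
        raise DocumentError("document is not in intersection_counts format")
    entries = _series_entries(document)
    if len(entries) != 1:
        raise DocumentError(
            "intersection_counts documents use a single series entry holding "
            "the label mappings"
        )
    entry = entries[0]
    raw_names = entry.get("name")
    if not isinstance(raw_names, Mapping) or not raw_names:
        raise DocumentError(
            'intersection_counts series entry needs a "name" label mapping'
        )
    labels = tuple(sorted(str(k) for k in raw_names))
    for lab in labels:
        if len(lab) != 1 or lab not in LABELS:
            raise DocumentError(f"invalid list label {lab!r}; use letters A-F")
    if len(labels) > MAX_LISTS:
        raise ListLimitError(
            f"{len(labels)} lists supplied; at most {MAX_LISTS} are supported"
        )
    names = {lab: str(raw_names[lab]) for lab in labels}

    def _canon(key: object) -> str:
        k = "".join(sorted(str(key)))
        if not k or len(set(k)) != len(k) or any(c not in labels for c in k):
            raise DocumentError(
                f"region key {key!r} uses labels outside the declared set "
                f"{''.join(labels)}"
            )
        return k

    raw_counts = document.get("values")
    counts: dict[str, int] = {}
    for key, val in raw_counts.items():
        if not isinstance(val, (int, float)) or val < 0 or int(val) != val:
            raise DocumentError(
                f"region {key!r}: count must be a non-negative integer, got {val!r}"
            )
        counts[_canon(key)] = int(val)

    elements = None
    raw_data = entry.get("data")
    if isinstance(raw_data, Mapping):
        elements = {}
        for key, members in raw_data.items():
            canon = _canon(key)
            if not isinstance(members, Sequence) or isinstance(members, (str, bytes)):
                raise DocumentError(f"region {key!r}: element list must be an array")
            elements[canon] = tuple(str(m).strip() for m in members)
        for key, members in elements.items():
            declared = counts.get(key, 0)
            if len(members) != declared:
                raise DocumentError(
                    f"region {key!r}: {len(members)} elements listed but count "
                    f"is {declared}"
                )

    # every region over the declared labels exists; unlisted ones are 0
    from .setcore import canonical_regions

    full_counts = {key: counts.get(key, 0) for key in canonical_regions(labels)}
    return IntersectionCountsDoc(
        names=names, counts=full_counts, elements=elements, labels=labels
    )


def parse_document(document: object):
    """Dispatch on :func:`detect_format`.

    Returns ``(format_tag, payload)`` where the payload is a list of
    :class:`VennSeries` or an :class:`IntersectionCountsDoc`.
    """
    fmt = detect_format(document)
    if fmt == FORMAT_LISTS:
        return fmt, parse_lists(document)
    if fmt == FORMAT_COUNT_LISTS:
        return fmt, parse_count_lists(document)
    return fmt, parse_intersection_counts(document)


def load_document(text: str):
    """Parse a JSON text document and dispatch on its format."""
    try:
        document = json.loads(text)
    except json.JSONDecodeError as exc:
        raise DocumentError(f"invalid JSON input: {exc}") from exc
    return parse_document(document)


def read_plain_lists(
    texts: Sequence[str], names: Sequence[str] | None = None
) -> list[VennSeries]:
    """Build series from plain-text blobs, one identifier per line.

    Lines are whitespace-trimmed, empty lines dropped, and repeated
    identifiers within one blob kept once.  ``names`` defaults to
    ``list1..listN``.
    """
    if not 1 <= len(texts) <= MAX_LISTS:
        if len(texts) > MAX_LISTS:
            raise ListLimitError(
                f"{len(texts)} lists supplied; at most {MAX_LISTS} are supported"
            )
        raise EmptyInputError("no input lists supplied")
    if names is None:
        names = [f"list{i + 1}" for i in range(len(texts))]
    if len(names) != len(texts):
        raise DocumentError(
            f"{len(names)} names supplied for {len(texts)} lists"
        )
    series = []
    for name, blob in zip(names, texts):
        idents = [line.strip() for line in blob.splitlines()]
        series.append(VennSeries.from_raw(name, [i for i in idents if i]))
    if all(len(s.data) == 0 for s in series):
        raise EmptyInputError("all input lists are empty")
    return _check_series_collection(series)


def serialize_series(series: Sequence[VennSeries]) -> dict:
    """Serialize series to the JSON document shape they were parsed from.

    Emits ``count_lists`` when every series carries values, else ``lists``.
    """
    with_values = all(s.values is not None for s in series)
    doc_series = []
    for s in series:
        entry: dict = {"name": s.name, "data": list(s.data)}
        if with_values:
            vals = [int(v) if float(v).is_integer() else float(v) for v in s.values]
            entry["values"] = vals
        doc_series.append(entry)
    return {"series": doc_series}


def write_intersection_csv(table) -> str:
    """Export a region table as CSV: one column per exclusive region.

    The header row holds every region key in canonical order (subset size
    ascending, then lexicographic); each column lists the identifiers that
    fall in exactly that region, shorter columns padded with empty fields.
    """
    if table.elements is None:
        raise ExportUnsupportedError(
            "CSV export needs element membership; the input supplied counts only"
        )
    from .setcore import canonical_regions

    regions = canonical_regions(table.labels)
    columns = [table.elements.get(key, ()) for key in regions]
    depth = max((len(c) for c in columns), default=0)
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(regions)
    for i in range(depth):
        writer.writerow([col[i] if i < len(col) else "" for col in columns])
    return buf.getvalue()


def read_intersection_csv(text: str):
    """Rebuild a region table from :func:`write_intersection_csv` output.

    Display names are not stored in the CSV, so labels stand in for names.
    """
    from .setcore import RegionTable, canonical_regions

    rows = list(csv.reader(io.StringIO(text)))
    if not rows or not rows[0]:
        raise DocumentError("intersection CSV lacks a header row")
    header = rows[0]
    labels = tuple(sorted({c for key in header for c in key}))
    if not labels or any(lab not in LABELS for lab in labels):
        raise DocumentError("intersection CSV header holds invalid region keys")
    if header != canonical_regions(labels):
        raise DocumentError(
            "intersection CSV header is not the canonical region sequence"
        )
    elements: dict[str, tuple[str, ...]] = {}
    for j, key in enumerate(header):
        col = [row[j] for row in rows[1:] if j < len(row) and row[j] != ""]
        elements[key] = tuple(col)
    counts = {key: len(vals) for key, vals in elements.items()}
    return RegionTable(
        labels=labels,
        names={lab: lab for lab in labels},
        counts=counts,
        elements=elements,
        mode="cardinality",
    )
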