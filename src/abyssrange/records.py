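"""Occurrence-record input, summaries and the species depth envelope.

Records are observations/collections of the target species at named deep-sea
sites.  The depth envelope (min..max recorded depth) is the one-dimensional
habitat model consumed by :mod:`abyssrange.habitat`.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigurationError, ValidationError

BASINS = ("Pacific", "Atlantic", "Indian", "Southern", "Arctic", "Mediterranean")
RECORD_TYPES = ("observation", "collection", "both")

#: default CSV header -> field mapping; override via ``column_map``
DEFAULT_COLUMNS = {
    "site_id": "site_id",
    "feature": "feature",
    "basin": "basin",
    "lat": "lat",
    "lon": "lon",
    "depth_m": "depth_m",
    "record_type": "record_type",
}


@dataclass(frozen=True)
class OccurrenceRecord:
    """One occurrence of the species at a site.

    ``depth_m`` is positive downward.  ``n_individuals`` is ``None`` when the
    source does not report a count (historical records often do not); such
    records are excluded from any abundance summary.
    """

    site_id: str
    feature_name: str
    basin: str
    latitude: float
    longitude: float
    depth_m: float
    record_type: str
    source_ref: str = ""
    n_individuals: int | None = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if not self.site_id:
            problems.append("empty site_id")
        if not -90.0 <= self.latitude <= 90.0:
            problems.append(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            problems.append(f"longitude {self.longitude} outside [-180, 180]")
        if not self.depth_m > 0:
            problems.append(f"depth_m {self.depth_m} not positive")
        if self.basin not in BASINS:
            problems.append(f"unknown basin {self.basin!r}")
        if self.record_type not in RECORD_TYPES:
            problems.append(f"unknown record_type {self.record_type!r}")
        if self.n_individuals is not None and self.n_individuals < 0:
            problems.append(f"negative n_individuals {self.n_individuals}")
        return problems


@dataclass(frozen=True)
class RecordSummary:
    n_records: int
    n_sites: int
    depth_min_m: float
    depth_max_m: float
    counts_per_feature: dict[str, int] = field(default_factory=dict)
    counts_per_basin: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class DepthEnvelope:
    """Closed depth interval [d_min_m, d_max_m], metres positive downward."""

    d_min_m: float
    d_max_m: float
    degenerate: bool = False

    def __post_init__(self):
        if not 0 < self.d_min_m <= self.d_max_m:
            raise ValidationError(
                f"invalid depth envelope ({self.d_min_m}, {self.d_max_m})"
            )

    def contains(self, depth_m: float) -> bool:
        return self.d_min_m <= depth_m <= self.d_max_m


def read_records(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    dialect: str = "excel",
) -> list[OccurrenceRecord]:
    """Read occurrence records from a CSV file.

    Parameters
    ----------
    path:
        CSV with one record per row.  Required logical columns: site_id,
        feature, basin, lat, lon, depth_m, record_type.  Optional: source_ref,
        n_individuals.
    column_map:
        Mapping from logical field name to the actual header name, merged over
        :data:`DEFAULT_COLUMNS`.

    Raises
    ------
    ConfigurationError
        If a required column is absent from the header.
    ValidationError
        If any row fails parsing or an invariant; the message lists the
        offending 1-based data row numbers.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, dialect=dialect)
        header = reader.fieldnames or []
        missing = [v for v in cols.values() if v not in header]
        if missing:
            raise ConfigurationError(
                f"missing required column(s) {missing} in {path} (header: {header})"
            )
        records: list[OccurrenceRecord] = []
        bad: list[tuple[int, str]] = []
        for i, row in enumerate(reader, start=1):
            try:
                n_ind = row.get("n_individuals", "")
                rec = OccurrenceRecord(
                    site_id=row[cols["site_id"]].strip(),
                    feature_name=row[cols["feature"]].strip(),
                    basin=row[cols["basin"]].strip(),
                    latitude=float(row[cols["lat"]]),
                    longitude=float(row[cols["lon"]]),
                    depth_m=float(row[cols["depth_m"]]),
                    record_type=row[cols["record_type"]].strip(),
                    source_ref=row.get("source_ref", "") or "",
                    n_individuals=int(n_ind) if n_ind not in ("", None) else None,
                )
            except (ValueError, KeyError) as exc:
                bad.append((i, f"unparseable row: {exc}"))
                continue
            problems = rec.validate()
            if problems:
                bad.append((i, "; ".join(problems)))
            else:
                records.append(rec)

    if bad:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in bad)
        raise ValidationError(
            f"{len(bad)} invalid record row(s) in {path}: {detail}",
            rows=[i for i, _ in bad],
        )
    return records


def summarize_records(records: list[OccurrenceRecord]) -> RecordSummary:
    """Counts, distinct-site count and depth extremes over the records.

    Sites are distinct by exact ``site_id`` string.  Order-free: any
    permutation of the input yields the same summary.
    """
    if not records:
        raise ValidationError("cannot summarize an empty record list")
    depths = [r.depth_m for r in records]
    per_feature: dict[str, int] = {}
    per_basin: dict[str, int] = {}
    for r in records:
        per_feature[r.feature_name] = per_feature.get(r.feature_name, 0) + 1
        per_basin[r.basin] = per_basin.get(r.basin, 0) + 1
    return RecordSummary(
        n_records=len(records),
        n_sites=len({r.site_id for r in records}),
        depth_min_m=min(depths),
        depth_max_m=max(depths),
        counts_per_feature=dict(sorted(per_feature.items())),
        counts_per_basin=dict(sorted(per_basin.items())),
    )


def envelope_from_records(records: list[OccurrenceRecord]) -> DepthEnvelope:
    """Depth envelope spanned by the records (min depth .. max depth).

    A single record (or all-equal depths) yields a degenerate envelope with a
    warning; downstream code may still use it.
    """
    if not records:
        raise ValidationError("cannot derive an envelope from an empty record list")
    depths = [r.depth_m for r in records]
    lo, hi = min(depths), max(depths)
    degenerate = lo == hi
    if degenerate:
        warnings.warn(
            f"degenerate depth envelope: single depth {lo} m", stacklevel=2
        )
    return DepthEnvelope(d_min_m=lo, d_max_m=hi, degenerate=degenerate)
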