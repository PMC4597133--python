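"""Occurrence records: loading, cleaning, and the germplasm/reference split.

Records are either germplasm accessions (type ``G``, material held ex situ
in a genebank) or reference records (type ``H``, herbarium vouchers,
literature and survey sightings).  The split drives every conservation
score downstream: SRS compares the two totals, GRS/ERS use only the
coordinate-bearing germplasm records.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .geodata import BinaryRange

#: duplicate coordinates are compared after rounding to this many decimals
#: (4 decimals is roughly 11 m at the equator)
DUPLICATE_COORD_DECIMALS = 4

#: accepted column-name aliases (Darwin-Core-ish)
COLUMN_ALIASES = {
    "decimallongitude": "lon",
    "decimallatitude": "lat",
    "longitude": "lon",
    "latitude": "lat",
    "species": "taxon",
    "record_type": "type",
}

RECORD_TYPES = ("G", "H")


@dataclass(frozen=True)
class OccurrenceRecord:
    record_id: str
    taxon: str
    record_type: str  # "G" germplasm accession, "H" reference record
    lon: float | None = None
    lat: float | None = None
    source: str = ""

    def __post_init__(self):
        if self.record_type not in RECORD_TYPES:
            raise ValueError(f"record_type must be G or H, got {self.record_type!r}")
        if (self.lon is None) != (self.lat is None):
            raise ValueError("lon and lat must be present together")
        if self.lat is not None and not -90 <= self.lat <= 90:
            raise ValueError(f"latitude {self.lat} out of range")
        if self.lon is not None and not -180 <= self.lon <= 180:
            raise ValueError(f"longitude {self.lon} out of range")

    @property
    def has_coords(self) -> bool:
        return self.lon is not None


def load_occurrences(path: str | Path) -> list[OccurrenceRecord]:
    """Read occurrence records from delimited text.

    Requires columns taxon, type, lon, lat, source (aliases accepted);
    rows whose coordinates do not parse are kept with coordinates absent
    so that totals (and hence SRS) are unaffected by bad georeferencing.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [COLUMN_ALIASES.get(c.strip().lower(), c.strip().lower()) for c in df.columns]
    missing = {"taxon", "type", "lon", "lat"} - set(df.columns)
    if missing:
        raise ValueError(f"occurrence file missing columns: {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        rtype = getattr(row, "type").strip()
        if rtype not in RECORD_TYPES:
            raise ValueError(f"row {i}: record type must be G or H, got {rtype!r}")
        try:
            lon = float(getattr(row, "lon"))
            lat = float(getattr(row, "lat"))
        except ValueError:
            lon = lat = None
        if lon is not None and not (-180 <= lon <= 180 and -90 <= lat <= 90):
            lon = lat = None
        rid = getattr(row, "record_id", "") or f"r{i:06d}"
        records.append(
            OccurrenceRecord(
                record_id=rid,
                taxon=getattr(row, "taxon").strip(),
                record_type=rtype,
                lon=lon,
                lat=lat,
                source=getattr(row, "source", ""),
            )
        )
    return records


def save_occurrences(records: Iterable[OccurrenceRecord], path: str | Path) -> None:
    rows = [
        {
            "record_id": r.record_id,
            "taxon": r.taxon,
            "type": r.record_type,
            "lon": "" if r.lon is None else repr(r.lon),
            "lat": "" if r.lat is None else repr(r.lat),
            "source": r.source,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["record_id", "taxon", "type", "lon", "lat", "source"]).to_csv(
        path, index=False
    )


def _dup_key(r: OccurrenceRecord):
    return (
        r.taxon,
        r.record_type,
        round(r.lon, DUPLICATE_COORD_DECIMALS),
        round(r.lat, DUPLICATE_COORD_DECIMALS),
    )


def deduplicate(records: Sequence[OccurrenceRecord]) -> list[OccurrenceRecord]:
    """Collapse records sharing (taxon, type, rounded coordinates).

    The first record by record_id order survives.  The record type is part
    of the key so a genebank accession never erases a herbarium voucher at
    the same site (conservative for SRS).  Coordinate-free records are
    never merged.
    """
    with_coords = sorted((r for r in records if r.has_coords), key=lambda r: r.record_id)
    seen: dict[tuple, OccurrenceRecord] = {}
    for r in with_coords:
        seen.setdefault(_dup_key(r), r)
    survivors = set(id(r) for r in seen.values())
    return [r for r in records if not r.has_coords or id(r) in survivors]


def partition_counts(
    records: Sequence[OccurrenceRecord], taxon: str
) -> tuple[int, int, int, int]:
    """(n_G, n_H, n_G_with_coords, n_H_with_coords) for one taxon.

    Totals count every record regardless of coordinates; the coordinate
    subsets are what the spatial scores can actually map.  An unknown
    taxon yields zeros.
    """
    n_g = n_h = n_gc = n_hc = 0
    for r in records:
        if r.taxon != taxon:
            continue
        if r.record_type == "G":
            n_g += 1
            n_gc += r.has_coords
        else:
            n_h += 1
            n_hc += r.has_coords
    return n_g, n_h, n_gc, n_hc


def taxa_of(records: Sequence[OccurrenceRecord]) -> list[str]:
    """Sorted unique taxon names present in the records."""
    return sorted({r.taxon for r in records})


def coords_of(
    records: Sequence[OccurrenceRecord], taxon: str, record_type: str | None = None
) -> list[tuple[float, float]]:
    """(lon, lat) pairs for a taxon, optionally restricted by record type."""
    return [
        (r.lon, r.lat)
        for r in records
        if r.taxon == taxon
        and r.has_coords
        and (record_type is None or r.record_type == record_type)
    ]


def filter_native(
    records: Sequence[OccurrenceRecord], native_mask: BinaryRange
) -> list[OccurrenceRecord]:
    """Drop coordinate-bearing records falling outside the native-area mask.

    Points are assigned to cells by containment; a point in a boundary
    cell flagged native is kept.  Coordinate-free records pass through.
    """
    out = []
    for r in records:
        if not r.has_coords:
            out.append(r)
            continue
        cell = native_mask.cell_of(r.lon, r.lat)
        if cell is not None and native_mask.values[cell] == 1.0:
            out.append(r)
    return out
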