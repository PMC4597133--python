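"""Ex situ conservation gap scores and collecting-priority products.

Per taxon, three representativeness scores on a 0-10 scale:

* SRS (sampling): 10 * germplasm records / all records — how much of the
  evidence for the taxon is actually banked material;
* GRS (geographic): 10 * area of the potential distribution within 50 km
  of an existing germplasm collection / total distribution area;
* ERS (ecological): 10 * ecoregion classes already collected from /
  ecoregion classes the distribution spans.

Their equal-weight mean is the final prioritization score (FPS), banded
into collecting priorities: high (HPS, FPS <= 3), medium (MPS, 3 < FPS
<= 5), low (LPS, 5 < FPS <= 7.5), and no further collecting required
(NFCR, FPS > 7.5).  SRS uses every record, mappable or not; GRS and ERS
use coordinate-bearing germplasm only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geodata import BinaryRange, GridLayer

CATEGORY_ORDER = ("HPS", "MPS", "LPS", "NFCR")
# FPS band upper edges, half-open on the left except the first band
_BANDS = ((3.0, "HPS"), (5.0, "MPS"), (7.5, "LPS"), (10.0, "NFCR"))


@dataclass
class GapScores:
    taxon: str
    srs: float
    grs: float
    ers: float
    fps: float
    category: str

    def __post_init__(self):
        assert abs(self.fps - (self.srs + self.grs + self.ers) / 3.0) < 1e-9


def srs(n_g: int, n_h: int) -> float:
    """Sampling representativeness: 10 * n_G / (n_G + n_H)."""
    if n_g < 0 or n_h < 0:
        raise ValueError("record counts must be non-negative")
    if n_g + n_h == 0:
        raise ValueError("taxon has no records at all")
    return 10.0 * n_g / (n_g + n_h)


def grs(germplasm_buffers: BinaryRange | None, taxon_range: BinaryRange) -> float:
    """Geographic representativeness: covered fraction of the range by area.

    Area is cosine-latitude weighted; a taxon with no mappable germplasm
    scores 0.
    """
    if taxon_range.cell_count == 0:
        raise ValueError("empty taxon range")
    if germplasm_buffers is None:
        return 0.0
    taxon_range.require_aligned(germplasm_buffers, "range and germplasm buffers")
    inter = (taxon_range.values == 1.0) & (germplasm_buffers.values == 1.0)
    covered = float(taxon_range.cell_areas_km2()[inter].sum())
    return 10.0 * covered / taxon_range.area_km2


def ers(
    ecoregions: GridLayer,
    taxon_range: BinaryRange,
    germplasm_buffers: BinaryRange | None,
) -> float:
    """Ecological representativeness: covered fraction of ecoregion classes.

    Classes are counted by presence/absence within the range (and within
    buffers-intersect-range for the numerator), not area-weighted.
    """
    taxon_range.require_aligned(ecoregions, "range and ecoregions")
    in_range = taxon_range.values == 1.0
    range_classes = _classes(ecoregions, in_range)
    if not range_classes:
        raise ValueError("taxon range covers only nodata ecoregion cells")
    if germplasm_buffers is None:
        return 0.0
    taxon_range.require_aligned(germplasm_buffers, "range and germplasm buffers")
    covered = _classes(ecoregions, in_range & (germplasm_buffers.values == 1.0))
    return 10.0 * len(covered & range_classes) / len(range_classes)


def _classes(ecoregions: GridLayer, where: np.ndarray) -> set[int]:
    vals = ecoregions.values[where]
    vals = vals[~np.isnan(vals)]
    return set(int(v) for v in np.unique(vals))


def fps_classify(taxon: str, srs_v: float, grs_v: float, ers_v: float) -> GapScores:
    """Combine the three scores into an FPS and its priority band."""
    for name, v in (("SRS", srs_v), ("GRS", grs_v), ("ERS", ers_v)):
        if not 0.0 <= v <= 10.0:
            raise ValueError(f"{name} = {v} outside [0, 10]")
    fps = (srs_v + grs_v + ers_v) / 3.0
    for edge, cat in _BANDS:
        if fps <= edge + 1e-12:
            return GapScores(taxon, srs_v, grs_v, ers_v, fps, cat)
    return GapScores(taxon, srs_v, grs_v, ers_v, fps, "NFCR")


def collecting_gap_map(
    taxon_range: BinaryRange, germplasm_buffers: BinaryRange | None
) -> BinaryRange:
    """Cells of the distribution not yet within reach of a collection."""
    if germplasm_buffers is None:
        return taxon_range.copy_with(taxon_range.values.copy())
    taxon_range.require_aligned(germplasm_buffers, "range and germplasm buffers")
    vals = taxon_range.values.copy()
    vals[(taxon_range.values == 1.0) & (germplasm_buffers.values == 1.0)] = 0.0
    return taxon_range.copy_with(vals)


def hotspot_map(gap_maps: Sequence[BinaryRange]) -> GridLayer:
    """Cell-wise count of high-priority collecting gaps (hotspots).

    An empty input yields an all-zero map (no high-priority taxa means no
    hotspots), with the caller expected to warn.
    """
    maps = list(gap_maps)
    if not maps:
        raise ValueError("hotspot_map needs at least one gap map")
    base = maps[0]
    total = np.zeros(base.shape)
    for m in maps:
        base.require_aligned(m, "gap maps")
        total += np.nan_to_num(m.values, nan=0.0)
    return GridLayer(total, base.origin_lon, base.origin_lat, base.cell_size, base.nodata)


def priority_table(
    scores: Sequence[GapScores],
    expert_scores: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Collecting-priority listing: category blocks, most urgent first.

    Rows sort by category (HPS < MPS < LPS < NFCR), then ascending FPS,
    then taxon name; a ``category_pct`` column gives each category's share
    of all taxa.  Expert scores, if supplied, are joined untouched.
    """
    rows = []
    n = len(scores)
    counts = {c: sum(1 for s in scores if s.category == c) for c in CATEGORY_ORDER}
    for s in scores:
        row = {
            "taxon": s.taxon,
            "SRS": s.srs,
            "GRS": s.grs,
            "ERS": s.ers,
            "FPS": s.fps,
            "category": s.category,
            "category_pct": 100.0 * counts[s.category] / n,
        }
        if expert_scores is not None:
            row["EPS"] = expert_scores.get(s.taxon, np.nan)
        rows.append(row)
    df = pd.DataFrame(rows)
    df["_cat"] = df["category"].map({c: i for i, c in enumerate(CATEGORY_ORDER)})
    df = df.sort_values(["_cat", "FPS", "taxon"], kind="stable").drop(columns="_cat")
    return df.reset_index(drop=True)
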