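"""Pairwise geographic niche and range overlap.

Niche overlap compares two taxa's suitability surfaces (or binary ranges,
treated as uniform distributions) after normalising each to a probability
distribution over the shared valid cells:

* Schoener's D = 1 - 0.5 * sum |p - q|
* Hellinger's I = 1 - 0.5 * sum (sqrt(p) - sqrt(q))^2, which equals the
  Bhattacharyya coefficient sum sqrt(p q).

Both run from 0 (no overlap) to 1 (identical distributions), and D <= I
always.  Range overlap compares binary distributions by shared cell
counts: the Sørensen fraction 2|A∩B|/(|A|+|B|), the overlap relative to
the larger range |A∩B|/max, and relative to the smaller range |A∩B|/min.
A pair is sympatric when it shares at least one cell at the analysis
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geodata import BinaryRange, GridLayer

#: a pair is "sympatric" at >= this many shared cells
SYMPATRY_MIN_SHARED_CELLS = 1
#: Table-2-style summaries call an overlap "perfect" at >= 1 - this
PERFECT_OVERLAP_TOL = 1e-6

_NORM_TOL = 1e-9


def normalize_pair(
    surf_a: GridLayer, surf_b: GridLayer
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale two aligned surfaces to distributions over shared valid cells."""
    surf_a.require_aligned(surf_b, "overlap surfaces")
    shared = surf_a.valid_mask & surf_b.valid_mask
    a = surf_a.values[shared].astype(float)
    b = surf_b.values[shared].astype(float)
    if a.size == 0:
        raise ValueError("no shared valid cells")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("suitability values must be non-negative")
    ta, tb = a.sum(), b.sum()
    if ta <= 0 or tb <= 0:
        raise ValueError("a surface has zero total over the shared cells")
    return a / ta, b / tb


def _check_normalized(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    for name, v in (("p", p), ("q", q)):
        if np.any(v < -_NORM_TOL) or abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} is not a normalized distribution")
    return p, q


def schoener_d(p: np.ndarray, q: np.ndarray) -> float:
    """Schoener's D = 1 - 0.5 * sum |p - q|; 0 disjoint, 1 identical."""
    p, q = _check_normalized(p, q)
    return float(1.0 - 0.5 * np.abs(p - q).sum())


def hellinger_i(p: np.ndarray, q: np.ndarray) -> float:
    """Hellinger-based I = 1 - 0.5 * sum (sqrt p - sqrt q)^2.

    Algebraically the Bhattacharyya coefficient sum sqrt(p q); the
    subtraction form is computed here, the product form serves as an
    internal cross-check in the test suite.
    """
    p, q = _check_normalized(p, q)
    sp, sq = np.sqrt(np.clip(p, 0, None)), np.sqrt(np.clip(q, 0, None))
    return float(1.0 - 0.5 * np.square(sp - sq).sum())


@dataclass
class OverlapResult:
    """Niche and range overlap for one unordered taxon pair."""

    taxon_a: str
    taxon_b: str
    d: float
    i: float
    shared_cells: int
    sorensen: float
    frac_larger: float
    frac_smaller: float
    sympatric: bool


def range_overlap(range_a: BinaryRange, range_b: BinaryRange) -> dict:
    """Shared-cell statistics for two binary ranges."""
    range_a.require_aligned(range_b, "ranges")
    na, nb = range_a.cell_count, range_b.cell_count
    if na == 0 or nb == 0:
        raise ValueError("range overlap of an empty range is undefined")
    shared = int(((range_a.values == 1.0) & (range_b.values == 1.0)).sum())
    return {
        "shared_cells": shared,
        "sorensen": 2.0 * shared / (na + nb),
        "frac_larger": shared / max(na, nb),
        "frac_smaller": shared / min(na, nb),
        "sympatric": shared >= SYMPATRY_MIN_SHARED_CELLS,
    }


def pairwise_driver(
    ranges: Mapping[str, BinaryRange],
    surfaces: Mapping[str, GridLayer] | None = None,
) -> list[OverlapResult]:
    """All unordered taxon pairs, lexicographic, n(n-1)/2 results.

    Niche statistics use each taxon's suitability surface when provided
    and its binary range (a uniform distribution over presence cells)
    otherwise — mirroring model-passed vs buffer-fallback taxa.
    """
    if not isinstance(ranges, Mapping):
        items = list(ranges)
        names = [n for n, _ in items]
        if len(names) != len(set(names)):
            raise ValueError("duplicate taxon names")
        ranges = dict(items)
    names = list(ranges)
    if len(names) < 2:
        raise ValueError("need at least two taxa")
    names = sorted(names)
    surfaces = surfaces or {}

    def dist_layer(name: str) -> GridLayer:
        surf = surfaces.get(name)
        if surf is not None:
            return surf
        rng = ranges[name]
        # uniform over presence cells: zero elsewhere, keep nodata
        return rng.copy_with(rng.values)

    results = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            geo = range_overlap(ranges[a], ranges[b])
            p, q = normalize_pair(dist_layer(a), dist_layer(b))
            results.append(
                OverlapResult(
                    taxon_a=a,
                    taxon_b=b,
                    d=schoener_d(p, q),
                    i=hellinger_i(p, q),
                    **geo,
                )
            )
    return results


def overlap_summary(
    results: Sequence[OverlapResult],
    cohort_labels: Mapping[tuple[str, str], Sequence[str]] | None = None,
    perfect_tol: float = PERFECT_OVERLAP_TOL,
) -> pd.DataFrame:
    """Cohort percentages of perfect / substantial / divergent niche overlap.

    Per cohort: % of pairs with max(D, I) >= 1 - perfect_tol ("perfect",
    rule recorded in the table), % with D or I above 0.5, and % with D or
    I below 0.2 (divergent niches); inequalities are strict.  A pair's
    cohorts come from ``cohort_labels`` keyed by (taxon_a, taxon_b); every
    pair is always in cohort "all".
    """
    cohorts: dict[str, list[OverlapResult]] = {"all": list(results)}
    if cohort_labels:
        for r in results:
            for label in cohort_labels.get((r.taxon_a, r.taxon_b), ()):
                cohorts.setdefault(label, []).append(r)
    rows = []
    for label, rs in cohorts.items():
        if not rs:
            rows.append(
                {"cohort": label, "n_pairs": 0, "perfect_pct": np.nan,
                 "over_0.5_pct": np.nan, "under_0.2_pct": np.nan}
            )
            continue
        n = len(rs)
        perfect = sum(max(r.d, r.i) >= 1.0 - perfect_tol for r in rs)
        over = sum(r.d > 0.5 or r.i > 0.5 for r in rs)
        under = sum(r.d < 0.2 or r.i < 0.2 for r in rs)
        rows.append(
            {
                "cohort": label,
                "n_pairs": n,
                "perfect_pct": 100.0 * perfect / n,
                "over_0.5_pct": 100.0 * over / n,
                "under_0.2_pct": 100.0 * under / n,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["perfect_rule"] = f"max(D, I) >= 1 - {perfect_tol:g}"
    return df


def asymmetry_stat(results: Sequence[OverlapResult]) -> float:
    """Mean extra overlap of the smaller range, in percentage points.

    Over sympatric pairs, mean of (frac_smaller - frac_larger) * 100;
    NaN when no pair is sympatric.
    """
    diffs = [
        100.0 * (r.frac_smaller - r.frac_larger) for r in results if r.sympatric
    ]
    if not diffs:
        return float("nan")
    return float(np.mean(diffs))


def niche_range(values: Sequence[float]) -> tuple[float, float]:
    """Middle-90% interval of per-occurrence environmental values.

    The (5th, 95th) percentiles with linear interpolation between order
    statistics — the plotted niche breadth with 10% outliers trimmed.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("niche_range needs at least two finite values")
    low, high = np.percentile(vals, [5.0, 95.0])
    return float(low), float(high)
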