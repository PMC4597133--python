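"""Validation of suitability surfaces, ROC thresholding, and the fallback rule.

The distribution model itself (a maximum-entropy SDM in typical use) is
fitted elsewhere; this module judges any supplied suitability surface.
A model is accepted when all three conditions hold:

* ATAUC: the mean test AUC across the five cross-validation folds
  exceeds 0.7;
* STAUC: the sample standard deviation of the fold AUCs is below 0.15;
* ASD15: at least 10% of valid cells have an across-fold prediction
  standard deviation below 0.15.

Taxa whose model fails any condition fall back to the CA50 distribution:
the union of 50-km circular buffers around their occurrence points.

The printed ASD15 criterion above is unusually permissive; the stricter
variant common in the gap-analysis literature (at most 10% of cells with
SD above the cut) is available via ``asd_variant="strict"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .geodata import (
    BinaryRange,
    DEFAULT_BUFFER_KM,
    GridLayer,
    apply_exclusion_mask,
    circular_buffer_range,
)

# validation defaults
K_FOLDS = 5
BACKGROUND_N = 10_000
ATAUC_MIN = 0.7
STAUC_MAX = 0.15
ASD_CUT = 0.15
ASD_FRAC = 0.10


def check_suitability(layer: GridLayer) -> GridLayer:
    """Assert a layer is a suitability surface: valid values in [0, 1]."""
    vals = layer.values[layer.valid_mask]
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError("suitability values must lie in [0, 1]")
    return layer


def kfold_split(
    points: Sequence, k: int = K_FOLDS, seed: int = 0
) -> list[list]:
    """Random partition of points into k folds with sizes differing by <= 1."""
    pts = list(points)
    if len(pts) < k:
        raise ValueError(f"need at least {k} points for {k}-fold split, got {len(pts)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pts))
    folds: list[list] = [[] for _ in range(k)]
    for i, idx in enumerate(order):
        folds[i % k].append(pts[idx])
    return folds


def auc(pos_scores: Sequence[float], bg_scores: Sequence[float]) -> float:
    """Rank-based AUC: P(pos > bg) + 0.5 P(pos = bg).

    Equivalent to the Mann-Whitney U statistic normalised by the number
    of (presence, background) pairs; ties share credit.
    """
    pos = np.asarray(pos_scores, dtype=float)
    bg = np.asarray(bg_scores, dtype=float)
    if pos.size == 0 or bg.size == 0:
        raise ValueError("auc requires non-empty presence and background scores")
    if np.isnan(pos).any() or np.isnan(bg).any():
        raise ValueError("auc scores must be finite")
    ranks = rankdata(np.concatenate([pos, bg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * bg.size))


@dataclass
class ModelMetrics:
    """Cross-validation metrics and the accept/reject verdict for one model."""

    fold_aucs: tuple[float, ...]
    atauc: float
    stauc: float
    asd_low_fraction: float
    valid: bool

    @property
    def ATAUC(self) -> float:  # noqa: N802 - field-standard acronym
        return self.atauc

    @property
    def STAUC(self) -> float:  # noqa: N802
        return self.stauc


def validate_model(
    fold_surfaces: Sequence[GridLayer],
    test_folds: Sequence[Sequence[tuple[float, float]]],
    bg_scores: Sequence[float] | Sequence[Sequence[float]],
    atauc_min: float = ATAUC_MIN,
    stauc_max: float = STAUC_MAX,
    asd_cut: float = ASD_CUT,
    asd_frac: float = ASD_FRAC,
    asd_variant: str = "as_printed",
) -> ModelMetrics:
    """Score one model from its per-fold surfaces and held-out test folds.

    ``bg_scores`` is either one shared background score vector or one per
    fold.  Fold i's AUC compares surface i's values at fold i's held-out
    points against the background scores.
    """
    surfaces = list(fold_surfaces)
    if len(surfaces) != len(test_folds):
        raise ValueError("one test fold per fold surface required")
    base = surfaces[0]
    for s in surfaces[1:]:
        base.require_aligned(s, "fold surfaces")
    per_fold_bg = (
        list(bg_scores)
        if len(bg_scores) > 0 and isinstance(bg_scores[0], (list, tuple, np.ndarray))
        else [bg_scores] * len(surfaces)
    )
    fold_aucs = []
    for surf, fold, bg in zip(surfaces, test_folds, per_fold_bg):
        pos = extract_scores(surf, fold)
        fold_aucs.append(auc(pos, bg))
    fold_aucs = tuple(fold_aucs)
    atauc = float(np.mean(fold_aucs))
    stauc = float(np.std(fold_aucs, ddof=1)) if len(fold_aucs) > 1 else 0.0
    stack = np.stack([s.values for s in surfaces])
    valid_cells = ~np.isnan(stack).any(axis=0)
    if valid_cells.any():
        cell_sd = np.std(stack[:, valid_cells], axis=0, ddof=1)
        low = float(np.mean(cell_sd < asd_cut))
        high = float(np.mean(cell_sd > asd_cut))
    else:
        low, high = 0.0, 1.0
    if asd_variant == "as_printed":
        asd_ok = low >= asd_frac
    elif asd_variant == "strict":
        asd_ok = high <= asd_frac
    else:
        raise ValueError(f"unknown asd_variant {asd_variant!r}")
    valid = (atauc > atauc_min) and (stauc < stauc_max) and asd_ok
    return ModelMetrics(fold_aucs, atauc, stauc, low, valid)


def extract_scores(
    surface: GridLayer, points: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Surface values at the cells containing the points (nodata dropped)."""
    vals = []
    for lon, lat in points:
        cell = surface.cell_of(lon, lat)
        if cell is None:
            continue
        v = surface.values[cell]
        if not np.isnan(v):
            vals.append(v)
    return np.asarray(vals, dtype=float)


def roc_threshold(
    surface: GridLayer,
    presence_points: Sequence[tuple[float, float]],
    bg_scores: Sequence[float],
) -> float:
    """Threshold maximising sensitivity + specificity over observed values.

    Candidates are the union of presence and background score values; a
    cell counts as predicted presence when its value >= threshold.  Ties
    resolve to the lowest candidate (the most inclusive distribution).
    """
    pos = extract_scores(surface, presence_points)
    if pos.size == 0:
        raise ValueError("no presence point falls on a valid surface cell")
    bg = np.asarray(bg_scores, dtype=float)
    candidates = np.unique(np.concatenate([pos, bg]))
    best_t, best_score = None, -np.inf
    for t in candidates:  # ascending, so strict > keeps the lowest tie
        sens = np.mean(pos >= t)
        spec = np.mean(bg < t)
        score = sens + spec
        if score > best_score + 1e-12:
            best_score, best_t = score, float(t)
    return best_t


def binarize(surface: GridLayer, threshold: float) -> BinaryRange:
    """Presence where suitability >= threshold; nodata preserved."""
    vals = np.where(surface.values >= threshold, 1.0, 0.0)
    vals[np.isnan(surface.values)] = np.nan
    return BinaryRange.from_layer(surface, vals)


@dataclass
class RealizedRange:
    """A taxon's working distribution plus where it came from."""

    range: BinaryRange
    provenance: str  # "model" or "buffer"
    threshold: float | None = None
    metrics: ModelMetrics | None = None


def realized_range(
    surface: GridLayer | None = None,
    metrics: ModelMetrics | None = None,
    points: Sequence[tuple[float, float]] | None = None,
    bg_scores: Sequence[float] | None = None,
    template: GridLayer | None = None,
    exclusion_mask: BinaryRange | None = None,
    buffer_radius_km: float = DEFAULT_BUFFER_KM,
) -> RealizedRange:
    """Apply the valid-model-vs-buffer rule for one taxon.

    With a surface whose metrics pass validation, the distribution is the
    ROC-thresholded, exclusion-masked surface.  Otherwise (failed metrics,
    or no surface at all) it is the CA50 buffer union around the taxon's
    points.  Needing neither surface nor points is an error.
    """
    use_model = surface is not None and (metrics is None or metrics.valid)
    if use_model:
        if points is None or bg_scores is None:
            raise ValueError("thresholding a surface needs presence points and background scores")
        t = roc_threshold(surface, points, bg_scores)
        rng = binarize(surface, t)
        if exclusion_mask is not None:
            rng = BinaryRange.from_layer(rng, apply_exclusion_mask(rng, exclusion_mask).values)
        return RealizedRange(rng, "model", threshold=t, metrics=metrics)
    if points is None or len(points) == 0:
        raise ValueError("no valid surface and no coordinates: cannot build a range")
    tpl = template if template is not None else surface
    if tpl is None:
        raise ValueError("a template grid is required for the buffer fallback")
    rng = circular_buffer_range(points, buffer_radius_km, tpl)
    if exclusion_mask is not None:
        rng = BinaryRange.from_layer(rng, apply_exclusion_mask(rng, exclusion_mask).values)
    return RealizedRange(rng, "buffer", metrics=metrics)
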