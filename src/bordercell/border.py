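"""Firing-field segmentation and the border score.

The border score b = (cM - dm) / (cM + dm) contrasts how completely a single
firing field covers one wall (cM) with how far, on average, the cell's
firing sits from the nearest wall (dm, normalized to [0, 1] by the largest
possible wall distance, half the shorter arena side).  b approaches +1 for a
field hugging a full wall and -1 for a central field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .maps import RateMap
from .session import ArenaGeometry

__all__ = ["FieldSet", "BorderScoreResult", "segment_fields",
           "wall_coverage", "mean_firing_distance", "border_score",
           "wall_count"]

#: Fields are supra-threshold regions at this fraction of the map peak.
FIELD_THRESHOLD_FRAC = 0.3
#: Minimum firing-field area (cm^2).
MIN_FIELD_AREA_CM2 = 200.0
#: A wall counts as covered when some field spans this fraction of it.
WALL_COVERED_FRAC = 0.25


@dataclass
class FieldSet:
    """Connected supra-threshold firing fields on a rate-map grid.

    ``labels`` assigns every bin a field id (0 = background, 1..n_fields);
    fields are 4-connected components with area >= the minimum.
    """

    labels: np.ndarray
    n_fields: int
    bin_size: float
    threshold: float
    field_bins: list[np.ndarray] = field(default_factory=list)
    valid: np.ndarray | None = None   # visited bins of the source map

    def __len__(self) -> int:
        return self.n_fields

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class BorderScoreResult:
    cM: float
    dm: float
    b: float
    fields: FieldSet


def segment_fields(ratemap: RateMap,
                   threshold_frac: float = FIELD_THRESHOLD_FRAC,
                   min_area_cm2: float = MIN_FIELD_AREA_CM2) -> FieldSet:
    """4-connected components of bins with rate >= threshold_frac * peak.

    Components smaller than ``min_area_cm2`` are discarded.  An all-zero
    map yields an empty FieldSet.
    """
    rate = ratemap.rate
    peak = np.nanmax(rate) if np.any(np.isfinite(rate)) else 0.0
    bs = ratemap.bin_size
    valid = ratemap.valid
    if not peak > 0:
        return FieldSet(np.zeros(rate.shape, int), 0, bs, 0.0, valid=valid)
    thr = threshold_frac * peak
    mask = np.isfinite(rate) & (rate >= thr)
    labels, n = ndimage.label(mask)          # default structure = 4-conn
    min_bins = min_area_cm2 / bs ** 2
    keep = []
    for lab in range(1, n + 1):
        bins = np.flatnonzero(labels.ravel() == lab)
        if len(bins) >= min_bins:
            keep.append(bins)
        else:
            labels[labels == lab] = 0
    relabeled = np.zeros_like(labels)
    for new, bins in enumerate(keep, start=1):
        relabeled.ravel()[bins] = new
    return FieldSet(relabeled, len(keep), bs, thr, keep, valid=valid)


def _wall_line_bins(shape, arena: ArenaGeometry, bin_size: float):
    """Flat bin indices of the wall-adjacent line for each outer wall.

    Square-like arenas yield the four border rows/columns keyed by label;
    circles yield a single ring of bins whose centres lie within one bin
    width of the outer boundary, keyed "ring".
    """
    ny, nx = shape
    if arena.wall_labels:
        idx = np.arange(ny * nx).reshape(ny, nx)
        return {"N": idx[ny - 1, :], "E": idx[:, nx - 1],
                "S": idx[0, :], "W": idx[:, 0]}
    x0, y0 = arena.bounds[0], arena.bounds[1]
    cx = x0 + (np.arange(nx) + 0.5) * bin_size
    cy = y0 + (np.arange(ny) + 0.5) * bin_size
    X, Y = np.meshgrid(cx, cy)
    d, _, _ = arena.nearest_boundary(X.ravel(), Y.ravel(), which="outer")
    inside = arena.contains(X.ravel(), Y.ravel())
    return {"ring": np.flatnonzero((d <= bin_size) & inside)}


def wall_coverage(fields: FieldSet, arena: ArenaGeometry,
                  per_wall: bool = False):
    """Maximal fraction of a single wall covered by a single field (cM).

    Coverage of a wall by a field is the fraction of that wall's
    wall-adjacent bin line occupied by the field; bins the animal never
    visited are excluded from the denominator.  With ``per_wall=True``
    also returns {wall: best coverage by any single field}.
    """
    shape = fields.labels.shape
    lines = _wall_line_bins(shape, arena, fields.bin_size)
    flat = fields.labels.ravel()
    vflat = fields.valid.ravel() if fields.valid is not None else \
        np.ones(flat.shape, bool)
    best = {w: 0.0 for w in lines}
    for w, bins in lines.items():
        bins = bins[vflat[bins]]
        if len(bins) == 0:
            continue
        lab_on_line = flat[bins]
        for lab in range(1, fields.n_fields + 1):
            cov = np.mean(lab_on_line == lab)
            if cov > best[w]:
                best[w] = float(cov)
    cM = max(best.values()) if best else 0.0
    return (cM, best) if per_wall else cM


def _distance_grid(shape, arena: ArenaGeometry, bin_size: float):
    ny, nx = shape
    x0, y0 = arena.bounds[0], arena.bounds[1]
    cx = x0 + (np.arange(nx) + 0.5) * bin_size
    cy = y0 + (np.arange(ny) + 0.5) * bin_size
    X, Y = np.meshgrid(cx, cy)
    d, _, _ = arena.nearest_boundary(X.ravel(), Y.ravel(), which="outer")
    return d.reshape(shape)


def mean_firing_distance(ratemap: RateMap, arena: ArenaGeometry,
                         fields: FieldSet | None = None) -> float:
    """Rate-weighted mean distance of field firing to the nearest outer wall,
    normalized by half the shorter arena side (so dm is in [0, 1])."""
    if fields is None:
        fields = segment_fields(ratemap)
    if fields.n_fields == 0:
        return np.nan
    dist = _distance_grid(ratemap.rate.shape, arena, ratemap.bin_size)
    m = fields.mask & np.isfinite(ratemap.rate)
    w = ratemap.rate[m]
    if w.sum() <= 0:
        return np.nan
    dm = float(np.sum(w * dist[m]) / w.sum())
    return dm / (arena.shorter_side / 2.0)


def border_score(ratemap: RateMap, arena: ArenaGeometry,
                 threshold_frac: float = FIELD_THRESHOLD_FRAC,
                 min_area_cm2: float = MIN_FIELD_AREA_CM2
                 ) -> BorderScoreResult:
    """Border score b = (cM - dm) / (cM + dm), in [-1, 1].

    NaN when the map has no qualifying firing field.
    """
    fields = segment_fields(ratemap, threshold_frac, min_area_cm2)
    if fields.n_fields == 0:
        return BorderScoreResult(np.nan, np.nan, np.nan, fields)
    cM = wall_coverage(fields, arena)
    dm = mean_firing_distance(ratemap, arena, fields)
    if not np.isfinite(dm) or cM + dm <= 0:
        return BorderScoreResult(cM, dm, np.nan, fields)
    return BorderScoreResult(cM, dm, (cM - dm) / (cM + dm), fields)


def wall_count(fields: FieldSet, arena: ArenaGeometry,
               covered_frac: float = WALL_COVERED_FRAC) -> int:
    """Number of walls covered (fraction >= ``covered_frac``) by any field."""
    if fields.n_fields == 0:
        return 0
    _, best = wall_coverage(fields, arena, per_wall=True)
    return int(sum(cov >= covered_frac for cov in best.values()))
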