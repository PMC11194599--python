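"""Shuffled nulls, the border-cell gate, and subtype classification.

A unit is accepted as a border cell only if both its border score and its
split-half spatial stability exceed the 99th percentile of a pooled
population null built from circularly time-shifted spike trains.  Gated
border cells are then sorted into allocentric and left/right egocentric
subtypes from the ratio of their firing rates during clockwise versus
counterclockwise travel along the boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import chi2_contingency

from . import border as _border
from . import maps as _maps
from .ebr import egocentric_bearing
from .session import ArenaGeometry, SpikeTrain, TrajectorySession, \
    MIN_SPEED_CM_S, speed_filter

__all__ = [
    "NullDistribution", "CellReport", "circular_shift", "build_null",
    "gate_border", "binomial_ztest", "cw_ccw_ratio", "classify_subtype",
    "classify_waveform", "peak_to_trough_us", "lateralization_table",
    "ShuffleEngine",
]

log = logging.getLogger(__name__)

#: Shuffles per cell when building the pooled null.
N_SHUFFLES = 100
#: Minimum circular time shift (s).
MIN_SHIFT_S = 20.0
#: Percentile of the pooled null used as the classification threshold.
NULL_PERCENTILE = 99.0
#: Subtype thresholds on fr_cw/ccw.
EGO_RATIO_HIGH = 2.0
EGO_RATIO_LOW = 0.5
#: Fast-spiking criteria: mean rate (Hz) and peak-to-trough width (µs).
FS_RATE_HZ = 5.0
FS_WIDTH_US = 300.0


@dataclass
class NullDistribution:
    """Pooled shuffled border scores and stabilities with 99th percentiles."""

    border_scores: np.ndarray
    stabilities: np.ndarray
    p99_border: float
    p99_stability: float
    n_shuffles_per_cell: int


@dataclass
class CellReport:
    """Per-unit metrics and gate outcomes assembled by the pipeline."""

    unit_id: str
    border_score: float = np.nan
    cM: float = np.nan
    dm: float = np.nan
    stability: float = np.nan
    is_border: bool = False
    subtype: str = "nonborder"
    fr_cw_ccw: float = np.nan
    time_cw_ccw: float = np.nan
    ebr_mvl: float = np.nan
    ebr_pref_angle: float = np.nan
    mean_rate: float = np.nan
    peak_rate: float = np.nan
    n_walls: int = 0
    tri: float = np.nan
    theta_peak_hz: float = np.nan
    is_theta: bool = False
    cell_class: str = "unclassified"
    hemisphere: str = "unknown"


# --------------------------------------------------------------------------
# Circular-shift shuffling
# --------------------------------------------------------------------------

def circular_shift(spike_times, duration: float, rng=None,
                   min_shift: float = MIN_SHIFT_S, t0: float = 0.0,
                   shift: float | None = None) -> np.ndarray:
    """Shift all spike times by one random offset, wrapping at ``duration``.

    The offset is drawn uniformly from [min_shift, duration - min_shift]
    unless ``shift`` is given explicitly.  Spike count and all inter-spike
    intervals except the one at the wrap point are preserved.
    """
    if shift is None:
        if duration <= 2 * min_shift:
            raise ValueError("session too short for the requested min_shift")
        rng = np.random.default_rng(rng)
        shift = rng.uniform(min_shift, duration - min_shift)
    st = np.asarray(spike_times, dtype=float)
    return np.sort(t0 + np.mod(st - t0 + shift, duration))


class ShuffleEngine:
    """Fast border-score + stability evaluation for many spike trains.

    Precomputes everything that depends only on the session (speed mask,
    per-sample spatial bin, smoothed occupancy for the full session and for
    each temporal half, wall-distance grid) so that scoring one spike train
    costs a histogram, three small Gaussian filters and a labelling pass.
    """

    def __init__(self, session: TrajectorySession,
                 arena: ArenaGeometry | None = None,
                 bin_size: float = _maps.BIN_SIZE_CM,
                 sigma_bins: float = _maps.SIGMA_BINS,
                 min_speed: float = MIN_SPEED_CM_S,
                 threshold_frac: float = _border.FIELD_THRESHOLD_FRAC,
                 min_area_cm2: float = _border.MIN_FIELD_AREA_CM2):
        self.session = session
        self.arena = arena or session.arena
        self.bin_size = bin_size
        self.sigma_bins = sigma_bins
        self.threshold_frac = threshold_frac
        self.min_area_cm2 = min_area_cm2
        self.mask, _ = speed_filter(session, np.empty(0), min_speed)
        iy, ix, self.shape, _ = _maps._bin_indices(session, bin_size)
        self.flat_bin = iy * self.shape[1] + ix
        t_mid = session.t0 + session.duration / 2.0
        self.halves = (self.mask & (session.t < t_mid),
                       self.mask & (session.t >= t_mid))
        self.occ = _maps.occupancy_map(session, bin_size, self.mask)
        self.occ_halves = tuple(
            _maps.occupancy_map(session, bin_size, h) for h in self.halves)
        self.dist_norm = _border._distance_grid(
            self.shape, self.arena, bin_size) / (self.arena.shorter_side / 2)
        lines = _border._wall_line_bins(self.shape, self.arena, bin_size)
        vflat = self.occ.valid.ravel()
        self.wall_lines = {w: b[vflat[b]] for w, b in lines.items()
                           if vflat[b].any()}
        self.min_bins = min_area_cm2 / bin_size ** 2

    def _ratemap(self, spike_samples, occ):
        counts = np.bincount(
            self.flat_bin[spike_samples],
            minlength=self.shape[0] * self.shape[1]
        ).astype(float).reshape(self.shape)
        return _maps._smooth_and_divide(counts, occ, self.sigma_bins)

    def score(self, spike_times: np.ndarray) -> tuple[float, float]:
        """(border score, split-half stability) for one spike train."""
        s = self.session
        st = np.asarray(spike_times, dtype=float)
        j = s.spike_sample_index(st) if st.size else np.empty(0, int)
        j = j[self.mask[j]] if st.size else j
        rate = self._ratemap(j, self.occ)
        b = self._border_score(rate)
        half_maps = []
        for h, occ_h in zip(self.halves, self.occ_halves):
            jh = j[h[j]] if len(j) else j
            half_maps.append(self._ratemap(jh, occ_h))
        va = self.occ_halves[0].valid & np.isfinite(half_maps[0])
        vb = self.occ_halves[1].valid & np.isfinite(half_maps[1])
        stab = _maps.spatial_correlation(
            np.where(va, half_maps[0], np.nan),
            np.where(vb, half_maps[1], np.nan))
        return b, stab

    def _border_score(self, rate: np.ndarray) -> float:
        peak = np.nanmax(rate) if np.any(np.isfinite(rate)) else 0.0
        if not peak > 0:
            return np.nan
        m = np.isfinite(rate) & (rate >= self.threshold_frac * peak)
        labels, n = ndimage.label(m)
        if n == 0:
            return np.nan
        sizes = np.bincount(labels.ravel())[1:]
        keep = np.flatnonzero(sizes >= self.min_bins) + 1
        if len(keep) == 0:
            return np.nan
        fmask = np.isin(labels, keep)
        flat = labels.ravel()
        cM = 0.0
        for bins in self.wall_lines.values():
            line = flat[bins]
            for lab in keep:
                cM = max(cM, float(np.mean(line == lab)))
        w = rate.ravel()[fmask.ravel()]
        dm = float(np.sum(w * self.dist_norm.ravel()[fmask.ravel()])
                   / w.sum())
        if cM + dm <= 0:
            return np.nan
        return (cM - dm) / (cM + dm)


def build_null(sessions, cells: Sequence[SpikeTrain],
               n_shuffles: int = N_SHUFFLES, rng=None,
               min_shift: float = MIN_SHIFT_S,
               engines: Sequence[ShuffleEngine] | None = None,
               **engine_kwargs) -> NullDistribution:
    """Pooled null of border scores and stabilities from circular shifts.

    ``sessions`` is either one TrajectorySession shared by all cells or a
    sequence parallel to ``cells``.  Both statistics are computed from the
    same shuffle draw so the joint gate sees matched nulls.  Cells whose
    shuffles fail (e.g. empty trains) are skipped with a log message.
    """
    rng = np.random.default_rng(rng)
    if isinstance(sessions, TrajectorySession):
        sessions = [sessions] * len(cells)
    if engines is None:
        cache: dict[int, ShuffleEngine] = {}
        engines = []
        for s in sessions:
            if id(s) not in cache:
                cache[id(s)] = ShuffleEngine(s, **engine_kwargs)
            engines.append(cache[id(s)])
    scores, stabs = [], []
    for cell, s, eng in zip(cells, sessions, engines):
        try:
            for _ in range(n_shuffles):
                shifted = circular_shift(cell.spike_times, s.duration,
                                         rng, min_shift, t0=s.t0)
                b, st = eng.score(shifted)
                scores.append(b)
                stabs.append(st)
        except ValueError as e:
            log.warning("skipping unit %s in null: %s", cell.unit_id, e)
    scores = np.asarray(scores)
    stabs = np.asarray(stabs)
    if not len(scores):
        raise ValueError("no cells contributed to the null distribution")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p99b = float(np.nanpercentile(scores, NULL_PERCENTILE))
        p99s = float(np.nanpercentile(stabs, NULL_PERCENTILE))
    return NullDistribution(scores, stabs, p99b, p99s, n_shuffles)


def gate_border(border_score: float, stability: float,
                null: NullDistribution) -> bool:
    """Strictly exceed the 99th-percentile null on both statistics."""
    if not (np.isfinite(border_score) and np.isfinite(stability)):
        return False
    return bool(border_score > null.p99_border
                and stability > null.p99_stability)


def binomial_ztest(k: int, n: int, p0: float) -> float:
    """Normal-approximation binomial z, no continuity correction."""
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if n <= 0:
        raise ValueError("n must be positive")
    return (k - n * p0) / np.sqrt(n * p0 * (1 - p0))


# --------------------------------------------------------------------------
# CW/CCW classification
# --------------------------------------------------------------------------

class CwCcwResult(NamedTuple):
    fr_ratio: float
    time_ratio: float
    cw_time: float
    ccw_time: float
    cw_spikes: int
    ccw_spikes: int


def _rotation_cw(session: TrajectorySession, arena: ArenaGeometry,
                 features: str) -> np.ndarray:
    """CW labels from the tangential sense of the heading about the feature.

    For the outer walls the reference point is the arena centre (the animal
    is inside the boundary); for an object it is the object centroid (the
    animal is outside).  Heading with a clockwise tangential component about
    the reference is labelled CW.
    """
    if features == "walls":
        xmin, ymin, xmax, ymax = arena.bounds
        refs = np.array([[(xmin + xmax) / 2, (ymin + ymax) / 2]])
        ref_idx = np.zeros(session.n_samples, int)
    else:
        idx = arena._segment_indices("objects")
        names = [n for n in arena.features if n.startswith("object")]
        cents = np.array([arena.segments[arena.features[n]][:, 0].mean(0)
                          for n in names])
        _, _, seg = arena.nearest_boundary(session.x, session.y,
                                           which="objects")
        seg_to_obj = np.zeros(int(idx.max()) + 1, int)
        for k, n in enumerate(names):
            seg_to_obj[arena.features[n]] = k
        refs, ref_idx = cents, seg_to_obj[seg]
    rx = session.x - refs[ref_idx, 0]
    ry = session.y - refs[ref_idx, 1]
    hx = np.cos(np.deg2rad(session.hd))
    hy = np.sin(np.deg2rad(session.hd))
    return (rx * hy - ry * hx) < 0      # negative angular sense = CW


def cw_ccw_ratio(session: TrajectorySession, spikes,
                 arena: ArenaGeometry | None = None,
                 band_cm: float = _maps.WALL_BAND_CM,
                 mask: np.ndarray | None = None,
                 features: str = "walls",
                 label_by: str = "bearing") -> CwCcwResult:
    """Firing-rate and dwell-time ratios for CW vs CCW boundary travel.

    Samples within ``band_cm`` of the selected boundary features are
    labelled CW when the egocentric bearing of the nearest boundary point
    is in (0, 180) deg — boundary on the left, which along the outer walls
    is clockwise perimeter travel (``label_by="bearing"``) — or by the
    rotational sense of the heading about the feature
    (``label_by="rotation"``; this is the labelling that flips sign around
    interior objects relative to the enclosing walls).
    """
    if arena is None:
        arena = session.arena
    st = spikes.spike_times if isinstance(spikes, SpikeTrain) else \
        np.asarray(spikes, dtype=float)
    if mask is None:
        mask = session.valid
    which = "outer" if features == "walls" else "objects"
    bearing, dist = egocentric_bearing(session, arena, which=which)
    in_band = mask & (dist <= band_cm)
    if features == "walls":
        d_all, _, _ = arena.nearest_boundary(session.x, session.y, "all")
        in_band &= dist <= d_all + 1e-9    # outer wall must be the nearest
    if label_by == "bearing":
        cw = (bearing > 0) & (bearing < 180)
    elif label_by == "rotation":
        cw = _rotation_cw(session, arena, features)
    else:
        raise ValueError("label_by must be 'bearing' or 'rotation'")
    cw_mask = in_band & cw
    ccw_mask = in_band & ~cw
    t_cw = cw_mask.sum() * session.dt
    t_ccw = ccw_mask.sum() * session.dt
    if st.size:
        j = session.spike_sample_index(st)
        n_cw = int(cw_mask[j].sum())
        n_ccw = int(ccw_mask[j].sum())
    else:
        n_cw = n_ccw = 0
    if t_cw == 0 or t_ccw == 0:
        warnings.warn("a CW/CCW band label has no dwell time; ratios "
                      "undefined", stacklevel=2)
        return CwCcwResult(np.nan, np.nan, t_cw, t_ccw, n_cw, n_ccw)
    time_ratio = t_cw / t_ccw
    r_cw = n_cw / t_cw
    r_ccw = n_ccw / t_ccw
    if r_ccw == 0:
        fr = np.inf if r_cw > 0 else np.nan
    else:
        fr = r_cw / r_ccw
    return CwCcwResult(fr, time_ratio, t_cw, t_ccw, n_cw, n_ccw)


def classify_subtype(fr_ratio: float) -> str:
    """Map fr_cw/ccw to a subtype label.

    Ratio > 2 -> left egocentric (fires with the boundary on the left);
    < 0.5 -> right egocentric; otherwise (including exactly 0.5 or 2)
    allocentric.  Applies only to units that passed the border gate.
    """
    if not np.isfinite(fr_ratio):
        if np.isposinf(fr_ratio):
            return "left_ego"
        warnings.warn("fr_cw/ccw is NaN; defaulting to allocentric",
                      stacklevel=2)
        return "allocentric"
    if fr_ratio > EGO_RATIO_HIGH:
        return "left_ego"
    if fr_ratio < EGO_RATIO_LOW:
        return "right_ego"
    return "allocentric"


# --------------------------------------------------------------------------
# Waveform class and lateralization
# --------------------------------------------------------------------------

def peak_to_trough_us(waveform: np.ndarray, sample_rate_hz: float) -> float:
    """Peak-to-trough width (µs) on the largest-amplitude channel."""
    w = np.atleast_2d(np.asarray(waveform, dtype=float))
    ch = int(np.argmax(np.nanmax(w, axis=1) - np.nanmin(w, axis=1)))
    tr = w[ch]
    return abs(int(np.nanargmin(tr)) - int(np.nanargmax(tr))) \
        / sample_rate_hz * 1e6


def classify_waveform(mean_rate: float,
                      peak_to_trough: float | None) -> str:
    """RS/FS split: FS iff rate > 5 Hz and width < 300 µs; RS iff rate
    <= 5 Hz and width >= 300 µs; anything else (or no waveform) is
    unclassified."""
    if peak_to_trough is None or not np.isfinite(peak_to_trough):
        return "unclassified"
    fs = mean_rate > FS_RATE_HZ and peak_to_trough < FS_WIDTH_US
    rs = mean_rate <= FS_RATE_HZ and peak_to_trough >= FS_WIDTH_US
    return "FS" if fs else ("RS" if rs else "unclassified")


def lateralization_table(reports: Sequence[CellReport]):
    """2x2 counts of left/right egocentric cells by hemisphere + chi-square.

    Returns (table, chi2) where ``table[i][j]`` counts subtype i
    (left_ego, right_ego) in hemisphere j (left, right); the statistic is
    Pearson's chi-square without continuity correction, NaN (with a
    warning) when any expected count is zero.
    """
    table = np.zeros((2, 2), dtype=int)
    for r in reports:
        if r.subtype in ("left_ego", "right_ego") and \
                r.hemisphere in ("left", "right"):
            table[("left_ego", "right_ego").index(r.subtype),
                  ("left", "right").index(r.hemisphere)] += 1
    row = table.sum(1)
    col = table.sum(0)
    if table.sum() == 0 or np.any(np.outer(row, col) == 0):
        warnings.warn("zero expected count in lateralization table",
                      stacklevel=2)
        return table, np.nan
    chi2 = chi2_contingency(table, correction=False).statistic
    return table, float(chi2)
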