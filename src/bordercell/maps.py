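"""Occupancy and firing-rate maps, spatial correlations, directional tuning.

Rate maps follow the usual open-field recipe: spikes and dwell time are
binned on the same grid, both grids are smoothed with the same Gaussian
kernel, and the smoothed counts are divided by the smoothed occupancy.
Smoothing the numerator and denominator separately keeps the estimate
unbiased in sparsely-visited bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .session import ArenaGeometry, SpikeTrain, TrajectorySession

__all__ = [
    "OccupancyMap", "RateMap", "HDTuningCurve",
    "occupancy_map", "rate_map", "spatial_correlation",
    "split_half_stability", "rate_occupancy_correlation",
    "hd_tuning_curve", "wall_band_mask", "per_wall_tuning",
    "mean_vector",
]

#: Spatial bin size (cm) shared by occupancy and rate maps.
BIN_SIZE_CM = 2.5
#: Gaussian smoothing sigma for 2D maps, in bins.
SIGMA_BINS = 2.0
#: Minimum dwell (s) for a spatial bin to count as visited.
MIN_DWELL_S = 0.02
#: Angular bin width (deg) for head-direction tuning curves.
HD_BIN_DEG = 6.0
#: Circular Gaussian smoothing sigma (bins) for head-direction curves.
HD_SIGMA_BINS = 1.0
#: Width (cm) of the boundary-adjacent band used for per-wall analyses.
WALL_BAND_CM = 15.0
#: Minimum number of jointly valid bins for a spatial correlation.
MIN_SHARED_BINS = 20


@dataclass
class OccupancyMap:
    """Dwell time (s) per spatial bin; row index increases with y."""

    grid: np.ndarray
    bin_size: float
    valid: np.ndarray
    origin: tuple[float, float]
    total_time: float

    @property
    def shape(self):
        return self.grid.shape


@dataclass
class RateMap:
    """Smoothed firing-rate grid (Hz) with its raw ingredients."""

    rate: np.ndarray
    counts: np.ndarray            # unsmoothed spike counts
    occupancy: OccupancyMap
    sigma_bins: float
    peak_rate: float
    mean_rate: float

    @property
    def bin_size(self) -> float:
        return self.occupancy.bin_size

    @property
    def valid(self) -> np.ndarray:
        return self.occupancy.valid


@dataclass
class HDTuningCurve:
    """Firing rate vs head direction with circular summary statistics."""

    bin_centers: np.ndarray       # deg
    rate: np.ndarray              # Hz, NaN where unoccupied
    occupancy_s: np.ndarray
    mvl: float
    preferred_dir: float          # deg in [0, 360)

    @property
    def peak_dir(self) -> float:
        """Centre of the angular bin with the highest rate."""
        if np.all(np.isnan(self.rate)):
            return np.nan
        return float(self.bin_centers[np.nanargmax(self.rate)])

    @property
    def peak_rate(self) -> float:
        return float(np.nanmax(self.rate)) if np.any(
            np.isfinite(self.rate)) else np.nan


def _grid_geometry(arena: ArenaGeometry, bin_size: float):
    xmin, ymin, xmax, ymax = arena.bounds
    nx = int(np.ceil((xmax - xmin) / bin_size - 1e-9))
    ny = int(np.ceil((ymax - ymin) / bin_size - 1e-9))
    return (xmin, ymin), nx, ny


def _bin_indices(session: TrajectorySession, bin_size: float):
    (x0, y0), nx, ny = _grid_geometry(session.arena, bin_size)
    ix = np.clip(((session.x - x0) / bin_size).astype(int), 0, nx - 1)
    iy = np.clip(((session.y - y0) / bin_size).astype(int), 0, ny - 1)
    return iy, ix, (ny, nx), (x0, y0)


def occupancy_map(session: TrajectorySession, bin_size: float = BIN_SIZE_CM,
                  mask: np.ndarray | None = None,
                  min_dwell_s: float = MIN_DWELL_S) -> OccupancyMap:
    """Dwell seconds per spatial bin for the retained samples."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if mask is None:
        mask = session.valid
    iy, ix, shape, origin = _bin_indices(session, bin_size)
    flat = np.bincount(iy[mask] * shape[1] + ix[mask],
                       minlength=shape[0] * shape[1]).astype(float)
    grid = flat.reshape(shape) * session.dt
    return OccupancyMap(grid, bin_size, grid >= min_dwell_s, origin,
                        float(mask.sum() * session.dt))


def rate_map(session: TrajectorySession, spikes, bin_size: float = BIN_SIZE_CM,
             sigma_bins: float = SIGMA_BINS, mask: np.ndarray | None = None,
             occupancy: OccupancyMap | None = None) -> RateMap:
    """2D firing-rate map: smoothed spike counts / smoothed dwell time.

    ``spikes`` may be a SpikeTrain or an array of spike times; spike
    positions are those of the nearest-in-time tracking sample.  Spikes
    falling on masked-out samples are excluded.
    """
    st = spikes.spike_times if isinstance(spikes, SpikeTrain) else \
        np.asarray(spikes, dtype=float)
    if mask is None:
        mask = session.valid
    if occupancy is None:
        occupancy = occupancy_map(session, bin_size, mask)
    if not occupancy.valid.any():
        raise ValueError("no valid occupancy bins")
    iy, ix, shape, _ = _bin_indices(session, occupancy.bin_size)
    if st.size:
        j = session.spike_sample_index(st)
        j = j[mask[j]]
        counts = np.bincount(iy[j] * shape[1] + ix[j],
                             minlength=shape[0] * shape[1]).astype(float)
        counts = counts.reshape(shape)
    else:
        counts = np.zeros(shape)
    rate = _smooth_and_divide(counts, occupancy, sigma_bins)
    mean_rate = counts.sum() / occupancy.total_time
    peak = float(np.nanmax(rate)) if np.any(np.isfinite(rate)) else np.nan
    return RateMap(rate, counts, occupancy, sigma_bins, peak, mean_rate)


def _smooth_and_divide(counts: np.ndarray, occupancy: OccupancyMap,
                       sigma_bins: float) -> np.ndarray:
    # 'reflect' boundary keeps the kernel mass (and hence the spike count
    # and total dwell) inside the grid.
    if sigma_bins > 0:
        sc = gaussian_filter(counts, sigma_bins, mode="reflect")
        so = gaussian_filter(occupancy.grid, sigma_bins, mode="reflect")
    else:
        sc, so = counts, occupancy.grid
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = sc / so
    rate[~occupancy.valid | (so <= 0)] = np.nan
    return rate


def _as_grid(m) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(m, RateMap):
        return m.rate, m.valid
    if isinstance(m, OccupancyMap):
        return m.grid, m.valid
    a = np.asarray(m, dtype=float)
    return a, np.isfinite(a)


def spatial_correlation(map_a, map_b) -> float:
    """Pearson correlation across bins valid in both maps.

    Returns NaN when fewer than ``MIN_SHARED_BINS`` bins are shared or a
    map is constant over the shared bins.
    """
    a, va = _as_grid(map_a)
    b, vb = _as_grid(map_b)
    if a.shape != b.shape:
        raise ValueError("maps have different grid shapes")
    both = va & vb & np.isfinite(a) & np.isfinite(b)
    if both.sum() < MIN_SHARED_BINS:
        return np.nan
    av, bv = a[both], b[both]
    if av.std() == 0 or bv.std() == 0:
        return np.nan
    return float(np.corrcoef(av, bv)[0, 1])


def split_half_stability(session: TrajectorySession, spikes,
                         bin_size: float = BIN_SIZE_CM,
                         sigma_bins: float = SIGMA_BINS,
                         mask: np.ndarray | None = None) -> float:
    """Spatial correlation between first- and second-half rate maps."""
    if session.duration < 120:
        raise ValueError("session shorter than 2 min")
    st = spikes.spike_times if isinstance(spikes, SpikeTrain) else \
        np.asarray(spikes, dtype=float)
    if mask is None:
        mask = session.valid
    t_mid = session.t0 + session.duration / 2.0
    first = mask & (session.t < t_mid)
    second = mask & (session.t >= t_mid)
    maps = [rate_map(session, st[(st < t_mid) if k == 0 else (st >= t_mid)],
                     bin_size, sigma_bins, mask=half)
            for k, half in enumerate((first, second))]
    return spatial_correlation(*maps)


def rate_occupancy_correlation(ratemap: RateMap,
                               occupancy: OccupancyMap | None = None) -> float:
    """Correlation between a rate map and its occupancy map.

    Near-zero values indicate the spatial tuning is not an artifact of
    uneven dwell-time coverage.
    """
    if occupancy is None:
        occupancy = ratemap.occupancy
    if ratemap.rate.shape != occupancy.grid.shape:
        raise ValueError("rate and occupancy grids differ in shape")
    return spatial_correlation(ratemap, occupancy)


def mean_vector(angles_deg: np.ndarray, weights: np.ndarray
                ) -> tuple[float, float]:
    """Weighted circular mean: returns (mvl, direction deg in [0, 360))."""
    w = np.asarray(weights, dtype=float)
    ok = np.isfinite(w)
    if not ok.any() or w[ok].sum() <= 0:
        return np.nan, np.nan
    th = np.deg2rad(np.asarray(angles_deg, dtype=float)[ok])
    z = np.sum(w[ok] * np.exp(1j * th)) / w[ok].sum()
    return float(np.abs(z)), float(np.mod(np.rad2deg(np.angle(z)), 360.0))


def hd_tuning_curve(session: TrajectorySession, spikes,
                    bin_deg: float = HD_BIN_DEG,
                    mask: np.ndarray | None = None,
                    sigma_bins: float = HD_SIGMA_BINS) -> HDTuningCurve:
    """Firing rate per head-direction bin, with mean vector length.

    Counts and angular dwell are smoothed with a wrapped Gaussian
    (``sigma_bins``) before division, suppressing spurious peaks in bins
    the animal barely sampled.  The MVL weights each occupied bin's unit
    vector by its firing rate: ``|sum r_k exp(i theta_k)| / sum r_k``;
    unoccupied bins are excluded.
    """
    st = spikes.spike_times if isinstance(spikes, SpikeTrain) else \
        np.asarray(spikes, dtype=float)
    if mask is None:
        mask = session.valid
    nb = int(round(360.0 / bin_deg))
    edges = np.linspace(0, 360, nb + 1)
    centers = edges[:-1] + bin_deg / 2.0
    hd_bin = np.clip((session.hd / bin_deg).astype(int), 0, nb - 1)
    occ = np.bincount(hd_bin[mask], minlength=nb) * session.dt
    if st.size:
        j = session.spike_sample_index(st)
        j = j[mask[j]]
        cnt = np.bincount(hd_bin[j], minlength=nb).astype(float)
    else:
        cnt = np.zeros(nb)
    if sigma_bins > 0:
        s_occ = gaussian_filter(occ, sigma_bins, mode="wrap")
        s_cnt = gaussian_filter(cnt, sigma_bins, mode="wrap")
    else:
        s_occ, s_cnt = occ, cnt
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = s_cnt / s_occ
    rate[s_occ <= 0] = np.nan
    mvl, pref = mean_vector(centers, rate)
    return HDTuningCurve(centers, rate, occ, mvl, pref)


# --------------------------------------------------------------------------
# Per-wall analyses
# --------------------------------------------------------------------------

_WALL_ORDER = ("N", "E", "S", "W")


def _nearest_wall_labels(session: TrajectorySession, arena: ArenaGeometry):
    """Distance to each labeled wall and the per-sample nearest label.

    Exact ties are broken in the fixed order N, E, S, W.
    """
    labels = [w for w in _WALL_ORDER if w in arena.wall_labels]
    if not labels:
        raise ValueError("arena has no labeled outer walls")
    P = np.column_stack([session.x, session.y])
    dists = np.empty((len(labels), len(P)))
    for k, lab in enumerate(labels):
        i = arena.wall_labels[lab]
        A, B = arena.segments[i]
        E = B - A
        t = np.clip((P - A) @ E / (E @ E), 0, 1)
        dists[k] = np.linalg.norm(P - (A + t[:, None] * E), axis=1)
    nearest = np.argmin(dists, axis=0)   # first occurrence wins ties
    return labels, dists, nearest


def wall_band_mask(session: TrajectorySession, arena: ArenaGeometry,
                   wall: str, band_cm: float = WALL_BAND_CM) -> np.ndarray:
    """Samples within ``band_cm`` of the labeled wall, nearest to that wall."""
    if wall not in arena.wall_labels:
        raise ValueError(f"unknown wall label {wall!r}")
    labels, dists, nearest = _nearest_wall_labels(session, arena)
    k = labels.index(wall)
    return (nearest == k) & (dists[k] <= band_cm)


def per_wall_tuning(session: TrajectorySession, spikes,
                    arena: ArenaGeometry | None = None,
                    band_cm: float = WALL_BAND_CM,
                    bin_deg: float = HD_BIN_DEG,
                    mask: np.ndarray | None = None) -> list[dict]:
    """Head-direction tuning restricted to each wall's boundary band.

    Returns one record per labeled wall with the tuning curve, its MVL and
    its peak direction.  For egocentric cells the peak directions advance in
    ~90 deg steps around the four walls of a square arena; for allocentric
    cells bidirectional firing along each wall cancels, giving low MVLs.
    """
    if arena is None:
        arena = session.arena
    if mask is None:
        mask = session.valid
    out = []
    for wall in (w for w in _WALL_ORDER if w in arena.wall_labels):
        band = wall_band_mask(session, arena, wall, band_cm) & mask
        if not band.any():
            continue
        curve = hd_tuning_curve(session, spikes, bin_deg, mask=band)
        out.append({"wall": wall, "curve": curve, "mvl": curve.mvl,
                    "peak_dir": curve.peak_dir})
    if not out:
        raise ValueError("no occupied wall bands")
    return out


def export_grid(path, grid: np.ndarray, bin_size: float,
                origin: tuple[float, float], **meta) -> None:
    """Write a 2D grid as delimited text with a metadata header."""
    items = {"bin_size_cm": bin_size, "origin_x": origin[0],
             "origin_y": origin[1], **meta}
    header = ", ".join(f"{k}={v}" for k, v in items.items())
    np.savetxt(path, grid, fmt="%.8g", delimiter=",", header=header)
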