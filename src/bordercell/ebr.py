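"""Egocentric boundary ratemaps (EBRs) by raycasting to the arena boundary.

For every retained video frame a fan of rays is cast from the animal's
position at each egocentric angle (3 deg steps across 360 deg, measured CCW
from the reference direction so that +90 deg is the animal's left).  The
distance at which each ray first meets a boundary segment is binned at
2.5 cm, accumulating dwell time; the same procedure at spike times
accumulates spike counts, and dividing (smoothed) spikes by (smoothed)
occupancy yields a polar firing-rate map over boundary bearing x distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .maps import mean_vector
from .session import ArenaGeometry, SpikeTrain, TrajectorySession

__all__ = ["EgocentricBoundaryRatemap", "ray_boundary_distance",
           "egocentric_boundary_ratemap", "ebr_mean_vector",
           "ebr_reference_comparison", "egocentric_bearing",
           "movement_direction"]

#: Egocentric angle bin width (deg): 120 bins across 360 deg.
EBR_ANGLE_BIN_DEG = 3.0
#: Radial bin width (cm).
EBR_DIST_BIN_CM = 2.5
#: Maximum boundary distance considered (cm).
EBR_MAX_DIST_CM = 50.0
#: Gaussian smoothing sigma (bins) applied in (angle, distance).
EBR_SIGMA_BINS = 1.0


@dataclass
class EgocentricBoundaryRatemap:
    """Polar (bearing x distance) occupancy, spike and rate arrays.

    Axis 0 is the egocentric angle (bin centres ``angles``), axis 1 the
    boundary distance (bin lower edges ``distances``).  0 deg means a
    boundary directly ahead, 90 deg on the left, 270 deg on the right.
    """

    occupancy: np.ndarray      # seconds
    spikes: np.ndarray         # counts
    rate: np.ndarray           # Hz, NaN where unoccupied
    angles: np.ndarray         # deg, bin centres
    distances: np.ndarray      # cm, bin lower edges
    reference: str             # {"head", "movement"}
    mvl: float
    pref_angle: float


def ray_boundary_distance(pos, allocentric_angle_deg,
                          arena: ArenaGeometry,
                          max_dist: float | None = None):
    """Distance from ``pos`` along the given allocentric direction to the
    first boundary segment, or NaN if beyond ``max_dist`` / no hit.

    Scalar in, scalar out; arrays broadcast.
    """
    pos = np.asarray(pos, dtype=float)
    x, y = pos[..., 0], pos[..., 1]
    if not np.all(arena.contains(np.atleast_1d(x), np.atleast_1d(y))):
        raise ValueError("position outside the arena")
    d = arena.ray_distance(x, y, allocentric_angle_deg)
    d = np.where(np.isinf(d), np.nan, d)
    if max_dist is not None:
        d = np.where(d > max_dist, np.nan, d)
    if pos.ndim == 1 and np.ndim(allocentric_angle_deg) == 0:
        return float(d.ravel()[0])
    return d


def movement_direction(session: TrajectorySession) -> np.ndarray:
    """Direction of travel (deg CCW from +x) from central differences."""
    vx = np.gradient(session.x, session.t)
    vy = np.gradient(session.y, session.t)
    return np.mod(np.rad2deg(np.arctan2(vy, vx)), 360.0)


def egocentric_bearing(session: TrajectorySession,
                       arena: ArenaGeometry | None = None,
                       which: str = "all",
                       indices: np.ndarray | None = None):
    """Egocentric bearing and distance of the nearest boundary point.

    Returns (bearing_deg, distance_cm) per sample; +90 deg = boundary on
    the animal's left.  ``which`` selects the boundary feature set.
    """
    if arena is None:
        arena = session.arena
    x, y, hd = session.x, session.y, session.hd
    if indices is not None:
        x, y, hd = x[indices], y[indices], hd[indices]
    d, q, _ = arena.nearest_boundary(x, y, which=which)
    phi = np.rad2deg(np.arctan2(q[:, 1] - y, q[:, 0] - x))
    return np.mod(phi - hd, 360.0), d


def egocentric_boundary_ratemap(session: TrajectorySession, spikes,
                                arena: ArenaGeometry | None = None,
                                reference: str = "head",
                                max_dist: float = EBR_MAX_DIST_CM,
                                angle_bin_deg: float = EBR_ANGLE_BIN_DEG,
                                dist_bin_cm: float = EBR_DIST_BIN_CM,
                                sigma_bins: float = EBR_SIGMA_BINS,
                                mask: np.ndarray | None = None
                                ) -> EgocentricBoundaryRatemap:
    """Construct the egocentric boundary ratemap for one unit.

    Every retained frame contributes dt to one distance cell per angle bin
    (the ray hit), and every retained spike contributes one count likewise;
    rays with no boundary within ``max_dist`` contribute nothing at that
    angle.  The rate is smoothed spikes / smoothed occupancy, with the
    angular axis wrapped.
    """
    if arena is None:
        arena = session.arena
    st = spikes.spike_times if isinstance(spikes, SpikeTrain) else \
        np.asarray(spikes, dtype=float)
    if mask is None:
        mask = session.valid
    if reference == "head":
        ref = session.hd
    elif reference == "movement":
        ref = movement_direction(session)
    else:
        raise ValueError("reference must be 'head' or 'movement'")

    n_ang = int(round(360.0 / angle_bin_deg))
    # include a final bin so a hit at exactly max_dist is retained
    n_dist = int(np.floor(max_dist / dist_bin_cm)) + 1
    angle_centers = (np.arange(n_ang) + 0.5) * angle_bin_deg
    dist_edges = np.arange(n_dist) * dist_bin_cm

    fi = np.flatnonzero(mask)
    fx, fy, fref = session.x[fi], session.y[fi], ref[fi]
    if st.size:
        sj = session.spike_sample_index(st)
        sj = sj[mask[sj]]
        sx, sy, sref = session.x[sj], session.y[sj], ref[sj]
    else:
        sx = sy = sref = np.empty(0)

    occ = np.zeros((n_ang, n_dist))
    spk = np.zeros((n_ang, n_dist))
    for k in range(n_ang):
        for (xx, yy, rr, grid, w) in ((fx, fy, fref, occ, session.dt),
                                      (sx, sy, sref, spk, 1.0)):
            if len(xx) == 0:
                continue
            d = arena.ray_distance(xx, yy, rr + angle_centers[k])
            ok = np.isfinite(d) & (d <= max_dist)
            if ok.any():
                b = np.minimum((d[ok] / dist_bin_cm).astype(int), n_dist - 1)
                grid[k] += w * np.bincount(b, minlength=n_dist)

    if sigma_bins > 0:
        so = gaussian_filter(occ, sigma_bins, mode=("wrap", "reflect"))
        ss = gaussian_filter(spk, sigma_bins, mode=("wrap", "reflect"))
    else:
        so, ss = occ, spk
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = ss / so
    rate[so <= 0] = np.nan
    mvl, pref = _rate_mean_vector(rate, angle_centers)
    return EgocentricBoundaryRatemap(occ, spk, rate, angle_centers,
                                     dist_edges, reference, mvl, pref)


def _rate_mean_vector(rate: np.ndarray, angles: np.ndarray):
    weights = np.nansum(np.where(np.isfinite(rate), rate, 0.0), axis=1)
    if not np.any(weights > 0):
        return np.nan, np.nan
    return mean_vector(angles, weights)


def ebr_mean_vector(ebr: EgocentricBoundaryRatemap) -> tuple[float, float]:
    """(MVL, preferred angle deg) of the distance-collapsed EBR.

    The rate is summed over distance per angle bin and the circular mean
    vector of the resulting angular profile is returned.
    """
    return _rate_mean_vector(ebr.rate, ebr.angles)


def ebr_reference_comparison(session: TrajectorySession, spikes,
                             arena: ArenaGeometry | None = None,
                             **kwargs) -> tuple[float, float]:
    """EBR tuning strength with head vs movement direction as reference.

    Returns (mvl_head, mvl_movement); for cells gated on head direction the
    head-referenced tuning is the stronger of the two.
    """
    mh = egocentric_boundary_ratemap(session, spikes, arena,
                                     reference="head", **kwargs).mvl
    mm = egocentric_boundary_ratemap(session, spikes, arena,
                                     reference="movement", **kwargs).mvl
    return mh, mm


def export_ebr(path, ebr: EgocentricBoundaryRatemap) -> None:
    """Write the EBR as delimited text (angle, distance, occ, spikes, rate)."""
    rows = []
    for i, a in enumerate(ebr.angles):
        for j, d in enumerate(ebr.distances):
            rows.append((a, d, ebr.occupancy[i, j], ebr.spikes[i, j],
                         ebr.rate[i, j]))
    np.savetxt(path, np.array(rows), delimiter=",", fmt="%.8g",
               header="angle_deg,dist_cm,occupancy_s,spikes,rate_hz")
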