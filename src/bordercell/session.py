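"""Session data model: arena geometry, tracking data, spike trains, kinematics.

The shared coordinate frame is a top view with the origin at the bottom-left
corner of the arena bounding box, x increasing rightward, y increasing upward,
and angles measured counter-clockwise from the +x axis, in degrees.  All
distances are in centimetres, all times in seconds.  With this convention a
boundary at egocentric bearing +90 deg lies on the animal's left.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import Polygon

__all__ = [
    "ArenaGeometry",
    "TrajectorySession",
    "SpikeTrain",
    "SUBTYPE_LABELS",
    "make_arena",
    "load_geometry",
    "save_geometry",
    "load_session",
    "write_session",
    "load_spikes",
    "write_spikes",
    "load_waveforms",
    "write_waveforms",
    "compute_speed",
    "speed_filter",
]

#: Subtype vocabulary shared by the classifier and the synthetic generator.
SUBTYPE_LABELS = ("allocentric", "left_ego", "right_ego", "nonborder")

#: Gaps in the tracking longer than this many seconds are not interpolated.
MAX_INTERP_GAP_S = 0.5

#: Default boxcar window for speed smoothing (s).
SPEED_WINDOW_S = 0.2

#: Default running-speed threshold (cm/s).
MIN_SPEED_CM_S = 2.5

#: Number of segments used to polygonize a circular wall (1 deg resolution).
CIRCLE_SEGMENTS = 360


# --------------------------------------------------------------------------
# Arena geometry
# --------------------------------------------------------------------------

@dataclass
class ArenaGeometry:
    """Directed boundary segments describing every wall, insert and object.

    ``segments`` has shape (S, 2, 2): segment s runs from ``segments[s, 0]``
    to ``segments[s, 1]``.  ``features`` maps a feature name ("outer",
    "insert0", "object0", ...) to the indices of its segments;
    ``wall_labels`` maps compass labels N/E/S/W to outer segment indices
    where applicable (square-like arenas).
    """

    segments: np.ndarray
    kind: str
    features: dict[str, np.ndarray] = field(default_factory=dict)
    wall_labels: dict[str, int] = field(default_factory=dict)
    spec: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=float)
        if self.segments.ndim != 3 or self.segments.shape[1:] != (2, 2):
            raise ValueError("segments must have shape (S, 2, 2)")
        lengths = np.linalg.norm(
            self.segments[:, 1] - self.segments[:, 0], axis=1)
        if np.any(lengths <= 0):
            raise ValueError("degenerate boundary segment (length 0)")
        self._free = self._build_free_polygon()
        self._free_buffered = self._free.buffer(1e-6)

    def _build_free_polygon(self) -> Polygon:
        outer_idx = self.features.get(
            "outer", np.arange(len(self.segments)))
        pts = [tuple(self.segments[i, 0]) for i in outer_idx]
        holes = []
        for name, idx in self.features.items():
            if name.startswith("object"):
                holes.append([tuple(self.segments[i, 0]) for i in idx])
        return Polygon(pts, holes)

    # -- queries -----------------------------------------------------------

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer boundary."""
        outer = self.segments[self.features["outer"]]
        xy = outer.reshape(-1, 2)
        return (xy[:, 0].min(), xy[:, 1].min(),
                xy[:, 0].max(), xy[:, 1].max())

    @property
    def shorter_side(self) -> float:
        xmin, ymin, xmax, ymax = self.bounds
        return min(xmax - xmin, ymax - ymin)

    def contains(self, x, y) -> np.ndarray:
        """True for points strictly inside the free space (tolerance 1e-6)."""
        return shapely.contains_xy(self._free_buffered, x, y)

    def _segment_indices(self, which: str) -> np.ndarray:
        if which == "all":
            return np.arange(len(self.segments))
        if which == "objects":
            idx = [i for name, ii in self.features.items()
                   if name.startswith("object") for i in ii]
            if not idx:
                raise ValueError("arena has no objects")
            return np.asarray(idx)
        if which in self.features:
            return np.asarray(self.features[which])
        raise ValueError(f"unknown feature selector {which!r}")

    def nearest_boundary(self, x, y, which: str = "all"):
        """Distance, foot point and segment index of the nearest boundary.

        Vectorized over points; returns (dist, point(N,2), seg_index).
        """
        idx = self._segment_indices(which)
        P = np.column_stack([np.atleast_1d(x), np.atleast_1d(y)]).astype(float)
        A = self.segments[idx, 0]          # (S, 2)
        E = self.segments[idx, 1] - A      # (S, 2)
        L2 = np.einsum("sd,sd->s", E, E)
        # projection parameter of each point on each segment, clipped to [0,1]
        t = np.einsum("nsd,sd->ns", P[:, None, :] - A[None], E) / L2
        t = np.clip(t, 0.0, 1.0)
        Q = A[None] + t[..., None] * E[None]          # (N, S, 2)
        d = np.linalg.norm(P[:, None, :] - Q, axis=2)
        j = np.argmin(d, axis=1)
        n = np.arange(len(P))
        return d[n, j], Q[n, j], idx[j]

    def ray_distance(self, x, y, angle_deg, which: str = "all") -> np.ndarray:
        """Distance from each point along its ray to the first boundary hit.

        ``angle_deg`` is allocentric, CCW from +x; broadcastable against the
        points.  Returns +inf where the ray hits nothing (should not happen
        for interior points with a closed outer boundary).
        """
        idx = self._segment_indices(which)
        x, y, angle_deg = np.broadcast_arrays(
            np.atleast_1d(x).astype(float), np.atleast_1d(y).astype(float),
            np.atleast_1d(angle_deg).astype(float))
        P = np.column_stack([x.ravel(), y.ravel()])
        th = np.deg2rad(angle_deg.ravel())
        D = np.column_stack([np.cos(th), np.sin(th)])
        A = self.segments[idx, 0]
        E = self.segments[idx, 1] - A
        V = A[None] - P[:, None, :]                      # (N, S, 2)
        denom = D[:, None, 0] * E[None, :, 1] - D[:, None, 1] * E[None, :, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (V[..., 0] * E[None, :, 1] - V[..., 1] * E[None, :, 0]) / denom
            u = (V[..., 0] * D[:, None, 1] - V[..., 1] * D[:, None, 0]) / denom
        ok = (np.abs(denom) > 1e-12) & (u >= -1e-9) & (u <= 1 + 1e-9) \
            & (t >= -1e-9)
        t = np.where(ok, np.maximum(t, 0.0), np.inf)
        return t.min(axis=1).reshape(angle_deg.shape)


def _rect_segments(xmin, ymin, xmax, ymax) -> np.ndarray:
    """Four directed segments tracing a rectangle CCW from bottom-left."""
    c = [(xmin, ymin), (xmax, ymin), (xmax, ymax), (xmin, ymax)]
    return np.array([[c[i], c[(i + 1) % 4]] for i in range(4)], dtype=float)


def make_arena(kind: str = "square", size_cm: float = 100.0,
               inserts: Sequence = (), objects: Sequence = ()) -> ArenaGeometry:
    """Build an :class:`ArenaGeometry`.

    Parameters
    ----------
    kind : {"square", "circle", "platform", "composite"}
        "platform" is geometrically a square whose outer boundary is a drop
        edge rather than a wall; the analysis treats both identically.
    size_cm : side length (square/platform) or diameter (circle).
    inserts : sequence of ((x0, y0), (x1, y1)) wall inserts; each produces
        two opposing directed segments (both faces of a thin wall).
    objects : sequence of (xmin, ymin, xmax, ymax) rectangular objects, each
        a closed 4-segment perimeter.
    """
    if size_cm <= 0:
        raise ValueError("size_cm must be positive")
    segs: list[np.ndarray] = []
    features: dict[str, np.ndarray] = {}
    wall_labels: dict[str, int] = {}
    if kind in ("square", "platform", "composite"):
        outer = _rect_segments(0, 0, size_cm, size_cm)
        segs.append(outer)
        features["outer"] = np.arange(4)
        wall_labels = {"S": 0, "E": 1, "N": 2, "W": 3}
    elif kind == "circle":
        r = size_cm / 2.0
        th = np.deg2rad(np.arange(CIRCLE_SEGMENTS + 1))
        pts = np.column_stack([r + r * np.cos(th), r + r * np.sin(th)])
        outer = np.stack([pts[:-1], pts[1:]], axis=1)
        segs.append(outer)
        features["outer"] = np.arange(CIRCLE_SEGMENTS)
    else:
        raise ValueError(f"unknown arena kind {kind!r}")
    n = sum(len(s) for s in segs)

    outer_poly = Polygon([tuple(p) for p in segs[0][:, 0]])
    interior_shapes = []
    for k, ins in enumerate(inserts):
        (x0, y0), (x1, y1) = ins
        seg = np.array([[[x0, y0], [x1, y1]], [[x1, y1], [x0, y0]]],
                       dtype=float)
        line = shapely.LineString([(x0, y0), (x1, y1)])
        if not outer_poly.covers(line):
            raise ValueError("insert extends outside the outer boundary")
        interior_shapes.append(line)
        segs.append(seg)
        features[f"insert{k}"] = np.arange(n, n + 2)
        n += 2
    for k, obj in enumerate(objects):
        xmin, ymin, xmax, ymax = obj
        box = shapely.box(xmin, ymin, xmax, ymax)
        if not outer_poly.contains(box):
            raise ValueError("object extends outside the outer boundary")
        interior_shapes.append(box)
        segs.append(_rect_segments(xmin, ymin, xmax, ymax))
        features[f"object{k}"] = np.arange(n, n + 4)
        n += 4
    for i in range(len(interior_shapes)):
        for j in range(i + 1, len(interior_shapes)):
            if interior_shapes[i].intersects(interior_shapes[j]):
                raise ValueError("overlapping interior features")

    spec = {"kind": kind, "size_cm": float(size_cm),
            "inserts": [[list(map(float, p)) for p in ins] for ins in inserts],
            "objects": [list(map(float, o)) for o in objects]}
    return ArenaGeometry(np.concatenate(segs, axis=0), kind,
                         features, wall_labels, spec)


def load_geometry(source) -> ArenaGeometry:
    """Load an arena from a YAML path/stream, a spec dict, or pass through."""
    if isinstance(source, ArenaGeometry):
        return source
    if isinstance(source, Mapping):
        spec = dict(source)
    else:
        with open(source) as fh:
            spec = yaml.safe_load(fh)
    return make_arena(kind=spec.get("kind", "square"),
                      size_cm=spec.get("size_cm", 100.0),
                      inserts=spec.get("inserts", []) or [],
                      objects=spec.get("objects", []) or [])


def save_geometry(arena: ArenaGeometry, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(arena.spec, fh)


# --------------------------------------------------------------------------
# Trajectory sessions
# --------------------------------------------------------------------------

@dataclass
class TrajectorySession:
    """Time-aligned position/heading samples on a fixed frame grid.

    ``valid`` marks samples usable for mapping (tracked, inside the arena,
    not inside an un-interpolated gap).  ``speed`` is in cm/s.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    hd: np.ndarray
    arena: ArenaGeometry
    speed: np.ndarray | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("t", "x", "y", "hd"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.hd) == n):
            raise ValueError("t, x, y, hd must have equal length")
        dts = np.diff(self.t)
        if n >= 2:
            if np.any(dts <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if np.ptp(dts) > 1e-6:
                raise ValueError("frame interval is not constant")
        self.hd = np.mod(self.hd, 360.0)
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        if self.speed is None and n >= 2:
            self.speed = compute_speed(self)

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else np.nan

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        """Total session span including the final frame's dwell."""
        return float(self.t[-1] - self.t[0] + self.dt)

    @property
    def t0(self) -> float:
        return float(self.t[0])

    def spike_sample_index(self, spike_times) -> np.ndarray:
        """Index of the nearest-in-time sample for each spike."""
        st = np.asarray(spike_times, dtype=float)
        j = np.searchsorted(self.t, st)
        j = np.clip(j, 1, len(self.t) - 1)
        left_closer = (st - self.t[j - 1]) <= (self.t[j] - st)
        return np.where(left_closer, j - 1, j)


def compute_speed(session: TrajectorySession,
                  window_s: float = SPEED_WINDOW_S) -> np.ndarray:
    """Instantaneous running speed (cm/s), boxcar-smoothed over ``window_s``.

    Central differences in the interior, one-sided at the endpoints.
    """
    x, y, t = session.x, session.y, session.t
    if len(t) < 2:
        raise ValueError("need at least two samples to compute speed")
    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    sp = np.hypot(vx, vy)
    win = max(1, int(round(window_s / session.dt)))
    if win > 1:
        from scipy.ndimage import uniform_filter1d
        sp = uniform_filter1d(sp, size=win, mode="nearest")
    return sp


def speed_filter(session: TrajectorySession, spike_times,
                 min_speed: float = MIN_SPEED_CM_S):
    """Retain samples (and spikes) recorded at running speed >= ``min_speed``.

    Returns ``(sample_mask, filtered_spike_times)``.  Each spike inherits the
    speed of its nearest-in-time sample.  ``min_speed=0`` is the identity.
    """
    if session.speed is None:
        raise ValueError("session speed not computed")
    mask = session.valid & (session.speed >= min_speed)
    if not mask.any():
        raise ValueError("no qualifying epochs: all samples below "
                         f"min_speed={min_speed}")
    st = np.asarray(spike_times, dtype=float)
    if st.size:
        st = st[mask[session.spike_sample_index(st)]]
    return mask, st


# --------------------------------------------------------------------------
# Spike trains
# --------------------------------------------------------------------------

@dataclass
class SpikeTrain:
    """One unit's spike times plus optional metadata."""

    unit_id: str
    spike_times: np.ndarray
    hemisphere: str = "unknown"
    waveform: np.ndarray | None = None   # (channels, samples), µV
    waveform_fs: float | None = None     # waveform sample rate, Hz

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, dtype=float)
        if st.size and np.any(np.diff(st) < 0):
            st = np.sort(st)
        self.spike_times = st
        if self.hemisphere not in ("left", "right", "unknown"):
            raise ValueError(f"bad hemisphere label {self.hemisphere!r}")

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    def mean_rate(self, duration: float) -> float:
        return self.n_spikes / duration


# --------------------------------------------------------------------------
# File I/O (delimited text formats)
# --------------------------------------------------------------------------

def write_session(session: TrajectorySession, path) -> None:
    """Write tracking samples as CSV with header ``t,x,y,hd`` (s/cm/cm/deg)."""
    df = pd.DataFrame({"t": session.t, "x": session.x,
                       "y": session.y, "hd": session.hd})
    df.to_csv(path, index=False, float_format="%.17g")


def _interp_angle(tq, tp, ang_deg):
    """Linear interpolation of an angle series via unwrapping, degrees."""
    unwrapped = np.unwrap(np.deg2rad(ang_deg))
    return np.mod(np.rad2deg(np.interp(tq, tp, unwrapped)), 360.0)


def load_session(position_path, geometry_spec,
                 max_gap_s: float = MAX_INTERP_GAP_S,
                 speed_window_s: float = SPEED_WINDOW_S) -> TrajectorySession:
    """Read a tracking file and build a validated :class:`TrajectorySession`.

    The file must be delimited text with header ``t,x,y,hd``.  Missing frames
    on the regular grid are linearly interpolated when the gap is at most
    ``max_gap_s``; samples inside longer gaps are marked invalid.  Samples
    outside the arena are treated like gaps; sessions with more than 10%
    such samples are rejected.
    """
    arena = load_geometry(geometry_spec)
    df = pd.read_csv(position_path, float_precision="round_trip")
    required = {"t", "x", "y", "hd"}
    if not required.issubset(df.columns):
        raise ValueError(f"position file must have columns {sorted(required)}")
    t = df["t"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("need at least two tracking samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("non-monotone timestamps in position file")
    dt = float(np.median(np.diff(t)))
    n = int(round((t[-1] - t[0]) / dt)) + 1
    grid = t[0] + dt * np.arange(n)
    # snap observed samples to grid slots, keeping their recorded values
    slots = np.round((t - t[0]) / dt).astype(int)
    observed = np.zeros(n, dtype=bool)
    observed[slots] = True
    grid[slots] = t

    x = np.interp(grid, t, df["x"].to_numpy(float))
    y = np.interp(grid, t, df["y"].to_numpy(float))
    hd = _interp_angle(grid, t, df["hd"].to_numpy(float))
    x[slots] = df["x"].to_numpy(float)
    y[slots] = df["y"].to_numpy(float)
    hd[slots] = np.mod(df["hd"].to_numpy(float), 360.0)

    inside = arena.contains(x, y)
    if np.mean(~inside) > 0.10:
        raise ValueError(
            f"{np.mean(~inside):.1%} of samples fall outside the arena; "
            "check tracking calibration or the geometry spec")
    good = observed & inside

    # gap handling: interpolate across runs of bad samples <= max_gap_s
    valid = good.copy()
    bad = ~good
    if bad.any():
        idx = np.flatnonzero(bad)
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        gx = grid[good]
        for run in splits:
            gap = (len(run) + 1) * dt
            interior = run[0] > 0 and run[-1] < n - 1
            if interior and gap <= max_gap_s:
                x[run] = np.interp(grid[run], gx, x[good])
                y[run] = np.interp(grid[run], gx, y[good])
                hd[run] = _interp_angle(grid[run], gx, hd[good])
                valid[run] = True
            else:
                warnings.warn(
                    f"gap of {gap:.2f} s at t={grid[run[0]]:.2f} s left "
                    "uninterpolated", stacklevel=2)
    session = TrajectorySession(grid, x, y, hd, arena, valid=valid)
    session.speed = compute_speed(session, speed_window_s)
    return session


def write_spikes(trains: Sequence[SpikeTrain], path) -> None:
    """Write spike tables as CSV with header ``unit_id,t``."""
    frames = [pd.DataFrame({"unit_id": tr.unit_id, "t": tr.spike_times})
              for tr in trains]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g")


def load_spikes(path, hemispheres: Mapping[str, str] | None = None
                ) -> list[SpikeTrain]:
    """Read a ``unit_id,t`` spike table into one SpikeTrain per unit."""
    df = pd.read_csv(path, dtype={"unit_id": str},
                     float_precision="round_trip")
    if not {"unit_id", "t"}.issubset(df.columns):
        raise ValueError("spike file must have columns unit_id,t")
    trains = []
    for uid, grp in df.groupby("unit_id", sort=True):
        hemi = (hemispheres or {}).get(uid, "unknown")
        trains.append(SpikeTrain(uid, grp["t"].to_numpy(float),
                                 hemisphere=hemi))
    return trains


def write_waveforms(trains: Sequence[SpikeTrain], path,
                    sample_rate_hz: float) -> None:
    """Write mean waveforms as ``unit_id,channel,sample_index,uV`` CSV."""
    rows = []
    for tr in trains:
        if tr.waveform is None:
            continue
        for ch in range(tr.waveform.shape[0]):
            for k in range(tr.waveform.shape[1]):
                rows.append((tr.unit_id, ch, k, tr.waveform[ch, k]))
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz={sample_rate_hz:g}\n")
        pd.DataFrame(rows, columns=["unit_id", "channel", "sample_index",
                                    "uV"]).to_csv(fh, index=False)


def load_waveforms(path) -> tuple[dict[str, np.ndarray], float]:
    """Read mean waveforms; returns ({unit_id: (channels, samples)}, fs)."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# sample_rate_hz="):
            raise ValueError("waveform file missing sample-rate header")
        fs = float(header.split("=", 1)[1])
        df = pd.read_csv(io.StringIO(fh.read()), dtype={"unit_id": str})
    out = {}
    for uid, grp in df.groupby("unit_id"):
        n_ch = int(grp["channel"].max()) + 1
        n_s = int(grp["sample_index"].max()) + 1
        w = np.full((n_ch, n_s), np.nan)
        w[grp["channel"], grp["sample_index"]] = grp["uV"]
        out[uid] = w
    return out, fs
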