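"""Synthetic foraging sessions and tuned spike trains with ground truth.

The generator emulates the study conditions the analysis assumes: ~20 min
of free foraging in a 1 x 1 m walled arena tracked at 50 Hz, with spike
trains drawn from parametric tuning models — a wall-distance Gaussian gain
for border cells, a von Mises gate on the egocentric bearing of the nearest
boundary for left/right egocentric cells, an optional 4-12 Hz sinusoidal
rate modulation, uniform-Poisson distractors and Gaussian place fields.
Spikes are drawn from the inhomogeneous Poisson process by thinning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .session import (ArenaGeometry, SpikeTrain, TrajectorySession,
                      compute_speed, make_arena, save_geometry,
                      write_session, write_spikes, write_waveforms)

__all__ = ["CellSpec", "TrajectoryParams", "simulate_trajectory",
           "rate_function", "generate_spikes", "make_population",
           "Population", "make_waveform"]

CELL_MODELS = ("uniform", "allocentric_border", "left_ego", "right_ego",
               "place")


@dataclass
class CellSpec:
    """Parametric firing model for one synthetic unit.

    ``dist_sigma`` sets the wall-distance scale of the border Gaussian
    (cm); ``bearing_pref``/``bearing_kappa`` parameterize the von Mises
    gate on the egocentric bearing of the nearest boundary point (90 deg =
    left, 270 deg = right); ``theta_depth`` > 0 multiplies the rate by
    1 + depth * cos(2 pi f t).
    """

    model: str = "uniform"
    base_rate: float = 1.0          # Hz
    gain: float = 10.0              # Hz, peak modulation above base
    dist_sigma: float = 8.0         # cm
    bearing_pref: float = 90.0      # deg (90 left, 270 right)
    bearing_kappa: float = 4.0
    theta_freq: float = 8.0         # Hz
    theta_depth: float = 0.0        # in [0, 1]
    place_center: tuple[float, float] = (50.0, 50.0)
    place_sigma: float = 10.0       # cm
    hemisphere: str = "unknown"
    waveform_width_us: float = 400.0

    def __post_init__(self) -> None:
        if self.model not in CELL_MODELS:
            raise ValueError(f"unknown cell model {self.model!r}")
        if not 0 <= self.theta_depth <= 1:
            raise ValueError("theta_depth must be in [0, 1]")
        if self.base_rate < 0 or self.gain < 0:
            raise ValueError("rates must be nonnegative")

    @property
    def lam_max(self) -> float:
        """Declared rate bound used by the thinning sampler."""
        peak = self.base_rate
        if self.model in ("allocentric_border", "left_ego", "right_ego",
                          "place"):
            peak += self.gain
        return peak * (1.0 + self.theta_depth)


@dataclass
class TrajectoryParams:
    """Correlated-random-walk parameters for the foraging simulator.

    Speed follows a clipped Ornstein-Uhlenbeck process around
    ``mean_speed``; heading diffuses with per-step turning noise plus a
    smooth bias away from boundaries inside ``wall_avoid_cm``.  Head
    direction is the movement direction plus wrapped-normal noise so that
    head- and movement-referenced analyses differ realistically.
    """

    duration: float = 1200.0        # s
    dt: float = 0.02                # s (50 Hz tracking)
    mean_speed: float = 15.0        # cm/s
    speed_sd: float = 7.0           # cm/s, stationary SD of the OU process
    speed_tau: float = 1.0          # s, OU relaxation time
    turn_sd_deg: float = 120.0      # deg/sqrt(s) heading diffusion
    wall_avoid_cm: float = 4.0      # range of the boundary-avoidance turn
    avoid_gain: float = 4.0         # rad/s full-strength avoidance turning
    hd_noise_deg: float = 10.0      # wrapped-normal head-direction noise

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < 60:
            raise ValueError("duration must be at least 60 s")


def simulate_trajectory(arena: ArenaGeometry, params: TrajectoryParams,
                        seed=None) -> TrajectorySession:
    """Simulate a heading-persistent random walk confined by the arena."""
    rng = np.random.default_rng(seed)
    if arena._free.area <= 0:
        raise ValueError("arena has no interior area")
    n = int(round(params.duration / params.dt))
    dt = params.dt
    x = np.empty(n)
    y = np.empty(n)
    phi = np.empty(n)                    # movement heading, rad

    # start at a random interior point clear of all boundaries
    xmin, ymin, xmax, ymax = arena.bounds
    for _ in range(1000):
        px = rng.uniform(xmin, xmax)
        py = rng.uniform(ymin, ymax)
        if bool(np.atleast_1d(arena.contains(px, py))[0]) and \
                arena.nearest_boundary(px, py)[0][0] > 1.0:
            break
    else:
        raise ValueError("could not place a start point inside the arena")
    heading = rng.uniform(0, 2 * np.pi)
    v = max(params.mean_speed, 1.0)
    a = np.exp(-dt / params.speed_tau)
    sig_v = params.speed_sd * np.sqrt(1 - a * a)
    turn_sd = np.deg2rad(params.turn_sd_deg) * np.sqrt(dt)

    margin = 0.2   # cm kept clear of any boundary
    for i in range(n):
        v = params.mean_speed + a * (v - params.mean_speed) \
            + sig_v * rng.standard_normal()
        v = min(max(v, 0.0), params.mean_speed + 4 * params.speed_sd)
        d, q, _ = arena.nearest_boundary(px, py)
        d, q = d[0], q[0]
        turn = turn_sd * rng.standard_normal()
        if params.wall_avoid_cm > 0 and 0 < d < params.wall_avoid_cm:
            away = np.arctan2(py - q[1], px - q[0])
            err = np.angle(np.exp(1j * (away - heading)))
            turn += params.avoid_gain * dt * err \
                * (1.0 - d / params.wall_avoid_cm)
        heading = np.mod(heading + turn, 2 * np.pi)
        for _ in range(8):
            step = v * dt
            nx_ = px + step * np.cos(heading)
            ny_ = py + step * np.sin(heading)
            # the ray check stops steps that would cross a thin insert
            clear = arena.ray_distance(px, py, np.rad2deg(heading))[0] \
                > step + margin
            if clear and bool(np.atleast_1d(
                    arena.contains(nx_, ny_))[0]) and \
                    arena.nearest_boundary(nx_, ny_)[0][0] > margin:
                px, py = nx_, ny_
                break
            # blocked: reflect the heading off the nearest boundary
            nrm = np.array([px - q[0], py - q[1]])
            nn = np.linalg.norm(nrm)
            dv = np.array([np.cos(heading), np.sin(heading)])
            if nn > 0 and dv @ (nrm / nn) < 0:
                nrm /= nn
                dv = dv - 2 * (dv @ nrm) * nrm
                heading = np.arctan2(dv[1], dv[0])
            else:
                heading = rng.uniform(0, 2 * np.pi)
        x[i], y[i], phi[i] = px, py, heading

    t = dt * np.arange(n)
    hd = np.rad2deg(phi) + params.hd_noise_deg * rng.standard_normal(n)
    session = TrajectorySession(t, x, y, np.mod(hd, 360.0), arena)
    session.speed = compute_speed(session)
    return session


def rate_function(spec: CellSpec, arena: ArenaGeometry):
    """Vectorized rate evaluator lambda(t, x, y, hd) in Hz for one spec."""

    def border_rate(x, y, hd):
        d, q, _ = arena.nearest_boundary(x, y)
        r = spec.base_rate \
            + spec.gain * np.exp(-d ** 2 / (2 * spec.dist_sigma ** 2))
        if spec.model in ("left_ego", "right_ego"):
            # the whole border response is gated by the egocentric bearing
            # of the nearest boundary point (von Mises, max 1 at pref)
            phi = np.rad2deg(np.arctan2(q[:, 1] - y, q[:, 0] - x))
            bearing = np.deg2rad(np.mod(phi - hd, 360.0)
                                 - spec.bearing_pref)
            r = r * np.exp(spec.bearing_kappa * (np.cos(bearing) - 1.0))
        return r

    def lam(t, x, y, hd):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        hd = np.atleast_1d(np.asarray(hd, dtype=float))
        r = np.full(len(t), spec.base_rate)
        if spec.model in ("allocentric_border", "left_ego", "right_ego"):
            r = border_rate(x, y, hd)
        elif spec.model == "place":
            d2 = (x - spec.place_center[0]) ** 2 \
                + (y - spec.place_center[1]) ** 2
            r = r + spec.gain * np.exp(-d2 / (2 * spec.place_sigma ** 2))
        if spec.theta_depth > 0:
            r = r * (1.0 + spec.theta_depth
                     * np.cos(2 * np.pi * spec.theta_freq * t))
        return r

    return lam


def generate_spikes(session: TrajectorySession, rate_fn, lam_max: float,
                    seed=None, unit_id: str = "u0") -> SpikeTrain:
    """Inhomogeneous Poisson spikes by thinning against ``lam_max``.

    Candidate spikes are drawn homogeneously at ``lam_max`` and accepted
    with probability lambda / lam_max, with position and heading linearly
    (circularly for heading) interpolated at candidate times.  Raises if
    the rate function ever exceeds the declared bound.
    """
    rng = np.random.default_rng(seed)
    dur = session.duration
    n_cand = rng.poisson(lam_max * dur)
    tc = np.sort(session.t0 + rng.uniform(0, dur, n_cand))
    if n_cand == 0:
        return SpikeTrain(unit_id, np.empty(0))
    xc = np.interp(tc, session.t, session.x)
    yc = np.interp(tc, session.t, session.y)
    hd_unwrapped = np.unwrap(np.deg2rad(session.hd))
    hc = np.mod(np.rad2deg(np.interp(tc, session.t, hd_unwrapped)), 360.0)
    lam = rate_fn(tc, xc, yc, hc)
    if np.any(lam > lam_max * (1 + 1e-9)):
        raise ValueError("rate function exceeds declared lam_max")
    keep = rng.uniform(0, lam_max, n_cand) < lam
    return SpikeTrain(unit_id, tc[keep])


def make_waveform(width_us: float, fs: float = 32000.0,
                  n_samples: int = 32, amp_uv: float = 150.0,
                  n_channels: int = 4) -> np.ndarray:
    """Stylized mean spike waveform with the requested peak-to-trough width.

    A positive peak followed ``width_us`` later by a negative trough, with
    attenuated copies on the remaining channels.
    """
    t = np.arange(n_samples) / fs * 1e6          # µs
    t_peak = t[n_samples // 4]
    t_trough = t_peak + width_us
    w = amp_uv * np.exp(-((t - t_peak) / 60.0) ** 2) \
        - 0.8 * amp_uv * np.exp(-((t - t_trough) / 120.0) ** 2)
    scale = np.array([1.0] + [0.4] * (n_channels - 1))
    return scale[:, None] * w[None, :]


@dataclass
class Population:
    """A batch of units sharing one trajectory, with ground-truth labels."""

    session: TrajectorySession
    cells: list[SpikeTrain]
    labels: pd.DataFrame            # unit_id, model, hemisphere
    specs: dict[str, CellSpec] = field(default_factory=dict)
    waveform_fs: float = 32000.0

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_session(self.session, out / "position.csv")
        save_geometry(self.session.arena, out / "geometry.yaml")
        write_spikes(self.cells, out / "spikes.csv")
        write_waveforms(self.cells, out / "waveforms.csv", self.waveform_fs)
        self.labels.to_csv(out / "labels.csv", index=False)


def _default_spec(model: str, gain: float, base_rate: float,
                  rng) -> CellSpec:
    if model == "left_ego":
        return CellSpec(model, base_rate, gain, bearing_pref=90.0,
                        hemisphere="right")
    if model == "right_ego":
        return CellSpec(model, base_rate, gain, bearing_pref=270.0,
                        hemisphere="left")
    hemi = "left" if rng.uniform() < 0.5 else "right"
    if model == "place":
        return CellSpec(model, base_rate, gain, hemisphere=hemi,
                        place_center=(rng.uniform(20, 80),
                                      rng.uniform(20, 80)))
    return CellSpec(model, base_rate, gain, hemisphere=hemi)


def make_population(n_allo: int = 10, n_left: int = 10, n_right: int = 10,
                    n_uniform: int = 20, n_place: int = 0,
                    arena: ArenaGeometry | None = None,
                    params: TrajectoryParams | None = None,
                    seed=None, gain: float = 10.0, base_rate: float = 1.0,
                    session: TrajectorySession | None = None) -> Population:
    """Generate a labeled population of units on one shared trajectory.

    Egocentric cells are assigned to the hemisphere contralateral to their
    preferred side (left-ego in the right hemisphere and vice versa),
    mirroring the lateralization the analysis is designed to detect; other
    models are split at random.
    """
    rng = np.random.default_rng(seed)
    arena = arena or make_arena("square", 100.0)
    params = params or TrajectoryParams()
    if session is None:
        session = simulate_trajectory(
            arena, params, rng.integers(2 ** 31))
    plan = (["allocentric_border"] * n_allo + ["left_ego"] * n_left
            + ["right_ego"] * n_right + ["uniform"] * n_uniform
            + ["place"] * n_place)
    cells, rows, specs = [], [], {}
    for k, model in enumerate(plan):
        uid = f"u{k:03d}"
        spec = _default_spec(model, gain, base_rate, rng)
        lam = rate_function(spec, arena)
        train = generate_spikes(session, lam, spec.lam_max,
                                rng.integers(2 ** 31), unit_id=uid)
        train.hemisphere = spec.hemisphere
        train.waveform = make_waveform(spec.waveform_width_us)
        cells.append(train)
        specs[uid] = spec
        truth = "nonborder" if model in ("uniform", "place") else \
            ("allocentric" if model == "allocentric_border" else model)
        rows.append({"unit_id": uid, "model": model, "true_subtype": truth,
                     "hemisphere": spec.hemisphere,
                     "n_spikes": train.n_spikes})
    return Population(session, cells, pd.DataFrame(rows), specs)
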