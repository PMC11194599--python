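"""Occupancy/rate maps, spatial correlations, and directional tuning."""

import numpy as np
import pytest

import bordercell as bc
from bordercell import synthetic as syn
from bordercell.maps import (hd_tuning_curve, mean_vector, occupancy_map,
                             per_wall_tuning, rate_map,
                             rate_occupancy_correlation, spatial_correlation,
                             split_half_stability, wall_band_mask)
from bordercell.session import TrajectorySession

from conftest import filtered


def stationary_session(arena, n=500, dt=0.02, xy=(50.0, 50.0), hd=0.0):
    t = dt * np.arange(n)
    return TrajectorySession(t, np.full(n, xy[0]), np.full(n, xy[1]),
                             np.full(n, float(hd)), arena)


def circdiff(a, b):
    return abs((a - b + 180) % 360 - 180)


class TestOccupancy:
    def test_stationary_dwell_in_single_bin(self, square_arena):
        s = stationary_session(square_arena, n=500)   # 10 s
        occ = occupancy_map(s)
        assert occ.grid.max() == pytest.approx(10.0)
        assert (occ.grid > 0).sum() == 1

    def test_total_dwell_conserved(self, session_600, mask_600):
        occ = occupancy_map(session_600, mask=mask_600)
        assert occ.grid.sum() == pytest.approx(
            mask_600.sum() * session_600.dt)

    def test_uniform_coverage_session_has_low_dwell_cv(self, square_arena):
        # without wall-avoidance steering the walk's stationary
        # distribution is uniform; 40 min gives dense per-bin sampling
        s = syn.simulate_trajectory(
            square_arena,
            syn.TrajectoryParams(duration=2400.0, wall_avoid_cm=0.0),
            seed=21)
        occ = occupancy_map(s)
        dwell = occ.grid[occ.valid]
        assert dwell.std() / dwell.mean() < 0.5

    def test_bad_bin_size_rejected(self, session_600):
        with pytest.raises(ValueError):
            occupancy_map(session_600, bin_size=0.0)


class TestRateMap:
    def test_homogeneous_cell_recovers_flat_rate(self, session_600,
                                                 mask_600, tuned_cells):
        st = filtered(session_600, tuned_cells["unif"])
        rm = rate_map(session_600, st, mask=mask_600)
        assert np.nanmean(rm.rate) == pytest.approx(5.0, abs=0.3)

    def test_no_spikes_gives_zero_map(self, session_600):
        rm = rate_map(session_600, np.empty(0))
        assert rm.peak_rate == 0.0
        assert np.nansum(rm.rate) == 0.0

    def test_single_bin_rate_is_count_over_dwell(self, square_arena):
        s = stationary_session(square_arena, n=500)   # 10 s in one bin
        rm = rate_map(s, np.array([1.0, 2.0, 3.0]), sigma_bins=0)
        assert np.nanmax(rm.rate) == pytest.approx(3 / 10.0)
        assert np.isfinite(rm.rate).sum() == 1

    def test_smoothing_conserves_spike_count(self, session_600, mask_600,
                                             tuned_cells):
        from scipy.ndimage import gaussian_filter
        st = filtered(session_600, tuned_cells["allo"])
        rm = rate_map(session_600, st, mask=mask_600)
        smoothed = gaussian_filter(rm.counts, rm.sigma_bins, mode="reflect")
        assert smoothed.sum() == pytest.approx(rm.counts.sum(), rel=1e-6)
        assert rm.counts.sum() == len(st)


class TestSpatialCorrelation:
    def test_identical_maps(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 5, (40, 40))
        assert spatial_correlation(a, a) == pytest.approx(1.0)

    def test_negation_about_mean(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 5, (40, 40))
        assert spatial_correlation(a, 2 * a.mean() - a) == pytest.approx(-1.)

    def test_independent_poisson_maps_uncorrelated(self, session_600,
                                                   mask_600, square_arena):
        maps = []
        for seed in (31, 32):
            spec = syn.CellSpec("uniform", base_rate=5.0)
            tr = syn.generate_spikes(
                session_600, syn.rate_function(spec, square_arena),
                spec.lam_max, seed=seed)
            st = filtered(session_600, tr)
            maps.append(rate_map(session_600, st, mask=mask_600))
        assert abs(spatial_correlation(*maps)) < 0.2

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            spatial_correlation(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_too_few_shared_bins_gives_nan(self):
        a = np.full((40, 40), np.nan)
        a[0, :10] = 1.0
        assert np.isnan(spatial_correlation(a, a))


class TestStability:
    def test_border_cell_is_stable(self, session_600, mask_600,
                                   tuned_cells):
        st = filtered(session_600, tuned_cells["allo"])
        r = split_half_stability(session_600, st, mask=mask_600)
        assert r > 0.5

    def test_spikes_only_in_first_half_not_stable(self, session_600,
                                                  mask_600, tuned_cells):
        st = filtered(session_600, tuned_cells["unif"])
        st = st[st < session_600.t0 + session_600.duration / 2]
        r = split_half_stability(session_600, st, mask=mask_600)
        assert np.isnan(r) or r <= 0

    def test_mirrored_halves_fully_stable(self, square_arena):
        n, dt = 15000, 0.02   # two identical 150 s halves
        t = dt * np.arange(2 * n)
        rng = np.random.default_rng(3)
        w = 0.4
        ang = w * t[:n] + rng.standard_normal(n).cumsum() * 0.01
        x = 50 + 30 * np.cos(ang)
        y = 50 + 30 * np.sin(ang)
        s = TrajectorySession(t, np.r_[x, x], np.r_[y, y],
                              np.zeros(2 * n), square_arena)
        spikes = np.sort(rng.uniform(0, n * dt, 500))
        both = np.sort(np.r_[spikes, spikes + n * dt])
        r = split_half_stability(s, both, mask=np.ones(2 * n, bool))
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_short_session_rejected(self, square_arena):
        s = stationary_session(square_arena, n=100)
        with pytest.raises(ValueError):
            split_half_stability(s, np.array([1.0]))


class TestRateOccupancyCorrelation:
    def test_rate_proportional_to_occupancy(self, session_600, mask_600):
        occ = occupancy_map(session_600, mask=mask_600)
        rm = rate_map(session_600, np.empty(0), mask=mask_600)
        rm.rate = np.where(occ.valid, 3.0 * occ.grid, np.nan)
        assert rate_occupancy_correlation(rm, occ) == pytest.approx(1.0)

    def test_homogeneous_cell_uncorrelated(self, session_600, mask_600,
                                           tuned_cells):
        st = filtered(session_600, tuned_cells["unif"])
        rm = rate_map(session_600, st, mask=mask_600)
        assert abs(rate_occupancy_correlation(rm)) < 0.2

    def test_border_cell_not_occupancy_artifact(self, session_600,
                                                mask_600, tuned_cells):
        st = filtered(session_600, tuned_cells["allo"])
        rm = rate_map(session_600, st, mask=mask_600)
        assert abs(rate_occupancy_correlation(rm)) < 0.3


class TestHDTuning:
    def test_all_spikes_one_direction_gives_unit_mvl(self, square_arena):
        s = stationary_session(square_arena, hd=33.0)
        curve = hd_tuning_curve(s, np.array([1.0, 2.0]), sigma_bins=0)
        assert curve.mvl == pytest.approx(1.0)
        assert circdiff(curve.preferred_dir, 33.0) <= 3.0

    def test_uniform_rate_gives_zero_mvl(self, square_arena):
        n = 3600
        t = 0.02 * np.arange(n)
        hd = np.tile(np.arange(0, 360, 6.0) + 3.0, n // 60)
        s = TrajectorySession(t, np.full(n, 50.), np.full(n, 50.), hd,
                              square_arena)
        curve = hd_tuning_curve(s, t.copy())   # one spike per sample
        assert curve.mvl == pytest.approx(0.0, abs=1e-9)

    def test_cosine_tuning_recovers_analytic_mvl(self, square_arena):
        # r(theta) = 1 + cos(theta - 40 deg)  =>  mvl 1/2, preferred 40
        nb = 60
        centers = np.arange(nb) * 6.0 + 3.0
        reps = 50
        hd = np.tile(np.repeat(centers, 10), reps)
        n = len(hd)
        t = 0.02 * np.arange(n)
        s = TrajectorySession(t, np.full(n, 50.), np.full(n, 50.), hd,
                              square_arena)
        counts = np.round(200 * (1 + np.cos(np.deg2rad(centers - 40))))
        spikes = []
        for k, c in enumerate(counts):
            sample = 10 * k + 5   # one sample inside bin k, first cycle
            spikes.extend([t[sample]] * int(c))
        curve = hd_tuning_curve(s, np.sort(spikes))
        assert curve.mvl == pytest.approx(0.5, abs=0.01)
        assert circdiff(curve.preferred_dir, 40.0) < 1.0

    def test_rotation_equivariance(self, session_600, mask_600,
                                   tuned_cells):
        st = filtered(session_600, tuned_cells["left"])
        base = hd_tuning_curve(session_600, st, mask=mask_600)
        rotated = TrajectorySession(
            session_600.t, session_600.x, session_600.y,
            (session_600.hd + 90.0) % 360.0, session_600.arena)
        rot = hd_tuning_curve(rotated, st, mask=mask_600)
        assert rot.mvl == pytest.approx(base.mvl, abs=1e-9)
        assert circdiff(rot.preferred_dir,
                        base.preferred_dir + 90.0) < 1e-6


class TestMeanVector:
    def test_single_angle(self):
        mvl, d = mean_vector(np.array([123.0]), np.array([2.0]))
        assert mvl == pytest.approx(1.0)
        assert d == pytest.approx(123.0)

    def test_empty_weights_give_nan(self):
        mvl, d = mean_vector(np.array([0.0, 90.0]),
                             np.array([np.nan, np.nan]))
        assert np.isnan(mvl) and np.isnan(d)


class TestWallBands:
    def test_point_near_north_wall(self, session_600, square_arena):
        s = stationary_session(square_arena, xy=(50.0, 95.0))
        assert wall_band_mask(s, square_arena, "N").all()
        for w in ("E", "S", "W"):
            assert not wall_band_mask(s, square_arena, w).any()

    def test_center_in_no_band(self, square_arena):
        s = stationary_session(square_arena, xy=(50.0, 50.0))
        for w in "NESW":
            assert not wall_band_mask(s, square_arena, w).any()

    def test_corner_assigned_to_exactly_one_wall(self, square_arena):
        s = stationary_session(square_arena, xy=(3.0, 3.0))
        hits = [w for w in "NESW"
                if wall_band_mask(s, square_arena, w).all()]
        assert len(hits) == 1
        assert hits[0] in ("S", "W")

    def test_unknown_wall_rejected(self, square_arena):
        s = stationary_session(square_arena)
        with pytest.raises(ValueError):
            wall_band_mask(s, square_arena, "X")


class TestPerWallTuning:
    def test_left_ego_strongly_tuned_on_every_wall(self, session_600,
                                                   mask_600, tuned_cells):
        st = filtered(session_600, tuned_cells["left"])
        rows = per_wall_tuning(session_600, st, mask=mask_600)
        assert len(rows) == 4
        assert all(r["mvl"] > 0.5 for r in rows)

    def test_allocentric_tuning_cancels_along_walls(self, session_600,
                                                    mask_600, tuned_cells):
        st = filtered(session_600, tuned_cells["allo"])
        rows = per_wall_tuning(session_600, st, mask=mask_600)
        assert all(r["mvl"] < 0.3 for r in rows)

    def test_right_ego_peaks_step_by_90_degrees(self, session_600,
                                                mask_600, tuned_cells):
        # CCW perimeter travel with the wall on the right: heading is
        # 180 on N, 90 on E, 0 on S and 270 on W (tolerance 4 bins)
        st = filtered(session_600, tuned_cells["right"])
        rows = {r["wall"]: r["peak_dir"]
                for r in per_wall_tuning(session_600, st, mask=mask_600)}
        expected = {"N": 180.0, "E": 90.0, "S": 0.0, "W": 270.0}
        for w, exp in expected.items():
            assert circdiff(rows[w], exp) <= 24.0, (w, rows[w])
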