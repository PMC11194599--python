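"""Shuffle null, border gate, CW/CCW subtype rules, waveform split."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bordercell as bc
from bordercell.classify import (CellReport, NullDistribution,
                                 binomial_ztest, circular_shift,
                                 classify_subtype, classify_waveform,
                                 cw_ccw_ratio, gate_border,
                                 lateralization_table, peak_to_trough_us)
from bordercell.session import TrajectorySession
from bordercell.synthetic import make_waveform

from conftest import filtered


class TestCircularShift:
    def test_explicit_shift_arithmetic(self):
        out = circular_shift(np.array([1.0, 2.0]), 10.0, shift=5.0)
        assert np.allclose(out, [6.0, 7.0])

    def test_wrap_point(self):
        out = circular_shift(np.array([1.0, 8.0]), 10.0, shift=5.0)
        assert np.allclose(out, [3.0, 6.0])

    @given(st.integers(0, 2 ** 31 - 1), st.integers(0, 200))
    @settings(max_examples=25, deadline=None)
    def test_count_and_sortedness_conserved(self, seed, n):
        rng = np.random.default_rng(seed)
        spikes = np.sort(rng.uniform(0, 300.0, n))
        out = circular_shift(spikes, 300.0, rng=rng)
        assert len(out) == n
        assert np.all(np.diff(out) >= 0)
        assert np.all((out >= 0) & (out <= 300.0))

    def test_too_short_session_rejected(self):
        with pytest.raises(ValueError):
            circular_shift(np.array([1.0]), 30.0, rng=0, min_shift=20.0)

    def test_shuffling_destroys_border_tuning(self, engine_600,
                                              tuned_cells, session_600):
        observed, _ = engine_600.score(tuned_cells["allo"].spike_times)
        rng = np.random.default_rng(5)
        shuffled = [engine_600.score(circular_shift(
            tuned_cells["allo"].spike_times, session_600.duration,
            rng=rng))[0] for _ in range(50)]
        assert np.nanmean(shuffled) < observed


class TestNullAndGate:
    def test_pooled_null_self_exceedance_is_one_percent(self, calibration):
        null, _ = calibration
        frac = np.mean(null.border_scores > null.p99_border)
        assert frac == pytest.approx(0.01, abs=2e-3)

    def test_border_cell_exceeds_own_null(self, session_600, tuned_cells,
                                          engine_600):
        null = bc.build_null(session_600, [tuned_cells["allo"]],
                             n_shuffles=100, rng=6,
                             engines=[engine_600])
        b, stab = engine_600.score(tuned_cells["allo"].spike_times)
        assert b > null.p99_border
        assert stab > null.p99_stability

    def test_gate_is_strict_and_nan_safe(self):
        null = NullDistribution(np.zeros(1), np.zeros(1), 0.58, 0.4, 1)
        assert gate_border(0.7, 0.8, null)
        assert not gate_border(0.58, 0.8, null)     # equality fails
        assert not gate_border(0.7, np.nan, null)
        assert not gate_border(np.nan, 0.8, null)


class TestBinomialZ:
    @pytest.mark.parametrize("k,n,p0,expected", [
        (110, 983, 0.01, 32.11),
        (5, 100, 0.01, 4.0201),
    ])
    def test_values(self, k, n, p0, expected):
        assert binomial_ztest(k, n, p0) == pytest.approx(expected, abs=5e-3)

    def test_zero_at_expectation(self):
        assert binomial_ztest(5, 500, 0.01) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_ztest(1, 10, 0.0)
        with pytest.raises(ValueError):
            binomial_ztest(1, 0, 0.5)


def perimeter_session(arena, laps=4, speed=15.0, inset=5.0, cw=True):
    """Deterministic travel around the square at ``inset`` from the walls.

    Clockwise travel keeps the walls on the animal's left.
    """
    side = 100 - 2 * inset
    per = 4 * side
    dt = 0.02
    n = int(laps * per / (speed * dt))
    s_along = (speed * dt * np.arange(n)) % per
    x = np.empty(n)
    y = np.empty(n)
    hd = np.empty(n)
    for i, a in enumerate(s_along):
        leg, u = int(a // side), a % side
        if leg == 0:      # W -> E along S side
            x[i], y[i], hd[i] = inset + u, inset, 0.0
        elif leg == 1:    # S -> N along E side
            x[i], y[i], hd[i] = 100 - inset, inset + u, 90.0
        elif leg == 2:    # E -> W along N side
            x[i], y[i], hd[i] = 100 - inset - u, 100 - inset, 180.0
        else:             # N -> S along W side
            x[i], y[i], hd[i] = inset, 100 - inset - u, 270.0
    if cw:                # reverse: CCW path traversed backwards is CW
        x, y, hd = x[::-1].copy(), y[::-1].copy(), (hd[::-1] + 180) % 360
    t = dt * np.arange(n)
    return TrajectorySession(t, x, y, hd, arena)


class TestCwCcw:
    def test_uniform_spiking_gives_unit_ratio(self, square_arena):
        cw = perimeter_session(square_arena, cw=True)
        ccw = perimeter_session(square_arena, cw=False)
        n = cw.n_samples
        t2 = np.r_[cw.t, ccw.t + n * 0.02]
        s = TrajectorySession(t2, np.r_[cw.x, ccw.x], np.r_[cw.y, ccw.y],
                              np.r_[cw.hd, ccw.hd], square_arena)
        spikes = s.t[::10].copy()
        res = cw_ccw_ratio(s, spikes, square_arena)
        assert res.time_ratio == pytest.approx(1.0, abs=0.01)
        assert res.fr_ratio == pytest.approx(1.0, abs=0.05)

    def test_spikes_only_with_boundary_on_left_gives_inf(self,
                                                         square_arena):
        cw = perimeter_session(square_arena, cw=True)
        ccw = perimeter_session(square_arena, cw=False)
        n = cw.n_samples
        s = TrajectorySession(np.r_[cw.t, ccw.t + n * 0.02],
                              np.r_[cw.x, ccw.x], np.r_[cw.y, ccw.y],
                              np.r_[cw.hd, ccw.hd], square_arena)
        # spikes only at CW-half samples far from corners, where the wall
        # is unambiguously on the animal's left
        mid_wall = (np.minimum(np.abs(s.x - 50), np.abs(s.y - 50)) < 30)
        idx = np.flatnonzero(mid_wall[:n])[::7]
        spikes = s.t[idx].copy()
        res = cw_ccw_ratio(s, spikes, square_arena)
        assert np.isposinf(res.fr_ratio)
        assert classify_subtype(res.fr_ratio) == "left_ego"

    def test_left_ego_cell_ratio(self, session_600, mask_600, tuned_cells):
        st = filtered(session_600, tuned_cells["left"])
        res = cw_ccw_ratio(session_600, st, mask=mask_600)
        assert res.fr_ratio > 2.0
        assert 0.5 < res.time_ratio < 2.0

    def test_reflection_swaps_labels_and_inverts_ratio(self, session_600,
                                                       tuned_cells):
        st = filtered(session_600, tuned_cells["left"])
        res = cw_ccw_ratio(session_600, st)
        mirrored = TrajectorySession(
            session_600.t, 100.0 - session_600.x, session_600.y,
            (180.0 - session_600.hd) % 360.0, session_600.arena)
        res_m = cw_ccw_ratio(mirrored, st)
        assert res_m.fr_ratio == pytest.approx(1.0 / res.fr_ratio,
                                               rel=1e-9)
        assert res_m.time_ratio == pytest.approx(1.0 / res.time_ratio,
                                                 rel=1e-9)


class TestSubtypeRule:
    @pytest.mark.parametrize("ratio,label", [
        (1.0, "allocentric"), (2.5, "left_ego"), (0.3, "right_ego"),
        (2.0, "allocentric"), (0.5, "allocentric"),
        (np.inf, "left_ego"),
    ])
    def test_thresholds(self, ratio, label):
        assert classify_subtype(ratio) == label

    def test_nan_defaults_to_allocentric_with_warning(self):
        with pytest.warns(UserWarning):
            assert classify_subtype(np.nan) == "allocentric"

    @given(st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_reciprocal_mirror_symmetry(self, ratio):
        flip = {"left_ego": "right_ego", "right_ego": "left_ego",
                "allocentric": "allocentric"}
        assert classify_subtype(1.0 / ratio) == flip[classify_subtype(ratio)]


class TestWaveformClass:
    @pytest.mark.parametrize("rate,width,expected", [
        (6.0, 250.0, "FS"), (1.0, 400.0, "RS"), (6.0, 400.0,
                                                 "unclassified"),
        (1.0, 250.0, "unclassified"),
    ])
    def test_rule(self, rate, width, expected):
        assert classify_waveform(rate, width) == expected

    def test_missing_waveform_unclassified(self):
        assert classify_waveform(3.0, None) == "unclassified"

    @pytest.mark.parametrize("width", [250.0, 400.0])
    def test_width_measured_from_synthetic_waveform(self, width):
        w = make_waveform(width)
        measured = peak_to_trough_us(w, 32000.0)
        assert measured == pytest.approx(width, abs=32.0)  # one sample


class TestLateralization:
    def _reports(self, counts):
        out = []
        for (sub, hemi), k in counts.items():
            out += [CellReport(unit_id="x", subtype=sub, hemisphere=hemi)
                    for _ in range(k)]
        return out

    def test_perfectly_lateralized_table(self):
        reports = self._reports({("left_ego", "left"): 10,
                                 ("right_ego", "right"): 10})
        table, chi2 = lateralization_table(reports)
        assert table.tolist() == [[10, 0], [0, 10]]
        assert chi2 == pytest.approx(20.0)

    def test_identical_rows_independent(self):
        reports = self._reports({("left_ego", "left"): 5,
                                 ("left_ego", "right"): 5,
                                 ("right_ego", "left"): 5,
                                 ("right_ego", "right"): 5})
        _, chi2 = lateralization_table(reports)
        assert chi2 == pytest.approx(0.0)

    def test_zero_expected_count_warns_nan(self):
        reports = self._reports({("left_ego", "left"): 5})
        with pytest.warns(UserWarning):
            _, chi2 = lateralization_table(reports)
        assert np.isnan(chi2)

    def test_generator_bias_recovered(self, recovery):
        _, result, frame = recovery
        table, chi2 = lateralization_table(result.reports)
        # generator places left-ego in the right hemisphere and vice versa
        assert table[0, 1] > table[0, 0]
        assert table[1, 0] > table[1, 1]
        assert chi2 > 10.0
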