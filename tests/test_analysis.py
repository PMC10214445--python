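"""Wrapping observables, state classifier, transitions, binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from vesiwrap.analysis import (ObservableSeries, StateThresholds, WrapState,
                               bin_time_average, classify_wrap_state,
                               compute_depth, compute_theta,
                               filter_equatorial_band, lobe_mesh,
                               transition_times, transition_summary,
                               wrapped_fraction)


class TestTheta:
    def test_aligned_and_orthogonal(self):
        n = np.array([0.0, 0.0, 1.0])
        assert compute_theta(n, n) == pytest.approx(0.0)
        assert compute_theta([1, 0, 0], n) == pytest.approx(90.0)
        assert compute_theta([0, 0, -1], n) == pytest.approx(0.0)  # folded

    def test_rotation_invariance(self, rng):
        # theta and d are invariant under global rotation + translation
        from scipy.spatial.transform import Rotation
        axis = rng.standard_normal(3)
        normal = rng.standard_normal(3)
        t0 = compute_theta(axis, normal)
        com = rng.standard_normal(3)
        center = rng.standard_normal(3)
        d0 = compute_depth(com, center, 5.0)
        for _ in range(5):
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.standard_normal(3)
            assert compute_theta(rot @ axis, rot @ normal) == pytest.approx(t0)
            assert compute_depth(rot @ com + shift, rot @ center + shift,
                                 5.0) == pytest.approx(d0)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            compute_theta([0, 0, 0], [0, 0, 1])


class TestDepth:
    def test_on_surface_is_zero(self):
        assert compute_depth([5.0, 0, 0], [0, 0, 0], 5.0) == pytest.approx(0.0)

    def test_sign_convention(self):
        assert compute_depth([3.0, 0, 0], [0, 0, 0], 5.0) > 0  # inside
        assert compute_depth([7.0, 0, 0], [0, 0, 0], 5.0) < 0  # outside


class TestBandFilter:
    def test_band_rule(self):
        frames = pd.DataFrame({"z": [0.0, 0.9, -0.85, 0.79, -0.79], "R": 1.0})
        kept = filter_equatorial_band(frames)
        assert kept["z"].tolist() == [0.0, 0.79, -0.79]

    def test_uniform_z_keeps_band_fraction(self, rng):
        z = rng.uniform(-1.0, 1.0, 200_000)
        frames = pd.DataFrame({"z": z, "R": 1.0})
        frac = len(filter_equatorial_band(frames)) / len(frames)
        assert frac == pytest.approx(0.8, abs=0.005)


class TestWrappedFraction:
    def test_no_beads(self):
        f1, f2 = wrapped_fraction(np.empty((0, 3)), np.zeros(3),
                                  [0, 0, 1], 1.0, 0.3)
        assert (f1, f2) == (0.0, 0.0)

    def test_one_lobe_fully_tiled(self):
        # beads tiling exactly the +axis lobe surface -> (1, 0)
        axis = np.array([0.0, 0.0, 1.0])
        a = 1.0
        mesh = lobe_mesh(2000) * (a + 0.15)
        beads = mesh + a * axis
        # drop tiling points occluded by the other lobe
        keep = np.linalg.norm(beads + a * axis, axis=1) - a >= 0.3
        f1, f2 = wrapped_fraction(beads[keep], np.zeros(3), axis, a, 0.3)
        assert f1 == pytest.approx(1.0, abs=0.02)
        assert f2 == pytest.approx(0.0, abs=0.02)

    def test_both_lobes_tiled(self):
        axis = np.array([0.0, 0.0, 1.0])
        a = 1.0
        mesh = lobe_mesh(2000) * (a + 0.15)
        beads = np.vstack([mesh + a * axis, mesh - a * axis])
        f1, f2 = wrapped_fraction(beads, np.zeros(3), axis, a, 0.3)
        assert f1 == pytest.approx(1.0, abs=0.02)
        assert f2 == pytest.approx(1.0, abs=0.02)


def _oracle_classify(f1, f2, theta, contact2, attached,
                     th=StateThresholds()):
    """Independent re-statement of the decision table (plain if-chains)."""
    if not attached:
        return WrapState.NONE
    if f1 < th.f_attach:
        if contact2:
            return WrapState.A3
        return WrapState.A1 if (theta is not None
                                and theta < th.theta_perp_deg) else WrapState.A2
    both = contact2 or f2 >= th.f_attach
    if f1 < th.f_shallow:
        if not both:
            return WrapState.B
        if f1 >= th.f_symmetric and f2 >= th.f_symmetric:
            return WrapState.E2
        return WrapState.C
    if f1 < th.f_full:
        return WrapState.E1 if both else WrapState.B
    if f2 >= th.f_full:
        return WrapState.F
    if both:
        return WrapState.E1
    return WrapState.D


class TestClassifier:
    def test_terminal_states(self):
        assert classify_wrap_state(0.95, 0.95) == WrapState.F
        assert classify_wrap_state(0.95, 0.0,
                                   second_lobe_contact=False) == WrapState.D

    def test_attachment_states(self):
        assert classify_wrap_state(0.0, 0.0, theta_deg=10.0) == WrapState.A1
        assert classify_wrap_state(0.0, 0.0, theta_deg=70.0) == WrapState.A2
        assert classify_wrap_state(0.0, 0.0, theta_deg=85.0,
                                   second_lobe_contact=True) == WrapState.A3

    def test_not_attached(self):
        assert classify_wrap_state(0.0, 0.0, attached=False) == WrapState.NONE

    def test_exhaustive_grid_matches_oracle(self):
        # every (f1, f2, flags) input maps to exactly one state, equal to
        # an independent re-implementation of the decision table
        grid = np.round(np.arange(0.0, 1.0001, 0.01), 3)
        for f1 in grid:
            for f2 in grid[grid <= f1]:
                for contact2 in (False, True):
                    for theta in (10.0, 60.0):
                        got = classify_wrap_state(
                            f1, f2, theta_deg=theta,
                            second_lobe_contact=contact2)
                        want = _oracle_classify(f1, f2, theta, contact2, True)
                        assert got == want, (f1, f2, contact2, theta)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            classify_wrap_state(1.2, 0.0)
        with pytest.raises(ValueError):
            classify_wrap_state(0.3, 0.6)  # violates f1 >= f2


class TestObservableSeries:
    def test_lobe_relabeling(self):
        s = ObservableSeries(time=[0, 1], theta=[10, 10], d=[0, 0],
                             z=[0, 0], f1=[0.2, 0.8], f2=[0.5, 0.1])
        assert np.all(s.f1 >= s.f2)
        assert s.f1[0] == 0.5 and s.f2[0] == 0.2

    def test_roundtrip_through_dataframe(self):
        s = ObservableSeries(time=[0, 1, 2], theta=[10, 20, 30],
                             d=[0.0, 0.1, 0.2], z=[0, 0, 0],
                             f1=[0.1, 0.5, 0.95], f2=[0.0, 0.2, 0.95])
        df = s.to_dataframe()
        back = ObservableSeries.from_dataframe(df)
        assert np.allclose(back.theta, s.theta)
        assert list(back.state) == list(s.state)


class TestTransitions:
    def test_simple_duration(self):
        states = ["B"] * 10 + ["E1"] * 10
        times = np.arange(20) * 10.0
        table = transition_times(states, times, debounce_frames=5)
        assert len(table) == 1
        row = table.iloc[0]
        assert (row["from"], row["to"]) == ("B", "E1")
        assert row["duration"] == pytest.approx(100.0)

    def test_debounce_drops_flicker(self):
        states = ["B"] * 20 + ["C"] + ["B"] * 20 + ["E1"] * 10
        times = np.arange(len(states), dtype=float)
        table = transition_times(states, times, debounce_frames=5)
        assert "C" not in set(table["from"]) | set(table["to"])
        assert len(table) == 1

    def test_empty_series(self):
        table = transition_times([], [])
        assert table.empty

    def test_non_monotone_times_raise(self):
        with pytest.raises(ValueError):
            transition_times(["B", "C"], [1.0, 0.5])

    def test_ensemble_summary(self):
        tables = [transition_times(["B"] * 6 + ["E1"] * 6,
                                   np.arange(12) * (10.0 + k))
                  for k in range(3)]
        summary = transition_summary(tables)
        assert len(summary) == 1
        assert summary.iloc[0]["n"] == 3
        assert summary.iloc[0]["mean"] == pytest.approx(66.0)


_vec = hnp.arrays(np.float64, 3,
                  elements=st.floats(-1e3, 1e3, allow_nan=False))


class TestObservableProperties:
    @given(axis=_vec, normal=_vec)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_theta_folded_range_and_symmetry(self, axis, normal):
        if np.linalg.norm(axis) < 1e-6 or np.linalg.norm(normal) < 1e-6:
            return
        t = compute_theta(axis, normal)
        assert 0.0 <= t <= 90.0
        # head-tail symmetry of the dumbbell
        assert compute_theta(-axis, normal) == pytest.approx(t, abs=1e-4)
        # scale invariance
        assert compute_theta(3.7 * axis, normal) == pytest.approx(t, abs=1e-4)

    @given(st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_binned_mean_preserves_global_mean(self, data):
        n = data.draw(st.integers(10, 300))
        vals = data.draw(hnp.arrays(np.float64, n,
                                    elements=st.floats(-1e3, 1e3)))
        t = np.arange(n, dtype=float)
        window = data.draw(st.floats(0.5, 50.0))
        out = bin_time_average(t, vals, window)
        # counts partition the frames, and the count-weighted bin means
        # reproduce the global mean
        assert out["count"].sum() == n
        weighted = float((out["value"] * out["count"]).sum() / n)
        assert weighted == pytest.approx(float(vals.mean()), abs=1e-6 * max(
            1.0, abs(vals).max()))


class TestBinning:
    def test_constant_series(self):
        t = np.arange(100) * 0.1
        out = bin_time_average(t, np.full(100, 3.3), window=1.0)
        assert np.allclose(out["value"], 3.3)
        assert np.all(out["count"] == 10)

    def test_whole_series_window(self):
        t = np.arange(50) * 1.0
        v = np.arange(50, dtype=float)
        out = bin_time_average(t, v, window=1e6)
        assert len(out) == 1
        assert out["value"].iloc[0] == pytest.approx(v.mean())

    def test_linear_ramp_closed_form(self):
        # theta(t) = t on [0, 10), 1 s windows -> means 0.5, 1.5, ..., 9.5
        t = np.linspace(0.0, 10.0, 10001)[:-1]
        out = bin_time_average(t, t, window=1.0)
        assert np.allclose(out["value"], np.arange(10) + 0.5, atol=1e-3)

    def test_bad_window_raises(self):
        with pytest.raises(ValueError):
            bin_time_average([0.0], [1.0], window=0.0)
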