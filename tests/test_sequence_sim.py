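"""Bloch simulator, grids, dictionary construction and splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mrfepi as m


class TestSchedule:
    def test_default_spans_acquisition_ranges(self, schedule):
        assert schedule.n_timepoints == 35
        assert (schedule.flip_angle_deg[0], schedule.flip_angle_deg[-1]) == (34.0, 86.0)
        assert (schedule.te_ms[0], schedule.te_ms[-1]) == (21.0, 81.5)
        assert (schedule.tr_ms[0], schedule.tr_ms[-1]) == (3530.0, 6570.0)

    def test_single_point_schedule(self):
        s = m.make_schedule(1, (90, 90), (50, 50), (1000, 1000))
        assert s.flip_angle_deg.tolist() == [90.0]
        assert s.te_ms.tolist() == [50.0]
        assert s.tr_ms.tolist() == [1000.0]

    def test_linear_interpolation_midpoint(self):
        s = m.make_schedule(3, (30, 60), (20, 40), (1000, 2000))
        assert s.flip_angle_deg.tolist() == [30.0, 45.0, 60.0]

    def test_linear_down_reverses(self):
        s = m.make_schedule(3, (30, 60), (20, 40), (1000, 2000), pattern="linear_down")
        assert s.flip_angle_deg.tolist() == [60.0, 45.0, 30.0]

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_timepoints=0),
            dict(te_range_ms=(2000, 3000), tr_range_ms=(1000, 1500)),  # TE >= TR
            dict(fa_range_deg=(0, 50)),
            dict(pattern="bogus"),
        ],
    )
    def test_invalid_schedules_rejected(self, kwargs):
        with pytest.raises(ValueError):
            m.make_schedule(**{"n_timepoints": 35, **kwargs})

    def test_schedule_file_round_trip(self, tmp_path, schedule):
        from mrfepi.io import save_schedule

        path = tmp_path / "sched.txt"
        save_schedule(schedule, path)
        loaded = m.schedule_from_file(path)
        np.testing.assert_allclose(loaded.flip_angle_deg, schedule.flip_angle_deg, atol=1e-6)
        np.testing.assert_allclose(loaded.tr_ms, schedule.tr_ms, atol=1e-6)


class TestSimulator:
    def test_zero_flip_efficiency_gives_zero_signal(self, schedule):
        fp = m.simulate_fingerprint(schedule, m.TissueParams(1000, 50, b1_eff=0.0))
        assert np.all(fp.values == 0)

    def test_single_echo_closed_form(self):
        s = m.make_schedule(1, (90, 90), (50, 50), (1000, 1000))
        fp = m.simulate_fingerprint(s, m.TissueParams(1000, 50, 1.0), m0=1.0)
        assert fp.values[0] == pytest.approx(np.sin(np.pi / 2) * np.exp(-1.0), abs=1e-12)

    def test_two_step_recursion_matches_hand_oracle(self):
        # manual two-step recursion: 90deg pulses, TE 50, TR 1000, T1 1000, T2* 50
        s = m.make_schedule(2, (90, 90), (50, 50), (1000, 1000))
        fp = m.simulate_fingerprint(s, m.TissueParams(1000, 50, 1.0), m0=1.0)
        # step 1: Mz=1 -> s0 = sin(90)*e^-1; post-pulse Mz=cos(90)=0
        # relax:  Mz = 1 + (0 - 1) e^-1 = 1 - e^-1
        # step 2: s1 = (1 - e^-1) * e^-1
        assert fp.values[0] == pytest.approx(np.exp(-1.0), abs=1e-12)
        assert fp.values[1] == pytest.approx((1 - np.exp(-1.0)) * np.exp(-1.0), abs=1e-12)

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_m0_scale_equivariance(self, c):
        s = m.make_schedule(5, (30, 80), (20, 60), (3000, 6000))
        base = m.simulate_fingerprint(s, m.TissueParams(1200, 60, 1.0), m0=1.0).values
        scaled = m.simulate_fingerprint(s, m.TissueParams(1200, 60, 1.0), m0=c).values
        np.testing.assert_allclose(scaled, c * base, rtol=1e-12)

    @given(st.floats(20, 250), st.floats(1.05, 3.0))
    @settings(max_examples=20, deadline=None)
    def test_t2s_monotonically_raises_amplitudes(self, t2s, factor):
        s = m.make_schedule(8, (30, 80), (20, 60), (3000, 6000))
        lo = m.simulate_fingerprint(s, m.TissueParams(1200, t2s, 1.0)).values
        hi = m.simulate_fingerprint(s, m.TissueParams(1200, t2s * factor, 1.0)).values
        assert np.all(hi > lo)

    def test_rejects_nonpositive_relaxation(self, schedule):
        with pytest.raises(ValueError):
            m.TissueParams(-5, 50)
        with pytest.raises(ValueError):
            m.simulate_fingerprints(schedule, np.array([0.0]), np.array([50.0]), np.array([1.0]))


class TestGrids:
    def test_two_percent_t1_sequence(self):
        grid = m.make_geometric_grid(100, 4000, 0.02)
        np.testing.assert_allclose(grid[:3], [100.0, 102.0, 104.04], rtol=1e-12)

    def test_two_percent_t2s_sequence(self):
        grid = m.make_geometric_grid(10, 3000, 0.02)
        np.testing.assert_allclose(grid[:3], [10.0, 10.2, 10.404], rtol=1e-12)

    def test_grid_length_matches_brute_force_loop(self):
        grid = m.make_geometric_grid(100, 4000, 0.02)
        # independent oracle: multiply up until the bound is exceeded
        count, value = 0, 100.0
        while value <= 4000.0 * (1 + 1e-12):
            count += 1
            value *= 1.02
        assert len(grid) == count == 187
        assert np.all(np.diff(grid) > 0)

    def test_b1_grid_enumeration(self):
        grid = m.make_linear_grid(0.6, 1.4, 0.05)
        expected = [0.6 + 0.05 * k for k in range(17)]
        assert len(grid) == 17
        np.testing.assert_allclose(grid, expected, atol=1e-12)


class TestDictionary:
    def test_exclusion_removes_t1_below_t2s(self, schedule):
        # single T1 value 1000 ms; the T2* axis straddles it, so every
        # pair with T2* > 1000 must be dropped
        grid = m.GridSpec(
            t1_min_ms=1000, t1_max_ms=1000, t2s_min_ms=50, t2s_max_ms=2000,
            increment_frac=0.99, b1_min=1.0, b1_max=1.0,
        )
        t2s_axis = grid.t2s_grid()
        d = m.generate_dictionary(schedule, grid)
        assert len(d) == int((t2s_axis <= 1000).sum())
        assert np.all(d.params[:, 0] >= d.params[:, 1])
        kept_off = m.generate_dictionary(
            schedule,
            m.GridSpec(t1_min_ms=1000, t1_max_ms=1000, t2s_min_ms=50, t2s_max_ms=2000,
                       increment_frac=0.99, b1_min=1.0, b1_max=1.0, exclude_t1_lt_t2s=False),
        )
        assert len(kept_off) == t2s_axis.size

    def test_all_signals_unit_norm(self, small_dict):
        norms = np.linalg.norm(small_dict.signals, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_b1_axis_enumerated(self, schedule):
        grid = m.GridSpec(
            t1_min_ms=1000, t1_max_ms=1000, t2s_min_ms=50, t2s_max_ms=50,
            increment_frac=0.02, b1_min=0.6, b1_max=1.4, b1_step=0.05,
        )
        d = m.generate_dictionary(schedule, grid)
        assert len(d) == 17
        np.testing.assert_allclose(sorted(set(d.params[:, 2])), m.make_linear_grid(0.6, 1.4, 0.05))

    def test_generation_deterministic(self, schedule):
        grid = m.GridSpec(t1_min_ms=500, t1_max_ms=900, t2s_min_ms=40, t2s_max_ms=90,
                          increment_frac=0.1, b1_min=0.9, b1_max=1.1, b1_step=0.1)
        d1 = m.generate_dictionary(schedule, grid)
        d2 = m.generate_dictionary(schedule, grid)
        assert np.array_equal(d1.signals, d2.signals)
        assert np.array_equal(d1.params, d2.params)


class TestSplits:
    def test_range_membership(self, schedule):
        grid = m.GridSpec(t1_min_ms=600, t1_max_ms=3000, t2s_min_ms=60, t2s_max_ms=1600,
                          increment_frac=0.5, b1_min=1.0, b1_max=1.0)
        d = m.generate_dictionary(schedule, grid)
        split = m.split_by_range(d, (500, 2500), (50, 1500))
        train_params = d.params[split.train_indices]
        valid_params = d.params[split.valid_indices]
        assert np.all((train_params[:, 0] >= 500) & (train_params[:, 0] <= 2500))
        assert np.all((train_params[:, 1] >= 50) & (train_params[:, 1] <= 1500))
        outside = (
            (valid_params[:, 0] < 500) | (valid_params[:, 0] > 2500)
            | (valid_params[:, 1] < 50) | (valid_params[:, 1] > 1500)
        )
        assert np.all(outside)

    def test_four_entry_toy_dictionary(self, schedule):
        # entries {600, 2600} x {60, 1600}: only (600, 60) falls in the training box
        from mrfepi.sequence_sim import Dictionary

        t1 = np.array([600.0, 600.0, 2600.0, 2600.0])
        t2s = np.array([60.0, 1600.0, 60.0, 1600.0])
        signals = m.simulate_fingerprints(schedule, t1, t2s, np.ones(4))
        signals /= np.linalg.norm(signals, axis=1, keepdims=True)
        d = Dictionary(params=np.column_stack([t1, t2s, np.ones(4)]), signals=signals,
                       schedule=schedule, grid=m.GridSpec())
        split = m.split_by_range(d, (500, 2500), (50, 1500))
        assert split.train_indices.tolist() == [0]
        np.testing.assert_allclose(d.params[split.train_indices[0], :2], [600, 60])

    def test_full_cover_split_flags_empty_validation(self, small_dict):
        with pytest.warns(UserWarning):
            split = m.split_by_range(small_dict, (1, 1e6), (1, 1e6))
        assert split.valid_indices.size == 0

    def test_increment_interval_one_is_identity(self, small_dict):
        split = m.split_by_increment(small_dict, 1)
        assert split.train_indices.size == len(small_dict)
        assert split.valid_indices.size == 0

    def test_increment_stride_indices(self, small_dict):
        split = m.split_by_increment(small_dict, 2)
        t1_idx = small_dict.t1_index[split.train_indices]
        t2s_idx = small_dict.t2s_index[split.train_indices]
        assert np.all(t1_idx % 2 == 0) and np.all(t2s_idx % 2 == 0)
        # manual stride oracle along the T1 axis: grid of 5 -> indices {0,2,4}
        n1 = small_dict.t1_index.max() + 1
        expected = set(range(0, n1, 2))
        assert set(t1_idx) <= expected

    def test_interval_subgrid_equals_compound_increment(self, schedule):
        # taking every k-th 2% value reproduces the (1.02^k - 1) grid
        base = m.make_geometric_grid(100, 4000, 0.02)
        for k in (2, 3, 5):
            compound = m.make_geometric_grid(100, 4000, 1.02**k - 1)
            np.testing.assert_allclose(base[::k], compound, rtol=1e-9)

    def test_interval_exceeding_grid_rejected(self, small_dict):
        with pytest.raises(ValueError):
            m.split_by_increment(small_dict, 10_000)

    def test_split_sets_partition_dictionary(self, small_dict):
        split = m.split_by_increment(small_dict, 3)
        union = np.union1d(split.train_indices, split.valid_indices)
        assert np.array_equal(union, np.arange(len(small_dict)))
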