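"""Inner-product matching, SNR and the noise bank."""

import numpy as np
import pytest

import mrfepi as m
from mrfepi.sequence_sim import Dictionary


def toy_dictionary(signals, params=None):
    """Wrap raw unit-norm rows as a Dictionary for matcher tests."""
    signals = np.asarray(signals, dtype=np.float64)
    n = signals.shape[0]
    if params is None:
        params = np.column_stack([np.arange(1, n + 1) * 100.0,
                                  np.arange(1, n + 1) * 10.0,
                                  np.ones(n)])
    sched = m.make_schedule(signals.shape[1], (30, 80), (20, 60), (3000, 6000))
    grid = m.GridSpec()
    return Dictionary(params=params, signals=signals, schedule=sched, grid=grid)


class TestMatchSignal:
    def test_self_match_returns_own_row(self, small_dict):
        j = 17
        params, score, idx = m.match_signal(small_dict.signals[j], small_dict)
        assert idx == j
        assert score == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self, small_dict):
        j = 5
        _, _, idx = m.match_signal(10.0 * small_dict.signals[j], small_dict)
        assert idx == j

    def test_three_entry_hand_oracle(self):
        d = toy_dictionary([[1, 0], [0, 1], [0.6, 0.8]])
        q = np.array([1.0, 1.0]) / np.sqrt(2)
        # hand dot products: 0.7071, 0.7071, 0.9899 -> row 2 wins
        _, score, idx = m.match_signal(q, d)
        assert idx == 2
        assert score == pytest.approx(1.4 / np.sqrt(2), abs=1e-12)

    def test_zero_query_rejected(self, small_dict):
        with pytest.raises(ValueError):
            m.match_signal(np.zeros(35), small_dict)

    def test_matches_brute_force_cosine_argmax(self, small_dict):
        rng = np.random.default_rng(3)
        queries = rng.normal(size=(200, 35))
        for q in queries:
            _, _, idx = m.match_signal(q, small_dict)
            qn = q / np.linalg.norm(q)
            cosines = small_dict.signals @ qn  # brute-force oracle
            assert idx == int(np.argmax(cosines))


class TestMatchStack:
    def _stack_from_entries(self, dictionary, rows, shape):
        data = np.zeros((*shape, dictionary.n_timepoints))
        mask = np.zeros(shape, dtype=bool)
        coords = list(zip(*np.unravel_index(np.arange(len(rows)), shape)))
        for (r, c), row in zip(coords, rows):
            data[r, c] = dictionary.signals[row]
            mask[r, c] = True
        return m.BaselineStack(data, mask), coords

    def test_perfect_recovery_of_generating_entries(self, small_dict):
        rows = [3, 40, 77, 101]
        stack, coords = self._stack_from_entries(small_dict, rows, (2, 2))
        result = m.match_stack(stack, small_dict)
        for (r, c), row in zip(coords, rows):
            assert result.index_map[r, c] == row
            assert result.t1_map[r, c] == small_dict.params[row, 0]
            assert result.t2s_map[r, c] == small_dict.params[row, 1]

    def test_all_zero_stack_counts_unmatched(self, small_dict):
        stack = m.BaselineStack(np.zeros((2, 2, 35)), np.ones((2, 2), bool))
        result = m.match_stack(stack, small_dict)
        assert result.n_unmatched == 4
        assert np.all(result.index_map == -1)
        assert np.all(result.t1_map == 0)

    def test_outside_mask_left_zero(self, small_dict):
        stack, _ = self._stack_from_entries(small_dict, [0], (3, 3))
        result = m.match_stack(stack, small_dict)
        assert result.t1_map[2, 2] == 0
        assert result.index_map[2, 2] == -1


class TestSNR:
    def test_closed_form_value(self):
        assert m.compute_snr([3, 4], [1, 0]) == pytest.approx(10 * np.log10(25), abs=1e-12)

    def test_zero_noise_gives_infinity(self):
        assert m.compute_snr([1, 2], [0, 0]) == np.inf

    def test_twenty_db_hand_case(self):
        s = np.ones(35)
        n = np.full(35, 0.1)
        assert m.compute_snr(s, n) == pytest.approx(20.0, abs=1e-12)

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            m.compute_snr([0, 0], [1, 1])

    def test_residual_scaling_shifts_by_twenty_db(self):
        rng = np.random.default_rng(0)
        s, n = rng.normal(size=35), rng.normal(size=35)
        assert m.compute_snr(s, 10 * n) == pytest.approx(m.compute_snr(s, n) - 20.0, abs=1e-10)


class TestNoiseBank:
    def test_noise_free_stack_gives_zero_residuals(self, small_dict):
        data = np.zeros((2, 2, 35))
        mask = np.ones((2, 2), bool)
        for k, (r, c) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
            data[r, c] = small_dict.signals[k * 3]
        stack = m.BaselineStack(data, mask)
        bank, snr_map = m.extract_noise_bank(stack, small_dict)
        assert np.abs(bank.residuals).max() < 1e-12
        assert np.all(np.isinf(snr_map[mask]) | (snr_map[mask] > 200))

    def test_known_perturbation_recovered(self, small_dict):
        j = 8
        d = np.zeros(35)
        d[0] = 1e-6  # small enough not to change the best match
        noisy = small_dict.signals[j] + d
        _, _, idx = m.match_signal(noisy, small_dict)
        assert idx == j
        stack = m.BaselineStack(noisy[None, None, :], np.ones((1, 1), bool))
        bank, _ = m.extract_noise_bank(stack, small_dict)
        expected = noisy / np.linalg.norm(noisy) - small_dict.signals[j]
        np.testing.assert_allclose(bank.residuals[0], expected, atol=1e-15)

    def test_pooled_value_bookkeeping(self, small_dict):
        rng = np.random.default_rng(1)
        rows = rng.integers(0, len(small_dict), 10)
        data = small_dict.signals[rows].reshape(5, 2, 35) + rng.normal(0, 1e-3, (5, 2, 35))
        stack = m.BaselineStack(data, np.ones((5, 2), bool))
        bank, _ = m.extract_noise_bank(stack, small_dict)
        assert bank.pooled_values.size == 10 * 35

    def test_sampling_deterministic_under_seed(self, gaussian_bank_20db):
        a = m.sample_noise(gaussian_bank_20db, 35, rng=123, size=4)
        b = m.sample_noise(gaussian_bank_20db, 35, rng=123, size=4)
        assert np.array_equal(a, b)

    def test_single_value_pool_returns_constant(self):
        bank = m.NoiseBank(np.full((1, 4), 0.25))
        draw = m.sample_noise(bank, 6, mode="pooled_iid", rng=0)
        assert np.all(draw == 0.25)

    def test_permuted_vector_preserves_multiset(self):
        row = np.arange(35, dtype=float) / 100
        bank = m.NoiseBank(row[None, :])
        draw = m.sample_noise(bank, 35, mode="permuted_vector", rng=5)
        assert sorted(draw) == pytest.approx(sorted(row))

    def test_round_trip_energy_preserved(self, small_dict):
        rng = np.random.default_rng(2)
        bank = m.NoiseBank(rng.normal(0, 1e-3, size=(50, 35)))
        j = 30
        noise = m.sample_noise(bank, 35, rng=7)
        noisy = small_dict.signals[j] + noise
        stack = m.BaselineStack(noisy[None, None, :], np.ones((1, 1), bool))
        new_bank, _ = m.extract_noise_bank(stack, small_dict)
        _, _, idx = m.match_signal(noisy, small_dict)
        if idx == j:  # unchanged match: energies agree up to renormalization
            e_in = np.sum(noise**2)
            e_out = np.sum(new_bank.residuals[0] ** 2)
            assert e_out == pytest.approx(e_in, abs=1e-6)

    def test_empty_bank_rejected(self):
        with pytest.raises(ValueError):
            m.sample_noise(m.NoiseBank(np.zeros((0, 35))), 35)
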