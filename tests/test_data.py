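"""Sensor-log parsing, scaling, windowing and fold-splitting behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsldmf.data import (DataError, FeatureFrame, FeatureSequence, FormatError,
                         InsufficientDataError, ScalingSpec, apply_minmax,
                         build_observations, compute_magnitudes, fit_minmax,
                         kfold_split, read_sensor_log)


def write_log(path, omega, accel, t=None):
    omega, accel = np.atleast_2d(omega), np.atleast_2d(accel)
    t = np.arange(len(omega)) / 30.0 if t is None else t
    pd.DataFrame({"t": t, "wx": omega[:, 0], "wy": omega[:, 1],
                  "wz": omega[:, 2], "ax": accel[:, 0], "ay": accel[:, 1],
                  "az": accel[:, 2]}).to_csv(path, index=False)
    return path


class TestMagnitudes:
    @pytest.mark.parametrize("omega,accel,expected", [
        ((3, 4, 0), (0, 0, 0), (5.0, 0.0)),
        ((0, 0, 0), (0, 0, 0), (0.0, 0.0)),
        ((0.3, 0.4, 1.2), (1, 2, 2), (1.3, 3.0)),
    ])
    def test_euclidean_norms(self, omega, accel, expected):
        assert compute_magnitudes(omega, accel) == pytest.approx(expected)

    def test_rejects_non_finite(self):
        with pytest.raises(DataError):
            compute_magnitudes((np.nan, 0, 0), (0, 0, 0))


class TestReadSensorLog:
    def test_zero_rows_give_zero_features(self, tmp_path):
        path = write_log(tmp_path / "z.csv", np.zeros((3, 3)), np.zeros((3, 3)))
        seq = read_sensor_log(path)
        assert len(seq) == 3
        assert np.all(seq.feature_matrix() == 0)

    def test_magnitudes_computed_on_read(self, tmp_path):
        path = write_log(tmp_path / "m.csv", [[3, 4, 0]], [[0, 0, 0]])
        frame = read_sensor_log(path).frames[0]
        assert frame.omega_T == pytest.approx(5.0)
        assert frame.A_T == pytest.approx(0.0)

    def test_sixty_second_log_has_1800_frames(self, tmp_path):
        n = 1800  # 60 s at 30 Hz
        rng = np.random.default_rng(0)
        path = write_log(tmp_path / "l.csv", rng.normal(size=(n, 3)),
                         rng.normal(size=(n, 3)))
        assert len(read_sensor_log(path)) == n

    def test_missing_channel_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"t": [0], "wx": [0], "wy": [0]}).to_csv(path, index=False)
        with pytest.raises(FormatError):
            read_sensor_log(path)

    def test_non_monotone_timestamps_rejected(self, tmp_path):
        path = write_log(tmp_path / "t.csv", np.zeros((3, 3)), np.zeros((3, 3)),
                         t=[0.0, 0.2, 0.1])
        with pytest.raises(DataError):
            read_sensor_log(path)


class TestMinMaxScaling:
    def test_single_feature_envelope(self):
        seq = FeatureSequence.from_arrays(
            [0.0, 1.0], [[0, 1, 2], [10, 2, 1]], [[1, 2, 3], [3, 4, 1]])
        spec = fit_minmax([seq])
        assert spec.minimum[0] == 0 and spec.maximum[0] == 10

    def test_envelope_covers_all_subjects(self):
        a = FeatureSequence.from_arrays(
            [0, 1], [[0, 1, 3], [1, 0, 2]], [[0, 1, 1], [1, 0, 2]])
        b = FeatureSequence.from_arrays(
            [0, 1], [[-1, 2, 1], [2, -1, 4]], [[2, 1, 0], [0, 2, 3]])
        spec = fit_minmax([a, b])
        assert spec.minimum[0] == -1 and spec.maximum[0] == 2

    def test_matches_elementwise_scan_oracle(self):
        rng = np.random.default_rng(5)
        seqs = [FeatureSequence.from_arrays(np.arange(20) / 30,
                                            rng.normal(size=(20, 3)),
                                            rng.normal(size=(20, 3)))
                for _ in range(4)]
        spec = fit_minmax(seqs)
        stacked = np.vstack([s.feature_matrix() for s in seqs])
        np.testing.assert_allclose(spec.minimum, stacked.min(axis=0))
        np.testing.assert_allclose(spec.maximum, stacked.max(axis=0))

    def test_constant_feature_is_degenerate(self):
        seq = FeatureSequence.from_arrays([0, 1], [[0, 0, 0], [1, 1, 1]],
                                          [[0, 0, 5], [0, 0, 5]])
        with pytest.raises(DataError):
            fit_minmax([seq])  # az (and A_T) constant

    @pytest.mark.parametrize("value,expected", [(0.0, 0.0), (10.0, 1.0),
                                                (5.0, 0.5)])
    def test_endpoints_and_midpoint(self, value, expected):
        spec = ScalingSpec(np.zeros(8), np.full(8, 10.0))
        frame = FeatureFrame.from_components([value, 0, 0], [0, 0, value], 0.0)
        scaled = apply_minmax(frame, spec)
        assert scaled[0] == pytest.approx(expected)

    def test_out_of_envelope_values_clip(self):
        spec = ScalingSpec(np.zeros(8), np.ones(8))
        assert np.all(spec.transform(np.full(8, 7.0)) == 1.0)
        assert np.all(spec.transform(np.full(8, -7.0)) == 0.0)

    @given(st.lists(st.floats(min_value=0.01, max_value=0.99), min_size=8,
                    max_size=8))
    @settings(deadline=None, max_examples=25)
    def test_roundtrip_recovers_in_range_values(self, scaled):
        spec = ScalingSpec(np.full(8, -2.0), np.full(8, 3.0))
        values = spec.inverse(np.array(scaled))
        np.testing.assert_allclose(spec.transform(values), scaled, atol=1e-9)

    def test_yaml_roundtrip(self, tmp_path):
        spec = ScalingSpec(np.arange(8.0), np.arange(8.0) + 1)
        spec.to_yaml(tmp_path / "s.yaml")
        loaded = ScalingSpec.from_yaml(tmp_path / "s.yaml")
        np.testing.assert_allclose(loaded.minimum, spec.minimum)
        np.testing.assert_allclose(loaded.maximum, spec.maximum)


class TestObservationWindows:
    @pytest.fixture
    def spec(self):
        return ScalingSpec(np.full(8, -10.0), np.full(8, 10.0))

    def make_seq(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return FeatureSequence.from_arrays(np.arange(n) / 30,
                                           rng.normal(size=(n, 3)),
                                           rng.normal(size=(n, 3)))

    def test_five_frames_give_three_windows(self, spec):
        obs = build_observations(self.make_seq(5), spec)
        assert len(obs) == 3
        assert obs.windows[0].time_index == 0 and obs.T == 2

    @pytest.mark.parametrize("n", [3, 10, 47])
    def test_every_window_is_24_dimensional(self, n, spec):
        obs = build_observations(self.make_seq(n), spec)
        assert all(w.values.shape == (24,) for w in obs.windows)

    def test_two_frames_is_insufficient(self, spec):
        with pytest.raises(InsufficientDataError):
            build_observations(self.make_seq(2), spec)

    def test_window_stacks_current_and_two_previous_frames(self, spec):
        seq = self.make_seq(6, seed=3)
        scaled = spec.transform(seq.feature_matrix())
        obs = build_observations(seq, spec)
        for t, w in enumerate(obs.windows):
            np.testing.assert_allclose(
                w.values, np.concatenate([scaled[t + 2], scaled[t + 1],
                                          scaled[t]]))

    def test_consecutive_windows_share_16_entries(self, spec):
        obs = build_observations(self.make_seq(30, seed=4), spec)
        for prev, cur in zip(obs.windows, obs.windows[1:]):
            np.testing.assert_allclose(cur.values[8:24], prev.values[0:16])


class TestKFoldSplit:
    def test_hundred_samples_give_20_percent_test_folds(self):
        folds = kfold_split(100, k=5)
        assert len(folds) == 5
        assert all(len(f.test_indices) == 20 for f in folds)

    def test_ten_samples_give_folds_of_two(self):
        assert all(len(f.test_indices) == 2 for f in kfold_split(10, 5))

    def test_remainder_goes_to_earlier_folds(self):
        # KFold convention: the first n % k folds are one element larger
        sizes = [len(f.test_indices) for f in kfold_split(7, 5)]
        assert sizes == [2, 2, 1, 1, 1]

    def test_folds_are_consecutive_blocks(self):
        for fold in kfold_split(23, 5):
            np.testing.assert_array_equal(
                fold.test_indices,
                np.arange(fold.test_indices[0], fold.test_indices[-1] + 1))

    @given(st.integers(min_value=5, max_value=200))
    @settings(deadline=None, max_examples=30)
    def test_test_sets_partition_the_index_range(self, n):
        folds = kfold_split(n, 5)
        all_test = np.concatenate([f.test_indices for f in folds])
        np.testing.assert_array_equal(np.sort(all_test), np.arange(n))
        for f in folds:
            assert set(f.train_indices).isdisjoint(f.test_indices)
            assert len(f.train_indices) + len(f.test_indices) == n

    def test_too_few_samples_raise(self):
        with pytest.raises(InsufficientDataError):
            kfold_split(4, 5)
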