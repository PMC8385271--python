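"""Spectrogram geometry, DFT-by-summation oracle, and dataset extraction."""

import numpy as np
import pytest

from boldspect import (
    CohortSpec,
    StftConfig,
    VoxelSelection,
    extract_dataset,
    load_dataset,
    normalize,
    save_dataset,
    simulate_cohort,
    stft,
)

BOXCAR = StftConfig(window_function="boxcar")


def _dft_oracle(series, tr, cfg: StftConfig):
    """Direct DFT by explicit summation over each windowed frame."""
    from scipy.signal import get_window

    win = cfg.window_samples(tr)
    taper = get_window(cfg.window_function, win, fftbins=True)
    n_frames = (len(series) - win) // cfg.hop_samples + 1
    n_freq = cfg.fft_length // 2 + 1 if cfg.one_sided else cfg.fft_length
    out = np.zeros((n_freq, n_frames), dtype=complex)
    for m in range(n_frames):
        frame = series[m * cfg.hop_samples : m * cfg.hop_samples + win] * taper
        padded = np.concatenate([frame, np.zeros(cfg.fft_length - win)])
        for k in range(n_freq):
            out[k, m] = sum(
                padded[n] * np.exp(-2j * np.pi * k * n / cfg.fft_length)
                for n in range(cfg.fft_length)
            )
    return np.abs(out)


class TestStft:
    def test_geometry_31_by_56(self, rng):
        """60 volumes, TR 2 s, 10-s window, hop 1, FFT 60 -> 31 x 56."""
        spec = stft(rng.normal(size=60), 2.0)
        assert spec.shape == (31, 56)
        assert len(spec.freq_axis_hz) == 31
        assert len(spec.time_axis_seconds) == 56

    def test_axis_metadata(self, rng):
        spec = stft(rng.normal(size=60), 2.0)
        # bin k at k / (fft_length * tr); Nyquist bin at 0.25 Hz
        assert spec.freq_axis_hz[1] == pytest.approx(1 / 120)
        assert spec.freq_axis_hz[-1] == pytest.approx(0.25)
        # frame m centred at (m * hop + window/2) * tr
        assert spec.time_axis_seconds[0] == pytest.approx(2.5 * 2.0)
        assert spec.time_axis_seconds[1] - spec.time_axis_seconds[0] == pytest.approx(2.0)

    def test_constant_series_all_energy_in_dc(self):
        """DC concentration needs an unpadded transform (FFT length = window)."""
        cfg = StftConfig(window_function="boxcar", fft_length=5)
        spec = stft(np.full(60, 3.0), 2.0, cfg)
        assert np.all(spec.values[0] == pytest.approx(15.0))  # 5 * 3.0
        assert np.all(np.abs(spec.values[1:]) < 1e-10)

    def test_on_bin_cosine_peaks_at_its_bin(self):
        """cos at bin k=10 of a full-length window peaks at row 10 everywhere."""
        cfg = StftConfig(window_seconds=120.0, hop_samples=1, fft_length=60,
                         window_function="boxcar")
        t = np.arange(60) * 2.0
        f0 = 10 / (60 * 2.0)
        spec = stft(np.cos(2 * np.pi * f0 * t), 2.0, cfg)
        assert spec.shape == (31, 1)
        assert np.all(spec.values.argmax(axis=0) == 10)

    @pytest.mark.parametrize("cfg", [
        BOXCAR,
        StftConfig(),
        StftConfig(window_function="boxcar", one_sided=False),
        StftConfig(hop_samples=3, fft_length=64),
    ], ids=["boxcar", "hann", "two-sided", "hop3-pad64"])
    def test_matches_dft_summation_oracle(self, cfg, rng):
        series = rng.normal(size=60)
        got = stft(series, 2.0, cfg)
        np.testing.assert_allclose(got.values, _dft_oracle(series, 2.0, cfg),
                                   atol=1e-8)

    def test_parseval_per_frame(self, rng):
        """Two-sided boxcar frames: sum |X|^2 = fft_length * sum |x_w|^2."""
        cfg = StftConfig(window_function="boxcar", one_sided=False,
                         magnitude=False)
        series = rng.normal(size=60)
        spec = stft(series, 2.0, cfg)
        win = cfg.window_samples(2.0)
        for m in range(spec.shape[1]):
            frame = series[m : m + win]
            lhs = spec.values[:, m].sum()
            rhs = cfg.fft_length * (frame**2).sum()
            assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_shift_covariance_by_one_hop(self, rng):
        series = rng.normal(size=61)
        a = stft(series[:-1], 2.0, BOXCAR)
        b = stft(series[1:], 2.0, BOXCAR)
        np.testing.assert_allclose(a.values[:, 1:], b.values[:, :-1], atol=1e-8)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter than"):
            stft(np.zeros(4), 2.0)


class TestNormalize:
    def test_constant_spectrogram_maps_to_zeros(self):
        spec = stft(np.full(60, 2.0), 2.0, BOXCAR)
        spec.values = np.full_like(spec.values, 7.0)
        for mode in ("minmax", "zscore"):
            assert np.all(normalize(spec, mode).values == 0.0)

    def test_minmax_bounds_exact(self, rng):
        spec = stft(rng.normal(size=60), 2.0)
        out = normalize(spec, "minmax").values
        assert out.min() == 0.0 and out.max() == 1.0

    def test_zscore_moments(self, rng):
        spec = stft(rng.normal(size=60), 2.0)
        out = normalize(spec, "zscore").values
        assert abs(out.mean()) < 1e-9 and abs(out.std() - 1.0) < 1e-9

    def test_unknown_mode_rejected(self, rng):
        spec = stft(rng.normal(size=60), 2.0)
        with pytest.raises(ValueError):
            normalize(spec, "log")


class TestExtractDataset:
    def _selection(self, coords):
        coords = np.asarray(coords)
        return VoxelSelection(coordinates=coords,
                              t_values=np.full(len(coords), 4.0),
                              cluster_ids=np.ones(len(coords), dtype=int))

    def test_count_and_ordering(self, noiseless_cohort):
        runs = noiseless_cohort[:3]
        sel = self._selection([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]])
        specs = extract_dataset(runs, sel)
        assert len(specs) == 12  # 3 subjects x 4 voxels, subject-major
        assert [s.subject_id for s in specs[:4]] == [runs[0].subject_id] * 4
        assert specs[1].voxel_coordinate == (1, 1, 1)

    def test_labels_propagate(self, noiseless_cohort):
        sel = self._selection([[0, 0, 0]])
        specs = extract_dataset(noiseless_cohort, sel)
        assert [s.label for s in specs] == [r.label for r in noiseless_cohort]

    def test_out_of_grid_coordinate_rejected(self, noiseless_cohort):
        sel = self._selection([[9, 9, 9]])
        with pytest.raises(IndexError):
            extract_dataset(noiseless_cohort, sel)

    def test_empty_selection_rejected(self, noiseless_cohort):
        sel = VoxelSelection(coordinates=np.empty((0, 3), dtype=int),
                             t_values=np.empty(0), cluster_ids=np.empty(0, int))
        with pytest.raises(ValueError):
            extract_dataset(noiseless_cohort, sel)

    def test_dataset_round_trip(self, tmp_path, noiseless_cohort):
        sel = self._selection([[0, 0, 0], [2, 1, 3]])
        specs = extract_dataset(noiseless_cohort, sel, normalize_mode="minmax")
        save_dataset(specs, tmp_path / "ds")
        back = load_dataset(tmp_path / "ds")
        assert len(back) == len(specs)
        for a, b in zip(specs, back):
            np.testing.assert_allclose(a.values, b.values, atol=1e-7)
            assert a.subject_id == b.subject_id
            assert a.label == b.label
            assert a.voxel_coordinate == b.voxel_coordinate
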