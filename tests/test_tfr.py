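"""Time-frequency transforms against brute-force oracles.

The CWT oracle evaluates the wavelet integral directly: the analysing
wavelet is recovered from its frequency-domain bump by numerical
quadrature, then the transform is a plain time-domain sum — fully
independent of the FFT implementation under test.  The STFT oracle is a
naive DFT of individually windowed frames.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegtfdx.tfr import BumpWavelet, ScaleGrid, cwt_bump, stft_spectrogram

FS = 256.0


def bump_psi_time(wavelet: BumpWavelet, s: np.ndarray) -> np.ndarray:
    """psi(s) = (1/2pi) integral Psi(w) exp(iws) dw by trapezoid quadrature."""
    w = np.linspace(wavelet.mu - wavelet.sigma, wavelet.mu + wavelet.sigma, 4001)
    psi_w = wavelet.freq_response(w)
    return np.trapezoid(
        psi_w[None, :] * np.exp(1j * np.outer(s, w)), w, axis=1
    ) / (2 * np.pi)


def cwt_direct(x: np.ndarray, a: float, b: int, wavelet: BumpWavelet) -> complex:
    """W(a, b) = (1/sqrt(a)) sum_t x[t] conj(psi((t - b) / a))."""
    t = np.arange(x.size)
    return np.sum(x * np.conj(bump_psi_time(wavelet, (t - b) / a))) / np.sqrt(a)


def sinusoid(freq, seconds=1.0, fs=FS):
    return np.sin(2 * np.pi * freq * np.arange(int(fs * seconds)) / fs)


class TestCwt:
    def test_zero_signal_zero_scalogram(self):
        out = cwt_bump(np.zeros(256), FS)
        assert out.kind == "scalogram"
        np.testing.assert_array_equal(out.values, 0)

    @pytest.mark.parametrize("probe", [4.0, 6.0, 10.0, 20.0, 35.0])
    def test_ridge_frequency_within_one_scale_step(self, probe):
        out = cwt_bump(sinusoid(probe), FS)
        mid = out.values.shape[1] // 2
        found = out.freq_axis[np.argmax(out.values[:, mid])]
        # grid spacing is 1/12 octave; allow one scale step
        assert abs(np.log2(found / probe)) <= 1.0 / 12 + 1e-9

    def test_matches_direct_integration_oracle(self):
        # five scales bracketing the 10 Hz probe, centre translation
        wavelet = BumpWavelet()
        x = sinusoid(10.0, seconds=2.0)
        b = x.size // 2
        a10 = wavelet.mu * FS / (2 * np.pi * 10.0)
        scales = a10 * 2.0 ** (np.arange(-2, 3) / 12.0)
        direct = np.array([abs(cwt_direct(x, a, b, wavelet)) for a in scales])
        grid = ScaleGrid(
            scales=np.sort(scales),
            center_freqs=(wavelet.mu * FS / (2 * np.pi * np.sort(scales))),
        )
        fast = cwt_bump(x, FS, wavelet=wavelet, grid=grid).values[::-1, b]
        # rows were stored freq-ascending == scale-descending; realign.
        # near-zero off-ridge coefficients carry quadrature error, hence the
        # absolute floor; at the ridge the agreement is ~0.1%
        np.testing.assert_allclose(
            fast, direct, rtol=0.05, atol=0.02 * direct.max()
        )
        assert np.argmax(fast) == np.argmax(direct)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=30.0))
    def test_homogeneous_of_degree_one(self, c):
        x = sinusoid(10.0)
        base = cwt_bump(x, FS).values
        scaled = cwt_bump(c * x, FS).values
        np.testing.assert_allclose(scaled, c * base, rtol=1e-9, atol=1e-12)

    def test_time_shift_covariance_interior(self):
        rng = np.random.default_rng(3)
        x = np.zeros(1024)
        x[300:700] = rng.standard_normal(400)
        k = 50
        xs = np.zeros(1024)
        xs[300 + k : 700 + k] = x[300:700]
        grid = ScaleGrid.from_freq_range(FS, freq_min=4.0, freq_max=40.0)
        v = cwt_bump(x, FS, grid=grid).values
        vs = cwt_bump(xs, FS, grid=grid).values
        np.testing.assert_allclose(vs[:, k:], v[:, :-k], atol=1e-8 * v.max())

    def test_nan_input_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            cwt_bump(np.array([0.0, np.nan, 1.0]), FS)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            ScaleGrid(scales=np.array([5.0]), center_freqs=np.array([10.0]))
        with pytest.raises(ValueError):
            ScaleGrid(scales=np.array([5.0, 5.0]), center_freqs=np.array([10.0, 10.0]))


def stft_frame_oracle(x, start, win):
    """|DFT|^2 of one windowed frame by explicit summation."""
    frame = x[start : start + win.size] * win
    n = win.size
    k = np.arange(n // 2 + 1)
    dft = np.array(
        [np.sum(frame * np.exp(-2j * np.pi * kk * np.arange(n) / n)) for kk in k]
    )
    return np.abs(dft) ** 2


class TestStft:
    def test_zero_signal_zero_spectrogram(self):
        out = stft_spectrogram(np.zeros(512), FS, window_len=128)
        assert out.kind == "spectrogram"
        np.testing.assert_array_equal(out.values, 0)

    @pytest.mark.parametrize("probe", [4.0, 6.0, 10.0, 20.0, 35.0])
    def test_ridge_bin_nearest_probe(self, probe):
        out = stft_spectrogram(sinusoid(probe), FS, window="hann", window_len=128)
        df = out.freq_axis[1] - out.freq_axis[0]
        for col in range(out.values.shape[1]):
            found = out.freq_axis[np.argmax(out.values[:, col])]
            assert abs(found - probe) <= df

    def test_matches_bruteforce_frame_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(300)
        out = stft_spectrogram(x, FS, window="rect", window_len=64, overlap=0.5)
        for j, start in enumerate(range(0, 300 - 64 + 1, 32)):
            oracle = stft_frame_oracle(x, start, np.ones(64))
            np.testing.assert_allclose(out.values[:, j], oracle, rtol=1e-8, atol=1e-8)

    def test_parseval_rect_window_zero_overlap(self):
        # energy accounting with one-sided doubling, in-grid sinusoid
        n, win = 512, 64
        x = np.sin(2 * np.pi * 5 * np.arange(n) / win)  # bin 5 of each frame
        out = stft_spectrogram(x, FS, window="rect", window_len=win, overlap=0.0)
        weights = np.full(out.freq_axis.size, 2.0)
        weights[0] = weights[-1] = 1.0
        energy_tf = float(np.sum(weights[:, None] * out.values)) / win
        energy_time = float(np.sum(x**2))
        assert energy_tf == pytest.approx(energy_time, rel=0.01)

    def test_homogeneous_of_degree_two(self):
        x = sinusoid(10.0)
        base = stft_spectrogram(x, FS, window_len=128).values
        scaled = stft_spectrogram(3.0 * x, FS, window_len=128).values
        np.testing.assert_allclose(scaled, 9.0 * base, rtol=1e-9, atol=1e-9 * base.max())

    def test_shift_by_one_hop_shifts_columns(self):
        rng = np.random.default_rng(5)
        x = np.zeros(640)
        x[200:400] = rng.standard_normal(200)
        hop = 64
        xs = np.roll(x, hop)
        v = stft_spectrogram(x, FS, window_len=128, overlap=0.5).values
        vs = stft_spectrogram(xs, FS, window_len=128, overlap=0.5).values
        np.testing.assert_allclose(vs[:, 1:], v[:, :-1], atol=1e-9 * v.max())

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError, match="window_len"):
            stft_spectrogram(np.zeros(100), FS, window_len=128)
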