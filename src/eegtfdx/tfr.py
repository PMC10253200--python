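"""Time-frequency representations: bump-wavelet CWT and STFT spectrogram.

The scalogram is the magnitude of the continuous wavelet transform

    W(a, b) = (1 / sqrt(a)) * integral x(t) psi*((t - b) / a) dt,

computed in the frequency domain.  The analysing wavelet is the *bump*
wavelet, an analytic wavelet whose Fourier transform is the compactly
supported C-infinity window

    Psi(w) = exp(1 - 1 / (1 - ((w - mu) / sigma)^2))   for |w - mu| < sigma,
    Psi(w) = 0                                         elsewhere,

with centre ``mu`` (radians/sample) and half-width ``sigma``.  A scale ``a``
therefore selects the analysis band centred at ``f = mu * fs / (2 pi a)``
Hz.  The spectrogram is the squared magnitude of the short-time Fourier
transform with equal-length windows on a uniform 0..fs/2 frequency grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window

__all__ = [
    "BumpWavelet",
    "ScaleGrid",
    "TFRMatrix",
    "cwt_bump",
    "stft_spectrogram",
]


@dataclass
class BumpWavelet:
    """Bump wavelet parameters: centre mu (rad/sample) and half-width sigma."""

    mu: float = 5.0
    sigma: float = 0.6

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not self.mu > self.sigma:
            raise ValueError("mu must exceed sigma so the support stays positive")

    def freq_response(self, omega: np.ndarray) -> np.ndarray:
        """Psi(omega) evaluated elementwise; zero outside (mu-sigma, mu+sigma)."""
        omega = np.asarray(omega, dtype=np.float64)
        out = np.zeros_like(omega)
        u = (omega - self.mu) / self.sigma
        inside = np.abs(u) < 1.0
        out[inside] = np.exp(1.0 - 1.0 / (1.0 - u[inside] ** 2))
        return out


@dataclass
class ScaleGrid:
    """Strictly increasing scales with their (decreasing) centre frequencies."""

    scales: np.ndarray
    center_freqs: np.ndarray
    voices_per_octave: int = 12

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=np.float64)
        self.center_freqs = np.asarray(self.center_freqs, dtype=np.float64)
        if self.scales.size < 2:
            raise ValueError("scale grid needs at least two scales")
        if not np.all(np.diff(self.scales) > 0):
            raise ValueError("scales must be strictly increasing")
        if not np.all(np.diff(self.center_freqs) < 0):
            raise ValueError("center frequencies must be strictly decreasing")
        if self.scales.size != self.center_freqs.size:
            raise ValueError("scales and center_freqs must have equal length")

    @classmethod
    def from_freq_range(
        cls,
        fs: float,
        freq_min: float = 1.0,
        freq_max: float = 40.0,
        voices_per_octave: int = 12,
        wavelet: BumpWavelet | None = None,
    ) -> "ScaleGrid":
        """Geometric frequency grid from freq_max down to freq_min."""
        if not (0 < freq_min < freq_max <= fs / 2):
            raise ValueError("need 0 < freq_min < freq_max <= fs/2")
        wavelet = wavelet or BumpWavelet()
        n_octaves = np.log2(freq_max / freq_min)
        n = int(np.floor(n_octaves * voices_per_octave)) + 1
        freqs = freq_max * 2.0 ** (-np.arange(n) / voices_per_octave)
        scales = wavelet.mu * fs / (2 * np.pi * freqs)
        return cls(scales=scales, center_freqs=freqs, voices_per_octave=voices_per_octave)


@dataclass
class TFRMatrix:
    """Non-negative time-frequency magnitudes/power with axis vectors.

    Rows follow ``freq_axis`` which is stored in *ascending* frequency
    order; renderers flip so frequency increases upward in images.
    """

    values: np.ndarray
    time_axis: np.ndarray
    freq_axis: np.ndarray
    kind: str  # "scalogram" | "spectrogram"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.time_axis = np.asarray(self.time_axis, dtype=np.float64)
        self.freq_axis = np.asarray(self.freq_axis, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_freq, n_time)")
        if self.values.shape != (self.freq_axis.size, self.time_axis.size):
            raise ValueError("axis lengths must match the value matrix")
        if np.any(self.values < 0):
            raise ValueError("time-frequency values must be non-negative")
        if self.kind not in ("scalogram", "spectrogram"):
            raise ValueError(f"unknown kind {self.kind!r}")


def cwt_bump(
    signal: np.ndarray,
    fs: float,
    wavelet: BumpWavelet | None = None,
    grid: ScaleGrid | None = None,
) -> TFRMatrix:
    """Bump-wavelet scalogram via frequency-domain multiplication.

    For each scale the row is ``|ifft(fft(x) * sqrt(a) * Psi(a * omega))|``
    with the signal zero-padded to the next power of two at least twice its
    length (so the implied convolution is effectively linear).  Edge effects
    are not masked; the full time plane is returned.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("signal must be a 1-D vector of length >= 2")
    if not np.isfinite(x).all():
        raise ValueError("signal contains NaN/inf")
    if not fs > 0:
        raise ValueError("fs must be positive")
    wavelet = wavelet or BumpWavelet()
    grid = grid or ScaleGrid.from_freq_range(fs, wavelet=wavelet)

    n = x.size
    m = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.fft(x, m)
    omega = 2 * np.pi * np.fft.fftfreq(m)  # rad/sample, signed
    pos = omega > 0

    rows = np.empty((grid.scales.size, n))
    for i, a in enumerate(grid.scales):
        psi = np.zeros(m)
        psi[pos] = wavelet.freq_response(a * omega[pos])
        coeff = np.fft.ifft(spec * (np.sqrt(a) * psi))[:n]
        rows[i] = np.abs(coeff)

    # grid is scale-ascending == frequency-descending; store freq-ascending
    return TFRMatrix(
        values=rows[::-1],
        time_axis=np.arange(n) / fs,
        freq_axis=grid.center_freqs[::-1],
        kind="scalogram",
    )


def stft_spectrogram(
    signal: np.ndarray,
    fs: float,
    window: str = "hann",
    window_len: int | None = None,
    overlap: float = 0.5,
) -> TFRMatrix:
    """Short-time Fourier spectrogram |X(t, f)|^2 with equal-length windows.

    Frames start at sample 0 and advance by ``hop = window_len * (1 -
    overlap)``; each frame is windowed and transformed with a real FFT onto
    the uniform one-sided grid 0..fs/2.  ``window`` may be ``hann``,
    ``hamming`` or ``rect``.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("signal must be a 1-D vector of length >= 2")
    if not np.isfinite(x).all():
        raise ValueError("signal contains NaN/inf")
    if window_len is None:
        window_len = int(round(fs))
    if window_len > x.size:
        raise ValueError(
            f"window_len={window_len} exceeds signal length {x.size}"
        )
    if not (0 <= overlap < 1):
        raise ValueError("overlap must lie in [0, 1)")
    if window not in ("hann", "hamming", "rect"):
        raise ValueError(f"unknown window {window!r}; expected hann/hamming/rect")
    win = (
        np.ones(window_len)
        if window == "rect"
        else get_window(window, window_len, fftbins=True)
    )
    hop = max(1, int(round(window_len * (1.0 - overlap))))
    starts = np.arange(0, x.size - window_len + 1, hop)
    frames = np.stack([x[s : s + window_len] * win for s in starts])
    power = np.abs(np.fft.rfft(frames, axis=1)) ** 2
    return TFRMatrix(
        values=power.T,
        time_axis=(starts + window_len / 2.0) / fs,
        freq_axis=np.fft.rfftfreq(window_len, d=1.0 / fs),
        kind="spectrogram",
    )
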