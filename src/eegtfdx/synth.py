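"""Synthetic two-class, three-condition EEG cohorts.

The generator emulates the statistical shape of an interictal-migraine
study cohort: two groups of subjects (MD = migraine, HC = healthy control,
defaults 18 + 21), multichannel recordings sampled at 512 Hz, recorded in
one of three stimulus conditions — resting (R), auditory entrainment (A)
and visual contrast-reversal (V).  Each channel is Gaussian 1/f^beta
coloured noise plus a small set of condition-specific sinusoidal drives:
a 10 Hz alpha rhythm at rest and 4/6 Hz stimulus-entrainment components
under the A and V drives.

The class contrast is a monotone knob, not a biophysical model: migraine
subjects have their 4-8 Hz (theta) band power raised and their 8-12 Hz
(alpha) power lowered by a factor ``1 + class_separation * CONTRAST_GAIN``.
At ``class_separation = 0`` the two class-generating distributions are
identical, which makes the generator usable as a null for calibrating the
downstream classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_signals import MultichannelRecording

__all__ = ["SynthConfig", "class_signature", "generate_recording", "generate_cohort"]

#: multiplies class_separation to give the band-power contrast factor
CONTRAST_GAIN = 0.5

#: weight of the shared (all-channel) noise source, a crude volume-conduction analog
SHARED_NOISE_WEIGHT = 0.3

# (frequency Hz, amplitude a.u.) per condition, before class contrast.
# R: dominant resting alpha with a weak theta component; A/V: dominant
# stimulus drive (6 Hz tones / 4 Hz contrast reversal) plus residual alpha.
_BASE_SIGNATURES = {
    "R": ((10.0, 1.0), (6.0, 0.4)),
    "A": ((6.0, 1.0), (10.0, 0.6)),
    "V": ((4.0, 1.0), (10.0, 0.6)),
}

_THETA = (4.0, 8.0)
_ALPHA = (8.0, 12.0)


@dataclass
class SynthConfig:
    """Cohort-generation parameters; defaults mirror the emulated study."""

    n_md: int = 18
    n_hc: int = 21
    n_channels: int = 64
    fs: float = 512.0
    duration: float = 10.0
    condition: str = "R"
    class_separation: float = 1.0
    noise_exponent: float = 1.0
    snr_db: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_md < 0 or self.n_hc < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.n_md + self.n_hc < 1:
            raise ValueError("cohort must contain at least one subject")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if not self.fs > 0 or not self.duration > 0:
            raise ValueError("fs and duration must be positive")
        if self.condition not in _BASE_SIGNATURES:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of "
                f"{tuple(_BASE_SIGNATURES)}"
            )
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")
        top = max(f for f, _ in _BASE_SIGNATURES[self.condition])
        if self.fs <= 2 * top:
            raise ValueError(
                f"fs={self.fs} must exceed twice the highest drive frequency {top}"
            )


def class_signature(
    label: str, condition: str, class_separation: float
) -> list[tuple[float, float]]:
    """Deterministic (frequency, amplitude) components for one class/condition.

    MD and HC differ only by amplitude: theta-band components are scaled up
    and alpha-band components scaled down for MD, by the square root of the
    band-power factor ``1 + class_separation * CONTRAST_GAIN``.
    """
    if label not in ("MD", "HC"):
        raise ValueError(f"unknown label {label!r}; expected 'MD' or 'HC'")
    if condition not in _BASE_SIGNATURES:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {tuple(_BASE_SIGNATURES)}"
        )
    if class_separation < 0:
        raise ValueError("class_separation must be >= 0")
    factor = 1.0 + class_separation * CONTRAST_GAIN
    comps = []
    for freq, amp in _BASE_SIGNATURES[condition]:
        if label == "MD":
            if _THETA[0] <= freq < _THETA[1]:
                amp = amp * np.sqrt(factor)
            elif _ALPHA[0] <= freq < _ALPHA[1]:
                amp = amp / np.sqrt(factor)
        comps.append((freq, float(amp)))
    return comps


def _colored_noise(rng: np.random.Generator, shape: tuple[int, int], beta: float) -> np.ndarray:
    """Gaussian 1/f^beta noise rows, synthesized in the frequency domain,
    normalized to unit variance per row."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-beta / 2.0)
    colored = np.fft.irfft(spec * gain, n=n, axis=1)
    sd = colored.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return colored / sd


def generate_recording(
    config: SynthConfig, label: str, subject_index: int
) -> MultichannelRecording:
    """One subject's recording: coloured noise + class-signature sinusoids.

    Reproducible given ``(config.seed, subject_index, label)``; the SNR is
    the per-channel ratio of summed sinusoid power to noise power,
    ``10 * log10(P_signal / P_noise) = snr_db``.
    """
    config.validate()
    if label not in ("MD", "HC"):
        raise ValueError(f"unknown label {label!r}; expected 'MD' or 'HC'")
    n = int(round(config.fs * config.duration))
    if n < 1:
        raise ValueError("duration too short for one sample")
    rng = np.random.default_rng(
        [int(config.seed) % (2**31), int(subject_index), 0 if label == "HC" else 1]
    )

    comps = class_signature(label, config.condition, config.class_separation)
    t = np.arange(n) / config.fs
    phases = rng.uniform(0.0, 2 * np.pi, size=(config.n_channels, len(comps)))
    signal = np.zeros((config.n_channels, n))
    for j, (freq, amp) in enumerate(comps):
        signal += amp * np.sin(2 * np.pi * freq * t[None, :] + phases[:, j : j + 1])

    # independent per-channel noise mixed with one shared source
    indep = _colored_noise(rng, (config.n_channels, n), config.noise_exponent)
    shared = _colored_noise(rng, (1, n), config.noise_exponent)
    w = SHARED_NOISE_WEIGHT
    noise = (1.0 - w) * indep + w * shared
    noise /= noise.std(axis=1, keepdims=True)

    sig_power = np.mean(signal**2, axis=1, keepdims=True)
    noise_amp = np.sqrt(sig_power / 10.0 ** (config.snr_db / 10.0))
    samples = signal + noise_amp * noise

    return MultichannelRecording(
        samples=samples,
        fs=config.fs,
        subject_id=f"{label}{subject_index:03d}",
        label=label,
        condition=config.condition,
    )


def generate_cohort(config: SynthConfig) -> list[MultichannelRecording]:
    """All ``n_md + n_hc`` recordings for one condition, MD subjects first."""
    config.validate()
    cohort = [generate_recording(config, "MD", i) for i in range(config.n_md)]
    cohort += [generate_recording(config, "HC", i) for i in range(config.n_hc)]
    return cohort
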