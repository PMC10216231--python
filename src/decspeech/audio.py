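"""Waveform container and PCM WAV input/output.

All feature extraction operates on mono float waveforms in [-1, 1] at a
known sample rate; inputs at other rates are resampled to the corpus
rate (48 kHz) before extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

CORPUS_SAMPLE_RATE = 48_000


@dataclass(frozen=True)
class Waveform:
    """Mono audio signal.

    Parameters
    ----------
    samples : ndarray
        Amplitude values, float64, nominally in [-1, 1].
    sample_rate : int
        Sampling rate in Hz (positive).
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"expected mono 1-D samples, got shape {samples.shape}")
        if samples.size == 0:
            raise ValueError("empty waveform")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def resample(self, target_rate: int) -> "Waveform":
        """Polyphase resampling to `target_rate`; identity if rates match."""
        if target_rate == self.sample_rate:
            return self
        g = np.gcd(int(self.sample_rate), int(target_rate))
        out = resample_poly(self.samples, target_rate // g, self.sample_rate // g)
        return Waveform(out, target_rate)


def read_wav(path, target_rate: int | None = CORPUS_SAMPLE_RATE) -> Waveform:
    """Read a PCM WAV file as a mono float waveform.

    Integer widths are rescaled to [-1, 1]; stereo is averaged to mono;
    if `target_rate` is given the signal is resampled to it.
    """
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":  # 8-bit WAV is unsigned
        data = (data.astype(np.float64) - 128.0) / 128.0
    wav = Waveform(data.astype(np.float64), int(rate))
    if target_rate is not None:
        wav = wav.resample(target_rate)
    return wav


def write_wav(path, wav: Waveform) -> None:
    """Write a waveform as 16-bit PCM."""
    clipped = np.clip(wav.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(path, wav.sample_rate, pcm)
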