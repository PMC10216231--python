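"""Acoustic feature extraction: 3D mel-spectrum and IS09 statistics.

Two utterance-level representations are produced:

* ``build_melspec3d`` — a 256x256x3 image stacking the log-mel
  spectrogram (64 bands, 25 ms Hamming window, 10 ms hop) with its
  first- and second-order temporal regression deltas; the input of the
  mean-teacher CNN.
* ``extract_is09`` — the Interspeech-2009 Emotion Challenge statistics
  vector: 16 low-level descriptors (ZCR, RMS energy, F0 normalized to
  500 Hz, HNR, HTK-style MFCC 1-12), each with its first-order delta,
  collapsed by 12 functionals, giving 16 x 2 x 12 = 384 features; the
  input of the autoencoder.

The implementation is self-contained and definition-level compatible
with the openSMILE IS09 configuration; it does not aim for
bit-compatibility with any specific openSMILE release.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize as _sk_resize

from decspeech.audio import Waveform

LOG_FLOOR = 1e-10
N_LLDS = 16
N_FUNCTIONALS = 12
IS09_DIM = N_LLDS * 2 * N_FUNCTIONALS  # 384

LLD_NAMES = ["zcr", "rms", "f0", "hnr"] + [f"mfcc{i}" for i in range(1, 13)]
FUNCTIONAL_NAMES = [
    "mean", "stddev", "kurtosis", "skewness", "max", "min",
    "maxposition", "minposition", "range", "offset", "slope", "mse",
]

# pitch search band and voicing threshold for the autocorrelation tracker
F0_MIN_HZ = 50.0
F0_MAX_HZ = 500.0
VOICING_THRESHOLD = 0.3
HNR_CLAMP_DB = 60.0
PREEMPHASIS = 0.97
N_MFCC_FILTERS = 26
CEP_LIFTER = 22


@dataclass(frozen=True)
class ExtractionConfig:
    """Parameters of both feature branches."""

    n_mels: int = 64
    win_ms: float = 25.0
    hop_ms: float = 10.0
    image_size: int = 256

    def to_dict(self) -> dict:
        return {
            "n_mels": self.n_mels,
            "win_ms": self.win_ms,
            "hop_ms": self.hop_ms,
            "image_size": self.image_size,
        }


# ---------------------------------------------------------------------------
# framing and mel filterbank
# ---------------------------------------------------------------------------

def frame_signal(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    """Slice a signal into overlapping frames, shape (T, win).

    T = 1 + floor((len - win) / hop); no centering, no padding.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < win:
        raise ValueError(
            f"signal of {x.size} samples is shorter than one {win}-sample window"
        )
    return sliding_window_view(x, win)[::hop]


def hz_to_mel(f):
    """HTK mel scale: 2595 * log10(1 + f / 700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(sample_rate: int, n_fft: int, n_mels: int,
                   fmin: float = 0.0, fmax: float | None = None) -> np.ndarray:
    """Triangular HTK-mel filterbank, shape (n_mels, n_fft // 2 + 1)."""
    if fmax is None:
        fmax = sample_rate / 2.0
    edges_hz = mel_to_hz(np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2))
    bin_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    fbank = np.zeros((n_mels, bin_freqs.size))
    for m in range(n_mels):
        lo, center, hi = edges_hz[m], edges_hz[m + 1], edges_hz[m + 2]
        up = (bin_freqs - lo) / max(center - lo, 1e-12)
        down = (hi - bin_freqs) / max(hi - center, 1e-12)
        fbank[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fbank


def _fft_size(win: int) -> int:
    return int(2 ** np.ceil(np.log2(win)))


# ---------------------------------------------------------------------------
# mel spectrogram branch
# ---------------------------------------------------------------------------

def compute_mel_spectrogram(wav: Waveform, n_mels: int = 64,
                            win_ms: float = 25.0, hop_ms: float = 10.0) -> np.ndarray:
    """Log mel-filterbank energies, shape (T, n_mels).

    25 ms Hamming-windowed frames with a 10 ms hop; power spectrum on an
    FFT of the next power of two >= the window length; log compression
    with a 1e-10 floor.
    """
    win = int(round(wav.sample_rate * win_ms / 1000.0))
    hop = int(round(wav.sample_rate * hop_ms / 1000.0))
    frames = frame_signal(wav.samples, win, hop)
    n_fft = _fft_size(win)
    spec = np.abs(np.fft.rfft(frames * np.hamming(win), n=n_fft)) ** 2
    fbank = mel_filterbank(wav.sample_rate, n_fft, n_mels)
    return np.log(spec @ fbank.T + LOG_FLOOR)


def compute_delta(feature_matrix: np.ndarray, order: int = 1, window: int = 2) -> np.ndarray:
    """Regression delta along the time (first) axis, HTK convention.

    d_t = sum_{n=1..W} n (x_{t+n} - x_{t-n}) / (2 sum n^2), with edge
    frames replicated.  ``order=2`` applies the operator twice.
    """
    x = np.asarray(feature_matrix, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty feature matrix")
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    if order == 2:
        return compute_delta(compute_delta(x, 1, window), 1, window)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    pad = np.concatenate([x[:1].repeat(window, axis=0), x,
                          x[-1:].repeat(window, axis=0)], axis=0)
    denom = 2.0 * sum(n * n for n in range(1, window + 1))
    out = np.zeros_like(x)
    T = x.shape[0]
    for n in range(1, window + 1):
        out += n * (pad[window + n:window + n + T] - pad[window - n:window - n + T])
    out /= denom
    return out[:, 0] if squeeze else out


def resize_image(img: np.ndarray, size: int) -> np.ndarray:
    """Deterministic bilinear resize of a 2-D array to (size, size)."""
    return _sk_resize(img, (size, size), order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)


def build_melspec3d(wav: Waveform, cfg: ExtractionConfig | None = None) -> np.ndarray:
    """3-channel mel-spectrum image, shape (size, size, 3).

    Channel 0 is the log-mel spectrogram (frequency on rows, time on
    columns), channels 1 and 2 its first- and second-order time deltas,
    computed before resizing.
    """
    cfg = cfg or ExtractionConfig()
    mel = compute_mel_spectrogram(wav, cfg.n_mels, cfg.win_ms, cfg.hop_ms)
    d1 = compute_delta(mel, 1)
    d2 = compute_delta(mel, 2)
    chans = [resize_image(c.T, cfg.image_size) for c in (mel, d1, d2)]
    return np.stack(chans, axis=-1)


# ---------------------------------------------------------------------------
# IS09 branch: low-level descriptors
# ---------------------------------------------------------------------------

def _autocorrelate(frames: np.ndarray) -> np.ndarray:
    """Biased autocorrelation of each frame via FFT, lags 0..win-1."""
    win = frames.shape[1]
    n_fft = _fft_size(2 * win)
    spec = np.abs(np.fft.rfft(frames, n=n_fft)) ** 2
    return np.fft.irfft(spec, n=n_fft)[:, :win]


def _mfcc(wav: Waveform, win: int, hop: int, n_coeffs: int = 12) -> np.ndarray:
    """HTK-style MFCC 1..n_coeffs per frame.

    Pre-emphasis 0.97, Hamming window, magnitude spectrum, 26 HTK-mel
    filters, log energies, DCT-II, cepstral liftering with L=22.
    """
    x = wav.samples
    pre = np.empty_like(x)
    pre[0] = x[0] * (1.0 - PREEMPHASIS)
    pre[1:] = x[1:] - PREEMPHASIS * x[:-1]
    frames = frame_signal(pre, win, hop)
    n_fft = _fft_size(win)
    mag = np.abs(np.fft.rfft(frames * np.hamming(win), n=n_fft))
    fbank = mel_filterbank(wav.sample_rate, n_fft, N_MFCC_FILTERS)
    logmel = np.log(np.maximum(mag @ fbank.T, LOG_FLOOR))
    n_filt = N_MFCC_FILTERS
    j = np.arange(n_filt)
    i = np.arange(1, n_coeffs + 1)[:, None]
    dct = np.sqrt(2.0 / n_filt) * np.cos(np.pi * i * (j + 0.5) / n_filt)
    cep = logmel @ dct.T
    lifter = 1.0 + (CEP_LIFTER / 2.0) * np.sin(np.pi * np.arange(1, n_coeffs + 1) / CEP_LIFTER)
    return cep * lifter


def extract_llds(wav: Waveform, win_ms: float = 25.0, hop_ms: float = 10.0) -> np.ndarray:
    """Per-frame low-level descriptors, shape (T, 16).

    Column order: ZCR, RMS, F0/500 Hz, HNR (dB), MFCC 1-12.

    * ZCR — fraction of adjacent sample pairs with a strict sign change.
    * RMS — root-mean-square frame amplitude.
    * F0 — autocorrelation peak in the 50-500 Hz lag band, divided by
      500 Hz; 0 for unvoiced frames (peak-to-lag-0 ratio below 0.3).
    * HNR — 10 log10(r_peak / (r_0 - r_peak)), clamped to +-60 dB; the
      clamp floor on unvoiced or silent frames.
    """
    win = int(round(wav.sample_rate * win_ms / 1000.0))
    hop = int(round(wav.sample_rate * hop_ms / 1000.0))
    frames = frame_signal(wav.samples, win, hop)
    T = frames.shape[0]

    zcr = np.mean(frames[:, 1:] * frames[:, :-1] < 0, axis=1)
    rms = np.sqrt(np.mean(frames ** 2, axis=1))

    r = _autocorrelate(frames)
    r0 = r[:, 0]
    lag_min = int(round(wav.sample_rate / F0_MAX_HZ))
    lag_max = min(int(round(wav.sample_rate / F0_MIN_HZ)), win - 1)
    band = r[:, lag_min:lag_max + 1]
    peak_lag = lag_min + np.argmax(band, axis=1)
    r_peak = band[np.arange(T), peak_lag - lag_min]
    voiced = (r0 > 0) & (r_peak > VOICING_THRESHOLD * r0)

    f0 = np.where(voiced, wav.sample_rate / np.maximum(peak_lag, 1), 0.0) / F0_MAX_HZ
    f0 = np.clip(f0, 0.0, 1.0)

    residual = r0 - r_peak
    with np.errstate(divide="ignore", invalid="ignore"):
        hnr = 10.0 * np.log10(np.where(residual > 0, r_peak / np.maximum(residual, 1e-300), np.inf))
    hnr = np.where(voiced & (r_peak > 0), hnr, -HNR_CLAMP_DB)
    hnr = np.clip(np.nan_to_num(hnr, nan=-HNR_CLAMP_DB, posinf=HNR_CLAMP_DB,
                                neginf=-HNR_CLAMP_DB), -HNR_CLAMP_DB, HNR_CLAMP_DB)

    mfcc = _mfcc(wav, win, hop)
    return np.column_stack([zcr, rms, f0, hnr, mfcc])


# ---------------------------------------------------------------------------
# IS09 branch: functionals
# ---------------------------------------------------------------------------

def apply_functionals(series: np.ndarray) -> np.ndarray:
    """The 12 IS09 functionals of a contour, in fixed order.

    mean, stddev (population), kurtosis (excess, m4/m2^2 - 3), skewness
    (m3/m2^1.5), max, min, maxposition, minposition (relative index of
    the first extremum in [0, 1]), range, offset, slope (least-squares
    line over time normalized to [0, 1]), MSE (mean squared residual of
    that line).  Moment ratios of a constant series are defined as 0.
    """
    y = np.asarray(series, dtype=np.float64)
    if y.ndim != 1 or y.size < 2:
        raise ValueError("series must be 1-D with at least 2 points")
    T = y.size
    mean = y.mean()
    centered = y - mean
    m2 = np.mean(centered ** 2)
    std = np.sqrt(m2)
    if m2 > 1e-30:
        kurt = np.mean(centered ** 4) / m2 ** 2 - 3.0
        skew = np.mean(centered ** 3) / m2 ** 1.5
    else:
        kurt = 0.0
        skew = 0.0
    ymax, ymin = y.max(), y.min()
    maxpos = int(np.argmax(y)) / (T - 1)
    minpos = int(np.argmin(y)) / (T - 1)
    t = np.arange(T) / (T - 1)
    t_mean = t.mean()
    var_t = np.mean((t - t_mean) ** 2)
    slope = np.mean((t - t_mean) * centered) / var_t
    offset = mean - slope * t_mean
    mse = np.mean((y - (offset + slope * t)) ** 2)
    return np.array([mean, std, kurt, skew, ymax, ymin,
                     maxpos, minpos, ymax - ymin, offset, slope, mse])


def is09_feature_names() -> list[str]:
    names = []
    for lld in LLD_NAMES:
        for d in ("", "_de"):
            for f in FUNCTIONAL_NAMES:
                names.append(f"{lld}{d}_{f}")
    return names


def extract_is09(wav: Waveform, win_ms: float = 25.0, hop_ms: float = 10.0) -> np.ndarray:
    """The 384-dim IS09 vector of an utterance.

    Layout: for each of the 16 LLDs, first the 12 functionals of the
    contour itself, then the 12 functionals of its regression delta.
    """
    lld = extract_llds(wav, win_ms, hop_ms)
    dlld = compute_delta(lld, 1)
    parts = []
    for col in range(N_LLDS):
        parts.append(apply_functionals(lld[:, col]))
        parts.append(apply_functionals(dlld[:, col]))
    vec = np.concatenate(parts)
    assert vec.size == IS09_DIM
    return vec
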