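"""Input perturbations for consistency training.

Three perturbations are wired into training:

* eta   — horizontal flip + random crop of the spectrogram image,
          applied to every CNN input (labeled and unlabeled, student
          and teacher, each with an independent random draw);
* eta'  — Gaussian noise on unlabeled spectrogram images, applied on
          top of eta for the student branch only;
* eta'' — Gaussian noise on unlabeled IS09 vectors entering the
          student autoencoder.

The noise amplitude (default 0.3) multiplies a robust per-tensor scale
(interquartile range / 1.349) so the same amplitude is meaningful for
log-mel images and normalized statistics vectors alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class AugmentConfig:
    flip_prob: float = 0.5
    crop_pad: int = 8
    noise_amplitude: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")


def feature_scale(x: np.ndarray) -> float:
    """Robust dispersion of a tensor: IQR/1.349, falling back to std, then 1."""
    q75, q25 = np.percentile(x, [75, 25])
    scale = (q75 - q25) / 1.349
    if scale <= 0:
        scale = float(np.std(x))
    return scale if scale > 0 else 1.0


def flip_crop(x: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Random horizontal (time-axis) flip then random crop (eta).

    The image is edge-padded by ``crop_pad`` on both spatial axes and a
    window of the original size is cut at a random offset; output shape
    equals input shape.  ``crop_pad=0, flip_prob=0`` is the identity.
    """
    if x.ndim != 3:
        raise ValueError(f"expected H x W x C image, got shape {x.shape}")
    out = x
    if cfg.flip_prob > 0 and rng.random() < cfg.flip_prob:
        out = out[:, ::-1, :]
    if cfg.crop_pad > 0:
        p = cfg.crop_pad
        h, w = out.shape[:2]
        padded = np.pad(out, ((p, p), (p, p), (0, 0)), mode="edge")
        i = rng.integers(0, 2 * p + 1)
        j = rng.integers(0, 2 * p + 1)
        out = padded[i:i + h, j:j + w, :]
    return np.ascontiguousarray(out)


def add_noise(x: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Additive i.i.d. Gaussian noise (eta' / eta'').

    The noise standard deviation is ``amplitude * feature_scale(x)``;
    amplitude 0 returns the input unchanged.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0:
        return x
    return x + amplitude * feature_scale(x) * rng.standard_normal(x.shape)
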