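"""Synthetic two-class truth/lie speech corpus.

Emulates the statistical shape of a self-built deception corpus:
~1,103 utterances of a few seconds (521 deceptive), 48 kHz mono, a 9:1
train/test split, and a labeled training subset of configurable size
with the remaining training items unlabeled.

Each utterance is a voiced-speech proxy: a harmonic glottal-like source
with a slowly drifting F0 contour and jitter, formant-style resonant
filtering, a syllabic amplitude envelope, silent pauses, and additive
noise.  The deceptive class draws its F0 mean, energy-modulation depth
and pause rate from distributions shifted upward by ``class_separation``
(in units of the between-utterance standard deviation), echoing the
finding that deceptive speech tends to carry a raised fundamental
frequency.  The signals are statistical proxies, not intelligible
speech: class separability is asserted on extracted features, never
perceptually.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

from decspeech.audio import Waveform, write_wav

TRUTH, LIE, UNLABELED = "truth", "lie", "unlabeled"

# baseline (truth-class) utterance-parameter distributions; the deceptive
# class shifts each mean by class_separation between-utterance SDs, so
# class_separation is the per-channel effect size d' at the parameter level
F0_BASE_HZ = 115.0          # between-utterance mean of the utterance F0 mean
F0_BETWEEN_SD_HZ = 12.0     # between-utterance SD; class shift is in these units
AM_DEPTH_BASE = 0.35        # syllabic energy-modulation depth
AM_DEPTH_SD = 0.05
PAUSE_RATE_BASE = 0.3       # pauses per second
PAUSE_RATE_SD = 0.12


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters for the synthetic corpus."""

    n_utterances: int = 1103
    deception_fraction: float = 521 / 1103
    n_labeled: int = 600
    duration_s: tuple[float, float] = (2.0, 8.0)
    sample_rate: int = 48_000
    class_separation: float = 2.0
    noise_level: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.deception_fraction < 1.0:
            raise ValueError("deception_fraction must be in (0, 1)")
        if self.n_labeled > self.n_utterances:
            raise ValueError("n_labeled cannot exceed n_utterances")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")


@dataclass
class CorpusManifest:
    """Utterance table with labels, labeled flags and train/test split.

    ``df`` columns: id, path, label (truth/lie/unlabeled as visible to
    the trainer), split (train/test), labeled (bool).  The true class of
    unlabeled items is withheld behind :meth:`hidden_labels` for
    post-hoc evaluation only.  ``waveforms`` optionally carries the
    in-memory audio (id -> Waveform) when no WAVs were written.
    """

    df: pd.DataFrame
    waveforms: dict[str, Waveform] | None = field(default=None, repr=False)

    @property
    def n_labeled(self) -> int:
        return int((self.df["labeled"] & (self.df["split"] == "train")).sum())

    @property
    def n_unlabeled(self) -> int:
        return int((~self.df["labeled"] & (self.df["split"] == "train")).sum())

    def hidden_labels(self) -> pd.Series:
        """True class of every utterance — evaluation only, never training."""
        return self.df["_hidden_label"]

    def visible(self) -> pd.DataFrame:
        """The trainer-facing view (no hidden-label column)."""
        return self.df.drop(columns=["_hidden_label"])

    def save(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def load(cls, path) -> "CorpusManifest":
        df = pd.read_csv(path, dtype={"path": str})
        df["path"] = df["path"].fillna("")
        if "_hidden_label" not in df.columns:
            df["_hidden_label"] = df["label"]
        return cls(df)


def synthesize_utterance(class_label: str, cfg: SynthConfig,
                         rng: np.random.Generator) -> Waveform:
    """One voiced-speech-like signal for the given class.

    The class enters only through shifted distributions of three
    utterance parameters (F0 mean, modulation depth, pause rate); at
    ``class_separation=0`` the two classes are generatively identical.
    """
    if class_label not in (TRUTH, LIE):
        raise ValueError(f"class_label must be '{TRUTH}' or '{LIE}'")
    sep = cfg.class_separation if class_label == LIE else 0.0
    sr = cfg.sample_rate
    dur = rng.uniform(*cfg.duration_s)
    n = max(int(dur * sr), sr // 2)
    t = np.arange(n) / sr

    f0_mean = max(rng.normal(F0_BASE_HZ + sep * F0_BETWEEN_SD_HZ, F0_BETWEEN_SD_HZ), 60.0)
    am_depth = float(np.clip(rng.normal(AM_DEPTH_BASE + sep * AM_DEPTH_SD, AM_DEPTH_SD), 0.0, 0.9))
    pause_rate = max(rng.normal(PAUSE_RATE_BASE + sep * PAUSE_RATE_SD, PAUSE_RATE_SD), 0.0)

    # F0 contour: slow sinusoidal drift + jitter, phase-continuous source
    drift = 0.04 * f0_mean * np.sin(2 * np.pi * rng.uniform(0.2, 0.5) * t + rng.uniform(0, 2 * np.pi))
    jitter = 0.01 * f0_mean * rng.standard_normal(n)
    f0_track = np.clip(f0_mean + drift + jitter, 50.0, 480.0)
    phase = 2 * np.pi * np.cumsum(f0_track) / sr

    # harmonic source, 1/h amplitude rolloff up to ~4 kHz
    n_harm = int(min(12, 4000.0 / f0_mean))
    x = np.zeros(n)
    for h in range(1, n_harm + 1):
        x += np.sin(h * phase + rng.uniform(0, 2 * np.pi)) / h

    # two formant-like resonators (500 and 1500 Hz)
    for fc, bw in ((500.0, 100.0), (1500.0, 200.0)):
        r = np.exp(-np.pi * bw / sr)
        theta = 2 * np.pi * fc / sr
        x = lfilter([1.0], [1.0, -2 * r * np.cos(theta), r * r], x)

    # syllabic amplitude modulation around 4 Hz
    syl = 2 * np.pi * rng.uniform(3.0, 5.0) * t + rng.uniform(0, 2 * np.pi)
    x *= 1.0 - am_depth + am_depth * 0.5 * (1.0 + np.sin(syl))

    # silent pauses: poisson count, 100-200 ms each, cosine-ramped edges
    n_pauses = rng.poisson(pause_rate * dur)
    env = np.ones(n)
    for _ in range(n_pauses):
        plen = int(rng.uniform(0.10, 0.20) * sr)
        start = rng.integers(0, max(n - plen, 1))
        ramp = min(int(0.01 * sr), plen // 2)
        seg = np.zeros(plen)
        if ramp > 0:
            edge = 0.5 * (1 + np.cos(np.linspace(0, np.pi, ramp)))
            seg[:ramp] = edge
            seg[-ramp:] = edge[::-1]
        env[start:start + plen] = np.minimum(env[start:start + plen], seg[:min(plen, n - start)])
    x *= env

    rms = np.sqrt(np.mean(x ** 2))
    if rms > 0:
        x *= 0.1 / rms
    x += cfg.noise_level * rng.standard_normal(n)
    peak = np.max(np.abs(x))
    if peak > 0.99:
        x *= 0.99 / peak
    return Waveform(x, sr)


def _stratified_take(labels: np.ndarray, n_take: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of a class-stratified random subset of exact size n_take.

    Per-class quotas are proportional with largest-remainder rounding.
    """
    idx = np.arange(labels.size)
    classes, counts = np.unique(labels, return_counts=True)
    exact = counts * n_take / labels.size
    quotas = np.floor(exact).astype(int)
    remainder = n_take - quotas.sum()
    order = np.argsort(-(exact - quotas))
    for k in order[:remainder]:
        quotas[k] += 1
    taken = []
    for cls, q in zip(classes, quotas):
        pool = idx[labels == cls]
        taken.append(rng.permutation(pool)[:q])
    return np.sort(np.concatenate(taken))


def build_manifest(cfg: SynthConfig, train_ratio: float = 0.9) -> CorpusManifest:
    """Labels, split and label budget for a corpus, without audio.

    Class counts follow ``deception_fraction`` to within rounding; the
    corpus is split ``train_ratio`` : 1-ratio (stratified); exactly
    ``n_labeled`` training items keep visible labels, the rest of the
    training set is presented as unlabeled.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_utterances
    n_lie = int(round(cfg.deception_fraction * n))
    labels = np.array([LIE] * n_lie + [TRUTH] * (n - n_lie))
    labels = labels[rng.permutation(n)]
    ids = [f"utt{i:05d}" for i in range(n)]
    df = pd.DataFrame({
        "id": ids, "path": "", "label": labels, "split": "train",
        "labeled": True, "_hidden_label": labels,
    })
    manifest = split_train_test(CorpusManifest(df), train_ratio, seed=cfg.seed)
    return assign_label_budget(manifest, cfg.n_labeled, seed=cfg.seed)


def generate_corpus(cfg: SynthConfig, out_dir=None, train_ratio: float = 0.9) -> CorpusManifest:
    """Synthesize a full corpus: manifest plus per-utterance audio.

    With ``out_dir`` set, WAV files, a manifest CSV and the config YAML
    are written there; otherwise waveforms are kept in memory.
    """
    manifest = build_manifest(cfg, train_ratio)
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_utterances)
    waveforms = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "wav").mkdir(parents=True, exist_ok=True)
    paths = []
    for i, (uid, lab) in enumerate(zip(manifest.df["id"], manifest.df["_hidden_label"])):
        wav = synthesize_utterance(lab, cfg, np.random.default_rng(seeds[i]))
        if out_dir is not None:
            p = out_dir / "wav" / f"{uid}.wav"
            write_wav(p, wav)
            paths.append(str(p))
        else:
            paths.append("")
        waveforms[uid] = wav
    manifest.df["path"] = paths
    manifest.waveforms = waveforms
    if out_dir is not None:
        manifest.save(out_dir / "manifest.csv")
        with open(out_dir / "synth_config.yaml", "w") as fh:
            yaml.safe_dump({**cfg.__dict__, "duration_s": list(cfg.duration_s)}, fh)
    return manifest


def split_train_test(manifest: CorpusManifest, train_ratio: float = 0.9,
                     seed: int = 0) -> CorpusManifest:
    """Stratified seeded train/test split.

    Train size is floor(train_ratio * N) exactly (1,103 at 9:1 gives
    992/111); stratification is by true class with largest-remainder
    quotas.  Test items always keep visible labels.
    """
    if not 0.0 < train_ratio < 1.0:
        raise ValueError("train_ratio must be in (0, 1)")
    df = manifest.df.copy()
    N = len(df)
    if N < 2:
        raise ValueError("need at least 2 utterances to split")
    n_train = int(np.floor(train_ratio * N))
    rng = np.random.default_rng(seed)
    train_idx = _stratified_take(df["_hidden_label"].to_numpy(), n_train, rng)
    df["split"] = "test"
    df.loc[df.index[train_idx], "split"] = "train"
    # test items are always labeled for evaluation
    df.loc[df["split"] == "test", "labeled"] = True
    df.loc[df["split"] == "test", "label"] = df.loc[df["split"] == "test", "_hidden_label"]
    return CorpusManifest(df, manifest.waveforms)


def assign_label_budget(manifest: CorpusManifest, n_labeled: int,
                        seed: int = 0) -> CorpusManifest:
    """Keep visible labels on a stratified random subset of the training set.

    The remaining training items become 'unlabeled'; their true class
    stays available via :meth:`CorpusManifest.hidden_labels` only.
    """
    df = manifest.df.copy()
    train_mask = (df["split"] == "train").to_numpy()
    n_train = int(train_mask.sum())
    if n_labeled > n_train:
        raise ValueError(f"n_labeled={n_labeled} exceeds training size {n_train}")
    rng = np.random.default_rng(seed + 1)
    train_pos = np.flatnonzero(train_mask)
    keep = train_pos[_stratified_take(df["_hidden_label"].to_numpy()[train_mask],
                                      n_labeled, rng)]
    df.loc[df.index[train_mask], "labeled"] = False
    df.loc[df.index[train_mask], "label"] = UNLABELED
    df.loc[df.index[keep], "labeled"] = True
    df.loc[df.index[keep], "label"] = df.loc[df.index[keep], "_hidden_label"]
    return CorpusManifest(df, manifest.waveforms)


def with_label_budget(manifest: CorpusManifest, n_labeled: int, seed: int = 0) -> CorpusManifest:
    """Alias of :func:`assign_label_budget` for label-budget sweeps."""
    return assign_label_budget(manifest, n_labeled, seed)
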