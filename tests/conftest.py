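import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from decspeech.corpus import SynthConfig, generate_corpus
from decspeech.extraction import FeatureSet, extract_corpus_features
from decspeech.features import ExtractionConfig, is09_feature_names

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def sine_wav():
    """1 s of a pure 1 kHz tone at 48 kHz."""
    from decspeech.audio import Waveform
    t = np.arange(48_000) / 48_000
    return Waveform(0.5 * np.sin(2 * np.pi * 1000 * t), 48_000)


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small in-memory synthetic corpus (16 kHz, short utterances)."""
    cfg = SynthConfig(n_utterances=16, n_labeled=8, class_separation=2.0,
                      duration_s=(1.0, 2.0), sample_rate=16_000, seed=3)
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def tiny_features(tiny_corpus):
    return extract_corpus_features(tiny_corpus, ExtractionConfig(image_size=64))


def make_toy_features(manifest_df: pd.DataFrame, seed: int = 0, shift: float = 1.5,
                      image_size: int = 64) -> FeatureSet:
    """Synthetic FeatureSet with a controllable class shift, no audio.

    IS09 vectors are standard normal with `shift` added on 20 dimensions
    for the deceptive class; mel images carry the same shift on a patch.
    """
    rng = np.random.default_rng(seed)
    names = is09_feature_names()
    vecs, mel = {}, {}
    for uid, lab in zip(manifest_df["id"], manifest_df["_hidden_label"]):
        v = rng.standard_normal(len(names))
        img = rng.standard_normal((image_size, image_size, 3)).astype(np.float32)
        if lab == "lie":
            v[:20] += shift
            img[:16, :16, 0] += shift
        vecs[uid] = v
        mel[uid] = img
    is09 = pd.DataFrame.from_dict(vecs, orient="index", columns=names)
    is09.index.name = "id"
    return FeatureSet(is09, mel, ExtractionConfig(image_size=image_size))


def make_toy_manifest(n: int = 24, n_labeled: int = 12, n_test: int = 8,
                      seed: int = 0) -> pd.DataFrame:
    """Balanced two-class manifest frame without waveforms."""
    rng = np.random.default_rng(seed)
    ids = [f"t{i:03d}" for i in range(n)]
    labels = np.array(["truth", "lie"] * (n // 2))
    split = np.array(["train"] * (n - n_test) + ["test"] * n_test)
    labeled = np.zeros(n, dtype=bool)
    train_idx = np.flatnonzero(split == "train")
    labeled[rng.permutation(train_idx)[:n_labeled]] = True
    labeled[split == "test"] = True
    visible = np.where(labeled, labels, "unlabeled")
    return pd.DataFrame({"id": ids, "path": "", "label": visible,
                         "split": split, "labeled": labeled,
                         "_hidden_label": labels})
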