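"""Corpus-level feature extraction and caching.

Runs both feature branches over every utterance in a manifest and keeps
the results in a :class:`FeatureSet`: the 384-dim IS09 vectors as a
DataFrame (one row per utterance) and the mel-spectrum images as a dict
of arrays.  A feature set can be written to disk as a CSV plus an
``.npz`` container with a JSON sidecar recording extraction parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from decspeech.audio import read_wav
from decspeech.corpus import CorpusManifest
from decspeech.features import ExtractionConfig, build_melspec3d, extract_is09, is09_feature_names


@dataclass
class FeatureSet:
    """Extracted features for a corpus, keyed by utterance id."""

    is09: pd.DataFrame                       # index: id, 384 columns
    mel: dict[str, np.ndarray]               # id -> (S, S, 3) float32
    config: ExtractionConfig = field(default_factory=ExtractionConfig)

    def ids(self) -> list[str]:
        return list(self.is09.index)

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.is09.to_csv(out_dir / "is09.csv")
        np.savez_compressed(out_dir / "melspec3d.npz",
                            **{k: v.astype(np.float32) for k, v in self.mel.items()})
        with open(out_dir / "extraction.json", "w") as fh:
            json.dump(self.config.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, out_dir) -> "FeatureSet":
        out_dir = Path(out_dir)
        is09 = pd.read_csv(out_dir / "is09.csv", index_col=0)
        with np.load(out_dir / "melspec3d.npz") as npz:
            mel = {k: npz[k] for k in npz.files}
        with open(out_dir / "extraction.json") as fh:
            cfg = ExtractionConfig(**json.load(fh))
        return cls(is09, mel, cfg)


def extract_corpus_features(manifest: CorpusManifest,
                            cfg: ExtractionConfig | None = None) -> FeatureSet:
    """Extract IS09 vectors and mel images for every manifest utterance.

    Waveforms are taken from the manifest's in-memory store when
    present, otherwise read from the WAV paths.
    """
    cfg = cfg or ExtractionConfig()
    vecs, mel = {}, {}
    for row in manifest.df.itertuples():
        uid = row.id
        if manifest.waveforms is not None and uid in manifest.waveforms:
            wav = manifest.waveforms[uid]
        else:
            wav = read_wav(row.path)
        vecs[uid] = extract_is09(wav, cfg.win_ms, cfg.hop_ms)
        mel[uid] = build_melspec3d(wav, cfg).astype(np.float32)
    is09 = pd.DataFrame.from_dict(vecs, orient="index", columns=is09_feature_names())
    is09.index.name = "id"
    return FeatureSet(is09, mel, cfg)
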