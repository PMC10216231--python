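"""Semi-supervised training loop, evaluation, ablations and checkpoints.

One optimization step assembles a mixed batch (a fixed labeled fraction
plus unlabeled items), perturbs the inputs (flip/crop on every CNN
image, extra Gaussian noise on unlabeled student inputs), runs the
student CNN + autoencoder, fuses the two 32-dim embeddings, and takes
one SGD-with-momentum step on

    L = L_ce + omega(epoch) * L_consis + a * L_recon,

after which the teacher receives an exponential-moving-average update
theta'' = alpha * theta' + (1 - alpha) * theta.  The learning rate
follows cosine annealing from its initial value to 0 over the epochs.

Ablation variants:

* ``MT``        — CNN branch only; L_ce + omega * L_consis.
* ``AE``        — autoencoder branch only; L_ce + a * L_recon.
* ``AE+MT``     — both branches fused, but omega = 0 (no consistency).
* ``AE+MT+CR``  — the full model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from decspeech.augment import AugmentConfig, add_noise, flip_crop
from decspeech.corpus import CorpusManifest, assign_label_budget
from decspeech.extraction import FeatureSet
from decspeech.losses import (
    LossWeights, consistency_loss, consistency_loss_grad, consistency_weight,
    evaluate, reconstruction_loss, reconstruction_loss_grad, supervised_loss,
)
from decspeech.nn.layers import Sequential
from decspeech.nn.networks import (
    AENetwork, DESK_INPUT, DESK_WIDTHS, FULL_INPUT, FULL_WIDTHS, FusionHead,
    StudentCNN, ema_update, softmax,
)

VARIANTS = ("MT", "AE", "AE+MT", "AE+MT+CR")
SCALES = {"full": (FULL_INPUT, FULL_WIDTHS), "desk": (DESK_INPUT, DESK_WIDTHS)}


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 3e-4
    momentum: float = 0.9
    epochs: int = 100
    batch_size: int = 12
    labeled_batch_fraction: float = 0.25
    dropout: float = 0.8          # interpreted via dropout_is_drop_prob
    dropout_is_drop_prob: bool = False  # 0.8 read as keep probability (drop 0.2)
    alpha_ema: float = 0.99
    weights: LossWeights = field(default_factory=LossWeights)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    consistency_on: str = "embedding"     # or "probs"
    consistency_reduce: str = "elementwise"  # per-dimension mean; or "batchmean"
    variant: str = "AE+MT+CR"
    scale: str = "full"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def drop_prob(self) -> float:
        return self.dropout if self.dropout_is_drop_prob else 1.0 - self.dropout


@dataclass
class ModelState:
    """Student and teacher networks plus input normalizers."""

    cfg: TrainConfig
    student_cnn: StudentCNN | None
    student_ae: AENetwork | None
    head: FusionHead
    teacher_cnn: StudentCNN | None
    teacher_ae: AENetwork | None
    teacher_head: FusionHead
    ae_min: np.ndarray | None = None
    ae_max: np.ndarray | None = None
    mel_mean: float = 0.0
    mel_std: float = 1.0

    def student_modules(self) -> list[Sequential]:
        mods = list(self.head.modules())
        if self.student_cnn is not None:
            mods += [self.student_cnn.backbone]
        if self.student_ae is not None:
            mods += [self.student_ae.encoder, self.student_ae.decoder]
        return mods

    def student_state(self) -> dict[str, np.ndarray]:
        return _component_state(self.student_cnn, self.student_ae, self.head)

    def teacher_state(self) -> dict[str, np.ndarray]:
        return _component_state(self.teacher_cnn, self.teacher_ae, self.teacher_head)

    def load_student(self, state):
        _load_component_state(state, self.student_cnn, self.student_ae, self.head)

    def load_teacher(self, state):
        _load_component_state(state, self.teacher_cnn, self.teacher_ae, self.teacher_head)

    def normalize_is09(self, x: np.ndarray) -> np.ndarray:
        span = np.maximum(self.ae_max - self.ae_min, 1e-12)
        return np.clip((x - self.ae_min) / span, 0.0, 1.0)

    def normalize_mel(self, x: np.ndarray) -> np.ndarray:
        return (x.astype(np.float64) - self.mel_mean) / self.mel_std


def _component_state(cnn, ae, head) -> dict[str, np.ndarray]:
    out = {f"head.{k}": v for k, v in head.state_dict().items()}
    if cnn is not None:
        out.update({f"cnn.{k}": v for k, v in cnn.state_dict().items()})
    if ae is not None:
        out.update({f"ae.{k}": v for k, v in ae.state_dict().items()})
    return out


def _load_component_state(state, cnn, ae, head):
    head.load_state_dict({k[5:]: v for k, v in state.items() if k.startswith("head.")})
    if cnn is not None:
        cnn.load_state_dict({k[4:]: v for k, v in state.items() if k.startswith("cnn.")})
    if ae is not None:
        ae.load_state_dict({k[3:]: v for k, v in state.items() if k.startswith("ae.")})


def init_model(cfg: TrainConfig) -> ModelState:
    """Build student and teacher networks for the configured variant."""
    input_size, widths = SCALES[cfg.scale]
    use_cnn = cfg.variant != "AE"
    use_ae = cfg.variant != "MT"
    p = cfg.drop_prob
    fused_dim = (32 if use_cnn else 0) + (32 if use_ae else 0)
    seed = cfg.seed

    def make(seed_shift):
        cnn = StudentCNN(input_size, widths, seed + seed_shift) if use_cnn else None
        ae = AENetwork(dropout=p, seed=seed + seed_shift + 100) if use_ae else None
        head = FusionHead(fused_dim, dropout=p, seed=seed + seed_shift + 200)
        return cnn, ae, head

    s_cnn, s_ae, s_head = make(0)
    t_cnn, t_ae, t_head = make(0)  # identical init; teacher starts equal to student
    state = ModelState(cfg, s_cnn, s_ae, s_head, t_cnn, t_ae, t_head)
    state.load_teacher(state.student_state())
    return state


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, modules: list[Sequential], lr: float, momentum: float = 0.9):
        self.entries = [(layer, name) for m in modules for layer, name in m.named_params()]
        self.velocity = [np.zeros_like(layer.params[name]) for layer, name in self.entries]
        self.lr = lr
        self.momentum = momentum

    def zero_grad(self):
        for layer, name in self.entries:
            layer.grads[name][...] = 0.0

    def step(self):
        for v, (layer, name) in zip(self.velocity, self.entries):
            v *= self.momentum
            v -= self.lr * layer.grads[name]
            layer.params[name] += v


def cosine_lr(epoch: int, n_epochs: int, lr0: float) -> float:
    """Cosine annealing: lr(0) = lr0, lr(n_epochs - 1) = 0."""
    if n_epochs <= 1:
        return lr0
    return lr0 * 0.5 * (1.0 + np.cos(np.pi * epoch / (n_epochs - 1)))


# ---------------------------------------------------------------------------
# batch assembly and the single optimization step
# ---------------------------------------------------------------------------

def _onehot(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


def _augmented_cnn_batch(state, mel_images, labeled_mask, aug, rng, noisy_unlabeled):
    """Stack flip/crop-perturbed, normalized CNN inputs."""
    out = []
    for img, is_labeled in zip(mel_images, labeled_mask):
        x = flip_crop(state.normalize_mel(img), aug, rng)
        if noisy_unlabeled and not is_labeled:
            x = add_noise(x, aug.noise_amplitude, rng)
        out.append(x)
    return np.stack(out)


def train_step(batch: dict, state: ModelState, cfg: TrainConfig,
               epoch: int, rng: np.random.Generator,
               lr: float | None = None) -> dict[str, float]:
    """One SGD update of the student followed by the EMA teacher update.

    ``batch`` carries ``mel_l``/``is09_l``/``y_l`` for the labeled part
    and ``mel_u``/``is09_u`` for the unlabeled part (entries may be
    omitted for variants that do not use them).  Returns the logged
    loss components.
    """
    use_cnn = state.student_cnn is not None
    use_ae = state.student_ae is not None
    aug = cfg.augment
    y_l = np.asarray(batch["y_l"])
    n_l = y_l.size
    n_u = len(batch.get("mel_u", batch.get("is09_u", []))) if cfg.variant != "AE" else len(batch.get("is09_u", []))
    omega = consistency_weight(epoch, cfg.epochs, cfg.weights)
    if cfg.variant in ("AE", "AE+MT"):
        omega = 0.0

    # ---- student forward -------------------------------------------------
    cnn_emb = tea_cnn_emb = None
    if use_cnn:
        mel_all = list(batch["mel_l"]) + list(batch.get("mel_u", []))
        labeled_mask = [True] * n_l + [False] * (len(mel_all) - n_l)
        x_cnn = _augmented_cnn_batch(state, mel_all, labeled_mask, aug, rng,
                                     noisy_unlabeled=True)
        cnn_emb = state.student_cnn.forward(x_cnn, train=True)
        if omega > 0 and n_u:
            x_tea = _augmented_cnn_batch(state, list(batch["mel_u"]),
                                         [True] * n_u, aug, rng,
                                         noisy_unlabeled=False)
            tea_cnn_emb = state.teacher_cnn.forward(x_tea, train=False)

    z = recon = ae_targets = tea_z = None
    if use_ae:
        ae_l = state.normalize_is09(np.atleast_2d(batch["is09_l"]))
        ae_u = state.normalize_is09(np.atleast_2d(batch["is09_u"])) \
            if n_u else np.zeros((0, ae_l.shape[1]))
        ae_targets = np.concatenate([ae_l, ae_u], axis=0)
        ae_u_noised = np.clip(add_noise(ae_u, aug.noise_amplitude, rng), 0.0, 1.0) \
            if n_u else ae_u
        ae_in = np.concatenate([ae_l, ae_u_noised], axis=0)
        z, recon = state.student_ae.forward(ae_in, train=True)
        if omega > 0 and n_u:
            tea_z, _ = state.teacher_ae.forward(ae_u, train=False)

    fused = _fuse(z, cnn_emb)

    l_consis = 0.0
    stu_u = tea_u = None
    if omega > 0 and n_u:
        stu_u = fused[n_l:]
        tea_u = _fuse(tea_z, tea_cnn_emb)
        if cfg.consistency_on == "probs":
            # eval-mode passes; run before the labeled pass so the head's
            # backward cache belongs to the labeled forward
            stu_u = softmax(state.head.forward(stu_u, train=False))
            tea_u = softmax(state.teacher_head.forward(tea_u, train=False))
        l_consis = consistency_loss(stu_u, tea_u, cfg.consistency_reduce)

    logits_l = state.head.forward(fused[:n_l], train=True)
    probs_l = softmax(logits_l)
    l_ce = supervised_loss(probs_l, y_l) if n_l else 0.0

    l_recon = reconstruction_loss(ae_targets, np.clip(recon.astype(np.float64), 1e-7, 1 - 1e-7)) if use_ae else 0.0
    total = l_ce + omega * l_consis + cfg.weights.a * l_recon
    if not np.isfinite(total):
        raise RuntimeError(
            f"non-finite loss: ce={l_ce} consis={l_consis} recon={l_recon}")

    # ---- backward --------------------------------------------------------
    for mod in state.student_modules():
        mod.zero_grad()
    dlogits = (probs_l - _onehot(y_l)) / max(n_l, 1)
    dfused_l = state.head.backward(dlogits)
    dfused = np.zeros_like(fused)
    dfused[:n_l] = dfused_l
    if omega > 0 and n_u and cfg.consistency_on == "embedding":
        dfused[n_l:] += omega * consistency_loss_grad(stu_u, tea_u, cfg.consistency_reduce)
    # (consistency on probabilities contributes through a frozen eval-mode
    # head pass and is treated as a stop-gradient target mode)

    offset = 0
    dz = dcnn = None
    if use_ae:
        dz = dfused[:, offset:offset + 32]
        offset += 32
    if use_cnn:
        dcnn = dfused[:, offset:offset + 32]
    if use_ae:
        drecon = cfg.weights.a * reconstruction_loss_grad(
            ae_targets, np.clip(recon.astype(np.float64), 1e-7, 1 - 1e-7))
        state.student_ae.backward(dz, drecon)
    if use_cnn:
        state.student_cnn.backward(dcnn)

    opt = batch["_optimizer"]
    opt.lr = lr if lr is not None else cfg.lr
    opt.step()
    ema_update(state.teacher_state(), state.student_state(), cfg.alpha_ema)

    return {"loss": float(total), "ce": float(l_ce), "consis": float(l_consis),
            "recon": float(l_recon), "omega": float(omega)}


def _fuse(z, cnn_emb):
    parts = [p for p in (z, cnn_emb) if p is not None]
    return np.concatenate(parts, axis=1)


# ---------------------------------------------------------------------------
# prediction / evaluation
# ---------------------------------------------------------------------------

def predict_probs(state: ModelState, features: FeatureSet, ids,
                  use_teacher: bool = False) -> np.ndarray:
    """Eval-mode class probabilities for the given utterance ids."""
    cnn = state.teacher_cnn if use_teacher else state.student_cnn
    ae = state.teacher_ae if use_teacher else state.student_ae
    head = state.teacher_head if use_teacher else state.head
    ids = list(ids)
    z = cnn_emb = None
    if ae is not None:
        x = state.normalize_is09(features.is09.loc[ids].to_numpy(dtype=np.float64))
        z, _ = ae.forward(x, train=False)
    if cnn is not None:
        imgs = np.stack([state.normalize_mel(features.mel[i]) for i in ids])
        cnn_emb = cnn.forward(imgs, train=False)
    return softmax(head.forward(_fuse(z, cnn_emb), train=False))


def evaluate_split(state: ModelState, features: FeatureSet,
                   manifest: CorpusManifest, split: str = "test",
                   use_teacher: bool = False):
    """(accuracy, f1, confusion) on a manifest split."""
    rows = manifest.df[manifest.df["split"] == split]
    probs = predict_probs(state, features, rows["id"], use_teacher)
    pred = probs.argmax(axis=1)
    return evaluate(pred, rows["label"].to_numpy())


# ---------------------------------------------------------------------------
# the full loop
# ---------------------------------------------------------------------------

def fit(manifest: CorpusManifest, features: FeatureSet,
        cfg: TrainConfig) -> tuple[ModelState, pd.DataFrame]:
    """Train on the manifest's training split, evaluating every epoch.

    Returns the model restored to its best-test-accuracy epoch and a
    per-epoch history (losses, omega, lr, student and teacher test
    metrics).  Unlabeled items enter only through their features; their
    true classes are never consulted.
    """
    visible = manifest.visible()
    train_rows = visible[visible["split"] == "train"]
    labeled = train_rows[train_rows["labeled"]]
    unlabeled = train_rows[~train_rows["labeled"]]
    if len(labeled) == 0:
        raise ValueError("no labeled training items: supervised loss undefined")

    state = init_model(cfg)
    _fit_normalizers(state, features, train_rows["id"])

    root = np.random.SeedSequence(cfg.seed)
    rng_batch, rng_aug, rng_drop = [np.random.default_rng(s) for s in root.spawn(3)]
    for mod in state.student_modules():
        mod.set_dropout_rng(rng_drop)

    opt = SGD(state.student_modules(), cfg.lr, cfg.momentum)
    label_idx = {"truth": 0, "lie": 1}
    lab_ids = labeled["id"].to_numpy()
    lab_y = np.array([label_idx[v] for v in labeled["label"]])
    unlab_ids = unlabeled["id"].to_numpy()

    n_l_batch = max(1, int(round(cfg.batch_size * cfg.labeled_batch_fraction)))
    n_u_batch = cfg.batch_size - n_l_batch
    if len(unlab_ids) == 0:
        n_l_batch, n_u_batch = min(cfg.batch_size, len(lab_ids)), 0

    history = []
    best = {"acc": -1.0, "student": None, "teacher": None, "epoch": -1}
    for epoch in range(cfg.epochs):
        lr = cosine_lr(epoch, cfg.epochs, cfg.lr)
        steps = max(1, int(np.ceil(len(unlab_ids) / n_u_batch)) if n_u_batch
                    else int(np.ceil(len(lab_ids) / n_l_batch)))
        unlab_order = rng_batch.permutation(len(unlab_ids))
        sums = {"loss": 0.0, "ce": 0.0, "consis": 0.0, "recon": 0.0, "omega": 0.0}
        for step in range(steps):
            pick = rng_batch.choice(len(lab_ids), size=min(n_l_batch, len(lab_ids)),
                                    replace=len(lab_ids) < n_l_batch)
            u_sel = unlab_order[step * n_u_batch:(step + 1) * n_u_batch]
            batch = {
                "y_l": lab_y[pick],
                "is09_l": features.is09.loc[lab_ids[pick]].to_numpy(dtype=np.float64),
                "mel_l": [features.mel[i] for i in lab_ids[pick]],
                "is09_u": features.is09.loc[unlab_ids[u_sel]].to_numpy(dtype=np.float64),
                "mel_u": [features.mel[i] for i in unlab_ids[u_sel]],
                "_optimizer": opt,
            }
            parts = train_step(batch, state, cfg, epoch, rng_aug, lr=lr)
            for k in sums:
                sums[k] += parts[k]
        acc_s, f1_s, _ = evaluate_split(state, features, manifest, "test")
        acc_t, f1_t, _ = evaluate_split(state, features, manifest, "test", use_teacher=True)
        history.append({"epoch": epoch, "lr": lr,
                        **{k: v / steps for k, v in sums.items()},
                        "test_acc_student": acc_s, "test_f1_student": f1_s,
                        "test_acc_teacher": acc_t, "test_f1_teacher": f1_t})
        if acc_s > best["acc"]:
            best.update(acc=acc_s, epoch=epoch,
                        student={k: v.copy() for k, v in state.student_state().items()},
                        teacher={k: v.copy() for k, v in state.teacher_state().items()})

    if best["student"] is not None:
        state.load_student(best["student"])
        state.load_teacher(best["teacher"])
    return state, pd.DataFrame(history)


def _fit_normalizers(state: ModelState, features: FeatureSet, train_ids) -> None:
    if state.student_ae is not None:
        x = features.is09.loc[list(train_ids)].to_numpy(dtype=np.float64)
        state.ae_min = x.min(axis=0)
        state.ae_max = x.max(axis=0)
    if state.student_cnn is not None:
        imgs = np.stack([features.mel[i] for i in train_ids]).astype(np.float64)
        state.mel_mean = float(imgs.mean())
        state.mel_std = float(imgs.std()) or 1.0


# ---------------------------------------------------------------------------
# ablation runner
# ---------------------------------------------------------------------------

def run_ablation(manifest: CorpusManifest, features: FeatureSet, cfg: TrainConfig,
                 variants=VARIANTS, label_budgets=(200, 400, 600),
                 seeds=(0,)) -> pd.DataFrame:
    """Train every variant at every label budget; one row per run."""
    for v in variants:
        if v not in VARIANTS:
            raise ValueError(f"unknown variant {v!r}; choose from {VARIANTS}")
    rows = []
    for budget in label_budgets:
        budgeted = assign_label_budget(manifest, budget, seed=cfg.seed)
        for variant in variants:
            for seed in seeds:
                run_cfg = replace(cfg, variant=variant, seed=seed)
                state, _ = fit(budgeted, features, run_cfg)
                acc, f1, _ = evaluate_split(state, features, budgeted, "test")
                rows.append({"variant": variant, "n_labeled": budget,
                             "seed": seed, "accuracy": acc, "f1": f1})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(state: ModelState, path) -> None:
    """Single-archive checkpoint: all parameters + config."""
    arrays = {}
    for prefix, sd in (("student", state.student_state()),
                       ("teacher", state.teacher_state())):
        arrays.update({f"{prefix}/{k}": v for k, v in sd.items()})
    if state.ae_min is not None:
        arrays["norm/ae_min"] = state.ae_min
        arrays["norm/ae_max"] = state.ae_max
    arrays["norm/mel"] = np.array([state.mel_mean, state.mel_std])
    cfg = state.cfg
    meta = {"variant": cfg.variant, "scale": cfg.scale, "seed": cfg.seed,
            "dropout": cfg.dropout, "dropout_is_drop_prob": cfg.dropout_is_drop_prob,
            "alpha_ema": cfg.alpha_ema, "lr": cfg.lr, "epochs": cfg.epochs,
            "batch_size": cfg.batch_size,
            "labeled_batch_fraction": cfg.labeled_batch_fraction}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> ModelState:
    with np.load(path) as npz:
        arrays = {k: npz[k] for k in npz.files}
    meta = json.loads(bytes(arrays.pop("meta")).decode())
    cfg = TrainConfig(**meta)
    state = init_model(cfg)
    state.load_student({k[8:]: v for k, v in arrays.items() if k.startswith("student/")})
    state.load_teacher({k[8:]: v for k, v in arrays.items() if k.startswith("teacher/")})
    if "norm/ae_min" in arrays:
        state.ae_min = arrays["norm/ae_min"]
        state.ae_max = arrays["norm/ae_max"]
    state.mel_mean, state.mel_std = arrays["norm/mel"]
    return state
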