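"""Network definitions: student/teacher CNN, autoencoder, fusion head, EMA.

The CNN mirrors the published layer table: three padded 3x3 conv blocks
to ``widths[0]`` channels, 2x2 max-pool, three padded conv blocks to
``widths[1]``, 2x2 max-pool, one *unpadded* conv to ``widths[2]``
(shrinking the map by 2 pixels), two padded convs to ``widths[3]`` and
``widths[4]``, global average pooling to a ``widths[4]``-dim embedding,
and an auxiliary 8-dim projection.  At full scale (256x256 input,
widths 32/64/128/64/32) the shape trace is

    (256,256,32) (128,128,32) (128,128,64) (64,64,64)
    (62,62,128) (62,62,64) (62,62,32) 32 -> 8

A desk-scale profile (64x64 input, widths 8/16/32/16/32) follows the
same rules for CPU-friendly training; the embedding stays 32-dim so
the fused representation is 32 + 32 = 64 at either scale.

The autoencoder compresses the 384-dim IS09 vector through
384-256-128-64-32 (BN + ELU, dropout at the bottleneck) and reconstructs
through 32-128-180-256-384 with a terminal sigmoid, so reconstructions
live in (0, 1) and match the min-max-normalized inputs of the binary
cross-entropy reconstruction loss.

The teacher is a structural copy of the student updated only by the
exponential moving average  theta'' = alpha * theta' + (1 - alpha) * theta;
no gradient ever flows into it.
"""

from __future__ import annotations

import numpy as np

from decspeech.nn.layers import (
    BatchNorm, Conv2d, Dropout, ELU, GlobalAvgPool, Linear, MaxPool2d,
    ReLU, Sequential, Sigmoid,
)

FULL_INPUT = 256
FULL_WIDTHS = (32, 64, 128, 64, 32)
DESK_INPUT = 64
DESK_WIDTHS = (8, 16, 32, 16, 32)
EMBED_DIM = 32
AUX_DIM = 8
IS09_DIM = 384
AE_BOTTLENECK = 32
FUSED_DIM = 2 * EMBED_DIM
N_CLASSES = 2


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _conv_block(in_c, out_c, padding, rng, dtype):
    return [Conv2d(in_c, out_c, padding=padding, rng=rng, dtype=dtype),
            BatchNorm(out_c, dtype=dtype), ReLU()]


def build_cnn(input_size: int = FULL_INPUT, widths=FULL_WIDTHS,
              seed: int = 0, dtype=np.float32) -> Sequential:
    """The convolutional backbone ending in global average pooling."""
    c1, c2, c3, c4, c5 = widths
    rng = np.random.default_rng(seed)
    layers = []
    layers += _conv_block(3, c1, "same", rng, dtype)
    layers += _conv_block(c1, c1, "same", rng, dtype)
    layers += _conv_block(c1, c1, "same", rng, dtype)
    layers.append(MaxPool2d())
    layers += _conv_block(c1, c2, "same", rng, dtype)
    layers += _conv_block(c2, c2, "same", rng, dtype)
    layers += _conv_block(c2, c2, "same", rng, dtype)
    layers.append(MaxPool2d())
    layers += _conv_block(c2, c3, "valid", rng, dtype)
    layers += _conv_block(c3, c4, "same", rng, dtype)
    layers += _conv_block(c4, c5, "same", rng, dtype)
    layers.append(GlobalAvgPool())
    return Sequential(*layers)


def shape_trace(input_size: int = FULL_INPUT, widths=FULL_WIDTHS) -> list[tuple[str, tuple]]:
    """Analytic shape propagation through the CNN, one row per table line."""
    c1, c2, c3, c4, c5 = widths
    s = input_size
    rows = [("input", (s, s, 3)),
            ("3x(conv1+bn+relu)", (s, s, c1)),
            ("max_pool", (s // 2, s // 2, c1))]
    s //= 2
    rows += [("3x(conv2+bn+relu)", (s, s, c2)),
             ("max_pool", (s // 2, s // 2, c2))]
    s //= 2
    s -= 2  # unpadded 3x3 conv
    rows += [("conv3+bn+relu", (s, s, c3)),
             ("conv4+bn+relu", (s, s, c4)),
             ("conv5+bn+relu", (s, s, c5)),
             ("sum_and_average", (c5,)),
             ("full_connection", (AUX_DIM,))]
    return rows


class StudentCNN:
    """Backbone + auxiliary 8-dim projection head."""

    def __init__(self, input_size: int = FULL_INPUT, widths=FULL_WIDTHS, seed: int = 0,
                 dtype=np.float32):
        self.input_size = input_size
        self.widths = tuple(widths)
        self.backbone = build_cnn(input_size, widths, seed, dtype)
        self.head8 = Sequential(Linear(widths[4], AUX_DIM,
                                       rng=np.random.default_rng(seed + 1), dtype=dtype))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        """Images (N, S, S, 3) -> embeddings (N, widths[4])."""
        if x.ndim == 3:
            x = x[None]
        s = self.input_size
        if x.shape[1:] != (s, s, 3):
            raise ValueError(f"expected input of shape ({s}, {s}, 3), got {x.shape[1:]}")
        return self.backbone.forward(x.transpose(0, 3, 1, 2), train)

    def backward(self, dembed: np.ndarray) -> None:
        self.backbone.backward(dembed)

    def state_dict(self):
        return {**{f"backbone.{k}": v for k, v in self.backbone.state_dict().items()},
                **{f"head8.{k}": v for k, v in self.head8.state_dict().items()}}

    def load_state_dict(self, state):
        self.backbone.load_state_dict(
            {k[9:]: v for k, v in state.items() if k.startswith("backbone.")})
        self.head8.load_state_dict(
            {k[6:]: v for k, v in state.items() if k.startswith("head8.")})

    def modules(self):
        return [self.backbone, self.head8]


class AENetwork:
    """Autoencoder over the IS09 vector: encoder, decoder, projection head."""

    ENCODER_WIDTHS = (256, 128, 64, AE_BOTTLENECK)
    DECODER_WIDTHS = (128, 180, 256, IS09_DIM)

    def __init__(self, dropout: float = 0.0, seed: int = 0, dtype=np.float32):
        rng = np.random.default_rng(seed)
        drop_rng = np.random.default_rng(seed + 7)
        enc, prev = [], IS09_DIM
        for w in self.ENCODER_WIDTHS:
            enc += [Linear(prev, w, rng=rng, dtype=dtype), BatchNorm(w, dtype=dtype), ELU()]
            prev = w
        enc.append(Dropout(dropout, drop_rng))
        self.encoder = Sequential(*enc)
        dec, prev = [], AE_BOTTLENECK
        for w in self.DECODER_WIDTHS:
            dec += [Linear(prev, w, rng=rng, dtype=dtype), BatchNorm(w, dtype=dtype), ELU()]
            prev = w
        dec.append(Dropout(dropout, drop_rng))
        dec.append(Sigmoid())
        self.decoder = Sequential(*dec)
        self.head8 = Sequential(Linear(AE_BOTTLENECK, AUX_DIM, rng=rng, dtype=dtype))

    def forward(self, x: np.ndarray, train: bool) -> tuple[np.ndarray, np.ndarray]:
        """(N, 384) in [0,1] -> (bottleneck (N, 32), reconstruction (N, 384))."""
        if x.ndim == 1:
            x = x[None]
        if x.shape[1] != IS09_DIM:
            raise ValueError(f"expected {IS09_DIM}-dim input, got {x.shape[1]}")
        z = self.encoder.forward(x, train)
        recon = self.decoder.forward(z, train)
        return z, recon

    def backward(self, dz: np.ndarray, drecon: np.ndarray | None = None) -> None:
        """Backprop bottleneck and (optionally) reconstruction gradients."""
        total_dz = np.array(dz, copy=True)
        if drecon is not None:
            total_dz += self.decoder.backward(drecon)
        self.encoder.backward(total_dz)

    def state_dict(self):
        out = {}
        for name, mod in (("encoder", self.encoder), ("decoder", self.decoder),
                          ("head8", self.head8)):
            out.update({f"{name}.{k}": v for k, v in mod.state_dict().items()})
        return out

    def load_state_dict(self, state):
        for name, mod in (("encoder", self.encoder), ("decoder", self.decoder),
                          ("head8", self.head8)):
            mod.load_state_dict({k[len(name) + 1:]: v for k, v in state.items()
                                 if k.startswith(name + ".")})

    def modules(self):
        return [self.encoder, self.decoder, self.head8]


class FusionHead:
    """Dropout + linear classifier over the fused 64-dim embedding."""

    def __init__(self, in_dim: int = FUSED_DIM, dropout: float = 0.0, seed: int = 0,
                 dtype=np.float32):
        self.in_dim = in_dim
        self.net = Sequential(Dropout(dropout, np.random.default_rng(seed + 13)),
                              Linear(in_dim, N_CLASSES, rng=np.random.default_rng(seed),
                                     dtype=dtype))

    def forward(self, fused: np.ndarray, train: bool) -> np.ndarray:
        """Fused embeddings -> logits (N, 2)."""
        if fused.shape[1] != self.in_dim:
            raise ValueError(f"expected fused dim {self.in_dim}, got {fused.shape[1]}")
        return self.net.forward(fused, train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.net.backward(dlogits)

    def state_dict(self):
        return self.net.state_dict()

    def load_state_dict(self, state):
        self.net.load_state_dict(state)

    def modules(self):
        return [self.net]


# ---------------------------------------------------------------------------
# functional conveniences mirroring the operation-level API
# ---------------------------------------------------------------------------

def cnn_forward(x: np.ndarray, net: StudentCNN, train: bool = False) -> np.ndarray:
    out = net.forward(x, train)
    return out[0] if np.ndim(x) == 3 else out


def ae_forward(x: np.ndarray, net: AENetwork, train: bool = False):
    z, recon = net.forward(x, train)
    if np.ndim(x) == 1:
        return z[0], recon[0]
    return z, recon


def fuse_and_classify(ae_emb: np.ndarray, cnn_emb: np.ndarray,
                      head: FusionHead, train: bool = False) -> np.ndarray:
    """Concatenate the two 32-dim embeddings and return class probabilities."""
    ae_emb = np.atleast_2d(ae_emb)
    cnn_emb = np.atleast_2d(cnn_emb)
    if ae_emb.shape[0] != cnn_emb.shape[0]:
        raise ValueError("batch sizes of the two embeddings differ")
    fused = np.concatenate([ae_emb, cnn_emb], axis=1)
    probs = softmax(head.forward(fused, train))
    return probs[0] if probs.shape[0] == 1 and ae_emb.shape[0] == 1 else probs


def ema_update(teacher_state: dict[str, np.ndarray],
               student_state: dict[str, np.ndarray],
               alpha_ema: float) -> dict[str, np.ndarray]:
    """In-place exponential moving average of every teacher array.

    theta'' = alpha * theta' + (1 - alpha) * theta.  Running BN buffers
    are averaged alongside the weights so the teacher's normalization
    follows its parameters.
    """
    if not 0.0 <= alpha_ema <= 1.0:
        raise ValueError("alpha_ema must be in [0, 1]")
    if set(teacher_state) != set(student_state):
        raise ValueError("teacher/student parameter structures differ")
    for k in teacher_state:
        if teacher_state[k].shape != student_state[k].shape:
            raise ValueError(f"shape mismatch at {k}")
        teacher_state[k] *= alpha_ema
        teacher_state[k] += (1.0 - alpha_ema) * student_state[k]
    return teacher_state
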