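"""Identity-embedding network for aligned face chips.

A 112x112 grayscale chip passes through four convolutional blocks —
each a grouped 3x3 convolution (stride 2), batch norm, ReLU and a
channel shuffle that mixes information across the convolution groups —
then global average pooling and a linear bottleneck to a length-512
embedding, L2-normalized onto the unit sphere.  Cosine similarity of
two embeddings measures how likely two chips show the same individual.

Group convolution keeps the parameter count small enough to train on
a few hundred chips; the shuffle is the standard reshape-transpose
permutation, so groups in consecutive layers see each other's features.

Training minimizes an additive-margin softmax over identities
(margin m subtracted from the target cosine, scaled by s before the
softmax) with SGD + momentum; the classification head is discarded
afterwards and only the embedding trunk is kept.  Horizontal flips are
the only augmentation: the spot constellation is position-coded, and a
mirrored face is still the same animal.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import logging

import numpy as np

from . import nn
from .annotations import ChipRecord

logger = logging.getLogger(__name__)

__all__ = [
    "EmbedderConfig",
    "EmbedderModel",
    "channel_shuffle",
    "build_embedder",
    "train_embedder",
    "embed_chips",
    "save_embedder",
    "load_embedder",
]


@dataclass
class EmbedderConfig:
    n_blocks: int = 4
    channels: tuple[int, ...] = (32, 64, 128, 256)
    groups: tuple[int, ...] = (2, 4, 4, 8)
    embedding_dim: int = 512
    input_size: int = 112
    margin: float = 0.35          # additive margin m
    loss_scale: float = 30.0      # logit scale s
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 0.05
    momentum: float = 0.9
    weight_decay: float = 5e-4
    flip_augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.embedding_dim != 512:
            raise ValueError("the embedding is defined as a length-512 vector")
        if len(self.channels) != self.n_blocks or len(self.groups) != self.n_blocks:
            raise ValueError("channels/groups must list one entry per block")


def channel_shuffle(features: np.ndarray, groups: int) -> np.ndarray:
    """Permute channels by the reshape-transpose shuffle.

    Channel c moves to position g*(c mod C/g) + floor(c / (C/g)) where
    g is ``groups`` — equivalently reshape (g, C/g) -> transpose ->
    flatten.  Accepts (C, ...) or (N, C, ...) arrays; spatial content
    is untouched.
    """
    x = np.asarray(features)
    axis = 1 if x.ndim >= 4 else 0
    perm = nn.shuffle_permutation(x.shape[axis], groups)
    return np.take(x, perm, axis=axis)


class EmbedderModel:
    def __init__(self, config: EmbedderConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        layers = []
        cin = 1
        for cout, g in zip(config.channels, config.groups):
            g_eff = g if (cin % g == 0 and cout % g == 0) else 1
            layers += [nn.Conv2d(cin, cout, 3, stride=2, groups=g_eff, rng=rng),
                       nn.BatchNorm2d(cout), nn.ReLU(),
                       nn.ChannelShuffle(g)]
            cin = cout
        layers += [nn.GlobalAvgPool(),
                   nn.Linear(cin, config.embedding_dim, rng=rng),
                   nn.L2Normalize()]
        self.net = nn.Sequential(*layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        size = self.config.input_size
        if x.shape[-2:] != (size, size):
            raise ValueError(f"embedder expects {size}x{size} chips, "
                             f"got {x.shape[-2:]}")
        return self.net.forward(x, train=train)

    def embed(self, chips: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Embed (N, H, W) uint8 chips -> (N, 512) unit vectors."""
        chips = np.asarray(chips)
        if chips.ndim == 2:
            chips = chips[None]
        x = standardize_chips(chips)
        out = [self.forward(x[i:i + batch_size], train=False)
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)

    def params(self):
        return self.net.params()

    def state_arrays(self):
        return self.net.state_arrays()


def standardize_chips(chips: np.ndarray) -> np.ndarray:
    """Per-chip zero-mean unit-variance, shaped (N, 1, H, W) float32."""
    x = np.asarray(chips, dtype=np.float32)
    if x.ndim == 3:
        x = x[:, None]
    mean = x.mean(axis=(2, 3), keepdims=True)
    std = x.std(axis=(2, 3), keepdims=True)
    return (x - mean) / np.maximum(std, 1e-6)


def build_embedder(config: EmbedderConfig | None = None) -> EmbedderModel:
    return EmbedderModel(config or EmbedderConfig())


class _AMSoftmaxHead:
    """Additive-margin softmax: logits = s * (cos - m * onehot)."""

    def __init__(self, dim: int, n_classes: int, margin: float, scale: float,
                 rng: np.random.Generator):
        self.W = rng.normal(0, 0.01, (n_classes, dim)).astype(np.float32)
        self.dW = np.zeros_like(self.W)
        self.margin, self.scale = margin, scale

    def loss_and_grad(self, emb: np.ndarray, labels: np.ndarray
                      ) -> tuple[float, np.ndarray]:
        """Cross-entropy with margin; returns (loss, grad wrt embeddings)."""
        norms = np.sqrt((self.W * self.W).sum(axis=1, keepdims=True)) + 1e-12
        Wn = self.W / norms
        cos = emb @ Wn.T  # (B, n_classes); emb already unit-norm
        logits = self.scale * cos
        b = np.arange(len(labels))
        logits[b, labels] -= self.scale * self.margin
        logits -= logits.max(axis=1, keepdims=True)
        exp = np.exp(logits)
        p = exp / exp.sum(axis=1, keepdims=True)
        loss = float(-np.log(p[b, labels] + 1e-12).mean())
        dlogit = p.copy()
        dlogit[b, labels] -= 1.0
        dlogit *= self.scale / len(labels)
        demb = dlogit @ Wn
        dWn = dlogit.T @ emb
        # backprop through row normalization of W
        self.dW[...] = (dWn - Wn * (dWn * Wn).sum(axis=1, keepdims=True)) / norms
        return loss, demb.astype(np.float32)

    def params(self):
        return [(self.W, self.dW)]


def train_embedder(model: EmbedderModel,
                   chips_by_identity: dict[str, list],
                   config: EmbedderConfig | None = None
                   ) -> tuple[EmbedderModel, list[float]]:
    """Train the embedding trunk on chips grouped by individual.

    ``chips_by_identity`` maps identity -> list of ChipRecord or (H, W)
    arrays.  At least two identities with two chips each are required
    (a margin between classes needs more than one class).  Returns
    (model, per-epoch mean loss); the classification head is dropped.
    """
    cfg = config or model.config
    identities = sorted(chips_by_identity)
    if len(identities) < 2:
        raise ValueError("margin training needs at least two identities")
    xs, ys = [], []
    for label, identity in enumerate(identities):
        chips = chips_by_identity[identity]
        if len(chips) < 2:
            raise ValueError(
                f"identity {identity!r} has {len(chips)} chip(s); need >= 2")
        for chip in chips:
            pixels = chip.pixels if isinstance(chip, ChipRecord) else chip
            xs.append(np.asarray(pixels))
            ys.append(label)
    chips_arr = np.stack(xs)
    labels = np.array(ys)

    rng = np.random.default_rng(cfg.seed + 17)
    head = _AMSoftmaxHead(cfg.embedding_dim, len(identities),
                          cfg.margin, cfg.loss_scale, rng)
    optimizer = nn.SGD(model.params() + head.params(), lr=cfg.learning_rate,
                       momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    x_all = standardize_chips(chips_arr)
    losses: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(labels))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = x_all[idx]
            if cfg.flip_augment:
                flip = rng.random(len(idx)) < 0.5
                xb = xb.copy()
                xb[flip] = xb[flip, :, :, ::-1]
            emb = model.forward(xb, train=True)
            loss, demb = head.loss_and_grad(emb, labels[idx])
            model.net.backward(demb)
            optimizer.step()
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / max(n_batches, 1))
        logger.info("embedder epoch %d/%d loss %.4f",
                    epoch + 1, cfg.epochs, losses[-1])
    return model, losses


def embed_chips(model: EmbedderModel, chips) -> np.ndarray:
    """Embed a list of ChipRecord / arrays into (N, 512) unit vectors."""
    pixels = [c.pixels if isinstance(c, ChipRecord) else np.asarray(c)
              for c in chips]
    return model.embed(np.stack(pixels))


def save_embedder(model: EmbedderModel, path) -> None:
    import json
    arrays = model.state_arrays()
    np.savez(path, __config__=np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8), **arrays)


def load_embedder(path) -> EmbedderModel:
    import json
    with np.load(path) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        cfg["channels"] = tuple(cfg["channels"])
        cfg["groups"] = tuple(cfg["groups"])
        model = EmbedderModel(EmbedderConfig(**cfg))
        arrays = {k: data[k] for k in data.files if k != "__config__"}
    state = model.state_arrays()
    for k, v in arrays.items():
        state[k][...] = v
    return model
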