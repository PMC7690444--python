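"""The parallel multi-parametric feature-embedded siamese network.

Each of the six MRI parameter maps has its own embedding branch (weights
are *not* shared across modalities); each branch is shared between the two
inputs of a pair (twin weight sharing), which makes the similarity output
exactly symmetric in the pair order. A branch is a convolutional backbone
followed by flatten -> batch normalization -> dense(20, ReLU) ->
dense(10, ReLU); the six 10-d branch outputs are concatenated into a 60-d
embedding and compared with a normalized cosine similarity
s = (1 + cos(u, v)) / 2 in [0, 1]. Training minimizes binary cross-entropy
between s and the binary same-class pair label with momentum SGD.

Two backbones are provided:

* ``vgg16`` — the 16-layer VGG convolutional stack at 150 x 150 x 3 input,
  with convolutional blocks 1-4 frozen and only block 5 fine-tuned. Built
  offline with random convolutional weights (loading externally pretrained
  ImageNet weights is an orthogonal initialization concern and is not
  bundled); its layer shapes and parameter counts are exact.
* ``toy`` — a two-block convolutional net with the same head, small enough
  to train on a CPU in seconds; first block frozen, second fine-tuned,
  mirroring the frozen-backbone transfer policy at desk scale.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import nn
from .io import MODALITIES
from .pairs import SamplePair
from .preprocess import PreparedSample

__all__ = [
    "BranchSpec",
    "SiameseSpec",
    "TrainConfig",
    "ModelState",
    "build_branch",
    "count_parameters",
    "normalized_cosine",
    "bce_cosine_loss",
    "forward_pair",
    "train",
]

_VGG_BLOCKS = ((64, 64), (128, 128), (256, 256, 256), (512, 512, 512), (512, 512, 512))
COSINE_EPS = 1e-8
_CLIP = 1e-7  # similarity clip inside the cross-entropy


@dataclass(frozen=True)
class BranchSpec:
    """Architecture and freeze policy of one embedding branch."""

    backbone: str = "vgg16"
    input_shape: tuple = (150, 150, 3)
    toy_filters: tuple = (8, 16)
    # number of leading conv blocks kept frozen; the remaining blocks are
    # fine-tuned (vgg16 default: blocks 1-4 frozen, block 5 trainable)
    freeze_blocks: Optional[int] = None

    def __post_init__(self) -> None:
        if self.backbone not in ("vgg16", "toy"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if len(self.input_shape) != 3 or self.input_shape[2] != 3:
            raise ValueError("input_shape must be H x W x 3")

    @property
    def n_frozen_blocks(self) -> int:
        if self.freeze_blocks is not None:
            return self.freeze_blocks
        return 4 if self.backbone == "vgg16" else 1


@dataclass(frozen=True)
class SiameseSpec:
    """Six per-modality branches, twin-shared within a pair; 60-d embedding."""

    branch: BranchSpec = field(default_factory=BranchSpec)
    modalities: tuple = MODALITIES

    @property
    def embedding_dim(self) -> int:
        return 10 * len(self.modalities)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults follow the reference protocol
    (SGD, lr 1e-4, momentum 0.9, batch 32, up to 20 epochs with an early
    stop once the training-loss decrease is <= 1e-4, patience 1; dense and
    batch-norm shift weights drawn from N(0, 0.01))."""

    lr: float = 1e-4
    momentum: float = 0.9
    batch_size: int = 32
    max_epochs: int = 20
    early_stop_min_delta: float = 1e-4
    patience: int = 1
    init_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr < 0 or self.momentum < 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("invalid training configuration")


def _conv_blocks(spec: BranchSpec) -> tuple:
    if spec.backbone == "vgg16":
        return _VGG_BLOCKS
    f1, f2 = spec.toy_filters
    return ((f1,), (f2,))


def build_branch(
    spec: BranchSpec,
    groups: int = 1,
    rng: Optional[np.random.Generator] = None,
    init_sd: float = 0.01,
) -> list:
    """Build the layer stack of one branch (replicated over ``groups``).

    Feature-map sizes halve (floor) at each pooling stage; for the vgg16
    backbone at 150 x 150 x 3 the block-5 pool output is 4 x 4 x 512,
    flattened to 8192 features ahead of the batch-norm/dense head.
    """
    rng = rng or np.random.default_rng(0)
    h, w, c_in = spec.input_shape
    layers: list = []
    n_frozen = spec.n_frozen_blocks
    for b, widths in enumerate(_conv_blocks(spec)):
        trainable = b >= n_frozen
        for c_out in widths:
            layers.append(nn.Conv2D(groups, c_in, c_out, trainable=trainable, rng=rng))
            layers.append(nn.ReLU())
            c_in = c_out
        layers.append(nn.MaxPool2D(2))
        h, w = h // 2, w // 2
    n_flat = h * w * c_in
    layers.append(nn.Flatten())
    layers.append(nn.BatchNorm(groups, n_flat))
    layers.append(nn.Dense(groups, n_flat, 20, relu=True, init_sd=init_sd, rng=rng))
    layers.append(nn.Dense(groups, 20, 10, relu=True, init_sd=init_sd, rng=rng))
    return layers


def count_parameters(network) -> tuple[int, int, int]:
    """(total, trainable, non_trainable) of a layer stack or model state."""
    layers = network.layers if isinstance(network, ModelState) else network
    return nn.count_parameters(layers)


def normalized_cosine(u: np.ndarray, v: np.ndarray, eps: float = COSINE_EPS) -> np.ndarray:
    """s = (1 + cos(u, v)) / 2 in [0, 1]; symmetric; 0.5 for a zero vector."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    dot = (u * v).sum(axis=-1)
    denom = np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1) + eps
    return (1.0 + dot / denom) / 2.0


def bce_cosine_loss(
    u: np.ndarray, v: np.ndarray, labels: np.ndarray, eps: float = COSINE_EPS
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean binary cross-entropy of the normalized cosine, with gradients.

    Returns (loss, dL/du, dL/dv) for batches u, v of shape (B, d). The
    similarity is clipped to [1e-7, 1 - 1e-7] inside the logarithms.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    b = np.asarray(labels, dtype=float)
    dot = (u * v).sum(axis=-1)
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    denom = nu * nv + eps
    cos = dot / denom
    s = np.clip((1.0 + cos) / 2.0, _CLIP, 1.0 - _CLIP)
    loss = float(np.mean(-(b * np.log(s) + (1 - b) * np.log(1 - s))))
    n = u.shape[0]
    ds = (s - b) / (s * (1 - s)) / n
    dcos = 0.5 * ds
    nu_safe = np.maximum(nu, 1e-12)
    nv_safe = np.maximum(nv, 1e-12)
    du = dcos[:, None] * (v / denom[:, None] - dot[:, None] * (nv / nu_safe)[:, None] * u / (denom**2)[:, None])
    dv = dcos[:, None] * (u / denom[:, None] - dot[:, None] * (nu / nv_safe)[:, None] * v / (denom**2)[:, None])
    return loss, du, dv


class ModelState:
    """Trained (or freshly built) model: layer stack, specs, and history."""

    def __init__(self, spec: SiameseSpec, config: TrainConfig, layers: list, history: Optional[dict] = None):
        self.spec = spec
        self.config = config
        self.layers = layers
        self.groups = len(spec.modalities)
        self.history = history if history is not None else {"train_loss": [], "val_loss": []}
        self._bstart = nn.first_backward_index(layers)

    @classmethod
    def initialize(cls, spec: SiameseSpec, config: TrainConfig) -> "ModelState":
        rng = np.random.default_rng(config.seed)
        layers = build_branch(spec.branch, groups=len(spec.modalities), rng=rng, init_sd=config.init_sd)
        return cls(spec, config, layers)

    # -- embedding ---------------------------------------------------------
    def _stack_inputs(self, samples: Sequence[PreparedSample]) -> np.ndarray:
        try:
            x = np.stack(
                [np.stack([np.asarray(s.slabs[m], dtype=nn.DTYPE) for s in samples]) for m in self.spec.modalities]
            )
        except KeyError as exc:
            raise ValueError(f"sample is missing modality slab {exc}") from exc
        expect = self.spec.branch.input_shape
        if x.shape[2:] != tuple(expect):
            raise ValueError(f"slab shape {x.shape[2:]} does not match branch input {tuple(expect)}")
        return x

    def embed(self, samples: Sequence[PreparedSample], train: bool = False) -> np.ndarray:
        """(N, 60) embeddings: per-modality branch outputs concatenated in
        modality order."""
        x = self._stack_inputs(samples)
        out = nn.forward_stack(self.layers, x, train=train, cache_from=self._bstart)  # (G, N, 10)
        return np.ascontiguousarray(out.transpose(1, 0, 2)).reshape(len(samples), -1)

    def backward_embeddings(self, d_emb: np.ndarray) -> None:
        g = self.groups
        dy = np.ascontiguousarray(d_emb.reshape(d_emb.shape[0], g, -1).transpose(1, 0, 2)).astype(nn.DTYPE)
        nn.backward_stack(self.layers, dy, stop_at=self._bstart)

    # -- persistence -------------------------------------------------------
    def save(self, path: "str | Path") -> None:
        path = Path(path)
        arrays = {}
        for i, layer in enumerate(self.layers):
            for name, p in {**layer.params(), **layer.buffers()}.items():
                arrays[f"{i}.{name}"] = p
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "spec": {"branch": asdict(self.spec.branch), "modalities": list(self.spec.modalities)},
            "config": asdict(self.config),
            "history": self.history,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: "str | Path") -> "ModelState":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        branch = BranchSpec(**{**meta["spec"]["branch"], "input_shape": tuple(meta["spec"]["branch"]["input_shape"]),
                               "toy_filters": tuple(meta["spec"]["branch"]["toy_filters"])})
        spec = SiameseSpec(branch=branch, modalities=tuple(meta["spec"]["modalities"]))
        config = TrainConfig(**meta["config"])
        state = cls.initialize(spec, config)
        state.history = meta["history"]
        with np.load(path.with_suffix(".npz")) as data:
            for i, layer in enumerate(state.layers):
                for name, p in {**layer.params(), **layer.buffers()}.items():
                    p[...] = data[f"{i}.{name}"]
        return state


def forward_pair(state: ModelState, pair: SamplePair) -> float:
    """Similarity of one pair, in [0, 1]; exactly symmetric in pair order."""
    emb = state.embed([pair.a, pair.b], train=False)
    return float(normalized_cosine(emb[0], emb[1]))


def train(
    spec: SiameseSpec,
    train_pairs: Sequence[SamplePair],
    val_pairs: Sequence[SamplePair],
    config: TrainConfig,
) -> ModelState:
    """Train the twin network on labelled pairs with momentum SGD.

    Pairs are reshuffled every epoch; each mini-batch runs both pair members
    through the shared branches in one forward pass (so batch-norm batch
    statistics cover both), and gradients from the cross-entropy on the
    normalized cosine flow back through both members. Per-epoch training and
    validation losses are recorded. Early stop: once an epoch's training-loss
    decrease is <= ``early_stop_min_delta``, training runs ``patience`` more
    epochs and halts.

    Frozen layers are never registered with the optimizer and are
    bit-identical before and after training.
    """
    train_pairs = list(train_pairs)
    if not train_pairs:
        raise ValueError("no training pairs")
    labels_present = {p.pair_label for p in train_pairs}
    if labels_present != {0, 1}:
        raise ValueError(
            f"training pairs must contain both labels; got only {sorted(labels_present)}"
        )

    state = ModelState.initialize(spec, config)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x5EED)))
    optimizer = nn.SGDMomentum(state.layers, lr=config.lr, momentum=config.momentum)

    # embed unique samples once per batch rather than once per pair member
    sample_index: dict = {}
    samples: list = []
    for p in train_pairs:
        for s in (p.a, p.b):
            if s.case_id not in sample_index:
                sample_index[s.case_id] = len(samples)
                samples.append(s)
    ia = np.array([sample_index[p.a.case_id] for p in train_pairs])
    ib = np.array([sample_index[p.b.case_id] for p in train_pairs])
    y = np.array([p.pair_label for p in train_pairs], dtype=float)

    trigger: Optional[int] = None
    prev_loss: Optional[float] = None
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_pairs))
        total, seen = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            sel = order[start : start + config.batch_size]
            ba, bb = ia[sel], ib[sel]
            uniq, inv = np.unique(np.concatenate([ba, bb]), return_inverse=True)
            emb = state.embed([samples[i] for i in uniq], train=True)
            pos_a, pos_b = inv[: len(sel)], inv[len(sel) :]
            u, v = emb[pos_a], emb[pos_b]
            loss, du, dv = bce_cosine_loss(u, v, y[sel])
            d_emb = np.zeros_like(emb)
            np.add.at(d_emb, pos_a, du)
            np.add.at(d_emb, pos_b, dv)
            state.backward_embeddings(d_emb)
            optimizer.step()
            total += loss * len(sel)
            seen += len(sel)
        epoch_loss = total / seen
        state.history["train_loss"].append(epoch_loss)
        state.history["val_loss"].append(_eval_loss(state, val_pairs))
        if trigger is None and prev_loss is not None and prev_loss - epoch_loss <= config.early_stop_min_delta:
            trigger = epoch
        prev_loss = epoch_loss
        if trigger is not None and epoch >= trigger + config.patience:
            break
    return state


def _eval_loss(state: ModelState, pairs: Sequence[SamplePair]) -> float:
    pairs = list(pairs)
    if not pairs:
        return float("nan")
    sample_index: dict = {}
    samples: list = []
    for p in pairs:
        for s in (p.a, p.b):
            if s.case_id not in sample_index:
                sample_index[s.case_id] = len(samples)
                samples.append(s)
    emb = state.embed(samples, train=False)
    u = emb[[sample_index[p.a.case_id] for p in pairs]]
    v = emb[[sample_index[p.b.case_id] for p in pairs]]
    y = np.array([p.pair_label for p in pairs], dtype=float)
    loss, _, _ = bce_cosine_loss(u, v, y)
    return loss
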