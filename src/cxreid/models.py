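"""Siamese architectures for patient verification and re-identification.

Both tasks share the twin-branch layout: one convolutional backbone (a single
parameter store — "two branches" is weight sharing, not a copy) maps each
radiograph to a feature volume, and a task head turns features into either a
similarity score (verification) or a 128-d embedding (retrieval).

* Verification head: backbone features -> flatten -> FC to 128 giving z; the
  merge computes ``|sigmoid(z1) - sigmoid(z2)|``, one FC reduces the 128-d
  difference to a single neuron, and a final sigmoid yields the score in
  [0, 1].
* Retrieval head: adaptive average pooling AND adaptive max pooling of the
  backbone features to 5x5 each, channel concatenation (2C maps), a 1x1
  convolution down to 100 maps, flatten (2500), then two FC layers
  (2500 -> 512 -> 128). Adaptive pooling makes the head resolution-agnostic.

The default backbone here is a deliberately small 3-block CNN so the whole
pipeline trains on a CPU in minutes; the full-scale configuration of the
method uses a 50-layer residual backbone pretrained on natural images, which
this package treats as a pluggable drop-in (any Module with ``feature_channels``
and a forward from (B,3,H,W) to (B,C,H',W')).
"""

from __future__ import annotations

import json
import pathlib

import numpy as np

from . import nn
from .nn import Tensor
from .nn import tensor as F

EMBEDDING_DIM = 128


class TinyBackbone(nn.Module):
    """Three conv/pool blocks; spatial stride 8, ``feature_channels`` maps."""

    def __init__(self, feature_channels: int = 48, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.feature_channels = feature_channels
        c = feature_channels
        self.blocks = nn.Sequential(
            nn.Conv2d(3, c // 4, 3, pad=1, rng=rng), nn.ReLU(), nn.MaxPool2d(2),
            nn.Conv2d(c // 4, c // 2, 3, pad=1, rng=rng), nn.ReLU(), nn.MaxPool2d(2),
            nn.Conv2d(c // 2, c, 3, pad=1, rng=rng), nn.ReLU(), nn.MaxPool2d(2),
        )
        self.min_side = 8

    def forward(self, x: Tensor) -> Tensor:
        return self.blocks(x)

    def conv_layers(self) -> dict[str, nn.Conv2d]:
        convs = [m for m in self.blocks.modules if isinstance(m, nn.Conv2d)]
        return {f"conv{i + 1}": m for i, m in enumerate(convs)}


class VerificationNet(nn.Module):
    """Twin-branch scorer: is this pair of radiographs one patient?"""

    def __init__(self, backbone: nn.Module | None = None, input_side: int = 64,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.backbone = backbone if backbone is not None else TinyBackbone(rng=rng)
        self.input_side = input_side
        feat_side = input_side // 8
        flat = self.backbone.feature_channels * feat_side * feat_side
        self.embed_fc = nn.Linear(flat, EMBEDDING_DIM, rng=rng)
        self.head_fc = nn.Linear(EMBEDDING_DIM, 1, rng=rng)

    def embed(self, x: Tensor) -> Tensor:
        """Pre-activation 128-d identity code z for a batch (B,3,S,S)."""
        if x.ndim != 4 or x.shape[1] != 3 or x.shape[2] != self.input_side \
                or x.shape[3] != self.input_side:
            raise ValueError(
                f"expected (B,3,{self.input_side},{self.input_side}), got {x.shape}")
        feats = self.backbone(x)
        return self.embed_fc(F.reshape(feats, (x.shape[0], -1)))

    def score_logit(self, z1: Tensor, z2: Tensor) -> Tensor:
        """Pre-sigmoid merge: FC(|sigmoid(z1) - sigmoid(z2)|)."""
        if z1.shape[-1] != EMBEDDING_DIM or z2.shape[-1] != EMBEDDING_DIM:
            raise ValueError("embeddings must be 128-dimensional")
        diff = F.absolute(F.add(F.sigmoid(z1), F.mul(F.sigmoid(z2), -1.0)))
        return self.head_fc(diff)

    def score(self, z1: Tensor, z2: Tensor) -> Tensor:
        """Similarity score in [0,1] for embedding pairs."""
        return F.sigmoid(self.score_logit(z1, z2))

    def forward(self, x1: Tensor, x2: Tensor) -> Tensor:
        return self.score(self.embed(x1), self.embed(x2))


class RetrievalNet(nn.Module):
    """Twin-branch embedder producing 128-d identity representations."""

    POOL_SIDE = 5
    REDUCED_MAPS = 100
    HIDDEN = 512

    def __init__(self, backbone: nn.Module | None = None, seed: int = 0,
                 l2_normalize: bool = False):
        rng = np.random.default_rng(seed)
        self.backbone = backbone if backbone is not None else TinyBackbone(rng=rng)
        self.l2_normalize = l2_normalize
        c2 = 2 * self.backbone.feature_channels
        self.reduce = nn.Conv2d(c2, self.REDUCED_MAPS, 1, rng=rng)
        flat = self.REDUCED_MAPS * self.POOL_SIDE * self.POOL_SIDE
        self.fc1 = nn.Linear(flat, self.HIDDEN, rng=rng)
        self.fc2 = nn.Linear(self.HIDDEN, EMBEDDING_DIM, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (B,3,H,W), got {x.shape}")
        if x.shape[2] < self.backbone.min_side or x.shape[3] < self.backbone.min_side:
            raise ValueError(f"input {x.shape[2]}x{x.shape[3]} below backbone stride")
        feats = self.backbone(x)
        avg = F.adaptive_avg_pool2d(feats, self.POOL_SIDE)
        mx = F.adaptive_max_pool2d(feats, self.POOL_SIDE)
        pooled = F.concat([avg, mx], axis=1)             # (B, 2C, 5, 5)
        red = F.relu(self.reduce(pooled))                # (B, 100, 5, 5)
        h = F.relu(self.fc1(F.reshape(red, (x.shape[0], -1))))
        z = self.fc2(h)
        if self.l2_normalize:
            n2 = F.tensor_sum(F.mul(z, z), axis=-1, keepdims=True)
            z = F.mul(z, F.power(F.maximum_const(n2, 1e-12), -0.5))
        return z

    embed = forward

    def head_parameters(self):
        for m in (self.reduce, self.fc1, self.fc2):
            yield from m.parameters()


SCHEMA_VERSION = 1


def save_checkpoint(model: nn.Module, path: str | pathlib.Path, meta: dict | None = None
                    ) -> None:
    path = pathlib.Path(path)
    state = model.state_dict()
    np.savez(path.with_suffix(".npz"), **state)
    info = {"schema_version": SCHEMA_VERSION, "class": type(model).__name__,
            "parameters": sorted(state)}
    info.update(meta or {})
    path.with_suffix(".json").write_text(json.dumps(info, indent=2))


def load_checkpoint(model: nn.Module, path: str | pathlib.Path) -> dict:
    path = pathlib.Path(path)
    info = json.loads(path.with_suffix(".json").read_text())
    if info.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported checkpoint schema {info.get('schema_version')}")
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return info
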