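"""Gradient-weighted class-activation maps for the siamese verifier.

For a chosen convolutional layer, the gradient of the pre-sigmoid pair
score with respect to that layer's activations is averaged per channel into
weights; the weighted activation sum, rectified, gives one spatial attention
map per branch. Because the branches share weights, swapping the inputs
swaps the two maps.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .nn import Tensor
from .nn import tensor as F
from .models import VerificationNet


@dataclasses.dataclass
class AttentionMap:
    values: np.ndarray
    layer_name: str
    branch: str                     # "first" | "second"

    def __post_init__(self):
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("attention maps must be non-negative and finite")

    def upsampled(self, side: int) -> np.ndarray:
        """Bilinear upsample for overlay rendering."""
        from PIL import Image
        im = Image.fromarray(self.values.astype(np.float32), mode="F")
        return np.asarray(im.resize((side, side), Image.BILINEAR))


def _backbone_activations(model: VerificationNet, x: Tensor
                          ) -> tuple[Tensor, dict[str, Tensor]]:
    """Run the backbone recording the post-ReLU output of each conv block."""
    acts: dict[str, Tensor] = {}
    h = x
    conv_i = 0
    for m in model.backbone.blocks.modules:
        h = m(h)
        if isinstance(m, nn.ReLU):
            conv_i += 1
            acts[f"conv{conv_i}"] = h
    return h, acts


def grad_cam_pair(model: VerificationNet, x1: np.ndarray, x2: np.ndarray,
                  layer_name: str) -> tuple[AttentionMap, AttentionMap]:
    """Attention maps of the verification score for both branch inputs.

    ``x1``/``x2`` are prepared single inputs of shape (3, S, S). The target
    scalar is the pre-sigmoid logit of the pair score.
    """
    maps = []
    captured = []
    zs = []
    for x in (x1, x2):
        xt = Tensor(np.asarray(x)[None, ...])
        feats, acts = _backbone_activations(model, xt)
        if layer_name not in acts:
            raise ValueError(f"unknown layer {layer_name!r}; "
                             f"available: {sorted(acts)}")
        captured.append(acts[layer_name])
        zs.append(model.embed_fc(F.reshape(feats, (1, -1))))
    logit = model.score_logit(zs[0], zs[1])
    logit.backward()
    for act, branch in zip(captured, ("first", "second")):
        a = act.numpy()[0]                       # (C, H, W)
        g = act.grad[0]
        weights = g.mean(axis=(1, 2))            # channel-wise average
        cam = np.maximum((weights[:, None, None] * a).sum(axis=0), 0.0)
        maps.append(AttentionMap(cam, layer_name, branch))
    return maps[0], maps[1]


def overlay_png(image: np.ndarray, amap: AttentionMap, path, alpha: float = 0.4,
                cmap: str = "jet") -> None:
    """Write a heatmap overlay PNG (presentation only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    side = image.shape[0]
    up = amap.upsampled(side)
    rng = up.max() - up.min()
    up = (up - up.min()) / rng if rng > 0 else up * 0.0
    fig, ax = plt.subplots(figsize=(3, 3), dpi=100)
    ax.imshow(image, cmap="gray")
    ax.imshow(up, cmap=cmap, alpha=alpha)
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight", pad_inches=0)
    plt.close(fig)
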