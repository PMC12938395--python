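"""Modality encoders.

Imaging: a small 3D residual convolutional network ending in global average
pooling (GAP) over spatial dimensions, plus a feature-bypass path for
precomputed imaging feature vectors. Pathology: a padding-aware transformer
aggregator that compresses a variable-length N x C patch-feature set into a
single C-dim slide feature through a learnable CLS token; a key padding
mask guarantees padded rows have zero influence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat, relu
from ._nn import Linear, Module, TransformerEncoderLayer, conv3d
from .containers import PatchFeatureSet

__all__ = [
    "AggregatorConfig", "PatchAggregator", "ImagingEncoder3D",
    "encode_imaging", "aggregate_patches", "global_average_pool", "pad_patch_sets",
]


@dataclass
class AggregatorConfig:
    """Transformer aggregator hyperparameters.

    feature_dim is the patch-feature dimension C (64 desk-scale default;
    set 1536 to mirror foundation-model patch features).
    """

    feature_dim: int = 64
    num_heads: int = 4
    depth: int = 2
    mlp_ratio: float = 4.0
    dropout: float = 0.1

    def __post_init__(self):
        if self.feature_dim % self.num_heads != 0:
            raise ValueError("feature_dim must be divisible by num_heads")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


class PatchAggregator(Module):
    """CLS-token transformer over a masked patch sequence.

    The learnable CLS token is prepended to the (padded) patch sequence;
    the transformed CLS position is the slide feature.
    """

    def __init__(self, config: AggregatorConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.cls = self.add_param("cls", rng.normal(0.0, 0.02, size=(1, 1, config.feature_dim)))
        self.layers = [
            self.add_module(f"layer{i}", TransformerEncoderLayer(
                config.feature_dim, config.num_heads, config.mlp_ratio,
                config.dropout, rng))
            for i in range(config.depth)
        ]

    def __call__(self, features: np.ndarray | Tensor, mask: np.ndarray) -> Tensor:
        """features: (B, N, C); mask: (B, N) bool, True = valid patch."""
        x = features if isinstance(features, Tensor) else Tensor(features)
        B, N, C = x.shape
        if C != self.config.feature_dim:
            raise ValueError(f"feature dim {C} != configured {self.config.feature_dim}")
        if not mask.any(axis=1).all():
            raise ValueError("every patch set must have at least one valid patch")
        cls_tok = self.cls * Tensor(np.ones((B, 1, C)))  # broadcast CLS to the batch
        x = concat([cls_tok, x], axis=1)
        full_mask = np.concatenate(
            [np.ones((B, 1), dtype=bool), mask.astype(bool)], axis=1)
        for layer in self.layers:
            x = layer(x, full_mask)
        return x[:, 0, :]


def pad_patch_sets(patch_sets: list[PatchFeatureSet]) -> tuple[np.ndarray, np.ndarray]:
    """Stack variable-length patch sets into (B, N_max, C) plus a validity mask."""
    if not patch_sets:
        raise ValueError("no patch sets given")
    dims = {ps.feature_dim for ps in patch_sets}
    if len(dims) != 1:
        raise ValueError(f"inconsistent patch feature dims: {sorted(dims)}")
    C = dims.pop()
    n_max = max(ps.features.shape[0] for ps in patch_sets)
    feats = np.zeros((len(patch_sets), n_max, C))
    mask = np.zeros((len(patch_sets), n_max), dtype=bool)
    for i, ps in enumerate(patch_sets):
        n = ps.features.shape[0]
        feats[i, :n] = ps.features
        mask[i, :n] = ps.mask
    return feats, mask


def aggregate_patches(patch_set: PatchFeatureSet, aggregator: PatchAggregator) -> np.ndarray:
    """Slide feature for one patch set (evaluation mode)."""
    aggregator.eval()
    feats, mask = pad_patch_sets([patch_set])
    return aggregator(feats, mask).data[0]


def global_average_pool(feature_map: np.ndarray | Tensor) -> Tensor:
    """GAP over spatial dims of a (B, C, D, H, W) feature map -> (B, C)."""
    x = feature_map if isinstance(feature_map, Tensor) else Tensor(feature_map)
    return x.reshape(x.shape[0], x.shape[1], -1).mean(axis=2)


class _ResBlock3D(Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        k = 3
        scale = 1.0 / np.sqrt(channels * k ** 3)
        self.w1 = self.add_param("w1", rng.uniform(-scale, scale, (channels, channels, k, k, k)))
        self.b1 = self.add_param("bias1", np.zeros(channels))
        self.w2 = self.add_param("w2", rng.uniform(-scale, scale, (channels, channels, k, k, k)))
        self.b2 = self.add_param("bias2", np.zeros(channels))

    def __call__(self, x: Tensor) -> Tensor:
        y = relu(conv3d(x, self.w1, self.b1, stride=1, padding=1))
        y = conv3d(y, self.w2, self.b2, stride=1, padding=1)
        return relu(x + y)


class ImagingEncoder3D(Module):
    """Small residual 3D CNN over 4-channel volumes, GAP, linear projection.

    Two downsampling stages with one residual block each (well under 200k
    parameters at the default widths); the output feature length defaults
    to 512. Larger stage widths/depths are configuration options.
    """

    def __init__(self, out_dim: int = 512, widths: tuple[int, int] = (16, 32),
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        w1, w2 = widths
        k = 3
        s0 = 1.0 / np.sqrt(4 * k ** 3)
        self.stem_w = self.add_param("stem_w", rng.uniform(-s0, s0, (w1, 4, k, k, k)))
        self.stem_b = self.add_param("stem_bias", np.zeros(w1))
        self.block1 = self.add_module("block1", _ResBlock3D(w1, rng))
        s1 = 1.0 / np.sqrt(w1 * k ** 3)
        self.down_w = self.add_param("down_w", rng.uniform(-s1, s1, (w2, w1, k, k, k)))
        self.down_b = self.add_param("down_bias", np.zeros(w2))
        self.block2 = self.add_module("block2", _ResBlock3D(w2, rng))
        self.head = self.add_module("head", Linear(w2, out_dim, rng))
        self.out_dim = out_dim

    def feature_map(self, volumes: np.ndarray | Tensor) -> Tensor:
        x = volumes if isinstance(volumes, Tensor) else Tensor(volumes)
        if x.ndim != 5 or x.shape[1] != 4:
            raise ValueError("expected volumes of shape (B, 4, D, H, W)")
        x = relu(conv3d(x, self.stem_w, self.stem_b, stride=2, padding=1))
        x = self.block1(x)
        x = relu(conv3d(x, self.down_w, self.down_b, stride=2, padding=1))
        return self.block2(x)

    def __call__(self, volumes: np.ndarray | Tensor) -> Tensor:
        return self.head(global_average_pool(self.feature_map(volumes)))


def encode_imaging(imaging: np.ndarray, encoder: ImagingEncoder3D | None = None) -> np.ndarray:
    """Imaging feature for one sample.

    A 1-d input is a precomputed feature vector and is returned unchanged
    (bypass mode); a 4-channel volume is run through the encoder in
    evaluation mode.
    """
    imaging = np.asarray(imaging, dtype=np.float64)
    if imaging.ndim == 1:
        return imaging
    if imaging.ndim != 4 or imaging.shape[0] != 4:
        raise ValueError("imaging must be a 1-d feature vector or a (4, D, H, W) volume")
    if encoder is None:
        raise ValueError("a volume input requires an encoder")
    encoder.eval()
    return encoder(imaging[None]).data[0]
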