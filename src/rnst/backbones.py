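"""Frozen convolutional feature extractors for style/content losses.

A style-transfer engine needs a fixed (never trained here) convolutional
network whose intermediate activations serve two roles: *content* features,
compared directly between images, and *style* features, compared through
their Gram matrices. Four backbones are named:

``vgg16``, ``resnet50``, ``resnet152``
    ImageNet-pretrained networks. Their tap layout (which layers feed the
    style and content losses) is declared here, but extracting features
    requires pretrained weights via the optional ``torch``/``torchvision``
    dependency; without it these backbones raise :class:`DependencyError`
    and the self-contained ``tiny-random`` backbone should be used instead.

``tiny-random``
    A small 4-layer convolutional stack (3x3 kernels, stride 1, valid
    padding, ReLU) whose weights are drawn deterministically from a seed.
    It ships with an analytic backward pass with respect to the *input
    image* (weights stay frozen), so the style-transfer optimization can
    run fully offline with no deep-learning framework.

Feature matrices follow the standard style-transfer convention: layer ``l``
with ``N_l`` feature maps over ``M_l`` spatial positions is flattened to an
``N_l x M_l`` matrix ``F^l``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._exceptions import ConfigurationError, DependencyError, ShapeError
from ._validate import as_image

__all__ = [
    "FeatureBackbone",
    "FeatureMapSet",
    "build_backbone",
    "extract_features",
]

# Tap layouts for the pretrained engines. VGG16: style from the first eight
# convolutional layers (rectifier outputs), content from the fourth
# convolutional layer. ResNets: style from the initial 7x7 convolution and
# residual stages 1-3; content from the 7x7 convolution and stages 1 and 3.
_PRETRAINED = {
    "vgg16": {
        "style": (
            "conv1_1", "conv1_2", "conv2_1", "conv2_2",
            "conv3_1", "conv3_2", "conv3_3", "conv4_1",
        ),
        "content": ("conv2_2",),
        "min_size": 32,
    },
    "resnet50": {
        "style": ("conv1", "layer1", "layer2", "layer3"),
        "content": ("conv1", "layer1", "layer3"),
        "min_size": 32,
    },
    "resnet152": {
        "style": ("conv1", "layer1", "layer2", "layer3"),
        "content": ("conv1", "layer1", "layer3"),
        "min_size": 32,
    },
}

_TINY_CHANNELS = (8, 8, 16, 16)
_TINY_LAYERS = ("conv1", "conv2", "conv3", "conv4")
_TINY_MIN_SIZE = 16  # four valid 3x3 convolutions need >= 9 px per side


@dataclass
class FeatureMapSet:
    """Per-layer flattened feature matrices ``F^l`` (shape ``N_l x M_l``).

    ``shapes`` records the unflattened ``(channels, height, width)`` of each
    tapped activation so spatial sizes (``M_l``) stay recoverable.
    """

    layers: Dict[str, np.ndarray]
    shapes: Dict[str, Tuple[int, int, int]]

    def __getitem__(self, key: str) -> np.ndarray:
        return self.layers[key]

    def keys(self):
        return self.layers.keys()

    def dims(self, key: str) -> Tuple[int, int]:
        """Return ``(N_l, M_l)`` for layer ``key``."""
        n, m = self.layers[key].shape
        return n, m


class _TinyConvNet:
    """Seeded 4-layer conv stack with analytic input gradients.

    Convolutions are 3x3, stride 1, *valid* (no padding) — a constant input
    therefore yields a constant activation in every layer, and shifting the
    input by one pixel shifts every activation by one pixel. He-scaled
    normal weights and small normal biases are drawn once from the seed and
    never updated.
    """

    def __init__(self, seed: int):
        rng = np.random.default_rng(seed)
        self.weights = []
        self.biases = []
        c_in = 1
        for c_out in _TINY_CHANNELS:
            std = np.sqrt(2.0 / (c_in * 9))
            self.weights.append(rng.normal(0.0, std, size=(c_out, c_in, 3, 3)))
            self.biases.append(rng.normal(0.0, 0.1, size=c_out))
            c_in = c_out

    @staticmethod
    def _conv(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
        # x: (C_in, H, W) -> (C_out, H-2, W-2); cross-correlation, valid.
        patches = sliding_window_view(x, (3, 3), axis=(1, 2))
        out = np.einsum("oikl,ihwkl->ohw", w, patches, optimize=True)
        return out + b[:, None, None]

    @staticmethod
    def _conv_input_grad(g: np.ndarray, w: np.ndarray) -> np.ndarray:
        # Vector-Jacobian product of _conv with respect to its input:
        # full convolution of the upstream gradient with flipped kernels.
        gpad = np.pad(g, ((0, 0), (2, 2), (2, 2)))
        patches = sliding_window_view(gpad, (3, 3), axis=(1, 2))
        wf = w[:, :, ::-1, ::-1]
        return np.einsum("oikl,ohwkl->ihw", wf, patches, optimize=True)

    def forward(self, image: np.ndarray):
        """Return (activations by layer name, cache for backward)."""
        x = image[None, :, :]
        acts: Dict[str, np.ndarray] = {}
        cache = []
        for name, w, b in zip(_TINY_LAYERS, self.weights, self.biases):
            pre = self._conv(x, w, b)
            x = np.maximum(pre, 0.0)
            cache.append(pre)
            acts[name] = x
        return acts, cache

    def input_grad(self, cache, tap_grads: Dict[str, np.ndarray]) -> np.ndarray:
        """Backpropagate gradients injected at tapped activations to the image."""
        g = None
        for idx in range(len(_TINY_LAYERS) - 1, -1, -1):
            name = _TINY_LAYERS[idx]
            pre = cache[idx]
            g_act = tap_grads.get(name)
            if g is None:
                g = np.zeros_like(pre) if g_act is None else g_act.copy()
            elif g_act is not None:
                g = g + g_act
            g = g * (pre > 0.0)
            g = self._conv_input_grad(g, self.weights[idx])
        return g[0]

    def param_checksum(self) -> str:
        h = hashlib.md5()
        for w, b in zip(self.weights, self.biases):
            h.update(np.ascontiguousarray(w).tobytes())
            h.update(np.ascontiguousarray(b).tobytes())
        return h.hexdigest()


@dataclass
class FeatureBackbone:
    """A frozen feature extractor with declared style/content tap layers."""

    name: str
    style_taps: Tuple[str, ...]
    content_taps: Tuple[str, ...]
    min_size: int
    frozen: bool = True
    seed: Optional[int] = None
    _net: Optional[_TinyConvNet] = field(default=None, repr=False, compare=False)

    @property
    def is_pretrained(self) -> bool:
        return self.name != "tiny-random"

    def taps(self, which: str) -> Tuple[str, ...]:
        if which == "style":
            return self.style_taps
        if which == "content":
            return self.content_taps
        raise ConfigurationError(f"which must be 'style' or 'content', got {which!r}")

    def param_checksum(self) -> str:
        """Checksum of all backbone parameters (frozen-weights invariant)."""
        self._require_net()
        return self._net.param_checksum()

    def _require_net(self) -> _TinyConvNet:
        if self._net is None:
            raise DependencyError(
                f"backbone {self.name!r} needs ImageNet-pretrained weights, which "
                "require the optional torch/torchvision dependency and a weights "
                "download; neither is available offline. Use the self-contained "
                "'tiny-random' backbone instead, e.g. "
                "build_backbone('tiny-random', seed=0)."
            )
        return self._net

    def forward_with_cache(self, image: np.ndarray):
        """Activations at all layers plus the cache needed for input gradients."""
        self._check_size(image)
        return self._require_net().forward(image)

    def input_grad(self, cache, tap_grads: Dict[str, np.ndarray]) -> np.ndarray:
        return self._require_net().input_grad(cache, tap_grads)

    def _check_size(self, image: np.ndarray) -> None:
        if min(image.shape) < self.min_size:
            raise ShapeError(
                f"image of shape {image.shape} is smaller than backbone "
                f"{self.name!r}'s minimum size {self.min_size}; inputs are "
                "rejected rather than padded"
            )


def build_backbone(
    name: str,
    seed: Optional[int] = None,
    style_taps: Optional[Sequence[str]] = None,
    content_taps: Optional[Sequence[str]] = None,
) -> FeatureBackbone:
    """Construct a frozen feature backbone by name.

    Parameters
    ----------
    name:
        One of ``vgg16``, ``resnet50``, ``resnet152``, ``tiny-random``.
    seed:
        Required for (and only for) ``tiny-random``; fixes its weights.
    style_taps, content_taps:
        Optional overrides for the default tap layers.
    """
    if name == "tiny-random":
        if seed is None:
            raise ConfigurationError("tiny-random backbone requires a seed")
        style = tuple(style_taps) if style_taps else _TINY_LAYERS
        content = tuple(content_taps) if content_taps else ("conv2",)
        for tap in (*style, *content):
            if tap not in _TINY_LAYERS:
                raise ConfigurationError(
                    f"unknown tiny-random layer {tap!r}; available: {_TINY_LAYERS}"
                )
        if not style or not content:
            raise ConfigurationError("style and content tap lists must be non-empty")
        return FeatureBackbone(
            name=name,
            style_taps=style,
            content_taps=content,
            min_size=_TINY_MIN_SIZE,
            seed=int(seed),
            _net=_TinyConvNet(int(seed)),
        )
    if name in _PRETRAINED:
        if seed is not None:
            raise ConfigurationError(f"seed applies only to tiny-random, not {name!r}")
        spec = _PRETRAINED[name]
        style = tuple(style_taps) if style_taps else spec["style"]
        content = tuple(content_taps) if content_taps else spec["content"]
        if not style or not content:
            raise ConfigurationError("style and content tap lists must be non-empty")
        return FeatureBackbone(
            name=name,
            style_taps=style,
            content_taps=content,
            min_size=spec["min_size"],
        )
    raise ConfigurationError(
        f"unknown backbone {name!r}; supported: "
        f"{sorted([*_PRETRAINED, 'tiny-random'])}"
    )


def extract_features(image, backbone: FeatureBackbone, which: str) -> FeatureMapSet:
    """Extract the flattened feature matrices ``F^l`` at the requested taps.

    ``which`` selects the ``style`` or ``content`` tap set. Extraction is
    deterministic: identical (image, backbone) pairs yield bit-identical
    features.
    """
    img = as_image(image)
    taps = backbone.taps(which)
    acts, _ = backbone.forward_with_cache(img)
    layers: Dict[str, np.ndarray] = {}
    shapes: Dict[str, Tuple[int, int, int]] = {}
    for tap in taps:
        a = acts[tap]
        layers[tap] = a.reshape(a.shape[0], -1).copy()
        shapes[tap] = a.shape
    return FeatureMapSet(layers=layers, shapes=shapes)
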