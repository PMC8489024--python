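"""The mini-UNet pupil segmenter.

A constant-width encoder–decoder ("hourglass") network: every hidden
convolution has 16 kernels of 3×3 with ReLU and same-shape padding.  The
encoder halves the spatial resolution with 2×2 max pooling at each level;
the decoder upsamples ×2 (nearest neighbor) and fuses each feature map
with the same-resolution encoder map by channel concatenation followed by
convolution.  A 1×1 convolution maps the final features to a per-pixel
pupil logit; a separate branch applies global average pooling to the
bottleneck feature map and a two-output fully connected layer for the
eye-present and blink logits.  Sigmoid turns all three into probabilities.

With the default configuration (128×128 single-channel input, width 16,
depth 3, two convolutions per level) the network has 25,699 trainable
parameters — 0.03 M after rounding, which ``build_segmenter`` asserts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._layers import Conv2d, GlobalAvgPool, Linear, MaxPool2, ReLU, UpsampleNearest2, sigmoid


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SegmenterConfig:
    """Architecture hyperparameters of the mini-UNet.

    ``depth`` counts resolution levels (3 → feature maps at 1×, 1/2×, 1/4×
    of the input); ``input_size`` must be divisible by 2**(depth-1).
    ``expected_param_millions``, when set, makes ``build_segmenter`` assert
    that the trainable-parameter count rounds to it (the default config's
    printed budget is 0.03 M); pass None for experimental configs.
    """

    input_size: int = 128
    channels_in: int = 1
    width: int = 16
    kernel_size: int = 3
    depth: int = 3
    convs_per_level: int = 2
    expected_param_millions: float | None = 0.03
    #: initial bias of the pixel head: the logit of the expected pupil-pixel
    #: prior (~5%), which skips the all-background phase early in training
    head_prior_logit: float = -3.0

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ConfigurationError("width must be >= 1")
        if self.depth < 2:
            raise ConfigurationError("depth must be >= 2")
        if self.input_size % (2 ** (self.depth - 1)) != 0:
            raise ConfigurationError(
                f"input_size {self.input_size} not divisible by 2^{self.depth - 1}"
            )


@dataclass
class Prediction:
    """The network's output for one frame: all values are probabilities."""

    pupil_map: np.ndarray  # (S, S) in [0, 1]
    eye_prob: float
    blink_prob: float


class Segmenter:
    """Mini-UNet with explicit forward/backward passes (NumPy).

    ``forward`` caches activations for ``backward``; inference paths
    (:meth:`predict`, :meth:`predict_batch`) are deterministic.
    """

    def __init__(self, config: SegmenterConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        w, k, cpl = config.width, config.kernel_size, config.convs_per_level

        def conv_block(c_in: int, n_convs: int):
            layers = []
            for i in range(n_convs):
                layers.append(Conv2d(c_in if i == 0 else w, w, k, rng, dtype))
                layers.append(ReLU())
            return layers

        # encoder levels 0..depth-2, then bottleneck
        self.enc_blocks = [conv_block(config.channels_in, cpl)]
        for _ in range(config.depth - 2):
            self.enc_blocks.append(conv_block(w, cpl))
        self.pools = [MaxPool2() for _ in range(config.depth - 1)]
        self.bottleneck = conv_block(w, cpl)
        # decoder: one fusion conv (2w -> w) then cpl-1 refinement convs per level
        self.ups = [UpsampleNearest2() for _ in range(config.depth - 1)]
        self.dec_blocks = []
        for _ in range(config.depth - 1):
            layers = [Conv2d(2 * w, w, k, rng, dtype), ReLU()]
            for _ in range(cpl - 1):
                layers.append(Conv2d(w, w, k, rng, dtype))
                layers.append(ReLU())
            self.dec_blocks.append(layers)
        self.head = Conv2d(w, 1, 1, rng, dtype)
        self.head.b[:] = config.head_prior_logit
        self.gap = GlobalAvgPool()
        self.fc = Linear(w, 2, rng, dtype)
        self._skip_channels = w

    # -- parameter plumbing -------------------------------------------------
    def _layers(self):
        for block in self.enc_blocks:
            yield from block
        yield from self.pools
        yield from self.bottleneck
        yield from self.ups
        for block in self.dec_blocks:
            yield from block
        yield self.head
        yield self.gap
        yield self.fc

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._layers() for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self._layers() for g in layer.grads]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state, strict=True):
            p[...] = s

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Compute logits for a batch.

        Returns ``(map_logits (N,1,S,S), cls_logits (N,2))`` where the
        class columns are (eye, blink).
        """
        x = np.ascontiguousarray(x, dtype=self.dtype)
        if x.ndim != 4 or x.shape[1] != self.config.channels_in:
            raise ValueError(f"expected (N, {self.config.channels_in}, S, S) input")
        if x.shape[2] != self.config.input_size or x.shape[3] != self.config.input_size:
            raise ValueError(
                f"expected spatial size {self.config.input_size}, got {x.shape[2:]}"
            )
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            for layer in block:
                x = layer.forward(x)
            skips.append(x)
            x = pool.forward(x)
        for layer in self.bottleneck:
            x = layer.forward(x)
        bottom = x
        for up, block, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            x = up.forward(x)
            x = np.concatenate([x, skip], axis=1)
            for layer in block:
                x = layer.forward(x)
        map_logits = self.head.forward(x)
        cls_logits = self.fc.forward(self.gap.forward(bottom))
        return map_logits, cls_logits

    def backward(self, d_map: np.ndarray, d_cls: np.ndarray) -> None:
        """Backpropagate loss gradients w.r.t. the two logit outputs."""
        d_bottom_cls = self.gap.backward(self.fc.backward(d_cls.astype(self.dtype)))
        dx = self.head.backward(d_map.astype(self.dtype))
        w = self._skip_channels
        d_skips = []
        for up, block in zip(reversed(self.ups), reversed(self.dec_blocks)):
            for layer in reversed(block):
                dx = layer.backward(dx)
            d_skips.append(dx[:, w:])
            dx = up.backward(dx[:, :w])
        dx = dx + d_bottom_cls
        for layer in reversed(self.bottleneck):
            dx = layer.backward(dx)
        # d_skips was collected decoder-last-first, i.e. shallowest level first
        for pool, block, d_skip in zip(
            reversed(self.pools), reversed(self.enc_blocks), reversed(d_skips)
        ):
            dx = pool.backward(dx) + d_skip
            for layer in reversed(block):
                dx = layer.backward(dx)

    # -- inference ----------------------------------------------------------
    def predict_batch(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sigmoid probabilities for a stack of (N, S, S) images."""
        images = np.asarray(images)
        if images.ndim != 3:
            raise ValueError("expected (N, S, S) image stack")
        map_logits, cls_logits = self.forward(images[:, None, :, :])
        probs = sigmoid(cls_logits)
        return sigmoid(map_logits[:, 0]), probs[:, 0], probs[:, 1]

    def predict(self, image: np.ndarray) -> Prediction:
        maps, eye, blink = self.predict_batch(np.asarray(image)[None])
        return Prediction(pupil_map=maps[0], eye_prob=float(eye[0]), blink_prob=float(blink[0]))

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        """Save weights plus architecture to an .npz checkpoint."""
        cfg = self.config
        arrays = {f"param_{i:03d}": p for i, p in enumerate(self.parameters())}
        np.savez(
            path,
            config=np.array(
                [cfg.input_size, cfg.channels_in, cfg.width, cfg.kernel_size,
                 cfg.depth, cfg.convs_per_level]
            ),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "Segmenter":
        with np.load(path) as data:
            c = data["config"]
            config = SegmenterConfig(
                input_size=int(c[0]), channels_in=int(c[1]), width=int(c[2]),
                kernel_size=int(c[3]), depth=int(c[4]), convs_per_level=int(c[5]),
                expected_param_millions=None,
            )
            net = cls(config)
            net.set_state([data[f"param_{i:03d}"] for i in range(len(net.parameters()))])
        return net


def count_parameters(model: Segmenter) -> int:
    """Total trainable scalar parameters (weights and biases)."""
    return int(sum(p.size for p in model.parameters()))


def build_segmenter(config: SegmenterConfig | None = None, seed: int = 0,
                    dtype=np.float32) -> Segmenter:
    """Build a mini-UNet; assert the printed parameter budget when declared.

    For the default config this checks that the count, divided by 1e6 and
    rounded to two decimals, equals 0.03.
    """
    config = config or SegmenterConfig()
    net = Segmenter(config, seed=seed, dtype=dtype)
    if config.expected_param_millions is not None:
        millions = round(count_parameters(net) / 1e6, 2)
        if millions != config.expected_param_millions:
            raise ConfigurationError(
                f"parameter count {count_parameters(net)} rounds to {millions} M, "
                f"expected {config.expected_param_millions} M"
            )
    return net


def predict_frame(model: Segmenter, image: np.ndarray) -> Prediction:
    """Predict pupil map and eye/blink probabilities for one [0,1] image."""
    image = np.asarray(image, dtype=float)
    s = model.config.input_size
    if image.shape != (s, s):
        raise ValueError(f"expected ({s}, {s}) image, got {image.shape}")
    return model.predict(image)
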