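"""Attention-augmented residual classification network.

Architecture (channel plan follows the reference design): a 3x3 conv stem,
three residual stages at strides (1, 2, 2) — so the final feature map sits
at 1/4 of the input resolution — a single-head self-attention layer over the
final-stage spatial tokens (residually added), an optional multiplicative
gating of the final map by an externally supplied weight map (the RL
action), global average pooling, and a linear head to two logits.

With the default 9 two-conv blocks per stage the network is the depth-56
configuration (stem + 54 convs + head); desk-scale experiments shrink
``blocks_per_stage`` and the channel plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from skimage.transform import resize

from . import nn
from .nn.layers import Module, Parameter, Conv2d, BatchNorm2d, Linear, ReLU


@dataclass(frozen=True)
class BackboneConfig:
    stem_channels: int = 16
    stage_channels: tuple[int, int, int] = (64, 128, 256)
    blocks_per_stage: int = 9
    n_classes: int = 2
    attention_enabled: bool = True
    input_size: int = 128
    in_channels: int = 1

    def __post_init__(self):
        if self.stem_channels <= 0 or any(c <= 0 for c in self.stage_channels):
            raise ValueError("channel counts must be positive")
        if self.input_size % 4 != 0:
            raise ValueError("input_size must be divisible by 4 (two stride-2 stages)")

    @property
    def state_dim(self) -> int:
        """Length of the pooled state vector = final stage channels."""
        return self.stage_channels[-1]

    @property
    def feature_hw(self) -> int:
        return self.input_size // 4


@dataclass
class BackboneOutput:
    logits: np.ndarray        # (B, n_classes)
    feature_map: np.ndarray   # (B, C, h, w) final-stage (post-attention, pre-gating)
    pooled_state: np.ndarray  # (B, C) spatial mean of feature_map


class SelfAttention2d(Module):
    """Single-head scaled dot-product self-attention over spatial tokens.

    Tokens are the ``h*w`` positions of a ``(B, C, h, w)`` feature map; the
    learned maps ``WQ, WK, WV`` act on the channel dimension and the
    attended values are added residually: ``Y = X + A V``.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        scale = 1.0 / np.sqrt(channels)
        self.WQ = Parameter(rng.normal(0.0, scale, size=(channels, channels)))
        self.WK = Parameter(rng.normal(0.0, scale, size=(channels, channels)))
        self.WV = Parameter(rng.normal(0.0, scale, size=(channels, channels)))
        self.d_k = channels
        self._cache = None
        self.last_attention: np.ndarray | None = None

    def attend(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Token-level attention: X (B, N, C) -> (A, Y) with Y = X + A V."""
        Q = X @ self.WQ.data
        K = X @ self.WK.data
        V = X @ self.WV.data
        S = Q @ K.transpose(0, 2, 1) / np.sqrt(self.d_k)
        A = nn.softmax(S, axis=-1)
        Y = X + A @ V
        self._cache = (X, Q, K, V, A)
        return A, Y

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, h, w = x.shape
        X = x.reshape(B, C, h * w).transpose(0, 2, 1)
        A, Y = self.attend(X)
        self.last_attention = A
        self._shape = (B, C, h, w)
        return Y.transpose(0, 2, 1).reshape(B, C, h, w)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, h, w = self._shape
        dY = grad.reshape(B, C, h * w).transpose(0, 2, 1)
        X, Q, K, V, A = self._cache
        sqrt_dk = np.sqrt(self.d_k)

        dA = dY @ V.transpose(0, 2, 1)
        dV = A.transpose(0, 2, 1) @ dY
        # softmax backward, row-wise
        dS = A * (dA - np.sum(dA * A, axis=-1, keepdims=True))
        dQ = dS @ K / sqrt_dk
        dK = dS.transpose(0, 2, 1) @ Q / sqrt_dk

        self.WQ.grad += np.einsum("bnc,bnd->cd", X, dQ, optimize=True)
        self.WK.grad += np.einsum("bnc,bnd->cd", X, dK, optimize=True)
        self.WV.grad += np.einsum("bnc,bnd->cd", X, dV, optimize=True)
        dX = dY + dQ @ self.WQ.data.T + dK @ self.WK.data.T + dV @ self.WV.data.T
        return dX.transpose(0, 2, 1).reshape(B, C, h, w)


class ResidualBlock(Module):
    """Two 3x3 conv/BN pairs with an identity (or projected) shortcut."""

    def __init__(self, in_channels: int, out_channels: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(in_channels, out_channels, 3, rng, stride=stride)
        self.bn1 = BatchNorm2d(out_channels)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_channels, out_channels, 3, rng)
        self.bn2 = BatchNorm2d(out_channels)
        self.project = in_channels != out_channels or stride != 1
        if self.project:
            self.short_conv = Conv2d(in_channels, out_channels, 1, rng,
                                     stride=stride, padding=0)
            self.short_bn = BatchNorm2d(out_channels)

    def forward(self, x: np.ndarray) -> np.ndarray:
        main = self.bn2.forward(self.conv2.forward(
            self.relu1.forward(self.bn1.forward(self.conv1.forward(x)))))
        short = self.short_bn.forward(self.short_conv.forward(x)) if self.project else x
        self._pre = main + short
        self._out_mask = self._pre > 0
        return self._pre * self._out_mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = grad * self._out_mask
        dmain = self.bn2.backward(grad)
        dmain = self.conv2.backward(dmain)
        dmain = self.relu1.backward(dmain)
        dmain = self.bn1.backward(dmain)
        dx = self.conv1.backward(dmain)
        if self.project:
            dx = dx + self.short_conv.backward(self.short_bn.backward(grad))
        else:
            dx = dx + grad
        return dx


class Backbone(Module):
    """The full classifier; ``forward`` returns a :class:`BackboneOutput`."""

    def __init__(self, config: BackboneConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.stem_conv = Conv2d(c.in_channels, c.stem_channels, 3, rng)
        self.stem_bn = BatchNorm2d(c.stem_channels)
        self.stem_relu = ReLU()
        self.stages: list[Module] = []
        in_ch = c.stem_channels
        for stage_idx, out_ch in enumerate(c.stage_channels):
            stride = 1 if stage_idx == 0 else 2
            for block_idx in range(c.blocks_per_stage):
                self.stages.append(ResidualBlock(
                    in_ch, out_ch, stride if block_idx == 0 else 1, rng))
                in_ch = out_ch
        self.attention = SelfAttention2d(in_ch, rng) if c.attention_enabled else None
        self.pool = nn.GlobalAvgPool2d()
        self.head = Linear(in_ch, c.n_classes, rng)
        self._gate_cache = None

    # -- forward ----------------------------------------------------------
    def features(self, images: np.ndarray) -> np.ndarray:
        """Run stem + stages + attention; returns the final feature map."""
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.shape[2] != self.config.input_size or x.shape[3] != self.config.input_size:
            raise ValueError(
                f"expected {self.config.input_size}px inputs, got {x.shape[2:]}" )
        x = self.stem_relu.forward(self.stem_bn.forward(self.stem_conv.forward(x)))
        for block in self.stages:
            x = block.forward(x)
        if self.attention is not None:
            x = self.attention.forward(x)
        return x

    def head_forward(self, fmap: np.ndarray,
                     weights: np.ndarray | None = None) -> BackboneOutput:
        """Gate + pool + classify an already-computed feature map."""
        pooled_state = fmap.mean(axis=(2, 3))
        if weights is not None:
            w = np.asarray(weights, dtype=np.float64)
            gated = fmap * w
        else:
            w = None
            gated = fmap
        self._gate_cache = (w, fmap.shape)
        pooled = self.pool.forward(gated)
        logits = self.head.forward(pooled)
        return BackboneOutput(logits=logits, feature_map=fmap, pooled_state=pooled_state)

    def forward(self, images: np.ndarray,
                weights: np.ndarray | None = None) -> BackboneOutput:
        """Full forward pass; ``weights`` (broadcastable over the feature
        map) multiplicatively gates the final map before pooling.  Absent
        weights behave exactly like gating by ones."""
        return self.head_forward(self.features(images), weights)

    def backward(self, dlogits: np.ndarray) -> None:
        """Backprop from logits into all classifier parameters.

        No gradient flows to the gating weights (the agent is trained by its
        own surrogate objective, never through the classifier loss)."""
        grad = self.head.backward(dlogits)
        grad = self.pool.backward(grad)
        w, _ = self._gate_cache
        if w is not None:
            grad = grad * w
        if self.attention is not None:
            grad = self.attention.backward(grad)
        for block in reversed(self.stages):
            grad = block.backward(grad)
        grad = self.stem_relu.backward(grad)
        grad = self.stem_bn.backward(grad)
        self.stem_conv.backward(grad)


def cross_entropy_loss(logits: np.ndarray, true_class: np.ndarray,
                       return_grad: bool = False):
    """Mean softmax cross-entropy: -log softmax(logits)[true_class].

    Returns the scalar loss, or ``(loss, dlogits)`` when ``return_grad``.
    """
    logits = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    labels = np.atleast_1d(np.asarray(true_class, dtype=int))
    n, k = logits.shape
    if np.any(labels < 0) or np.any(labels >= k):
        raise ValueError("class index out of range")
    logp = logits - logsumexp(logits, axis=1, keepdims=True)
    loss = float(-logp[np.arange(n), labels].mean())
    if not return_grad:
        return loss
    probs = np.exp(logp)
    dlogits = probs
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return loss, dlogits


def class_activation_map(feature_map: np.ndarray, head_weights: np.ndarray,
                         target_class: int, output_size: int | None = None) -> np.ndarray:
    """Project head weights onto the feature map (CAM) and normalise.

    ``feature_map`` is (C, h, w); ``head_weights`` is the head's (C, n_classes)
    weight matrix or its (n_classes, C) transpose.  The weighted channel sum
    is bilinearly upsampled to ``output_size`` and min-max scaled to [0, 1].
    """
    fmap = np.asarray(feature_map, dtype=np.float64)
    W = np.asarray(head_weights, dtype=np.float64)
    C = fmap.shape[0]
    if W.shape[0] != C:          # accept (n_classes, C)
        W = W.T
    cam = np.tensordot(W[:, target_class], fmap, axes=(0, 0))
    if output_size is not None and cam.shape != (output_size, output_size):
        cam = resize(cam, (output_size, output_size), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    lo, hi = cam.min(), cam.max()
    if hi > lo:
        cam = (cam - lo) / (hi - lo)
    else:
        cam = np.zeros_like(cam)
    return cam
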