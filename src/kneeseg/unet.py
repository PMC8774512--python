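"""The modified U-net used for both slice detection and bone segmentation.

Architecture (depth ``d``, base width ``b``): a contraction path of
``d - 1`` levels, each two same-padded 3x3 convolutions + ReLU at width
``b * 2^level`` followed by 2x2 max pooling; a bottleneck of two 3x3
convolutions at ``b * 2^(d-1)``; an expansion path of ``d - 1`` levels,
each a 2x2 stride-2 transposed convolution halving the channel count,
concatenation with the encoder skip at the same resolution, and two 3x3
convolutions; and a final 1x1 convolution to the output channels with a
sigmoid.  Same padding keeps the output map the size of the input, so
the network emits one probability per input pixel.

Departures from the original U-net that this class encodes: same
padding everywhere (no border loss), sigmoid instead of softmax on the
head, and training with Adam against binary cross-entropy (detection)
or soft Dice (segmentation).  There is no batch norm and no dropout;
upsampling is a learned transposed convolution.  With one input channel,
one output channel, base width 64 and depth 5 this comes to 23
convolutional layers and 31,030,593 trainable parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn import Adam, Conv2d, ConvTranspose2x2, MaxPool2, ReLU

__all__ = ["ConfigurationError", "UNetSpec", "UNet", "build_unet", "count_parameters", "count_conv_layers"]


class ConfigurationError(ValueError):
    """An architecture or run configuration violates its invariants."""


@dataclass(frozen=True)
class UNetSpec:
    """Hyperparameters that fully determine the network and its parameter count."""

    in_channels: int = 1
    out_channels: int = 1
    base_width: int = 64
    depth: int = 5
    input_size: int = 352
    final_activation: str = "sigmoid"

    def validate(self) -> None:
        if self.base_width < 1:
            raise ConfigurationError(f"base_width must be >= 1, got {self.base_width}")
        if self.depth < 2:
            raise ConfigurationError(f"depth must be >= 2, got {self.depth}")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ConfigurationError("channel counts must be >= 1")
        factor = 2 ** (self.depth - 1)
        if self.input_size % factor != 0:
            raise ConfigurationError(
                f"input_size {self.input_size} not divisible by 2^(depth-1) = {factor}"
            )
        if self.final_activation != "sigmoid":
            raise ConfigurationError("only the sigmoid head is supported")


def _widths(spec: UNetSpec) -> list[int]:
    return [spec.base_width * 2**level for level in range(spec.depth)]


def count_parameters(spec: UNetSpec) -> int:
    """Closed-form trainable-parameter count.

    Per layer: 3x3 conv = 9*Cin*Cout + Cout; 2x2 transposed conv =
    4*Cin*Cout + Cout; 1x1 conv = Cin*Cout + Cout.  Must equal the
    instantiated model's enumeration (see :attr:`UNet.n_parameters`).
    """
    spec.validate()
    w = _widths(spec)
    total = 0
    cin = spec.in_channels
    for level in range(spec.depth):  # encoder levels + bottleneck
        total += 9 * cin * w[level] + w[level]
        total += 9 * w[level] * w[level] + w[level]
        cin = w[level]
    for level in range(spec.depth - 2, -1, -1):  # decoder
        total += 4 * w[level + 1] * w[level] + w[level]  # up-conv
        total += 9 * (2 * w[level]) * w[level] + w[level]  # conv on concat
        total += 9 * w[level] * w[level] + w[level]
    total += spec.base_width * spec.out_channels + spec.out_channels  # 1x1 head
    return total


def count_conv_layers(spec: UNetSpec) -> int:
    """Number of weight-bearing convolutional layers (3x3, transposed, final 1x1)."""
    spec.validate()
    d = spec.depth
    return 2 * (d - 1) + 2 + 3 * (d - 1) + 1


class UNet:
    """Instantiated modified U-net with explicit forward/backward passes.

    ``forward`` returns sigmoid probabilities; training code drives
    ``backward`` with the gradient of the loss w.r.t. the pre-sigmoid
    logits (numerically stabler than differentiating through the
    sigmoid separately).
    """

    def __init__(self, spec: UNetSpec, seed: int = 0, dtype=np.float32):
        spec.validate()
        self.spec = spec
        self.seed = int(seed)
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        w = _widths(spec)
        d = spec.depth

        self.enc: list[tuple[Conv2d, ReLU, Conv2d, ReLU]] = []
        cin = spec.in_channels
        for level in range(d - 1):
            self.enc.append(
                (Conv2d(cin, w[level], 3, rng, dtype), ReLU(), Conv2d(w[level], w[level], 3, rng, dtype), ReLU())
            )
            cin = w[level]
        self.pools = [MaxPool2() for _ in range(d - 1)]
        self.bott = (Conv2d(cin, w[d - 1], 3, rng, dtype), ReLU(), Conv2d(w[d - 1], w[d - 1], 3, rng, dtype), ReLU())
        self.ups: list[ConvTranspose2x2] = []
        self.dec: list[tuple[Conv2d, ReLU, Conv2d, ReLU]] = []
        for level in range(d - 2, -1, -1):
            self.ups.append(ConvTranspose2x2(w[level + 1], w[level], rng, dtype))
            self.dec.append(
                (Conv2d(2 * w[level], w[level], 3, rng, dtype), ReLU(), Conv2d(w[level], w[level], 3, rng, dtype), ReLU())
            )
        self.head = Conv2d(spec.base_width, spec.out_channels, 1, rng, dtype)

    # -- parameter bookkeeping -------------------------------------------------

    def _layers(self):
        for blk in self.enc:
            yield from blk
        yield from self.pools
        yield from self.bott
        for up, blk in zip(self.ups, self.dec):
            yield up
            yield from blk
        yield self.head

    def parameters(self):
        """(param, grad) array pairs, in a fixed order."""
        pairs = []
        for layer in self._layers():
            pairs.extend(zip(layer.params, layer.grads))
        return pairs

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.copy() for i, (p, _) in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        pairs = self.parameters()
        if len(state) != len(pairs):
            raise ValueError("state does not match this architecture")
        for i, (p, _) in enumerate(pairs):
            p[...] = state[f"p{i}"]

    def make_optimizer(self, lr: float, **kwargs) -> Adam:
        return Adam(self.parameters(), lr, **kwargs)

    # -- forward / backward ----------------------------------------------------

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != self.spec.in_channels:
            raise ValueError(f"expected NCHW input with {self.spec.in_channels} channel(s), got {x.shape}")
        if x.shape[2] != self.spec.input_size or x.shape[3] != self.spec.input_size:
            raise ValueError(
                f"expected {self.spec.input_size}x{self.spec.input_size} input, got {x.shape[2]}x{x.shape[3]}"
            )

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._check_input(x)
        x = np.ascontiguousarray(x, dtype=self.dtype)
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            c1, r1, c2, r2 = blk
            x = r2.forward(c2.forward(r1.forward(c1.forward(x, train), train), train), train)
            skips.append(x)
            x = pool.forward(x, train)
        c1, r1, c2, r2 = self.bott
        x = r2.forward(c2.forward(r1.forward(c1.forward(x, train), train), train), train)
        self._skip_channels = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            # skip features first, upsampled features second
            x = np.concatenate([skip, x], axis=1)
            self._skip_channels.append(skip.shape[1])
            c1, r1, c2, r2 = blk
            x = r2.forward(c2.forward(r1.forward(c1.forward(x, train), train), train), train)
        return self.head.forward(x, train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Sigmoid probability map, same spatial size as the input."""
        z = self.forward_logits(x, train)
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-z))

    # alias used by the pipeline's model protocol
    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False)

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate from d(loss)/d(logits); fills every layer's grads."""
        dy = self.head.backward(np.ascontiguousarray(dlogits, dtype=self.dtype))
        dskips = []
        for up, blk, cskip in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._skip_channels)
        ):
            c1, r1, c2, r2 = blk
            dy = c1.backward(r1.backward(c2.backward(r2.backward(dy))))
            dskip, dup = dy[:, :cskip], dy[:, cskip:]
            dskips.append(dskip)
            dy = up.backward(np.ascontiguousarray(dup))
        c1, r1, c2, r2 = self.bott
        dy = c1.backward(r1.backward(c2.backward(r2.backward(dy))))
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self.pools), reversed(dskips)):
            dy = pool.backward(dy) + dskip
            c1, r1, c2, r2 = blk
            dy = c1.backward(r1.backward(c2.backward(r2.backward(dy))))

    # -- persistence -----------------------------------------------------------

    def save(self, path) -> None:
        """Weights as .npz plus a plain-text sidecar with the spec and seed."""
        path = Path(path)
        np.savez_compressed(path, **self.state_dict())
        sidecar = path.with_suffix(path.suffix + ".spec.json")
        sidecar.write_text(json.dumps({"spec": asdict(self.spec), "seed": self.seed}, indent=1))

    @classmethod
    def load(cls, path) -> "UNet":
        path = Path(path)
        sidecar = path.with_suffix(path.suffix + ".spec.json")
        meta = json.loads(sidecar.read_text())
        model = cls(UNetSpec(**meta["spec"]), seed=meta.get("seed", 0))
        with np.load(path) as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model


def build_unet(spec: UNetSpec, seed: int = 0, dtype=np.float32) -> UNet:
    """Instantiate the modified U-net; asserts the closed-form count holds."""
    model = UNet(spec, seed=seed, dtype=dtype)
    expected = count_parameters(spec)
    if model.n_parameters != expected:  # pragma: no cover - internal consistency
        raise AssertionError(
            f"enumerated parameters {model.n_parameters} != closed form {expected}"
        )
    return model
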