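"""2D U-Net style segmentation backbone.

The network follows the canonical encoder-decoder layout: ``depth``
encoder stages of conv-BN-ReLU double blocks with channel width doubling
and 2x2 max pooling between stages, a bottleneck block, and ``depth``
decoder stages that upsample (nearest-neighbour 2x followed by a 3x3
convolution), concatenate the matching encoder skip feature and apply
another double block. A 1x1 classification head followed by a softmax
produces per-pixel class probabilities, so the output at every pixel is a
distribution over the ``num_classes`` classes.

The default configuration (16 initial channels, four down/upsampling
stages) targets 256x256 slices; a lighter profile (8 channels, three
stages, 64x64) trains the full pipeline on one CPU.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from io import BytesIO

import numpy as np

from ._autodiff import Tensor
from .nn import Conv2d, DoubleConv, Module


class ConfigurationError(ValueError):
    """An architecture or training configuration field is invalid."""


class InputError(ValueError):
    """An input array violates a shape or value contract."""


@dataclass(frozen=True)
class ArchSpec:
    """Architecture descriptor for the segmentation backbone."""

    in_channels: int = 1
    num_classes: int = 2
    base_channels: int = 16
    depth: int = 4

    def __post_init__(self):
        if self.in_channels < 1:
            raise ConfigurationError(f"in_channels must be >= 1, got {self.in_channels}")
        if self.num_classes < 2:
            raise ConfigurationError(f"num_classes must be >= 2, got {self.num_classes}")
        if self.base_channels < 1:
            raise ConfigurationError(
                f"base_channels must be >= 1, got {self.base_channels}")
        if self.depth < 1:
            raise ConfigurationError(f"depth must be >= 1, got {self.depth}")

    @property
    def encoder_channels(self) -> tuple:
        """Widths of the encoder stages (doubling per stage)."""
        return tuple(self.base_channels * 2 ** i for i in range(self.depth))

    @property
    def bottleneck_channels(self) -> int:
        return self.base_channels * 2 ** self.depth

    def check_spatial(self, h: int, w: int) -> None:
        div = 2 ** self.depth
        if h % div or w % div:
            raise InputError(
                f"spatial size {h}x{w} not divisible by 2**depth = {div}")


# light profile used by the tests and the desk-scale experiments
TEST_PROFILE = ArchSpec(in_channels=1, num_classes=2, base_channels=8, depth=3)


class UNet(Module):
    def __init__(self, arch: ArchSpec, rng: np.random.Generator):
        self.arch = arch
        widths = arch.encoder_channels
        cin = arch.in_channels
        for i, w in enumerate(widths):
            setattr(self, f"enc{i}", DoubleConv(cin, w, rng))
            cin = w
        self.bottleneck = DoubleConv(widths[-1], arch.bottleneck_channels, rng)
        cin = arch.bottleneck_channels
        for i, w in reversed(list(enumerate(widths))):
            setattr(self, f"up{i}", Conv2d(cin, w, 3, rng))
            setattr(self, f"dec{i}", DoubleConv(2 * w, w, rng))
            cin = w
        self.head = Conv2d(widths[0], arch.num_classes, 1, rng)

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        arch = self.arch
        skips = []
        for i in range(arch.depth):
            x = getattr(self, f"enc{i}")(x, train)
            skips.append(x)
            x = x.maxpool2()
        x = self.bottleneck(x, train)
        for i in reversed(range(arch.depth)):
            x = getattr(self, f"up{i}")(x.upsample2())
            x = getattr(self, f"dec{i}")(Tensor.concat([skips[i], x], axis=1), train)
        return self.head(x).softmax(axis=1)


@dataclass
class ModelState:
    """A backbone plus its role in the pipeline.

    ``role`` is one of ``student`` / ``teacher`` / ``frozen``; a frozen
    model (the Stage-A pseudo-labeler) never receives optimizer updates.
    """

    arch: ArchSpec
    net: UNet
    role: str = "student"
    iteration: int = 0

    ROLES = ("student", "teacher", "frozen")

    def __post_init__(self):
        if self.role not in self.ROLES:
            raise ConfigurationError(f"role must be one of {self.ROLES}, got {self.role!r}")

    @property
    def params(self) -> dict:
        return self.net.state_dict()

    def clone(self, role: str | None = None) -> "ModelState":
        rng = np.random.default_rng(0)
        net = UNet(self.arch, rng)
        net.load_state_dict(self.net.state_dict())
        return ModelState(self.arch, net, role or self.role, self.iteration)

    def freeze(self) -> "ModelState":
        out = self.clone(role="frozen")
        out.net.set_requires_grad(False)
        return out


def build_model(arch: ArchSpec, seed: int, role: str = "student") -> ModelState:
    """Construct a backbone with seed-deterministic He-normal weights."""
    rng = np.random.default_rng(seed)
    return ModelState(arch, UNet(arch, rng), role=role)


def forward(model: ModelState, images: np.ndarray) -> np.ndarray:
    """Per-pixel class probabilities for a batch, in inference mode.

    ``images`` is (batch, in_channels, H, W); returns (batch, C, H, W)
    with the class axis summing to one at every pixel.
    """
    images = np.asarray(images, dtype=np.float32)
    if images.ndim != 4 or images.shape[1] != model.arch.in_channels:
        raise InputError(
            f"expected (batch, {model.arch.in_channels}, H, W), got {images.shape}")
    model.arch.check_spatial(images.shape[2], images.shape[3])
    return model.net(Tensor(images), train=False).data


def save_checkpoint(model: ModelState, path) -> None:
    """Single-archive checkpoint: architecture, role, iteration, weights."""
    meta = {
        "arch": {
            "in_channels": model.arch.in_channels,
            "num_classes": model.arch.num_classes,
            "base_channels": model.arch.base_channels,
            "depth": model.arch.depth,
        },
        "role": model.role,
        "iteration": model.iteration,
    }
    buf = BytesIO()
    np.savez(buf, **model.net.state_dict())
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        zf.writestr("params.npz", buf.getvalue())


def load_checkpoint(path) -> ModelState:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        with np.load(BytesIO(zf.read("params.npz"))) as npz:
            state = {k: npz[k] for k in npz.files}
    arch = ArchSpec(**meta["arch"])
    model = build_model(arch, seed=0, role=meta["role"])
    model.net.load_state_dict(state)
    model.iteration = int(meta["iteration"])
    if model.role == "frozen":
        model.net.set_requires_grad(False)
    return model
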