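"""3D U-Net with a ResNet-18-style residual encoder.

The encoder replicates the ResNet-18 stage pattern in 3D: a convolutional
stem, then one stage per resolution level with two 2-conv residual blocks,
channels doubling and resolution halving between stages.  The decoder
mirrors it with nearest-neighbour upsampling and skip concatenation; the
head is a 1x1x1 convolution with a sigmoid, so the output is a
single-channel probability volume the same size as the input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import nn


@dataclass
class NetConfig:
    """Architecture hyperparameters.

    ``patch`` must be divisible by ``2**(depth-1)`` so the decoder can
    reconstruct the input resolution exactly.
    """

    base_channels: int = 8
    depth: int = 3
    patch: int = 96
    in_channels: int = 1
    norm_scale: float = 10000.0  # input HU are divided by this before the net
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")
        if self.patch % (2 ** (self.depth - 1)) != 0:
            raise ValueError(
                f"patch {self.patch} not divisible by 2^(depth-1) = {2 ** (self.depth - 1)}"
            )

    def to_dict(self) -> dict:
        return asdict(self)


class UNet3D:
    """Encoder-decoder with residual encoder stages and skip connections."""

    def __init__(self, cfg: NetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.params: dict[str, nn.Tensor] = {}
        ch = [cfg.base_channels * 2**i for i in range(cfg.depth)]
        self._channels = ch

        def conv_param(name, cin, cout, k=3, norm=True):
            fan_in = cin * k**3
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k, k))
            self.params[f"{name}.w"] = nn.Tensor(w)
            self.params[f"{name}.b"] = nn.Tensor(np.zeros(cout))
            if norm:
                self.params[f"{name}.g"] = nn.Tensor(np.ones(cout))
                self.params[f"{name}.beta"] = nn.Tensor(np.zeros(cout))

        conv_param("stem", cfg.in_channels, ch[0])
        for i in range(cfg.depth):
            if i > 0:
                conv_param(f"down{i}", ch[i - 1], ch[i])
            for b in range(2):  # two residual blocks per stage (ResNet-18 pattern)
                conv_param(f"enc{i}.{b}.c1", ch[i], ch[i])
                conv_param(f"enc{i}.{b}.c2", ch[i], ch[i])
        for i in range(cfg.depth - 2, -1, -1):
            conv_param(f"up{i}.reduce", ch[i + 1], ch[i])
            conv_param(f"up{i}.c1", 2 * ch[i], ch[i])
            conv_param(f"up{i}.c2", ch[i], ch[i])
        conv_param("head", ch[0], 1, k=1, norm=False)

    # -- taped forward ------------------------------------------------------

    def _p(self, name):
        return self.params[f"{name}.w"], self.params[f"{name}.b"]

    def _cnr(self, t, name, activate=True):
        """conv -> channel norm -> relu (taped)."""
        t = nn.conv3d(t, *self._p(name))
        t = nn.channel_norm(t, self.params[f"{name}.g"], self.params[f"{name}.beta"])
        return nn.relu(t) if activate else t

    def forward(self, x: np.ndarray) -> nn.Tensor:
        """Taped forward pass; ``x`` is (C, D, H, W) already normalized."""
        t = nn.Tensor(x)
        t = self._cnr(t, "stem")
        skips = []
        for i in range(self.cfg.depth):
            if i > 0:
                t = self._cnr(t, f"down{i}")
                t = nn.down2(t)
            for b in range(2):
                h = self._cnr(t, f"enc{i}.{b}.c1")
                h = self._cnr(h, f"enc{i}.{b}.c2", activate=False)
                t = nn.relu(nn.add(t, h))
            skips.append(t)
        for i in range(self.cfg.depth - 2, -1, -1):
            t = nn.up2(t)
            t = self._cnr(t, f"up{i}.reduce")
            t = nn.concat(skips[i], t)
            t = self._cnr(t, f"up{i}.c1")
            t = self._cnr(t, f"up{i}.c2")
        return nn.sigmoid(nn.conv3d(t, *self._p("head")))

    # -- no-grad forward ----------------------------------------------------

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Plain-array forward pass (no tape), same arithmetic as forward()."""
        f = nn.conv3d_forward

        def p(name):
            return self.params[f"{name}.w"].data, self.params[f"{name}.b"].data

        def cnr(t, name, activate=True):
            t = f(t, *p(name))
            t = nn.channel_norm_forward(
                t, self.params[f"{name}.g"].data, self.params[f"{name}.beta"].data
            )
            return np.maximum(t, 0) if activate else t

        t = cnr(np.asarray(x, dtype=np.float32), "stem")
        skips = []
        for i in range(self.cfg.depth):
            if i > 0:
                t = cnr(t, f"down{i}")
                t = nn.down2_forward(t)
            for b in range(2):
                h = cnr(t, f"enc{i}.{b}.c1")
                h = cnr(h, f"enc{i}.{b}.c2", activate=False)
                t = np.maximum(t + h, 0)
            skips.append(t)
        for i in range(self.cfg.depth - 2, -1, -1):
            t = nn.up2_forward(t)
            t = cnr(t, f"up{i}.reduce")
            t = np.concatenate([skips[i], t], axis=0)
            t = cnr(t, f"up{i}.c1")
            t = cnr(t, f"up{i}.c2")
        z = f(t, *p("head"))
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    # -- bookkeeping --------------------------------------------------------

    def parameters(self) -> list[nn.Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        missing = set(self.params) - set(state)
        if missing:
            raise ValueError(f"checkpoint is missing parameters: {sorted(missing)}")
        for k, v in self.params.items():
            v.data = np.asarray(state[k], dtype=np.float32).reshape(v.data.shape)

    def normalize(self, volume: np.ndarray) -> np.ndarray:
        return (np.asarray(volume, dtype=np.float32) / self.cfg.norm_scale)[None]


def build_unet(cfg: NetConfig | None = None) -> UNet3D:
    """Construct a 3D U-Net; identical seeds give identical initial weights."""
    return UNet3D(cfg or NetConfig())


def save_checkpoint(model: UNet3D, path: str | Path, extra: dict | None = None) -> None:
    """Weights as .npz plus a JSON sidecar with the architecture config."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = {"net_config": model.cfg.to_dict(), **(extra or {})}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> UNet3D:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = NetConfig(**sidecar["net_config"])
    model = build_unet(cfg)
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as state:
        model.load_state_dict(dict(state))
    return model
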