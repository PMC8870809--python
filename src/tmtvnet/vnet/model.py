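"""3D V-NET: residual encoder-decoder with skip connections.

The network follows the standard V-NET layout: ``levels`` resolutions,
``base_channels`` feature maps at the finest level doubling at each
down-transition (2x2x2 stride-2 convolutions), nearest-neighbor
up-transitions halving the channel count, skip connections concatenated
into the decoder, a residual stage at every resolution, and a final
1x1x1 convolution with a single sigmoid output channel — the voxel-wise
tumor probability.

The default configuration (4 levels, 8 base channels, 2 input channels
for CT+PET) is the one used for lymphoma TMTV segmentation; spatial
input dimensions must be divisible by ``2**(levels-1)``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["VnetConfig", "VNet", "build_model"]


@dataclass
class VnetConfig:
    """Architecture and training hyper-parameters.

    Optimizer settings (SGD, learning rate 0.001, momentum 0.9, soft dice
    loss, one additional augmented copy per case) follow the published
    TMTV training setup; epochs and batch size default to desk scale.
    """

    levels: int = 4
    base_channels: int = 8
    in_channels: int = 2
    out_channels: int = 1
    learning_rate: float = 0.001
    momentum: float = 0.9
    epochs: int = 30
    batch_size: int = 1
    seed: int = 0
    augment_per_case: int = 1
    # augmentation ranges (uniformly sampled)
    translation_mm: float = 16.0
    rotation_deg: float = 10.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    dice_eps: float = 1e-6
    leaky_alpha: float = 0.1

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if min(self.base_channels, self.in_channels, self.out_channels) < 1:
            raise ValueError("channel counts must be positive")
        if min(self.learning_rate, self.momentum) < 0 or self.learning_rate == 0:
            raise ValueError("learning rate must be positive, momentum non-negative")
        if self.out_channels != 1:
            raise ValueError("the TMTV model has a single sigmoid output channel")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


class VNet:
    """Desk-scale V-NET over float32 numpy volumes ``(channels, x, y, z)``."""

    def __init__(self, cfg: VnetConfig):
        self.cfg = cfg
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(cfg.seed)
        c = cfg.base_channels
        chans = [c * 2**l for l in range(cfg.levels)]
        self._chans = chans

        self._add_conv(rng, "in_conv", cfg.in_channels, chans[0], k=3)
        for l in range(cfg.levels):
            self._add_conv(rng, f"enc{l}_res", chans[l], chans[l], k=3)
            if l + 1 < cfg.levels:
                self._add_conv(rng, f"down{l}", chans[l], chans[l + 1], k=2)
        for l in range(cfg.levels - 2, -1, -1):
            self._add_conv(rng, f"up{l}", chans[l + 1], chans[l], k=1)
            self._add_conv(rng, f"dec{l}_merge", 2 * chans[l], chans[l], k=3)
            self._add_conv(rng, f"dec{l}_res", chans[l], chans[l], k=3)
        self._add_conv(rng, "out_conv", chans[0], cfg.out_channels, k=1)
        # start predictions near zero: tumor voxels are rare, and a low
        # initial foreground prior stabilizes the first dice-loss steps
        self.params["out_conv_b"].data[:] = -2.0

    def _add_conv(self, rng, name: str, ci: int, co: int, k: int) -> None:
        fan_in = ci * k**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(co, ci, k, k, k))
        self.params[f"{name}_w"] = Tensor(w.astype(np.float32), requires_grad=True)
        self.params[f"{name}_b"] = Tensor(np.zeros(co, np.float32), requires_grad=True)

    # -- forward -----------------------------------------------------------

    def _conv(self, name: str, x: Tensor, down: bool = False) -> Tensor:
        op = ag.down_conv if down else ag.conv3d
        return op(x, self.params[f"{name}_w"], self.params[f"{name}_b"])

    def _res_stage(self, name: str, x: Tensor) -> Tensor:
        """Residual stage: x + conv(x), then nonlinearity."""
        return ag.leaky_relu(ag.add(x, self._conv(name, x)), self.cfg.leaky_alpha)

    def forward(self, x: np.ndarray) -> Tensor:
        """Input ``(in_channels, D, H, W)`` -> sigmoid probability tensor
        of shape ``(1, D, H, W)``."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[0] != self.cfg.in_channels:
            raise ValueError(
                f"expected ({self.cfg.in_channels}, D, H, W) input, got {x.shape}"
            )
        div = 2 ** (self.cfg.levels - 1)
        if any(s % div for s in x.shape[1:]):
            raise ValueError(
                f"spatial shape {x.shape[1:]} must be divisible by 2^(levels-1)={div}"
            )
        a = self.cfg.leaky_alpha
        h = ag.leaky_relu(self._conv("in_conv", Tensor(x)), a)
        skips: list[Tensor] = []
        for l in range(self.cfg.levels):
            h = self._res_stage(f"enc{l}_res", h)
            if l + 1 < self.cfg.levels:
                skips.append(h)
                h = ag.leaky_relu(self._conv(f"down{l}", h, down=True), a)
        for l in range(self.cfg.levels - 2, -1, -1):
            up = ag.leaky_relu(self._conv(f"up{l}", ag.upsample_nn(h)), a)
            h = ag.leaky_relu(
                self._conv(f"dec{l}_merge", ag.concat_channels(up, skips[l])), a
            )
            h = self._res_stage(f"dec{l}_res", h)
        return ag.sigmoid(self._conv("out_conv", h))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Voxel-wise tumor probability, shape ``(D, H, W)``."""
        return self.forward(x).data[0]

    # -- parameter plumbing ------------------------------------------------

    def parameters(self) -> dict[str, Tensor]:
        return self.params

    def n_parameters(self) -> int:
        return sum(int(np.prod(p.data.shape)) for p in self.params.values())

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        missing = set(self.params) - set(state)
        if missing:
            raise KeyError(f"missing parameters: {sorted(missing)}")
        for k, v in self.params.items():
            v.data = np.asarray(state[k], dtype=np.float32).reshape(v.data.shape)


def build_model(cfg: VnetConfig) -> VNet:
    """Construct a V-NET from its configuration (seeded initialization)."""
    return VNet(cfg)
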