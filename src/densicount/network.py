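"""The two-branch density-map estimation network.

Architecture: a VGG-19-style backbone truncated before its last max-pool
(four stride-2 pooling stages, so features sit at 1/16 input resolution),
followed by x2 bilinear upsampling to 1/8, feeding two parallel heads:

* a segmentation branch (conv3-conv3-conv1, sigmoid) predicting per-cell
  foreground probability, and
* a density branch (conv3-conv3-conv1, ReLU) regressing per-cell density.

The segmentation prediction builds a feature mask ``M_d = 1[S_pred >= 0.5]
+ alpha * 1[S_pred < 0.5]`` that dampens background locations of the shared
features before the density branch sees them; the mask is a constant in the
backward pass. At inference the two outputs are fused, ``D_out = D_pred *
1[S_pred >= 0.5]``, and the count is the total mass of the fused map.

Inputs of arbitrary size are zero-padded bottom/right to a multiple of 16 so
no pixels drop out of the pooling stages; both output maps have spatial size
(padded input)/8. A reduced-width "tiny" backbone with the identical pooling
structure is provided for CPU-scale training and tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import Adam, BilinearUp2, Conv2d, MaxPool2, Param, ReLU, Sequential, Sigmoid
from .nn.layers import DTYPE, Layer
from .targets import ConfigError, ContractError, DensityMap, SegmentationMap

__all__ = [
    "ModelConfig",
    "NetworkOutput",
    "Network",
    "build_network",
    "pad_to_multiple",
    "make_feature_mask",
    "fuse_inference",
    "predict_count",
    "save_checkpoint",
    "load_checkpoint",
]

# VGG-19 convolutional trunk up to (and excluding) the fifth max-pool;
# 'M' marks a 2x2 stride-2 max-pool.
_VGG19_TRUNK = [64, 64, "M", 128, 128, "M", 256, 256, 256, 256, "M",
                512, 512, 512, 512, "M", 512, 512, 512, 512]
# Same downsampling structure at 1/8 width, for desk-scale training.
_TINY_TRUNK = [8, 8, "M", 16, 16, "M", 32, 32, 32, 32, "M",
               64, 64, 64, 64, "M", 64, 64, 64, 64]

# Channel-wise input normalization (ImageNet statistics, the convention for
# VGG-family backbones; applied to images scaled to [0, 1]).
_DEFAULT_MEAN = (0.485, 0.456, 0.406)
_DEFAULT_STD = (0.229, 0.224, 0.225)


@dataclass
class ModelConfig:
    """Model hyperparameters.

    alpha is the background-feature dampening factor of the mask; branch
    channel widths follow the "gradually reduce to 1" design (512 -> 256 ->
    64 -> 1 for the full backbone). ``use_pretrained_backbone`` loads
    backbone conv weights from ``pretrained_path`` (.npz of weight/bias
    arrays in trunk order) instead of random initialization.
    """

    backbone: str = "vgg19-truncated"
    use_pretrained_backbone: bool = False
    pretrained_path: str | None = None
    alpha: float = 0.1
    branch_channels: list[int] = field(default_factory=lambda: [256, 64])
    pad_multiple: int = 16
    norm_mean: tuple[float, float, float] = _DEFAULT_MEAN
    norm_std: tuple[float, float, float] = _DEFAULT_STD
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.pad_multiple != 16:
            raise ConfigError("pad_multiple is fixed at 16 (four 2x2 pooling stages)")
        if len(self.branch_channels) != 2:
            raise ConfigError("branch_channels must list two widths")

    @property
    def output_divisor(self) -> int:
        return self.pad_multiple // 2

    @classmethod
    def tiny(cls, seed: int = 0, **kw) -> "ModelConfig":
        kw.setdefault("branch_channels", [32, 16])
        return cls(backbone="tiny", seed=seed, **kw)


@dataclass
class NetworkOutput:
    """Paired branch outputs at 1/8 (padded) input resolution."""

    density: DensityMap
    segmentation: SegmentationMap

    def __post_init__(self) -> None:
        if self.density.shape != self.segmentation.shape:
            raise ContractError("density and segmentation outputs must share shape")
        if self.segmentation.mode != "probability":
            raise ContractError("network segmentation output is a probability map")


def pad_to_multiple(image: np.ndarray, multiple: int = 16) -> tuple[np.ndarray, tuple[int, int]]:
    """Zero-pad bottom/right so both spatial dims are multiples of ``multiple``.

    Returns the padded image and the original (height, width) for cropping
    outputs back.
    """
    if multiple < 1:
        raise ConfigError("multiple must be >= 1")
    h, w = image.shape[:2]
    ph, pw = -h % multiple, -w % multiple
    if ph == 0 and pw == 0:
        return image, (h, w)
    pad = [(0, ph), (0, pw)] + [(0, 0)] * (image.ndim - 2)
    return np.pad(image, pad), (h, w)


def make_feature_mask(spred: SegmentationMap | np.ndarray, alpha: float = 0.1) -> np.ndarray:
    """Feature mask from the predicted segmentation: 1 on foreground cells
    (probability >= 0.5, inclusive), ``alpha`` on background cells."""
    if isinstance(spred, SegmentationMap):
        if spred.mode != "probability":
            raise ContractError("feature mask needs a probability-mode map")
        p = spred.values
    else:
        p = np.asarray(spred)
    return np.where(p >= 0.5, 1.0, alpha)


class Network:
    """Backbone + upsampler + two heads, with explicit forward/backward."""

    def __init__(self, cfg: ModelConfig) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        if cfg.backbone == "vgg19-truncated":
            trunk = _VGG19_TRUNK
        elif cfg.backbone == "tiny":
            trunk = _TINY_TRUNK
        else:
            raise ConfigError(f"unknown backbone {cfg.backbone!r}")

        layers: list[Layer] = []
        cin = 3
        for i, spec in enumerate(trunk):
            if spec == "M":
                layers.append(MaxPool2())
            else:
                layers.append(Conv2d(cin, int(spec), 3, rng, name=f"backbone.{i}"))
                layers.append(ReLU())
                cin = int(spec)
        self.backbone = Sequential(layers)
        self.upsample = BilinearUp2()
        feat_ch = cin
        c1, c2 = cfg.branch_channels

        def branch(name: str) -> Sequential:
            # branch weights ~ N(0, 0.01); first two convs 3x3, final conv 1x1
            return Sequential([
                Conv2d(feat_ch, c1, 3, rng, weight_std=0.01, name=f"{name}.0"),
                ReLU(),
                Conv2d(c1, c2, 3, rng, weight_std=0.01, name=f"{name}.1"),
                ReLU(),
                Conv2d(c2, 1, 1, rng, weight_std=0.01, name=f"{name}.2"),
            ])

        self.seg_branch = branch("seg")
        self.seg_head = Sigmoid()
        self.dens_branch = branch("dens")
        self.dens_head = ReLU()
        self._mask: np.ndarray | None = None

        if cfg.use_pretrained_backbone:
            self._load_backbone_weights(cfg.pretrained_path)

    def _load_backbone_weights(self, path: str | None) -> None:
        if path is None:
            raise ConfigError(
                "use_pretrained_backbone requires pretrained_path (.npz of conv weights)"
            )
        data = np.load(path)
        convs = [l for l in self.backbone.layers if isinstance(l, Conv2d)]
        for i, conv in enumerate(convs):
            w, b = data[f"w{i}"], data[f"b{i}"]
            conv.weight.value = np.ascontiguousarray(
                w.reshape(conv.weight.value.shape), dtype=DTYPE
            )
            conv.bias.value = np.ascontiguousarray(b, dtype=DTYPE)

    # -- parameters ---------------------------------------------------------
    def params(self) -> list[Param]:
        return (
            self.backbone.params()
            + self.seg_branch.params()
            + self.dens_branch.params()
        )

    def normalize(self, image: np.ndarray) -> np.ndarray:
        """HWC (or HW gray) image in [0,1] or uint8 -> normalized CHW float32."""
        img = np.asarray(image)
        if img.dtype == np.uint8:
            img = img.astype(np.float32) / 255.0
        img = img.astype(np.float32)
        if img.ndim == 2:
            img = np.repeat(img[:, :, None], 3, axis=2)
        if img.shape[2] != 3:
            raise ContractError(f"expected 3 channels, got {img.shape[2]}")
        mean = np.asarray(self.cfg.norm_mean, dtype=np.float32)
        std = np.asarray(self.cfg.norm_std, dtype=np.float32)
        return ((img - mean) / std).transpose(2, 0, 1)

    # -- forward / backward -------------------------------------------------
    def forward_batch(self, x: np.ndarray, train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Normalized NCHW batch (dims divisible by 16) -> (density, seg) N1hw."""
        n, c, h, w = x.shape
        if c != 3:
            raise ContractError(f"expected 3-channel input, got {c}")
        if h % self.cfg.pad_multiple or w % self.cfg.pad_multiple:
            raise ContractError("input dims must be multiples of 16; use pad_to_multiple")
        feats = self.backbone.forward(x.astype(DTYPE), train=train)
        feats = self.upsample.forward(feats, train=train)
        seg_logit_out = self.seg_branch.forward(feats, train=train)
        seg = self.seg_head.forward(seg_logit_out, train=train)
        # segmentation-guided dampening of background features; the mask is
        # constant w.r.t. gradients (indicator has zero derivative a.e.)
        mask = np.where(seg >= 0.5, 1.0, self.cfg.alpha).astype(DTYPE)
        dens = self.dens_branch.forward(feats * mask, train=train)
        dens = self.dens_head.forward(dens, train=train)
        if train:
            self._mask = mask
        return dens, seg

    def backward_batch(self, d_dens: np.ndarray, d_seg: np.ndarray) -> None:
        """Push loss gradients (w.r.t. the two head outputs) to all parameters."""
        g_dens = self.dens_branch.backward(
            self.dens_head.backward(d_dens.astype(DTYPE))
        )
        g_feats = g_dens * self._mask
        g_seg = self.seg_branch.backward(self.seg_head.backward(d_seg.astype(DTYPE)))
        g_feats = g_feats + g_seg
        self.backbone.backward(self.upsample.backward(g_feats))
        self._mask = None

    def forward(self, image: np.ndarray) -> NetworkOutput:
        """Single padded image (HWC, dims divisible by 16) -> NetworkOutput."""
        x = self.normalize(image)[None]
        dens, seg = self.forward_batch(x, train=False)
        return NetworkOutput(
            density=DensityMap(dens[0, 0].astype(np.float64), resolution_divisor=8),
            segmentation=SegmentationMap(
                np.clip(seg[0, 0].astype(np.float64), 0.0, 1.0), mode="probability"
            ),
        )


def build_network(cfg: ModelConfig | None = None) -> Network:
    """Construct (and seed-initialize) the two-branch network."""
    return Network(cfg or ModelConfig())


def fuse_inference(out: NetworkOutput) -> DensityMap:
    """Fuse the branches: zero the density wherever the predicted foreground
    probability is below 0.5; keep it unchanged elsewhere."""
    d, s = out.density.values, out.segmentation.values
    if d.shape != s.shape:
        raise ContractError("fusion requires matching shapes")
    return DensityMap(d * (s >= 0.5), resolution_divisor=out.density.resolution_divisor)


def predict_count(
    net: Network, image: np.ndarray
) -> tuple[float, DensityMap, SegmentationMap]:
    """Count the objects in an arbitrary-size image.

    Pads to a multiple of 16, runs the network, fuses the branches, and
    returns the total mass of the fused map as the count together with the
    fused density map and the segmentation probability map (both at 1/8 of
    the padded size). The count is therefore identical whether or not the
    caller pre-pads, and always equals the mass of the returned map.
    """
    padded, _orig = pad_to_multiple(image, net.cfg.pad_multiple)
    out = net.forward(padded)
    fused = fuse_inference(out)
    return fused.total_mass, fused, out.segmentation


# -- checkpoints ------------------------------------------------------------

def save_checkpoint(
    path: str | Path,
    net: Network,
    optimizer: Adam | None = None,
    extra: dict | None = None,
) -> None:
    """Save parameters (+ optional optimizer state) with the config embedded."""
    arrays: dict[str, np.ndarray] = {}
    for i, p in enumerate(net.params()):
        arrays[f"param_{i}"] = p.value
    meta = {"config": asdict(net.cfg), "extra": extra or {}}
    if optimizer is not None:
        state = optimizer.state_dict()
        meta["optimizer"] = {"t": state["t"], "lr": optimizer.lr,
                             "weight_decay": optimizer.weight_decay}
        for i, (m, v) in enumerate(zip(state["m"], state["v"])):
            arrays[f"adam_m_{i}"] = m
            arrays[f"adam_v_{i}"] = v
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[Network, dict]:
    """Rebuild a network from a checkpoint; returns (network, metadata)."""
    data = np.load(path)
    meta = json.loads(bytes(data["meta_json"]).decode())
    cfg_d = dict(meta["config"])
    cfg_d["branch_channels"] = list(cfg_d["branch_channels"])
    cfg_d["norm_mean"] = tuple(cfg_d["norm_mean"])
    cfg_d["norm_std"] = tuple(cfg_d["norm_std"])
    cfg_d["use_pretrained_backbone"] = False  # weights come from the checkpoint
    cfg_d["pretrained_path"] = None
    cfg = ModelConfig(**cfg_d)
    net = Network(cfg)
    for i, p in enumerate(net.params()):
        p.value = np.ascontiguousarray(data[f"param_{i}"], dtype=DTYPE)
    meta["_arrays"] = {
        k: data[k] for k in data.files if k.startswith("adam_")
    }
    return net, meta
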