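"""The four computation graphs of the co-optimized segmenter.

* ``ReconstructorNet`` (R): residual encoder + plain upsampling decoder,
  Tanh output — an autoencoder trained on pseudo-unlabeled slices.
* ``SegmenterNet`` (S): the same encoder layout (independently initialized)
  + U-style decoder with skip connections, softmax output.
* ``DiscriminatorNet`` (D): 4 strided 3x3 convolutions + FC-512 + FC-2 +
  softmax, judging reconstructed vs real slices.
* ``TransferBlock`` (T): Conv1x1 -> BN -> ReLU applied to R's bottleneck
  ("middle") feature, fused into S's bottleneck by elementwise addition.

The encoder follows a ResNet-18-style layout: a 3x3 stem followed by
``n_stages`` stages of two residual blocks each; the first block of every
stage downsamples by 2 and doubles the channel count, so the bottleneck is
``8*base_width`` channels at ``H/2^n_stages`` resolution (for the default
4 stages). Residual blocks use a 1x1 -> 3x3 -> 1x1 conv path and fuse it
with the identity path either by concatenation followed by a 1x1 projection
(default) or by elementwise addition.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn import Tensor
from .image_io import MultiModalSlice

__all__ = [
    "NetworkConfig", "ResidualBlock", "Encoder", "SegmenterNet",
    "ReconstructorNet", "DiscriminatorNet", "TransferBlock", "ColNetModel",
    "build_model", "forward_segmenter", "forward_reconstructor",
    "forward_discriminator", "transfer_fuse", "as_batch",
]


@dataclass(frozen=True)
class NetworkConfig:
    in_channels: int = 6
    base_width: int = 32
    n_stages: int = 4
    num_classes: int = 2
    skip_fusion: str = "concat"     # residual-block fusion: concat | add
    dropout: float = 0.01

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.skip_fusion not in ("concat", "add"):
            raise ValueError("skip_fusion must be 'concat' or 'add'")
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")

    @property
    def bottleneck_channels(self) -> int:
        return self.base_width * (2 ** (self.n_stages - 1))


def _check_divisible(h: int, w: int, n_stages: int) -> None:
    d = 2 ** n_stages
    if h % d or w % d:
        raise ValueError(
            f"spatial dims ({h}, {w}) must be divisible by 2^{n_stages}={d}; "
            f"pad the input to the next multiple")


def as_batch(batch) -> Tensor:
    """Stack MultiModalSlices / arrays into an (N, C, H, W) tensor."""
    if isinstance(batch, Tensor):
        return batch
    arrays = []
    for item in (batch if isinstance(batch, (list, tuple)) else [batch]):
        if isinstance(item, MultiModalSlice):
            arrays.append(item.values)
        else:
            arr = np.asarray(item, dtype=np.float32)
            arrays.append(arr)
    stacked = np.stack(arrays)
    if stacked.ndim != 4:
        raise ValueError(f"expected (N, C, H, W) batch, got shape {stacked.shape}")
    return Tensor(stacked)


class ResidualBlock(nn.Module):
    """1x1 -> 3x3(stride) -> 1x1 conv path fused with the identity path."""

    def __init__(self, in_ch: int, out_ch: int, rng, stride: int = 1,
                 fusion: str = "concat"):
        super().__init__()
        mid = max(out_ch // 2, 4)
        self.fusion = fusion
        self.stride = stride
        self.conv1 = nn.Conv2d(in_ch, mid, 1, rng)
        self.bn1 = nn.BatchNorm2d(mid)
        self.conv2 = nn.Conv2d(mid, mid, 3, rng, stride=stride)
        self.bn2 = nn.BatchNorm2d(mid)
        self.conv3 = nn.Conv2d(mid, out_ch, 1, rng)
        self.bn3 = nn.BatchNorm2d(out_ch)
        if fusion == "concat":
            self.proj = nn.Conv2d(out_ch + in_ch, out_ch, 1, rng)
        elif stride != 1 or in_ch != out_ch:
            self.proj = nn.Conv2d(in_ch, out_ch, 1, rng, stride=stride)
        else:
            self.proj = None    # pure identity: zero conv path passes x through

    def _identity(self, x: Tensor) -> Tensor:
        if self.fusion == "concat" and self.stride != 1:
            # spatial match for concat: subsample the identity path
            return Tensor._make(
                x.data[:, :, ::self.stride, ::self.stride], (x,),
                _strided_slice_backward(x, self.stride))
        return x

    def __call__(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h)).relu()
        h = self.bn3(self.conv3(h))
        ident = self._identity(x)
        if self.fusion == "concat":
            return self.proj(nn.concat([h, ident], axis=1))
        if self.proj is not None:
            ident = self.proj(ident)
        return h + ident


def _strided_slice_backward(x: Tensor, stride: int):
    def bw(g):
        dx = np.zeros_like(x.data)
        dx[:, :, ::stride, ::stride] = g
        x._accum(dx)
    return bw


class Encoder(nn.Module):
    """Stem + n_stages of two residual blocks; returns all stage outputs."""

    def __init__(self, cfg: NetworkConfig, rng):
        super().__init__()
        w = cfg.base_width
        self.cfg = cfg
        self.stem_conv = nn.Conv2d(cfg.in_channels, w, 3, rng)
        self.stem_bn = nn.BatchNorm2d(w)
        self.stages = []
        in_ch = w
        for s in range(cfg.n_stages):
            out_ch = w * (2 ** s)
            self.stages.append([
                ResidualBlock(in_ch, out_ch, rng, stride=2, fusion=cfg.skip_fusion),
                ResidualBlock(out_ch, out_ch, rng, stride=1, fusion=cfg.skip_fusion),
            ])
            in_ch = out_ch
        # flatten for module discovery
        self._blocks = [b for stage in self.stages for b in stage]

    def modules(self):
        yield self.stem_conv
        yield self.stem_bn
        yield from self._blocks

    def parameters(self):
        for m in self.modules():
            yield from m.parameters()

    def _named_entries(self, prefix=""):
        yield from self.stem_conv._named_entries(prefix + "stem_conv.")
        yield from self.stem_bn._named_entries(prefix + "stem_bn.")
        for i, b in enumerate(self._blocks):
            yield from b._named_entries(prefix + f"block{i}.")

    def __call__(self, x: Tensor) -> list[Tensor]:
        _check_divisible(x.shape[2], x.shape[3], self.cfg.n_stages)
        feats = [self.stem_bn(self.stem_conv(x)).relu()]
        h = feats[0]
        for stage in self.stages:
            for block in stage:
                h = block(h)
            feats.append(h)
        return feats            # [stem, stage1, ..., bottleneck]


class _UpBlock(nn.Module):
    """Upsample x2 -> (concat skip) -> Conv-BN-ReLU x n_convs."""

    def __init__(self, in_ch: int, skip_ch: int, out_ch: int, rng,
                 n_convs: int = 2, dropout: float = 0.0,
                 dropout_rng=None):
        super().__init__()
        self.has_skip = skip_ch > 0
        ch = in_ch + skip_ch
        self.convs = []
        self.bns = []
        for i in range(n_convs):
            self.convs.append(nn.Conv2d(ch if i == 0 else out_ch, out_ch, 3, rng))
            self.bns.append(nn.BatchNorm2d(out_ch))
        self.drop = nn.Dropout(dropout, dropout_rng) if dropout > 0 else None

    def __call__(self, x: Tensor, skip: Tensor | None = None) -> Tensor:
        h = x.upsample2x()
        if self.has_skip:
            h = nn.concat([h, skip], axis=1)
        for conv, bn in zip(self.convs, self.bns):
            h = bn(conv(h)).relu()
        if self.drop is not None:
            h = self.drop(h)
        return h


class SegmenterNet(nn.Module):
    """Encoder-decoder with skip connections and per-pixel softmax."""

    def __init__(self, cfg: NetworkConfig, rng, dropout_rng=None):
        super().__init__()
        self.cfg = cfg
        w = cfg.base_width
        self.encoder = Encoder(cfg, rng)
        enc_chs = [w] + [w * (2 ** s) for s in range(cfg.n_stages)]
        self.up_blocks = []
        in_ch = enc_chs[-1]
        for s in range(cfg.n_stages - 1, -1, -1):
            skip_ch = enc_chs[s]
            out_ch = enc_chs[s]
            self.up_blocks.append(_UpBlock(in_ch, skip_ch, out_ch, rng,
                                           dropout=cfg.dropout,
                                           dropout_rng=dropout_rng))
            in_ch = out_ch
        self.head = nn.Conv2d(in_ch, cfg.num_classes, 1, rng)

    def encode(self, x: Tensor) -> tuple[list[Tensor], Tensor]:
        feats = self.encoder(x)
        return feats[:-1], feats[-1]

    def decode(self, bottleneck: Tensor, skips: list[Tensor]) -> Tensor:
        h = bottleneck
        for up, skip in zip(self.up_blocks, reversed(skips)):
            h = up(h, skip)
        return self.head(h).softmax(axis=1)

    def __call__(self, x: Tensor, fused_bottleneck: Tensor | None = None) -> Tensor:
        skips, bottleneck = self.encode(x)
        if fused_bottleneck is not None:
            if fused_bottleneck.shape != bottleneck.shape:
                raise ValueError(
                    f"fused bottleneck shape {fused_bottleneck.shape} does not "
                    f"match encoder bottleneck {bottleneck.shape}")
            bottleneck = fused_bottleneck
        return self.decode(bottleneck, skips)


class ReconstructorNet(nn.Module):
    """Autoencoder: shared encoder layout + plain upsampling decoder + Tanh."""

    def __init__(self, cfg: NetworkConfig, rng, dropout_rng=None):
        super().__init__()
        self.cfg = cfg
        w = cfg.base_width
        self.encoder = Encoder(cfg, rng)
        enc_chs = [w] + [w * (2 ** s) for s in range(cfg.n_stages)]
        self.up_blocks = []
        in_ch = enc_chs[-1]
        for s in range(cfg.n_stages - 1, -1, -1):
            out_ch = enc_chs[s]
            self.up_blocks.append(_UpBlock(in_ch, 0, out_ch, rng, n_convs=1,
                                           dropout=cfg.dropout,
                                           dropout_rng=dropout_rng))
            in_ch = out_ch
        self.head = nn.Conv2d(in_ch, cfg.in_channels, 1, rng)

    def encode(self, x: Tensor) -> Tensor:
        """The 'middle' feature: the deepest encoder output."""
        return self.encoder(x)[-1]

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        middle = self.encode(x)
        h = middle
        for up in self.up_blocks:
            h = up(h)
        # clip keeps the output strictly inside (-1, 1) even where float32
        # tanh rounds to exactly +-1; the gradient there is ~0 regardless
        recon = self.head(h).tanh().clip(-1.0 + 1e-6, 1.0 - 1e-6)
        return recon, middle


class DiscriminatorNet(nn.Module):
    """4 strided 3x3 conv layers, FC-512, FC-2, softmax over (fake, real)."""

    def __init__(self, cfg: NetworkConfig, rng, input_hw: tuple[int, int]):
        super().__init__()
        self.cfg = cfg
        self.input_hw = tuple(input_hw)
        w = max(cfg.base_width // 2, 4)
        chs = [cfg.in_channels, w, 2 * w, 4 * w, 8 * w]
        self.convs = [nn.Conv2d(chs[i], chs[i + 1], 3, rng, stride=2)
                      for i in range(4)]
        h, wd = input_hw
        fh, fw = max(h // 16, 1), max(wd // 16, 1)
        self.flat_dim = chs[-1] * fh * fw
        self.fc1 = nn.Linear(self.flat_dim, 512, rng)
        self.fc2 = nn.Linear(512, 2, rng)

    def __call__(self, x: Tensor) -> Tensor:
        if (x.shape[2], x.shape[3]) != self.input_hw:
            raise ValueError(
                f"discriminator built for {self.input_hw} inputs, got "
                f"{(x.shape[2], x.shape[3])}")
        h = x
        for conv in self.convs:
            h = conv(h).relu()
        h = h.reshape(h.shape[0], self.flat_dim)
        h = self.fc1(h).relu()
        return self.fc2(h).softmax(axis=1)


class TransferBlock(nn.Module):
    """Conv1x1 -> BN -> ReLU from R's middle feature to S's bottleneck width."""

    def __init__(self, cfg: NetworkConfig, rng):
        super().__init__()
        ch = cfg.bottleneck_channels
        self.conv = nn.Conv2d(ch, ch, 1, rng)
        self.bn = nn.BatchNorm2d(ch)

    def __call__(self, middle_feature: Tensor) -> Tensor:
        return self.bn(self.conv(middle_feature)).relu()


def transfer_fuse(middle_feature_r: Tensor, bottleneck_feature_s: Tensor,
                  t_block: TransferBlock) -> Tensor:
    """T(middle_R) + bottleneck_S, the additive bottleneck fusion."""
    if middle_feature_r.shape[2:] != bottleneck_feature_s.shape[2:]:
        raise ValueError(
            f"spatial mismatch: {middle_feature_r.shape} vs "
            f"{bottleneck_feature_s.shape}")
    return t_block(middle_feature_r) + bottleneck_feature_s


# -- the model bundle -------------------------------------------------------

class ColNetModel:
    """R, S, D and T with their config and a training step counter."""

    def __init__(self, config: NetworkConfig, seed: int,
                 input_hw: tuple[int, int] = (64, 64)):
        self.config = config
        self.seed = int(seed)
        self.input_hw = tuple(input_hw)
        self.step = 0
        ss = np.random.SeedSequence([self.seed & 0x7FFFFFFF, 17])
        rng_r, rng_s, rng_d, rng_t, rng_dr, rng_ds = \
            [np.random.default_rng(c) for c in ss.spawn(6)]
        self.r = ReconstructorNet(config, rng_r, dropout_rng=rng_dr)
        self.s = SegmenterNet(config, rng_s, dropout_rng=rng_ds)
        self.d = DiscriminatorNet(config, rng_d, input_hw)
        self.t = TransferBlock(config, rng_t)

    # -- modes --------------------------------------------------------------

    def train(self):
        for net in (self.r, self.s, self.d, self.t):
            net.train()
        return self

    def eval(self):
        for net in (self.r, self.s, self.d, self.t):
            net.eval()
        return self

    # -- persistence --------------------------------------------------------

    def state_dict(self) -> dict:
        out = {}
        for name, net in (("r", self.r), ("s", self.s), ("d", self.d), ("t", self.t)):
            for k, v in net.state_dict().items():
                out[f"{name}.{k}"] = v
        return out

    def load_state_dict(self, state: dict) -> None:
        for name, net in (("r", self.r), ("s", self.s), ("d", self.d), ("t", self.t)):
            prefix = name + "."
            sub = {k[len(prefix):]: v for k, v in state.items()
                   if k.startswith(prefix)}
            net.load_state_dict(sub)

    def save(self, path, rng_state: dict | None = None) -> None:
        meta = {
            "config": asdict(self.config),
            "seed": self.seed,
            "input_hw": list(self.input_hw),
            "step": self.step,
            "format_version": 1,
        }
        if rng_state is not None:
            meta["rng_state"] = rng_state
        arrays = {k.replace(".", "/"): v for k, v in self.state_dict().items()}
        np.savez_compressed(str(path), __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "ColNetModel":
        with np.load(str(path)) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            state = {k.replace("/", "."): archive[k] for k in archive.files
                     if k != "__meta__"}
        model = cls(NetworkConfig(**meta["config"]), meta["seed"],
                    tuple(meta["input_hw"]))
        model.step = meta["step"]
        model.load_state_dict(state)
        model._loaded_rng_state = meta.get("rng_state")
        return model


def build_model(config: NetworkConfig, seed: int,
                input_hw: tuple[int, int] = (64, 64)) -> ColNetModel:
    return ColNetModel(config, seed, input_hw)


# -- functional forward wrappers -------------------------------------------

def forward_segmenter(model: ColNetModel, batch,
                      fused_bottleneck: Tensor | None = None) -> Tensor:
    """Per-pixel class probabilities, (N, num_classes, H, W)."""
    return model.s(as_batch(batch), fused_bottleneck=fused_bottleneck)


def forward_reconstructor(model: ColNetModel, batch) -> tuple[Tensor, Tensor]:
    """(reconstruction in (-1,1), middle bottleneck feature)."""
    return model.r(as_batch(batch))


def forward_discriminator(model: ColNetModel, batch) -> Tensor:
    """(N, 2) softmax pairs interpreted as (P(reconstructed), P(real))."""
    return model.d(as_batch(batch))
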