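"""Segmentation architectures: the parallel multi-scale model and a U-net baseline.

The proposed model has two parts:

* **Feature Extraction Network (FEN)** — a five-stage encoder of conv units
  (3x3 conv, stride 1, same padding -> BN -> ReLU).  Stage 1 has four units,
  stages 2-5 have two (twelve conv layers in total); stages 1-4 end with a
  2x2 stride-2 max pool followed by dropout.  Eight feature maps are tapped:
  all four stage-1 unit outputs at full resolution, plus the last-unit output
  of stages 2-5 at 1/2, 1/4, 1/8 and 1/16 resolution.

* **Multi-scale Feature Fusing Network (MSFFN)** — the lower-resolution taps
  are up-sampled bilinearly (2x/4x/8x/16x) back to the input size, all eight
  maps are concatenated along channels (4*16 + 32 + 64 + 128 + 256 = 544 with
  the default widths), fused by three conv units at width 64, passed through
  dropout and a 1x1 conv to 5 classes, and normalized by a softmax.

Default channel widths (16, 32, 64, 128, 256) and fusing width 64 are chosen
so the total parameter storage (kernels, biases and the four BN values per
channel at 4 bytes each) prints as 6.3 MB, while preserving the conventional
doubling pattern.  The baseline is a standard U-net with encoder channels
(32, 64, 128, 256, 512), skip concatenations and a bilinear-upsampling
decoder, sharing the same input/output contract.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .nn import (
    F32,
    BilinearUpsample,
    Conv2d,
    ConvUnit,
    Dropout,
    Layer,
    MaxPool2x2,
    Param,
    Softmax,
)

NUM_STAGES = 5


@dataclass
class NetConfig:
    """Architecture hyper-parameters of the multi-scale fusion model."""

    input_size: int = 176
    in_channels: int = 4
    num_classes: int = 5
    stage_channels: tuple[int, ...] = (16, 32, 64, 128, 256)
    stage_units: tuple[int, ...] = (4, 2, 2, 2, 2)
    fusing_channels: int = 64
    dropout_rate: float = 0.2
    padding_mode: str = "zeros"
    seed: int = 0

    def __post_init__(self) -> None:
        self.stage_channels = tuple(int(c) for c in self.stage_channels)
        self.stage_units = tuple(int(u) for u in self.stage_units)
        if self.input_size % 16 != 0:
            raise ValueError(
                f"input_size must be divisible by 16 (four 2x poolings), got {self.input_size}"
            )
        if len(self.stage_channels) != NUM_STAGES or len(self.stage_units) != NUM_STAGES:
            raise ValueError("stage_channels and stage_units must have five entries")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


class _Network(Layer):
    """Base with parameter/state enumeration, dropout reseeding and snapshots."""

    def iter_layers(self):  # pragma: no cover - overridden
        raise NotImplementedError

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.iter_layers():
            out.extend(layer.params())
        return out

    def state(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.iter_layers():
            out.extend(layer.state())
        return out

    def reseed_dropout(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        for layer in self.iter_layers():
            if isinstance(layer, Dropout):
                layer.rng = rng

    def snapshot(self) -> list[np.ndarray]:
        return [a.copy() for a in [p.data for p in self.params()] + self.state()]

    def restore(self, arrays: Sequence[np.ndarray]) -> None:
        targets = [p.data for p in self.params()] + self.state()
        if len(arrays) != len(targets):
            raise ValueError("snapshot does not match network structure")
        for dst, src in zip(targets, arrays):
            dst[...] = src


class FeatureExtractionNetwork(_Network):
    """Five-stage encoder exposing the eight-tap feature set."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.stages: list[list[ConvUnit]] = []
        cin = cfg.in_channels
        for s in range(NUM_STAGES):
            units = []
            for _ in range(cfg.stage_units[s]):
                units.append(ConvUnit(cin, cfg.stage_channels[s], rng=rng,
                                      padding_mode=cfg.padding_mode))
                cin = cfg.stage_channels[s]
            self.stages.append(units)
        self.pools = [MaxPool2x2() for _ in range(NUM_STAGES - 1)]
        self.dropouts = [Dropout(cfg.dropout_rate) for _ in range(NUM_STAGES - 1)]

    @property
    def num_conv_layers(self) -> int:
        return sum(len(units) for units in self.stages)

    @property
    def tap_channels(self) -> tuple[int, ...]:
        c = self.cfg.stage_channels
        return (c[0],) * self.cfg.stage_units[0] + tuple(c[1:])

    @property
    def tap_resolutions(self) -> tuple[int, ...]:
        s = self.cfg.input_size
        return (s,) * self.cfg.stage_units[0] + tuple(s >> (i + 1) for i in range(NUM_STAGES - 1))

    def iter_layers(self):
        for s in range(NUM_STAGES):
            yield from self.stages[s]
            if s < NUM_STAGES - 1:
                yield self.pools[s]
                yield self.dropouts[s]

    def forward(self, x: np.ndarray, training: bool = False) -> list[np.ndarray]:
        taps: list[np.ndarray] = []
        for s, units in enumerate(self.stages):
            for u, unit in enumerate(units):
                x = unit.forward(x, training)
                if s == 0 or u == len(units) - 1:
                    taps.append(x)
            if s < NUM_STAGES - 1:
                x = self.pools[s].forward(x, training)
                x = self.dropouts[s].forward(x, training)
        return taps

    def backward(self, d_taps: Sequence[np.ndarray]) -> np.ndarray:
        d: Optional[np.ndarray] = None
        tap_i = len(d_taps) - 1
        for s in reversed(range(NUM_STAGES)):
            if s < NUM_STAGES - 1:
                d = self.dropouts[s].backward(d)
                d = self.pools[s].backward(d)
            units = self.stages[s]
            for u in reversed(range(len(units))):
                if s == 0 or u == len(units) - 1:
                    dt = d_taps[tap_i]
                    tap_i -= 1
                    d = dt if d is None else d + dt
                d = units[u].backward(d)
        return d


class MultiScaleFusingNetwork(_Network):
    """Parallel fusion head: upsample taps, concatenate, fuse, classify."""

    N_FUSE_UNITS = 3

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        self.cfg = cfg
        wrap = cfg.padding_mode == "circular"
        self.upsamples = [BilinearUpsample(2 ** (i + 1), wrap=wrap)
                          for i in range(NUM_STAGES - 1)]
        c = cfg.stage_channels
        self.concat_channels = cfg.stage_units[0] * c[0] + sum(c[1:])
        self.fuse_units: list[ConvUnit] = []
        cin = self.concat_channels
        for _ in range(self.N_FUSE_UNITS):
            self.fuse_units.append(ConvUnit(cin, cfg.fusing_channels, rng=rng,
                                            padding_mode=cfg.padding_mode))
            cin = cfg.fusing_channels
        self.dropout = Dropout(cfg.dropout_rate)
        self.classifier = Conv2d(cfg.fusing_channels, cfg.num_classes, ksize=1, rng=rng)
        self.softmax = Softmax()
        self._split: Optional[list[int]] = None

    def iter_layers(self):
        yield from self.upsamples
        yield from self.fuse_units
        yield self.dropout
        yield self.classifier
        yield self.softmax

    def forward(self, taps: Sequence[np.ndarray], training: bool = False) -> np.ndarray:
        n_full = self.cfg.stage_units[0]
        ups = list(taps[:n_full])
        for i, up in enumerate(self.upsamples):
            ups.append(up.forward(taps[n_full + i], training))
        target = ups[0].shape[1:3]
        for u in ups:
            assert u.shape[1:3] == target, "resolution mismatch after upsampling"
        self._split = [u.shape[-1] for u in ups]
        x = np.concatenate(ups, axis=-1)
        for unit in self.fuse_units:
            x = unit.forward(x, training)
        x = self.dropout.forward(x, training)
        logits = self.classifier.forward(x, training)
        return self.softmax.forward(logits, training)

    def backward(self, dP: np.ndarray) -> list[np.ndarray]:
        d = self.softmax.backward(dP)
        d = self.classifier.backward(d)
        d = self.dropout.backward(d)
        for unit in reversed(self.fuse_units):
            d = unit.backward(d)
        d_taps: list[np.ndarray] = []
        edges = np.cumsum([0] + self._split)
        n_full = self.cfg.stage_units[0]
        for i in range(len(self._split)):
            piece = np.ascontiguousarray(d[..., edges[i]:edges[i + 1]])
            if i < n_full:
                d_taps.append(piece)
            else:
                d_taps.append(self.upsamples[i - n_full].backward(piece))
        self._split = None
        return d_taps


class MSFFNet(_Network):
    """Full segmentation model: FEN encoder + MSFFN fusion head.

    All tensors are channels-last: ``forward`` maps (B, H, W, 4) inputs to
    (B, H, W, 5) softmax probability maps.
    """

    kind = "msffn"

    def __init__(self, cfg: NetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.fen = FeatureExtractionNetwork(cfg, rng)
        self.msffn = MultiScaleFusingNetwork(cfg, rng)
        self.reseed_dropout(cfg.seed + 1)

    def iter_layers(self):
        yield from self.fen.iter_layers()
        yield from self.msffn.iter_layers()

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        tap_mask: Optional[Sequence[bool]] = None,
    ) -> np.ndarray:
        x = np.asarray(x, dtype=F32)
        if x.ndim != 4 or x.shape[-1] != self.cfg.in_channels:
            raise ValueError(
                f"expected input (B, H, W, {self.cfg.in_channels}), got {x.shape}"
            )
        taps = self.fen.forward(np.ascontiguousarray(x), training)
        if tap_mask is not None:
            taps = [t if keep else np.zeros_like(t) for t, keep in zip(taps, tap_mask)]
        return self.msffn.forward(taps, training)

    def backward(self, dP: np.ndarray) -> np.ndarray:
        d_taps = self.msffn.backward(np.asarray(dP, dtype=F32))
        return self.fen.backward(d_taps)


class UNetBaseline(_Network):
    """Standard U-net with BN conv units and a bilinear-upsampling decoder."""

    kind = "unet"
    ENCODER_CHANNELS = (32, 64, 128, 256, 512)

    def __init__(self, cfg: NetConfig, encoder_channels: Optional[tuple[int, ...]] = None):
        self.cfg = cfg
        ch = tuple(encoder_channels or self.ENCODER_CHANNELS)
        if len(ch) != NUM_STAGES:
            raise ValueError("encoder_channels must have five entries")
        self.encoder_channels = ch
        rng = np.random.default_rng(cfg.seed)
        pm = cfg.padding_mode
        self.enc_stages: list[list[ConvUnit]] = []
        cin = cfg.in_channels
        for c in ch:
            self.enc_stages.append([ConvUnit(cin, c, rng=rng, padding_mode=pm),
                                    ConvUnit(c, c, rng=rng, padding_mode=pm)])
            cin = c
        self.pools = [MaxPool2x2() for _ in range(NUM_STAGES - 1)]
        self.enc_dropouts = [Dropout(cfg.dropout_rate) for _ in range(NUM_STAGES - 1)]
        wrap = pm == "circular"
        self.upsamples = [BilinearUpsample(2, wrap=wrap) for _ in range(NUM_STAGES - 1)]
        self.dec_stages: list[list[ConvUnit]] = []
        cin = ch[-1]
        for c in reversed(ch[:-1]):
            self.dec_stages.append([ConvUnit(cin + c, c, rng=rng, padding_mode=pm),
                                    ConvUnit(c, c, rng=rng, padding_mode=pm)])
            cin = c
        self.classifier = Conv2d(ch[0], cfg.num_classes, ksize=1, rng=rng)
        self.softmax = Softmax()
        self.reseed_dropout(cfg.seed + 1)

    def iter_layers(self):
        for s in range(NUM_STAGES):
            yield from self.enc_stages[s]
            if s < NUM_STAGES - 1:
                yield self.pools[s]
                yield self.enc_dropouts[s]
        for i in range(NUM_STAGES - 1):
            yield self.upsamples[i]
            yield from self.dec_stages[i]
        yield self.classifier
        yield self.softmax

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=F32)
        if x.ndim != 4 or x.shape[-1] != self.cfg.in_channels:
            raise ValueError(
                f"expected input (B, H, W, {self.cfg.in_channels}), got {x.shape}"
            )
        h = np.ascontiguousarray(x)
        skips: list[np.ndarray] = []
        for s in range(NUM_STAGES):
            for unit in self.enc_stages[s]:
                h = unit.forward(h, training)
            if s < NUM_STAGES - 1:
                skips.append(h)
                h = self.pools[s].forward(h, training)
                h = self.enc_dropouts[s].forward(h, training)
        self._skip_channels = [s.shape[-1] for s in skips]
        for i in range(NUM_STAGES - 1):
            h = self.upsamples[i].forward(h, training)
            h = np.concatenate([h, skips[-(i + 1)]], axis=-1)
            for unit in self.dec_stages[i]:
                h = unit.forward(h, training)
        logits = self.classifier.forward(h, training)
        return self.softmax.forward(logits, training)

    def backward(self, dP: np.ndarray) -> np.ndarray:
        d = self.softmax.backward(np.asarray(dP, dtype=F32))
        d = self.classifier.backward(d)
        d_skips: list[np.ndarray] = [None] * (NUM_STAGES - 1)  # type: ignore[list-item]
        for i in reversed(range(NUM_STAGES - 1)):
            for unit in reversed(self.dec_stages[i]):
                d = unit.backward(d)
            c_up = d.shape[-1] - self._skip_channels[-(i + 1)]
            d_skips[NUM_STAGES - 2 - i] = np.ascontiguousarray(d[..., c_up:])
            d = self.upsamples[i].backward(np.ascontiguousarray(d[..., :c_up]))
        for s in reversed(range(NUM_STAGES)):
            if s < NUM_STAGES - 1:
                d = self.enc_dropouts[s].backward(d)
                d = self.pools[s].backward(d)
                d = d + d_skips[s]
            for unit in reversed(self.enc_stages[s]):
                d = unit.backward(d)
        return d


def build_fen(cfg: NetConfig) -> FeatureExtractionNetwork:
    return FeatureExtractionNetwork(cfg, np.random.default_rng(cfg.seed))


def build_msffn(cfg: NetConfig) -> MultiScaleFusingNetwork:
    """Build the fusion head alone; it consumes the tap set of a matching FEN."""
    return MultiScaleFusingNetwork(cfg, np.random.default_rng(cfg.seed))


def build_model(cfg: Optional[NetConfig] = None) -> MSFFNet:
    return MSFFNet(cfg or NetConfig())


def build_unet_baseline(cfg: Optional[NetConfig] = None) -> UNetBaseline:
    return UNetBaseline(cfg or NetConfig())


def count_parameters(network: _Network) -> tuple[int, int]:
    """(parameter count, bytes at 32-bit).

    Counts every convolution kernel and bias plus all four batch-norm values
    per channel (scale, shift, moving mean, moving variance), the usual
    framework "total parameters" convention.
    """
    count = sum(p.data.size for p in network.params())
    count += sum(a.size for a in network.state())
    return count, 4 * count


def parameter_megabytes(network: _Network) -> float:
    """Parameter storage in decimal megabytes."""
    return count_parameters(network)[1] / 1e6


def save_checkpoint(network: _Network, path: Union[str, Path]) -> Path:
    """Serialize weights + config; format follows the network's ``kind``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"kind": network.kind, "config": asdict(network.cfg)}
    if network.kind == "unet":
        meta["encoder_channels"] = list(network.encoder_channels)  # type: ignore[attr-defined]
    arrays = {f"a{i}": a for i, a in enumerate(network.snapshot())}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def load_checkpoint(path: Union[str, Path]) -> _Network:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such checkpoint: {path}")
    with np.load(path) as zf:
        meta = json.loads(bytes(zf["__meta__"]).decode())
        cfg = NetConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in meta["config"].items()})
        if meta["kind"] == "msffn":
            net: _Network = MSFFNet(cfg)
        elif meta["kind"] == "unet":
            net = UNetBaseline(cfg, tuple(meta.get("encoder_channels") or ()) or None)
        else:
            raise ValueError(f"unknown checkpoint kind {meta['kind']!r}")
        arrays = [zf[f"a{i}"] for i in range(len(zf.files) - 1)]
    net.restore(arrays)
    return net
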