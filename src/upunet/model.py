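"""Restoration-network architectures.

Two encoder-decoder networks for background-emission removal:

* :class:`UpUNet` — the primary architecture.  The contracting path is L
  blocks of [3x3 stride-2 convolution (symmetric, edge-excluding padding),
  batch norm, ReLU], doubling the channel count from ``f0`` each block.  The
  expansive path is L blocks of [2x2 stride-2 transposed convolution, ReLU],
  halving channels from ``f0 * 2**(L-1)``.  Instead of the classical
  same-level skip, encoder level ``l`` is routed through its own 2x2
  stride-2 transposed convolution (channel-preserving) + ReLU and added
  element-wise to the output of the expansive block that is one spatial
  level finer than the encoder activation — the learned up-convolutions on
  the skips act as smoothing filters.  A 1x1 convolution + ReLU collapses
  the last block's filters into the non-negative restored image.

* :class:`BaselineUNet` — a classical 3-level U-net regression network with
  max-pooling, concatenation skips, dropout before the deepest pooling, and
  batch normalization inserted after each conv+ReLU pair.

With L=5 and f0=8 the upU-net has 295,593 learnable parameters; the depth-3
baseline with f0=8 has 121,385 — both close to the two published
approximate counts for these configurations, which pins down the otherwise
unstated transposed-convolution kernel size (2x2) and additive skip merge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .nn import (
    DTYPE,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Dropout,
    Layer,
    MaxPool2d,
    Param,
    ReLU,
)


@dataclass(frozen=True)
class UpUNetSpec:
    """Architecture description: L blocks, first-block filter count f0.

    Encoder channels are ``f0 * 2**(l-1)`` for blocks l=1..L; decoder output
    channels ``f0 * 2**(L-j)`` for blocks j=1..L.  Input spatial size must be
    divisible by ``2**L``.
    """

    blocks: int = 5
    f0: int = 8

    def __post_init__(self) -> None:
        if self.blocks < 1 or self.f0 < 1:
            raise ValueError("blocks and f0 must be >= 1")

    @property
    def encoder_channels(self) -> tuple[int, ...]:
        return tuple(self.f0 * 2 ** l for l in range(self.blocks))

    @property
    def decoder_channels(self) -> tuple[int, ...]:
        return tuple(reversed(self.encoder_channels))


@dataclass(frozen=True)
class BaselineUNetSpec:
    """Classical U-net: encoder depth, first filter count, dropout prob."""

    depth: int = 3
    f0: int = 8
    dropout: float = 0.5

    @property
    def encoder_channels(self) -> tuple[int, ...]:
        return tuple(self.f0 * 2 ** l for l in range(self.depth))

    @property
    def bridge_channels(self) -> int:
        return self.f0 * 2 ** self.depth


class ShapeError(ValueError):
    """Input spatial size incompatible with the network's downsampling."""


class Network:
    """Base class: parameter bookkeeping and checkpointing shared by both nets."""

    levels: int  # input size must be divisible by 2**levels
    spec: object

    def layers(self) -> list[Layer]:
        raise NotImplementedError

    def params(self) -> list[Param]:
        out = []
        for layer in self.layers():
            out.extend(layer.params())
        return out

    def buffers(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for layer in self.layers():
            out.update(layer.buffers())
        return out

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        raise NotImplementedError

    def check_input(self, x: np.ndarray) -> None:
        h, w = x.shape[-2:]
        d = 2 ** self.levels
        if h % d or w % d:
            raise ShapeError(
                f"input size {h}x{w} not divisible by 2^{self.levels}={d}; "
                f"pad or crop the frame to a multiple of {d}"
            )

    # -- persistence ------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {p.name: p.value for p in self.params()}
        arrays.update(self.buffers())
        return arrays

    def save(self, path) -> None:
        """Checkpoint: JSON-described spec plus the weight arrays (npz)."""
        header = {"kind": type(self).__name__, "spec": asdict(self.spec)}
        np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
                 **self.state_arrays())

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = arrays[p.name]
        for name, buf in self.buffers().items():
            buf[...] = arrays[name]


def load_checkpoint(path) -> "Network":
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__header__"}
    if header["kind"] == "UpUNet":
        net = build_upunet(UpUNetSpec(**header["spec"]))
    elif header["kind"] == "BaselineUNet":
        net = build_baseline_unet(BaselineUNetSpec(**header["spec"]))
    else:
        raise ValueError(f"unknown checkpoint kind {header['kind']!r}")
    net.load_state(arrays)
    return net


class UpUNet(Network):
    def __init__(self, spec: UpUNetSpec, seed: int = 0):
        self.spec = spec
        self.levels = spec.blocks
        rng = np.random.default_rng(seed)
        L = spec.blocks
        enc_c = spec.encoder_channels
        dec_c = spec.decoder_channels

        self.enc_convs: list[Conv2d] = []
        self.enc_bns: list[BatchNorm2d] = []
        self.enc_relus: list[ReLU] = []
        c_prev = 1
        for l, c in enumerate(enc_c, start=1):
            self.enc_convs.append(Conv2d(c_prev, c, 3, stride=2, pad=1, rng=rng, name=f"enc{l}.conv"))
            self.enc_bns.append(BatchNorm2d(c, name=f"enc{l}.bn"))
            self.enc_relus.append(ReLU())
            c_prev = c

        self.dec_convs: list[ConvTranspose2d] = []
        self.dec_relus: list[ReLU] = []
        d_prev = enc_c[-1]
        for j, d in enumerate(dec_c, start=1):
            self.dec_convs.append(ConvTranspose2d(d_prev, d, 2, 2, rng=rng, name=f"dec{j}.upconv"))
            self.dec_relus.append(ReLU())
            d_prev = d

        # one channel-preserving up-convolution per encoder level
        self.skip_convs: list[ConvTranspose2d] = []
        self.skip_relus: list[ReLU] = []
        for l, c in enumerate(enc_c, start=1):
            self.skip_convs.append(ConvTranspose2d(c, c, 2, 2, rng=rng, name=f"skip{l}.upconv"))
            self.skip_relus.append(ReLU())

        self.head_conv = Conv2d(dec_c[-1], 1, 1, stride=1, pad=0, rng=rng, name="head.conv")
        # a small positive head bias keeps the output ReLU alive at init
        # (a dead head would zero every gradient and the net could not train)
        self.head_conv.bias.value[...] = 1.0
        self.head_relu = ReLU()

    def layers(self):
        return (self.enc_convs + self.enc_bns + self.dec_convs
                + self.skip_convs + [self.head_conv])

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self.check_input(x)
        L = self.spec.blocks
        E: list[np.ndarray] = []
        h = np.ascontiguousarray(x, dtype=DTYPE)
        for conv, bn, relu in zip(self.enc_convs, self.enc_bns, self.enc_relus):
            h = relu.forward(bn.forward(conv.forward(h, training), training), training)
            E.append(h)
        d = E[-1]
        for j in range(L):
            d = self.dec_relus[j].forward(self.dec_convs[j].forward(d, training), training)
            l = L - j  # 0-based index of the encoder level merging at this stage
            s = self.skip_relus[l - 1].forward(
                self.skip_convs[l - 1].forward(E[l - 1], training), training)
            d = d + s
        return self.head_relu.forward(self.head_conv.forward(d, training), training)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        L = self.spec.blocks
        dd = self.head_conv.backward(self.head_relu.backward(dout))
        dE: list[np.ndarray | None] = [None] * L
        for j in reversed(range(L)):
            l = L - j
            ds = self.skip_convs[l - 1].backward(self.skip_relus[l - 1].backward(dd))
            dE[l - 1] = ds if dE[l - 1] is None else dE[l - 1] + ds
            dd = self.dec_convs[j].backward(self.dec_relus[j].backward(dd))
        dE[L - 1] = dd if dE[L - 1] is None else dE[L - 1] + dd
        g = None
        for l in reversed(range(L)):
            g = dE[l] if g is None else dE[l] + g
            g = self.enc_convs[l].backward(
                self.enc_bns[l].backward(self.enc_relus[l].backward(g)))
        return g


class BaselineUNet(Network):
    def __init__(self, spec: BaselineUNetSpec, seed: int = 0):
        self.spec = spec
        self.levels = spec.depth
        rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(seed + 1)

        def unit(c_in, c_out, name):
            return [Conv2d(c_in, c_out, 3, stride=1, pad=1, rng=rng, name=f"{name}.conv"),
                    ReLU(), BatchNorm2d(c_out, name=f"{name}.bn")]

        enc_c = spec.encoder_channels
        self.enc_blocks: list[list[Layer]] = []
        c_prev = 1
        for l, c in enumerate(enc_c, start=1):
            self.enc_blocks.append(unit(c_prev, c, f"enc{l}a") + unit(c, c, f"enc{l}b"))
            c_prev = c
        self.dropout = Dropout(spec.dropout, rng=self.dropout_rng)
        self.pools = [MaxPool2d(2) for _ in enc_c]
        cb = spec.bridge_channels
        self.bridge = unit(c_prev, cb, "bridge_a") + unit(cb, cb, "bridge_b")

        self.dec_upconvs: list[ConvTranspose2d] = []
        self.dec_uprelus: list[ReLU] = []
        self.dec_blocks: list[list[Layer]] = []
        c_prev = cb
        for j, c in enumerate(reversed(enc_c), start=1):
            self.dec_upconvs.append(ConvTranspose2d(c_prev, c, 2, 2, rng=rng, name=f"dec{j}.upconv"))
            self.dec_uprelus.append(ReLU())
            self.dec_blocks.append(unit(2 * c, c, f"dec{j}a") + unit(c, c, f"dec{j}b"))
            c_prev = c
        self.head_conv = Conv2d(spec.f0, 1, 1, stride=1, pad=0, rng=rng, name="head.conv")

    def layers(self):
        out: list[Layer] = []
        for blk in self.enc_blocks:
            out.extend(blk)
        out.extend(self.bridge)
        out.extend(self.dec_upconvs)
        for blk in self.dec_blocks:
            out.extend(blk)
        out.append(self.head_conv)
        return out

    @staticmethod
    def _run_block(block, x, training):
        for layer in block:
            x = layer.forward(x, training)
        return x

    @staticmethod
    def _back_block(block, d):
        for layer in reversed(block):
            d = layer.backward(d)
        return d

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self.check_input(x)
        h = np.ascontiguousarray(x, dtype=DTYPE)
        skips = []
        for l, blk in enumerate(self.enc_blocks):
            h = self._run_block(blk, h, training)
            skips.append(h)
            if l == len(self.enc_blocks) - 1:
                h = self.dropout.forward(h, training)
            h = self.pools[l].forward(h, training)
        h = self._run_block(self.bridge, h, training)
        self._skip_channels = [s.shape[1] for s in skips]
        for j in range(len(self.dec_blocks)):
            h = self.dec_uprelus[j].forward(self.dec_upconvs[j].forward(h, training), training)
            skip = skips[-(j + 1)]
            h = np.concatenate([skip, h], axis=1)
            h = self._run_block(self.dec_blocks[j], h, training)
        return self.head_conv.forward(h, training)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.head_conv.backward(dout)
        dskips: list[np.ndarray | None] = [None] * len(self.enc_blocks)
        for j in reversed(range(len(self.dec_blocks))):
            d = self._back_block(self.dec_blocks[j], d)
            c = self._skip_channels[-(j + 1)]
            dskip, d = d[:, :c], d[:, c:]
            i = len(self.enc_blocks) - 1 - j
            dskips[i] = dskip if dskips[i] is None else dskips[i] + dskip
            d = self.dec_upconvs[j].backward(self.dec_uprelus[j].backward(d))
        d = self._back_block(self.bridge, d)
        for l in reversed(range(len(self.enc_blocks))):
            d = self.pools[l].backward(d)
            if l == len(self.enc_blocks) - 1:
                d = self.dropout.backward(d)
            d = d + dskips[l]
            d = self._back_block(self.enc_blocks[l], d)
        return d


def build_upunet(spec: UpUNetSpec | None = None, seed: int = 0) -> UpUNet:
    """Construct a seeded upU-net (default: 5 blocks, 8 first-block filters)."""
    return UpUNet(spec or UpUNetSpec(), seed=seed)


def build_baseline_unet(spec: BaselineUNetSpec | None = None, seed: int = 0) -> BaselineUNet:
    """Construct the seeded classical 3-level U-net baseline."""
    return BaselineUNet(spec or BaselineUNetSpec(), seed=seed)


def count_parameters(network: Network) -> int:
    """Total learnable parameters (batch-norm running statistics excluded)."""
    return int(sum(p.size for p in network.params()))


def parameter_table(network: Network):
    """Per-parameter summary (name, shape, count) as a pandas DataFrame."""
    import pandas as pd

    rows = [{"name": p.name, "shape": "x".join(map(str, p.value.shape)), "count": p.size}
            for p in network.params()]
    return pd.DataFrame(rows)


def restore_frame(network: Network, frame: np.ndarray) -> np.ndarray:
    """Restore a single 2D frame (inference mode, batch-norm running stats)."""
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("restore_frame expects a 2D frame")
    out = network.forward(frame[None, None].astype(DTYPE), training=False)
    return out[0, 0].astype(np.float64)


def restore_frames(network: Network, frames, batch_size: int = 16) -> list[np.ndarray]:
    """Restore a sequence of equally shaped frames in mini-batches."""
    frames = [np.asarray(f) for f in frames]
    out: list[np.ndarray] = []
    for i in range(0, len(frames), batch_size):
        batch = np.stack(frames[i:i + batch_size])[:, None].astype(DTYPE)
        pred = network.forward(batch, training=False)
        out.extend(pred[:, 0].astype(np.float64))
    return out
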