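"""3D residual U-Net for single-volume super-resolution.

A multi-scale encoder/decoder of 3x3x3 convolutions with ReLU
nonlinearities.  The encoder halves the grid per level (max pooling by
default), the decoder mirrors it with nearest-neighbour upsampling followed
by a convolution, and skip connections concatenate encoder features into the
decoder at matching scales.  The last convolution produces a single-channel
*residual* with no nonlinearity; the residual is added to the input and the
sum is projected to non-negative values by a final ReLU, since magnitude MR
images cannot be negative.  Setting ``residual=False`` turns the same trunk
into a plain U-Net that predicts the output directly — the comparator
configuration rather than the default.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .nn import Adam, Conv3d, MaxPool2x, MeanPool2x, ReLU, UpsampleNearest2x
from .volume import Volume

__all__ = ["NetworkConfig", "Network", "build_network", "super_resolve"]

_F32 = np.float32


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``levels`` resolution scales with ``base_channels`` filters at the finest
    scale, doubling per level.  The kernel is fixed at 3x3x3; filters are
    isotropic so no spatial direction is favoured.
    """

    levels: int = 3
    base_channels: int = 16
    convs_per_level: int = 2
    residual: bool = True
    nonneg_output: bool = True
    downsample: str = "max"  # or "mean"
    zero_init_final: bool = True
    seed: int = 0
    kernel: tuple[int, int, int] = (3, 3, 3)

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError(f"levels must be >= 1, got {self.levels}")
        if self.base_channels < 1:
            raise ValueError(f"base_channels must be >= 1, got {self.base_channels}")
        if self.convs_per_level < 1:
            raise ValueError(f"convs_per_level must be >= 1, got {self.convs_per_level}")
        if tuple(self.kernel) != (3, 3, 3):
            raise ValueError("kernel is fixed at (3, 3, 3)")
        if self.downsample not in ("max", "mean"):
            raise ValueError(f"downsample must be 'max' or 'mean', got {self.downsample!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kernel"] = list(self.kernel)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["kernel"] = tuple(d.get("kernel", (3, 3, 3)))
        return cls(**d)


class Network:
    """Parameter container + forward/backward for the residual U-Net.

    Use :func:`build_network` to construct one.  ``apply``/``super_resolve``
    handle arbitrary grids by symmetric zero-padding to a multiple of
    ``2**(levels-1)``; ``forward``/``backward`` are the training-time entry
    points and cache activations between calls.
    """

    def __init__(self, config: NetworkConfig):
        self.config = config
        self.provenance: dict = {}
        rng = np.random.default_rng(config.seed)
        L, B, K = config.levels, config.base_channels, config.convs_per_level
        pool_cls = MaxPool2x if config.downsample == "max" else MeanPool2x

        self.enc: list[list] = []
        for l in range(L):
            ch = B * 2**l
            cin = 1 if l == 0 else B * 2 ** (l - 1)
            block = [Conv3d(cin, ch, rng), ReLU()]
            for _ in range(K - 1):
                block += [Conv3d(ch, ch, rng), ReLU()]
            self.enc.append(block)
        self.pools = [pool_cls() for _ in range(L - 1)]

        self.ups: list[UpsampleNearest2x] = []
        self.upconv: list[Conv3d] = []
        self.uprelu: list[ReLU] = []
        self.dec: list[list] = []
        for i in range(L - 1):
            l = L - 2 - i  # target level of this decoder block
            ch = B * 2**l
            self.ups.append(UpsampleNearest2x())
            self.upconv.append(Conv3d(ch * 2, ch, rng))
            self.uprelu.append(ReLU())
            block = [Conv3d(ch * 2, ch, rng), ReLU()]
            for _ in range(K - 1):
                block += [Conv3d(ch, ch, rng), ReLU()]
            self.dec.append(block)

        self.final = Conv3d(B, 1, rng)
        if config.zero_init_final:
            # start exactly at the identity: the residual is zero until the
            # optimizer moves the last layer, so early epochs only improve
            self.final.W[...] = 0
            self.final.b[...] = 0
        self._convs: list[Conv3d] = [
            layer
            for block in self.enc
            for layer in block
            if isinstance(layer, Conv3d)
        ]
        self._convs += self.upconv
        self._convs += [layer for block in self.dec for layer in block if isinstance(layer, Conv3d)]
        self._convs.append(self.final)

    # -- parameters ---------------------------------------------------------

    def params(self):
        out = []
        for conv in self._convs:
            out.extend(conv.params())
        return out

    @property
    def parameter_count(self) -> int:
        return int(sum(p.size for p, _ in self.params()))

    def zero_residual_(self) -> "Network":
        """Zero the final layer so the network acts as the identity
        (for non-negative input, in residual mode)."""
        self.final.W[...] = 0
        self.final.b[...] = 0
        return self

    # -- forward / backward -------------------------------------------------

    @property
    def _grid_factor(self) -> int:
        return 2 ** (self.config.levels - 1)

    def _pad_amounts(self, shape):
        f = self._grid_factor
        pads = []
        for n in shape:
            m = (-n) % f
            pads.append((m // 2, m - m // 2))
        return pads

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        """x: (D, H, W) non-negative float array -> output of same shape.

        With ``cache=True`` activations are kept for a subsequent
        :meth:`backward`; inference should pass ``cache=False``.
        """
        x = np.asarray(x, dtype=_F32)
        if x.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {x.shape}")
        if x.size and x.min() < 0:
            raise ValueError("network input must be non-negative (magnitude images)")
        self._pads = self._pad_amounts(x.shape)
        self._in_shape = x.shape
        xp = np.pad(x, self._pads)[None]  # (1, D', H', W')
        self._x = xp

        L = self.config.levels
        skips = []
        h = xp
        for l in range(L):
            for layer in self.enc[l]:
                h = layer.forward(h, cache)
            if l < L - 1:
                skips.append(h)
                h = self.pools[l].forward(h, cache)
        self._nskip = []
        for i in range(L - 1):
            l = L - 2 - i
            h = self.ups[i].forward(h, cache)
            h = self.uprelu[i].forward(self.upconv[i].forward(h, cache), cache)
            self._nskip.append(skips[l].shape[0])
            h = np.concatenate([skips[l], h], axis=0)
            for layer in self.dec[i]:
                h = layer.forward(h, cache)
        res = self.final.forward(h, cache)

        pre = xp + res if self.config.residual else res
        if self.config.nonneg_output:
            self._out_mask = pre > 0
            out = np.where(self._out_mask, pre, _F32(0))
        else:
            self._out_mask = None
            out = pre
        self._residual = res
        sl = tuple(slice(p0, p0 + n) for (p0, _), n in zip(self._pads, self._in_shape))
        return out[0][sl]

    def backward(self, g_out: np.ndarray) -> None:
        """Accumulate parameter gradients for d(loss)/d(output) ``g_out``."""
        g = np.zeros(self._x.shape, dtype=_F32)
        sl = tuple(slice(p0, p0 + n) for (p0, _), n in zip(self._pads, self._in_shape))
        g[0][sl] = g_out.astype(_F32)
        if self._out_mask is not None:
            g = np.where(self._out_mask, g, _F32(0))
        # in residual mode the input branch of (x + res) carries no parameters
        L = self.config.levels
        gskips: dict[int, np.ndarray] = {}
        g_dec = self.final.backward(g)
        for i in range(L - 2, -1, -1):
            l = L - 2 - i
            for layer in reversed(self.dec[i]):
                g_dec = layer.backward(g_dec)
            nskip = self._nskip[i]
            gskips[l] = g_dec[:nskip]
            g_dec = g_dec[nskip:]
            g_dec = self.ups[i].backward(self.upconv[i].backward(self.uprelu[i].backward(g_dec)))
        for l in range(L - 1, -1, -1):
            for layer in reversed(self.enc[l]):
                g_dec = layer.backward(g_dec)
            if l > 0:
                g_dec = self.pools[l - 1].backward(g_dec)
                g_dec = g_dec + gskips[l - 1]

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0

    # -- inference ----------------------------------------------------------

    def apply(self, data: np.ndarray) -> np.ndarray:
        """Deterministic inference on a (D, H, W) array (no activation cache)."""
        return self.forward(data, cache=False)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        arrays = {}
        for i, conv in enumerate(self._convs):
            arrays[f"W_{i}"] = conv.W
            arrays[f"b_{i}"] = conv.b
        arrays["config_json"] = np.frombuffer(
            json.dumps(self.config.to_dict(), sort_keys=True).encode(), dtype=np.uint8
        )
        arrays["provenance_json"] = np.frombuffer(
            json.dumps(self.provenance, sort_keys=True).encode(), dtype=np.uint8
        )
        np.savez(str(path), **arrays)

    @classmethod
    def load(cls, path) -> "Network":
        with np.load(str(path)) as f:
            config = NetworkConfig.from_dict(json.loads(bytes(f["config_json"]).decode()))
            net = cls(config)
            for i, conv in enumerate(net._convs):
                conv.W[...] = f[f"W_{i}"]
                conv.b[...] = f[f"b_{i}"]
            net.provenance = json.loads(bytes(f["provenance_json"]).decode())
        return net


def build_network(config: NetworkConfig) -> Network:
    """Construct a seeded, deterministically initialized residual U-Net."""
    return Network(config)


def super_resolve(net: Network, vol: Volume) -> Volume:
    """Apply the network to a normalized magnitude volume.

    Output has the input's shape and spacing and is non-negative (when the
    network projects its output, which is the default).
    """
    if vol.data.size and vol.data.min() < 0:
        raise ValueError("super_resolve requires a non-negative magnitude volume")
    out = net.apply(np.asarray(vol.data, dtype=_F32))
    out = np.asarray(out, dtype=np.float64)
    return Volume(data=out, spacing=vol.spacing, normalized=bool(out.max() <= 1 + 1e-9) if out.size else True)
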