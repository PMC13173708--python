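"""A minimal 3D convolutional network framework in numpy.

Implements exactly the pieces the cascaded dose-prediction models need
— 3D convolutions via im2col, ReLU/softplus, 2x average-pool
downsampling, nearest-neighbour upsampling, plain and residual
encoder–decoder (U-Net) assemblies, and Adam — with hand-written
backward passes.  Single-sample (batch-free) training is intentional:
whole volumes are one training example each.

All layers are stateful across one forward/backward pair; a layer
instance appears exactly once in a network.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np


class ShapeError(ValueError):
    """Input tensor incompatible with the network configuration."""


class Conv3d:
    """'Same' 3D cross-correlation, kernel k^3, stride 1.

    Implemented as one small GEMM per kernel offset over a zero-padded
    copy of the input — much cheaper in time and memory than a full
    im2col unfold at these volume sizes.
    """

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator,
                 zero_init: bool = False, dtype=np.float32):
        self.cin, self.cout, self.ksize = cin, cout, ksize
        fan_in = cin * ksize**3
        if zero_init:
            w = np.zeros((cout, cin, ksize, ksize, ksize))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin, ksize, ksize, ksize))
        self.params = {"W": w.astype(dtype), "b": np.zeros(cout, dtype=dtype)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._xp: Optional[np.ndarray] = None

    def _offsets(self):
        k = self.ksize
        return [(a, b, c) for a in range(k) for b in range(k) for c in range(k)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[0] != self.cin:
            raise ShapeError(f"Conv3d expected {self.cin} input channels, got {x.shape[0]}")
        self._in_shape = x.shape
        d, h, w_ = x.shape[1:]
        pad = (self.ksize - 1) // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad))) if pad else x
        self._xp = xp
        n = d * h * w_
        wt = self.params["W"]
        y = np.broadcast_to(self.params["b"][:, None], (self.cout, n)).copy()
        for a, b, c in self._offsets():
            xs = xp[:, a:a + d, b:b + h, c:c + w_].reshape(self.cin, n)
            y += wt[:, :, a, b, c] @ xs
        return y.reshape(self.cout, d, h, w_)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d, h, w_ = self._in_shape[1:]
        n = d * h * w_
        dyf = dy.reshape(self.cout, n)
        self.grads["b"] += dyf.sum(axis=1)
        xp = self._xp
        self._xp = None
        wt = self.params["W"]
        dW = self.grads["W"]
        dxp = np.zeros_like(xp)
        for a, b, c in self._offsets():
            xs = xp[:, a:a + d, b:b + h, c:c + w_].reshape(self.cin, n)
            dW[:, :, a, b, c] += dyf @ xs.T
            dxp[:, a:a + d, b:b + h, c:c + w_] += (wt[:, :, a, b, c].T @ dyf).reshape(
                self.cin, d, h, w_
            )
        pad = (self.ksize - 1) // 2
        if pad:
            return dxp[:, pad:-pad, pad:-pad, pad:-pad]
        return dxp


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Softplus:
    """Numerically stable softplus; guarantees a non-negative output."""

    def forward(self, x):
        self._x = x
        return np.logaddexp(0.0, x)

    def backward(self, dy):
        return dy * (0.5 * (1.0 + np.tanh(0.5 * self._x)))


class AvgPool2:
    """2x2x2 average pooling (requires even spatial dims)."""

    def forward(self, x):
        c, d, h, w = x.shape
        self._shape = x.shape
        return x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(2, 4, 6))

    def backward(self, dy):
        c, d, h, w = self._shape
        up = np.repeat(np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2), 2, axis=3)
        return up / 8.0


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        return np.repeat(np.repeat(np.repeat(x, 2, axis=1), 2, axis=2), 2, axis=3)

    def backward(self, dy):
        c, d, h, w = dy.shape
        return dy.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(2, 4, 6))


class ConvBlock:
    """conv-relu-conv(-residual)-relu."""

    def __init__(self, cin, cout, rng, residual=False, dtype=np.float32):
        self.residual = residual
        self.conv1 = Conv3d(cin, cout, 3, rng, dtype=dtype)
        self.conv2 = Conv3d(cout, cout, 3, rng, dtype=dtype)
        self.proj = Conv3d(cin, cout, 1, rng, dtype=dtype) if residual and cin != cout else None
        self.r1, self.r2 = ReLU(), ReLU()

    def forward(self, x):
        h = self.conv2.forward(self.r1.forward(self.conv1.forward(x)))
        if self.residual:
            h = h + (self.proj.forward(x) if self.proj is not None else x)
        return self.r2.forward(h)

    def backward(self, dy):
        dh = self.r2.backward(dy)
        dx_main = self.conv1.backward(self.r1.backward(self.conv2.backward(dh)))
        if not self.residual:
            return dx_main
        dx_skip = self.proj.backward(dh) if self.proj is not None else dh
        return dx_main + dx_skip

    def layers(self):
        out = {"conv1": self.conv1, "conv2": self.conv2}
        if self.proj is not None:
            out["proj"] = self.proj
        return out


class UNet3D:
    """Encoder–decoder with skip connections; optional residual blocks.

    ``depth`` is the number of 2x downsamplings, so every spatial input
    dimension must be divisible by ``2**depth``.  ``final_zero`` zeroes
    the output convolution (used by the refinement stage so that it
    starts as the identity correction).
    """

    def __init__(self, cin: int, width: int = 16, depth: int = 3, *,
                 residual: bool = False, final_zero: bool = False,
                 final_activation: str = "softplus", seed: int = 0,
                 dtype=np.float32):
        if width < 1 or depth < 1:
            raise ShapeError(f"invalid width/depth ({width}, {depth})")
        rng = np.random.default_rng(seed)
        self.cin, self.width, self.depth = cin, width, depth
        self.residual = residual
        self.final_activation = final_activation
        widths = [width * 2**i for i in range(depth + 1)]
        self.enc = [
            ConvBlock(cin if i == 0 else widths[i - 1], widths[i], rng, residual, dtype)
            for i in range(depth + 1)
        ]
        self.dec = [
            ConvBlock(widths[i + 1] + widths[i], widths[i], rng, residual, dtype)
            for i in reversed(range(depth))
        ]
        self.pools = [AvgPool2() for _ in range(depth)]
        self.ups = [Upsample2() for _ in range(depth)]
        self.final = Conv3d(widths[0], 1, 3, rng, zero_init=final_zero, dtype=dtype)
        self.final_act = Softplus() if final_activation == "softplus" else None

    # -- execution --------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[0] != self.cin:
            raise ShapeError(
                f"expected input of shape ({self.cin}, D, H, W), got {x.shape}"
            )
        div = 2**self.depth
        if any(s % div for s in x.shape[1:]):
            raise ShapeError(
                f"spatial shape {x.shape[1:]} not divisible by 2^depth={div}; "
                f"pad the grid or reduce the network depth"
            )
        skips = []
        h = x
        for i, blk in enumerate(self.enc):
            h = blk.forward(h)
            if i < self.depth:
                skips.append(h)
                h = self.pools[i].forward(h)
        self._cat_sizes: List[int] = []
        for j, blk in enumerate(self.dec):
            h = self.ups[j].forward(h)
            s = skips[self.depth - 1 - j]
            self._cat_sizes.append(s.shape[0])
            h = blk.forward(np.concatenate([s, h], axis=0))
        y = self.final.forward(h)
        if self.final_act is not None:
            y = self.final_act.forward(y)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.final_act is not None:
            dy = self.final_act.backward(dy)
        dh = self.final.backward(dy)
        skip_grads: Dict[int, np.ndarray] = {}
        for j in reversed(range(self.depth)):
            d_cat = self.dec[j].backward(dh)
            s_ch = self._cat_sizes[j]
            skip_grads[self.depth - 1 - j] = d_cat[:s_ch]
            dh = self.ups[j].backward(d_cat[s_ch:])
        for i in reversed(range(self.depth + 1)):
            if i < self.depth:
                dh = self.pools[i].backward(dh) + skip_grads[i]
            dh = self.enc[i].backward(dh)
        return dh

    # -- parameters -------------------------------------------------------
    def _named_layers(self) -> Dict[str, Conv3d]:
        out: Dict[str, Conv3d] = {}
        for i, blk in enumerate(self.enc):
            for name, layer in blk.layers().items():
                out[f"enc{i}.{name}"] = layer
        for j, blk in enumerate(self.dec):
            for name, layer in blk.layers().items():
                out[f"dec{j}.{name}"] = layer
        out["final"] = self.final
        return out

    def parameters(self) -> Dict[str, np.ndarray]:
        return {
            f"{lname}.{p}": arr
            for lname, layer in self._named_layers().items()
            for p, arr in layer.params.items()
        }

    def gradients(self) -> Dict[str, np.ndarray]:
        return {
            f"{lname}.{p}": arr
            for lname, layer in self._named_layers().items()
            for p, arr in layer.grads.items()
        }

    def zero_grads(self) -> None:
        for g in self.gradients().values():
            g[...] = 0.0

    def load_parameters(self, values: Dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(values)
        if missing:
            raise ShapeError(f"checkpoint missing parameters: {sorted(missing)[:5]}...")
        for name, arr in params.items():
            arr[...] = values[name]

    def n_parameters(self) -> int:
        return int(sum(a.size for a in self.parameters().values()))

    @property
    def config(self) -> dict:
        return dict(
            cin=self.cin, width=self.width, depth=self.depth,
            residual=self.residual, final_activation=self.final_activation,
            final_zero=False,
        )


class Adam:
    """Adam over a named parameter dict."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


# -- checkpoints -----------------------------------------------------------

def save_checkpoint(path: str | Path, net: UNet3D, extra: Optional[dict] = None) -> None:
    """Single-file archive: parameters plus embedded JSON config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"net": net.config}
    if extra:
        meta["extra"] = extra
    arrays = {f"param/{k}": v for k, v in net.parameters().items()}
    with open(path, "wb") as fh:  # keep the exact filename (no .npz suffixing)
        np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path):
    """Rebuild a network (and its extra metadata) from an archive."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        values = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    cfg = meta["net"]
    net = UNet3D(
        cin=cfg["cin"], width=cfg["width"], depth=cfg["depth"],
        residual=cfg["residual"], final_activation=cfg["final_activation"],
    )
    net.load_parameters(values)
    return net, meta.get("extra", {})
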