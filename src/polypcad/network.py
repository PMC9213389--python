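"""Member CNN: a small 3-D residual network for 50^3 CT subvolumes.

Architecture (identical for both ensemble variants apart from the input
channel count):

    three residual blocks with filter counts (16, 32, 64); each block is
        main:     conv 3x3x3 stride 2, SAME -> ReLU -> conv 3x3x3 stride 1, SAME -> ReLU
        shortcut: conv 3x3x3 stride 2, SAME with a single filter
        output:   main + shortcut (the 1-channel shortcut is broadcast
                  across the main branch's channels)
    then global average pooling over the final 7^3 grid, dropout, and a
    fully connected layer onto one logistic output unit
    (0.0 = benign, 1.0 = premalignant).

Downsampling uses ceil-mode SAME padding so the spatial sizes follow
50 -> 25 -> 13 -> 7; this sequence is asserted at build time.

The forward/backward passes are implemented directly on numpy float32
arrays (channels-last), with patch extraction done by numba kernels and
the contractions by BLAS. Stochastic gradient descent and binary
cross-entropy live here as well, so a member network is self-contained.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from ._kernels import im2col_3x3x3, col2im_3x3x3

__all__ = [
    "NetworkConfig",
    "MemberNetwork",
    "build_member",
    "forward",
    "EXPECTED_SPATIAL_SIZES",
]

#: spatial edge lengths after the input and each residual block
EXPECTED_SPATIAL_SIZES = (50, 25, 13, 7)

_F32 = np.float32


def _same_pad(n: int, stride: int, k: int = 3) -> tuple[int, tuple[int, int]]:
    """Ceil-mode SAME padding: output size and (before, after) pad."""
    out = -(-n // stride)
    total = max((out - 1) * stride + k - n, 0)
    return out, (total // 2, total - total // 2)


@dataclass
class NetworkConfig:
    """Hyperparameters of one member CNN.

    in_channels is 1 (image only, noSEG) or 2 (image + mask, SEG);
    block_filters defaults to the (16, 32, 64) layout; dropout precedes the
    output layer and is active only in training mode.
    """

    in_channels: int = 1
    block_filters: tuple[int, int, int] = (16, 32, 64)
    dropout_rate: float = 0.5
    activation: str = "relu"

    def __post_init__(self) -> None:
        self.block_filters = tuple(int(f) for f in self.block_filters)
        if self.in_channels not in (1, 2):
            raise ValueError(f"in_channels must be 1 or 2, got {self.in_channels}")
        if len(self.block_filters) != 3 or not all(
            a < b for a, b in zip(self.block_filters, self.block_filters[1:])
        ):
            raise ValueError("block_filters must be three strictly increasing counts")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.activation != "relu":
            raise ValueError("only the rectifier activation is supported")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "NetworkConfig":
        d = json.loads(text)
        d["block_filters"] = tuple(d["block_filters"])
        return cls(**d)


def _glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_F32)


class _ResBlock:
    """One downsampling residual block (two main convs + 1-filter shortcut).

    The stride-2 main conv and the shortcut conv read the same patch matrix,
    so im2col runs once per input tensor.
    """

    def __init__(self, c_in: int, filters: int):
        self.c_in = c_in
        self.filters = filters
        # flat kernels: (27*C_in, F); patch order is (i, j, k, c)
        self.Wa = np.zeros((27 * c_in, filters), _F32)
        self.ba = np.zeros(filters, _F32)
        self.Wsc = np.zeros((27 * c_in, 1), _F32)
        self.bsc = np.zeros(1, _F32)
        self.Wb = np.zeros((27 * filters, filters), _F32)
        self.bb = np.zeros(filters, _F32)
        self._cache = None
        self._bufs: dict[str, np.ndarray] = {}

    def init_params(self, rng: np.random.Generator) -> None:
        # He-normal fan-in scaling: keeps activation variance roughly
        # constant through the rectified convolution stack
        for name in ("Wa", "Wsc", "Wb"):
            W = getattr(self, name)
            init = rng.normal(0.0, np.sqrt(2.0 / W.shape[0]), W.shape)
            setattr(self, name, init.astype(_F32))
        self.ba[:] = 0.0
        self.bsc[:] = 0.0
        self.bb[:] = 0.0

    @property
    def params(self):
        return {"Wa": self.Wa, "ba": self.ba, "Wsc": self.Wsc, "bsc": self.bsc,
                "Wb": self.Wb, "bb": self.bb}

    @staticmethod
    def _pad(x: np.ndarray, stride: int) -> tuple[np.ndarray, tuple[int, int, int]]:
        dims = [_same_pad(n, stride) for n in x.shape[1:4]]
        pads = [(0, 0)] + [d[1] for d in dims] + [(0, 0)]
        return np.pad(x, pads), tuple(d[0] for d in dims)

    def _buffer(self, key: str, shape) -> np.ndarray:
        # large scratch arrays are reused across steps to avoid page-fault churn
        buf = self._bufs.get(key)
        if buf is None or buf.shape != tuple(shape):
            buf = np.empty(shape, _F32)
            self._bufs[key] = buf
        return buf

    def _im2col(self, x: np.ndarray, stride: int, key: str):
        xp, (Do, Ho, Wo) = self._pad(x, stride)
        n = x.shape[0]
        cols = self._buffer(key, (n * Do * Ho * Wo, 27 * x.shape[4]))
        im2col_3x3x3(xp, cols, stride, Do, Ho, Wo)
        return cols, xp.shape, (Do, Ho, Wo)

    def forward(self, x: np.ndarray, keep_cache: bool) -> np.ndarray:
        n = x.shape[0]
        cols0, xp_shape, (Do, Ho, Wo) = self._im2col(x, 2, "cols0")
        za = np.dot(cols0, self.Wa, out=self._buffer("za", (cols0.shape[0], self.filters)))
        za += self.ba
        a = np.maximum(za, 0.0).reshape(n, Do, Ho, Wo, self.filters)
        zsc = cols0 @ self.Wsc
        zsc += self.bsc
        cols1, ap_shape, _ = self._im2col(a, 1, "cols1")
        zb = np.dot(cols1, self.Wb, out=self._buffer("zb", (cols1.shape[0], self.filters)))
        zb += self.bb
        out = np.maximum(zb, 0.0)
        out += zsc  # broadcast 1-channel shortcut across filters
        out = out.reshape(n, Do, Ho, Wo, self.filters)
        if keep_cache:
            self._cache = (cols0, za, cols1, zb, xp_shape, ap_shape, (Do, Ho, Wo), x.shape)
        return out

    def backward(self, dout: np.ndarray, need_input_grad: bool):
        cols0, za, cols1, zb, xp_shape, ap_shape, (Do, Ho, Wo), x_shape = self._cache
        F = self.filters
        df = np.ascontiguousarray(dout.reshape(-1, F))
        dsc = df.sum(axis=1, keepdims=True)
        dm = df
        dm[zb <= 0] = 0.0  # ReLU gate of the second conv (in place, df not reused)
        # (F, 27F) gemm orientation is ~2x faster than (27F, F) here
        self.dWb = np.dot(dm.T, cols1).T
        self.dbb = dm.sum(0)
        # gradient wrt the intermediate activation a
        dcols1 = np.dot(dm, self.Wb.T,
                        out=self._buffer("dcols1", cols1.shape))
        dap = np.zeros(ap_shape, _F32)
        col2im_3x3x3(dcols1, dap, 1, Do, Ho, Wo)
        pd = [_same_pad(s, 1)[1] for s in (Do, Ho, Wo)]
        da = dap[:, pd[0][0]:pd[0][0] + Do, pd[1][0]:pd[1][0] + Ho, pd[2][0]:pd[2][0] + Wo, :]
        da = np.ascontiguousarray(da.reshape(-1, F))
        da[za <= 0] = 0.0
        self.dWa = np.dot(da.T, cols0).T
        self.dba = da.sum(0)
        self.dWsc = np.dot(dsc.T, cols0).T
        self.dbsc = dsc.sum(0)
        dx = None
        if need_input_grad:
            dcols0 = np.dot(da, self.Wa.T, out=self._buffer("dcols0", cols0.shape))
            dcols0 += dsc @ self.Wsc.T
            dxp = np.zeros(xp_shape, _F32)
            col2im_3x3x3(dcols0, dxp, 2, Do, Ho, Wo)
            D, H, W = x_shape[1:4]
            pads = [_same_pad(s, 2)[1] for s in (D, H, W)]
            dx = dxp[:, pads[0][0]:pads[0][0] + D, pads[1][0]:pads[1][0] + H,
                     pads[2][0]:pads[2][0] + W, :]
        self._cache = None
        return dx

    def release(self) -> None:
        self._bufs = {}
        self._cache = None

    def sgd_step(self, lr: float) -> None:
        self.Wa -= lr * self.dWa
        self.ba -= lr * self.dba
        self.Wsc -= lr * self.dWsc
        self.bsc -= lr * self.dbsc
        self.Wb -= lr * self.dWb
        self.bb -= lr * self.dbb


class MemberNetwork:
    """One member CNN with its parameters and training history."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        f1, f2, f3 = config.block_filters
        self.blocks = [_ResBlock(config.in_channels, f1),
                       _ResBlock(f1, f2),
                       _ResBlock(f2, f3)]
        self.w_out = np.zeros(f3, _F32)
        self.b_out = np.zeros(1, _F32)
        self.trained = False
        self.history: dict[str, list[float]] = {"loss": [], "val_auc": []}
        self._assert_spatial_sizes()

    # -- construction -----------------------------------------------------
    def _assert_spatial_sizes(self) -> None:
        sizes = [EXPECTED_SPATIAL_SIZES[0]]
        for _ in self.blocks:
            sizes.append(_same_pad(sizes[-1], 2)[0])
        if tuple(sizes) != EXPECTED_SPATIAL_SIZES:
            raise AssertionError(
                f"spatial size chain {tuple(sizes)} != {EXPECTED_SPATIAL_SIZES}")

    def init_params(self, seed_or_rng) -> "MemberNetwork":
        rng = np.random.default_rng(seed_or_rng)
        for b in self.blocks:
            b.init_params(rng)
        f3 = self.config.block_filters[-1]
        self.w_out = _glorot_uniform(rng, (f3,), f3, 1)
        self.b_out[:] = 0.0
        return self

    @property
    def n_parameters(self) -> int:
        n = self.w_out.size + self.b_out.size
        for b in self.blocks:
            n += sum(p.size for p in b.params.values())
        return n

    # -- forward ----------------------------------------------------------
    def _validate_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, _F32)
        if x.ndim == 4:
            x = x[None]
        if x.ndim != 5 or x.shape[1:4] != (50, 50, 50):
            raise ValueError(f"expected input (n, 50, 50, 50, c), got {x.shape}")
        if x.shape[4] != self.config.in_channels:
            raise ValueError(
                f"input has {x.shape[4]} channel(s) but network expects "
                f"{self.config.in_channels}")
        return np.ascontiguousarray(x)

    def forward_logits(self, x: np.ndarray, train: bool = False,
                       dropout_rng: np.random.Generator | None = None) -> np.ndarray:
        """Pre-sigmoid scores, shape (n,). Dropout is applied only in training mode."""
        x = self._validate_input(x)
        h = x
        for b in self.blocks:
            h = b.forward(h, keep_cache=train)
        feats = h  # (n, 7, 7, 7, F3)
        g = feats.mean(axis=(1, 2, 3))
        if train:
            p = self.config.dropout_rate
            if p > 0.0:
                if dropout_rng is None:
                    raise ValueError("training-mode forward needs a dropout rng")
                mask = (dropout_rng.random(g.shape) >= p).astype(_F32) / _F32(1.0 - p)
            else:
                mask = np.ones_like(g)
            hdrop = g * mask
            self._head_cache = (g, mask, hdrop)
        else:
            hdrop = g
        z = hdrop @ self.w_out + self.b_out[0]
        if not np.all(np.isfinite(z)):
            raise FloatingPointError("non-finite activations at the output layer")
        return z

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Evaluation-mode scores in [0, 1], shape (n,)."""
        return _sigmoid(self.forward_logits(x, train=False))

    def predict_scores(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        x = self._validate_input(x)
        out = np.empty(x.shape[0], _F32)
        for i in range(0, x.shape[0], batch_size):
            out[i:i + batch_size] = self.forward(x[i:i + batch_size])
        return out

    def final_features(self, x: np.ndarray) -> np.ndarray:
        """Activations of the last residual stage (add3), shape (n, 7, 7, 7, F3)."""
        x = self._validate_input(x)
        h = x
        for b in self.blocks:
            h = b.forward(h, keep_cache=False)
        return h

    # -- training ---------------------------------------------------------
    def train_step(self, x: np.ndarray, y: np.ndarray, lr: float,
                   dropout_rng: np.random.Generator) -> float:
        """One SGD step on a mini-batch; returns the mean BCE loss."""
        y = np.asarray(y, _F32)
        z = self.forward_logits(x, train=True, dropout_rng=dropout_rng)
        n = z.shape[0]
        # stable BCE-with-logits: softplus(z) - y*z
        loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
        dz = ((_sigmoid(z) - y) / n).astype(_F32)
        g, mask, hdrop = self._head_cache
        dw = hdrop.T @ dz
        db = dz.sum()
        dg = np.outer(dz, self.w_out) * mask
        F3 = self.config.block_filters[-1]
        dA = np.broadcast_to(dg[:, None, None, None, :] / _F32(343.0),
                             (n, 7, 7, 7, F3)).astype(_F32)
        dh = dA
        for i, b in enumerate(reversed(self.blocks)):
            dh = b.backward(dh, need_input_grad=(i < len(self.blocks) - 1))
        for b in self.blocks:
            b.sgd_step(lr)
        self.w_out -= _F32(lr) * dw
        self.b_out -= _F32(lr) * db
        self._head_cache = None
        return loss

    def release_buffers(self) -> None:
        """Drop large reusable scratch buffers (keeps parameters)."""
        for b in self.blocks:
            b.release()

    # -- weights ----------------------------------------------------------
    def get_weights(self) -> dict[str, np.ndarray]:
        w = {"w_out": self.w_out.copy(), "b_out": self.b_out.copy()}
        for i, b in enumerate(self.blocks):
            for k, p in b.params.items():
                w[f"block{i}_{k}"] = p.copy()
        return w

    def set_weights(self, w: dict[str, np.ndarray]) -> None:
        self.w_out = np.asarray(w["w_out"], _F32).copy()
        self.b_out = np.asarray(w["b_out"], _F32).copy()
        for i, b in enumerate(self.blocks):
            for k in b.params:
                setattr(b, k, np.asarray(w[f"block{i}_{k}"], _F32).copy())

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, **self.get_weights())
        meta = {"config": asdict(self.config), "trained": self.trained,
                "history": self.history}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "MemberNetwork":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg = meta["config"]
        cfg["block_filters"] = tuple(cfg["block_filters"])
        net = cls(NetworkConfig(**cfg))
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
            net.set_weights({k: z[k] for k in z.files})
        net.trained = meta["trained"]
        net.history = meta["history"]
        return net


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=_F32)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def build_member(config: NetworkConfig, seed: int | None = None) -> MemberNetwork:
    """Construct (and optionally initialize) a member network."""
    net = MemberNetwork(config)
    if seed is not None:
        net.init_params(seed)
    return net


def forward(net: MemberNetwork, x: np.ndarray) -> np.ndarray:
    """Evaluation-mode output score(s) in [0, 1] for ``x``."""
    return net.forward(x)
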