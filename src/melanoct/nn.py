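"""Minimal numpy convolutional encoder-decoder (U-Net) with backprop.

The DOPU-synthesis task only needs a tiny image-to-image regressor (3
resolution levels, tens of thousands of parameters), so the network is
implemented directly on numpy: im2col 3x3 convolutions, ReLU, 2x2 average
pooling, nearest-neighbour upsampling with skip concatenation, a sigmoid
output head, and Adam. Everything is float32 and deterministic under a
seed. Training a desk-scale model takes minutes on one CPU.
"""

from __future__ import annotations

import json

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["UNet", "bce_loss", "mse_loss", "save_model", "load_model"]


def _conv3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """3x3 same-padding convolution. x (N,C,H,W); w (C*9, O); b (O,)."""
    n, c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))        # (N,C,H,W,3,3)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h, wd, c * 9)
    y = cols @ w + b                                          # (N,H,W,O)
    return np.ascontiguousarray(y.transpose(0, 3, 1, 2)), cols


def _conv3_backward(dy: np.ndarray, cols: np.ndarray, w: np.ndarray, c_in: int):
    n, o, h, wd = dy.shape
    dyr = dy.transpose(0, 2, 3, 1).reshape(-1, o)
    dw = cols.reshape(-1, c_in * 9).T @ dyr
    db = dyr.sum(axis=0)
    dcols = (dyr @ w.T).reshape(n, h, wd, c_in, 3, 3)
    dxp = np.zeros((n, c_in, h + 2, wd + 2), dtype=dy.dtype)
    for i in range(3):
        for j in range(3):
            dxp[:, :, i:i + h, j:j + wd] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dxp[:, :, 1:-1, 1:-1], dw, db


def _pool2(x):
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _pool2_back(dy):
    return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) * 0.25


def _up2(x):
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def _up2_back(dy):
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    """Per-pixel binary cross-entropy with continuous targets in [0, 1]."""
    pc = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))


def mse_loss(p: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((p - y) ** 2))


class UNet:
    """3-level encoder-decoder with skip connections and sigmoid output."""

    def __init__(self, base_channels: int = 8, seed: int = 0):
        self.base_channels = int(base_channels)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        b = self.base_channels
        spec = {
            "c1a": (1, b), "c1b": (b, b),
            "c2a": (b, 2 * b), "c2b": (2 * b, 2 * b),
            "c3a": (2 * b, 4 * b), "c3b": (4 * b, 4 * b),
            "d2a": (6 * b, 2 * b), "d2b": (2 * b, 2 * b),
            "d1a": (3 * b, b), "d1b": (b, b),
        }
        self.channels_in = {k: cin for k, (cin, _) in spec.items()}
        self.params: dict[str, np.ndarray] = {}
        for name, (cin, cout) in spec.items():
            std = np.sqrt(2.0 / (cin * 9))
            self.params[f"{name}_w"] = rng.normal(0, std, (cin * 9, cout)).astype(np.float32)
            self.params[f"{name}_b"] = np.zeros(cout, dtype=np.float32)
        self.params["out_w"] = rng.normal(0, np.sqrt(2.0 / b), (b, 1)).astype(np.float32)
        self.params["out_b"] = np.zeros(1, dtype=np.float32)
        self._adam: dict[str, tuple[np.ndarray, np.ndarray]] | None = None
        self._adam_t = 0
        self.trained = False

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())

    # ---- forward / backward -------------------------------------------
    def _conv_relu(self, name, x, cache):
        y, cols = _conv3_forward(x, self.params[f"{name}_w"], self.params[f"{name}_b"])
        mask = y > 0
        cache[name] = (cols, mask)
        return y * mask

    def forward(self, x: np.ndarray, want_cache: bool = False):
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("input must be (N, 1, H, W)")
        if x.shape[2] % 4 or x.shape[3] % 4:
            raise ValueError("H and W must be multiples of 4")
        cache: dict = {}
        e1 = self._conv_relu("c1b", self._conv_relu("c1a", x, cache), cache)
        p1 = _pool2(e1)
        e2 = self._conv_relu("c2b", self._conv_relu("c2a", p1, cache), cache)
        p2 = _pool2(e2)
        m = self._conv_relu("c3b", self._conv_relu("c3a", p2, cache), cache)
        cat2 = np.concatenate([_up2(m), e2], axis=1)
        d2 = self._conv_relu("d2b", self._conv_relu("d2a", cat2, cache), cache)
        cat1 = np.concatenate([_up2(d2), e1], axis=1)
        d1 = self._conv_relu("d1b", self._conv_relu("d1a", cat1, cache), cache)
        # 1x1 output head
        n, c, h, w = d1.shape
        flat = d1.transpose(0, 2, 3, 1).reshape(-1, c)
        logits = (flat @ self.params["out_w"] + self.params["out_b"]).reshape(n, h, w, 1)
        logits = logits.transpose(0, 3, 1, 2)
        p = 1.0 / (1.0 + np.exp(-logits))
        if want_cache:
            cache["_d1"] = d1
            cache["_shapes"] = (e1.shape, e2.shape, m.shape)
        return (p, cache) if want_cache else p

    def _conv_relu_back(self, name, dy, cache):
        cols, mask = cache[name]
        dy = dy * mask
        dx, dw, db = _conv3_backward(dy, cols, self.params[f"{name}_w"],
                                     self.channels_in[name])
        return dx, {f"{name}_w": dw, f"{name}_b": db}

    def backward(self, p: np.ndarray, y: np.ndarray, cache: dict,
                 loss: str = "bce") -> dict[str, np.ndarray]:
        """Gradients of the mean loss; for sigmoid+BCE dlogits = (p - y)/N."""
        n_pix = p.size
        if loss == "bce":
            dlogits = (p - y).astype(np.float32) / n_pix
        elif loss == "mse":
            dlogits = (2.0 * (p - y) * p * (1.0 - p)).astype(np.float32) / n_pix
        else:
            raise ValueError("loss must be 'bce' or 'mse'")
        grads: dict[str, np.ndarray] = {}
        d1 = cache["_d1"]
        n, c, h, w = d1.shape
        dlr = dlogits.transpose(0, 2, 3, 1).reshape(-1, 1)
        grads["out_w"] = d1.transpose(0, 2, 3, 1).reshape(-1, c).T @ dlr
        grads["out_b"] = dlr.sum(axis=0)
        dd1 = (dlr @ self.params["out_w"].T).reshape(n, h, w, c).transpose(0, 3, 1, 2)

        d, g = self._conv_relu_back("d1b", dd1, cache); grads.update(g)
        dcat1, g = self._conv_relu_back("d1a", d, cache); grads.update(g)
        b2 = 2 * self.base_channels
        dd2 = _up2_back(dcat1[:, :b2]); de1 = dcat1[:, b2:]
        d, g = self._conv_relu_back("d2b", dd2, cache); grads.update(g)
        dcat2, g = self._conv_relu_back("d2a", d, cache); grads.update(g)
        b4 = 4 * self.base_channels
        dm = _up2_back(dcat2[:, :b4]); de2 = dcat2[:, b4:]
        d, g = self._conv_relu_back("c3b", dm, cache); grads.update(g)
        dp2, g = self._conv_relu_back("c3a", d, cache); grads.update(g)
        de2 = de2 + _pool2_back(dp2)
        d, g = self._conv_relu_back("c2b", de2, cache); grads.update(g)
        dp1, g = self._conv_relu_back("c2a", d, cache); grads.update(g)
        de1 = de1 + _pool2_back(dp1)
        d, g = self._conv_relu_back("c1b", de1, cache); grads.update(g)
        _, g = self._conv_relu_back("c1a", d, cache); grads.update(g)
        return grads

    # ---- optimization --------------------------------------------------
    def adam_step(self, grads: dict[str, np.ndarray], lr: float = 1e-3,
                  beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if self._adam is None:
            self._adam = {k: (np.zeros_like(v), np.zeros_like(v))
                          for k, v in self.params.items()}
        self._adam_t += 1
        t = self._adam_t
        for k, p in self.params.items():
            g = grads[k].astype(np.float32).reshape(p.shape)
            m, v = self._adam[k]
            m = beta1 * m + (1 - beta1) * g
            v = beta2 * v + (1 - beta2) * g * g
            self._adam[k] = (m, v)
            mh = m / (1 - beta1**t)
            vh = v / (1 - beta2**t)
            p -= (lr * mh / (np.sqrt(vh) + eps)).astype(np.float32)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float32).copy()


def save_model(model: UNet, path: str, extra: dict | None = None) -> None:
    """Single-file checkpoint: parameters plus embedded config JSON."""
    meta = {"base_channels": model.base_channels, "seed": model.seed,
            "trained": model.trained}
    if extra:
        meta.update(extra)
    np.savez(path, _meta=json.dumps(meta), **model.params)


def load_model(path: str) -> UNet:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["_meta"]))
        model = UNet(base_channels=meta["base_channels"], seed=meta["seed"])
        model.load_state_dict({k: data[k] for k in model.params})
        model.trained = bool(meta.get("trained", False))
    return model
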