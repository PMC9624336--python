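"""A small, dependency-free U-Net for binary segmentation.

Implements the classic encoder-decoder with skip connections in plain
NumPy: im2col convolutions, max pooling, nearest-neighbour upsampling,
hand-derived backpropagation and an Adam optimizer. Sized for the
desk-scale configurations this package trains (depth 2, 8 base filters,
64x64 inputs); everything is float32 and fully seeded, so a fixed seed
reproduces the training history bit for bit on one machine.

The network outputs logits; :func:`sigmoid` maps them to a per-pixel
object-probability heatmap in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

_F = np.float32


@dataclass
class UNetConfig:
    """Architecture and training hyperparameters.

    ``input_size`` must be divisible by 2**depth so pooling and
    upsampling invert each other exactly. The loss is binary
    cross-entropy plus a soft-Dice term in equal weights ("bce_dice"),
    or plain "bce"; the combined loss is robust on small foregrounds
    such as chromocenters.
    """

    depth: int = 2
    base_filters: int = 8
    input_size: tuple[int, int] = (64, 64)
    loss: str = "bce_dice"
    epochs: int = 10
    batch_size: int = 8
    learning_rate: float = 3e-3
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.input_size
        if self.depth < 1 or self.base_filters < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("depth, base_filters, epochs and batch_size must be positive")
        if h % (1 << self.depth) or w % (1 << self.depth):
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2**depth = {1 << self.depth}"
            )
        if self.loss not in ("bce", "bce_dice"):
            raise ValueError("loss must be 'bce' or 'bce_dice'")


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Conv2D:
    """Same-padding k x k convolution via im2col."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        self.W = (rng.standard_normal((fan_in, cout)) * np.sqrt(2.0 / fan_in)).astype(_F)
        self.b = np.zeros(cout, dtype=_F)
        self.k, self.cin, self.cout = k, cin, cout
        self._cols = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, H, W, C * self.k * self.k)
        self._cols = cols
        self._in_shape = x.shape
        out = cols @ self.W + self.b
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, H, W = self._in_shape
        k, p = self.k, self.k // 2
        dm = dout.transpose(0, 2, 3, 1)                          # (B,H,W,cout)
        cols = self._cols
        self.dW = cols.reshape(-1, cols.shape[-1]).T @ dm.reshape(-1, self.cout)
        self.db = dm.sum(axis=(0, 1, 2))
        dcols = (dm @ self.W.T).reshape(B, H, W, C, k, k)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=_F)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + H, j : j + W] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p : p + H, p : p + W]

    def params(self):
        return [("W", self), ("b", self)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _MaxPool2:
    def forward(self, x):
        B, C, H, W = x.shape
        r = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            B, C, H // 2, W // 2, 4
        )
        self._idx = r.argmax(axis=-1)
        self._shape = x.shape
        return np.ascontiguousarray(np.take_along_axis(r, self._idx[..., None], axis=-1)[..., 0])

    def backward(self, dout):
        B, C, H, W = self._shape
        dr = np.zeros((B, C, H // 2, W // 2, 4), dtype=_F)
        np.put_along_axis(dr, self._idx[..., None], dout[..., None], axis=-1)
        return dr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            B, C, H, W
        )


class _Upsample2:
    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout):
        B, C, H, W = dout.shape
        return dout.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5)).astype(_F)


class _Block:
    """conv-relu-conv-relu."""

    def __init__(self, cin, cout, rng):
        self.c1, self.r1 = _Conv2D(cin, cout, 3, rng), _ReLU()
        self.c2, self.r2 = _Conv2D(cout, cout, 3, rng), _ReLU()

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, d):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(d))))

    def convs(self):
        return [self.c1, self.c2]


class UNet:
    """Encoder-decoder segmentation network with skip connections."""

    def __init__(self, config: UNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f = config.base_filters
        d = config.depth

        self.enc = []
        cin = 1
        for i in range(d):
            self.enc.append(_Block(cin, f * 2**i, rng))
            cin = f * 2**i
        self.pools = [_MaxPool2() for _ in range(d)]
        self.bottleneck = _Block(cin, f * 2**d, rng)
        self.ups = []
        self.upconvs = []
        self.dec = []
        for i in reversed(range(d)):
            self.ups.append(_Upsample2())
            self.upconvs.append(_Conv2D(f * 2 ** (i + 1), f * 2**i, 3, rng))
            self.dec.append(_Block(f * 2 ** (i + 1), f * 2**i, rng))
        self.final = _Conv2D(f, 1, 1, rng)

    # -- plumbing -------------------------------------------------------
    def convs(self) -> list[_Conv2D]:
        out = []
        for b in self.enc:
            out += b.convs()
        out += self.bottleneck.convs()
        for uc, b in zip(self.upconvs, self.dec):
            out.append(uc)
            out += b.convs()
        out.append(self.final)
        return out

    def n_parameters(self) -> int:
        return sum(c.W.size + c.b.size for c in self.convs())

    # -- forward / backward --------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, 1, H, W) float32 in [0, 1] -> logits (B, 1, H, W)."""
        skips = []
        h = x.astype(_F)
        for block, pool in zip(self.enc, self.pools):
            h = block.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        self._skip_channels = []
        for up, upconv, block, skip in zip(self.ups, self.upconvs, self.dec, reversed(skips)):
            h = upconv.forward(up.forward(h))
            self._skip_channels.append(skip.shape[1])
            h = np.concatenate([skip, h], axis=1)
            h = block.forward(h)
        return self.final.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.final.backward(dlogits)
        dskips = []
        for block, upconv, up, cs in zip(
            reversed(self.dec), reversed(self.upconvs), reversed(self.ups),
            reversed(self._skip_channels),
        ):
            d = block.backward(d)
            dskips.append(d[:, :cs])
            d = up.backward(upconv.backward(d[:, cs:]))
        d = self.bottleneck.backward(d)
        # dskips were collected decoder-first, i.e. for skips[0], skips[1], ...
        for block, pool, dskip in zip(reversed(self.enc), reversed(self.pools), reversed(dskips)):
            d = pool.backward(d) + dskip
            d = block.backward(d)

    def predict_probs(self, images: np.ndarray) -> np.ndarray:
        """(N, H, W) in [0, 1] -> per-pixel probabilities (N, H, W)."""
        logits = self.forward(np.asarray(images, dtype=_F)[:, None])
        return sigmoid(logits)[:, 0]

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        arrays = {}
        for i, c in enumerate(self.convs()):
            arrays[f"W{i}"] = c.W
            arrays[f"b{i}"] = c.b
        cfg = asdict(self.config)
        cfg["input_size"] = list(cfg["input_size"])
        np.savez(path, config=json.dumps(cfg), **arrays)

    @classmethod
    def load(cls, path) -> "UNet":
        with np.load(path, allow_pickle=False) as data:
            cfg = json.loads(str(data["config"]))
            cfg["input_size"] = tuple(cfg["input_size"])
            model = cls(UNetConfig(**cfg))
            for i, c in enumerate(model.convs()):
                c.W = data[f"W{i}"].astype(_F)
                c.b = data[f"b{i}"].astype(_F)
        return model


def bce_dice_loss(logits: np.ndarray, targets: np.ndarray, dice_weight: float = 1.0):
    """Binary cross-entropy + soft-Dice loss and its gradient w.r.t. logits."""
    y = targets.astype(_F)
    p = sigmoid(logits)
    n = logits.size
    eps = 1e-7
    bce = float(-(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)).mean())
    dlogits = (p - y) / n

    loss = bce
    if dice_weight > 0:
        s1 = float((p * y).sum())
        s2 = float(p.sum() + y.sum())
        dice_l = 1.0 - (2 * s1 + 1.0) / (s2 + 1.0)
        dnum = -(2 * y * (s2 + 1.0) - (2 * s1 + 1.0)) / (s2 + 1.0) ** 2
        dlogits = dlogits + dice_weight * dnum * p * (1 - p)
        loss = loss + dice_weight * float(dice_l)
    return loss, dlogits.astype(_F)


class Adam:
    def __init__(self, model: UNet, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.convs = model.convs()
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [(np.zeros_like(c.W), np.zeros_like(c.b)) for c in self.convs]
        self.v = [(np.zeros_like(c.W), np.zeros_like(c.b)) for c in self.convs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for c, (mW, mb), (vW, vb) in zip(self.convs, self.m, self.v):
            for param, grad, m, v in ((c.W, c.dW, mW, vW), (c.b, c.db, mb, vb)):
                m *= self.b1
                m += (1 - self.b1) * grad
                v *= self.b2
                v += (1 - self.b2) * grad**2
                param -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def build_unet(config: UNetConfig) -> UNet:
    """Build a seeded U-Net; the same config (incl. seed) gives identical
    initial parameters."""
    return UNet(config)


def train_stage(model: UNet, images: np.ndarray, masks: np.ndarray, config: UNetConfig | None = None):
    """Train one cascade stage on (N, H, W) images and binary masks.

    Images must already be normalized to [0, 1] and sized to the model's
    input size. Returns ``(model, loss_history)`` where the history has
    one mean loss per epoch. Fully seeded: a fixed config reproduces the
    history exactly.
    """
    if config is None:
        config = model.config
    images = np.asarray(images, dtype=_F)
    masks = np.asarray(masks, dtype=_F)
    if images.ndim != 3 or images.shape != masks.shape:
        raise ValueError("images and masks must be matching (N, H, W) arrays")
    n = images.shape[0]
    if n == 0:
        raise ValueError("empty training set")

    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model, config.learning_rate)
    dice_w = 1.0 if config.loss == "bce_dice" else 0.0
    history = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward(images[idx][:, None])
            loss, dlogits = bce_dice_loss(logits, masks[idx][:, None], dice_w)
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history
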