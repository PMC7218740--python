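"""Siamese patch classifier that turns two source images into a weight map.

Two parameter-sharing branches (conv 3x3 -> conv 3x3 -> max-pool 2x2 ->
conv 3x3, ReLU after each convolution) each map a 16x16 patch to a feature
block; the blocks are concatenated and a fully connected layer produces two
scores, read through a softmax as "patch 1 is the clear one" (label 1)
versus "patch 2 is the clear one" (label 0). Training pairs are co-located
clear/blurred patches manufactured by iterated Gaussian blurring, so the
network learns a local sharpness comparison that transfers to comparing two
co-registered modalities pixel-by-pixel.

Everything is plain NumPy with hand-written backpropagation (im2col plus
BLAS matmuls), trained by momentum SGD with weight decay folded into the
velocity update:

    v <- 0.9 v - 0.0005 lr w - lr dL/dw;    w <- w + v

For fusion the fully connected head is rewritten as an equivalent
convolution so the whole network runs fully convolutionally over any-size
images, yielding one prediction per 16x16 window at stride 2 (one pooling
stage); window weights are binarized and averaged over overlaps into a
dense per-pixel weight map.

Layer widths are configurable; defaults (8, 16, 32) keep the channel count
increasing with depth while training comfortably on a single CPU.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

__all__ = [
    "NetConfig",
    "PatchPair",
    "SiameseNet",
    "DenseSiameseNet",
    "DivergenceError",
    "softmax2",
    "make_blur_stack",
    "sample_pairs",
    "pairs_to_arrays",
    "train",
    "evaluate_accuracy",
    "to_dense",
    "weight_map",
]

PATCH = 16  # patch side; three valid 3x3 convs + one 2x2 pool map 16 -> 4


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, loss: float):
        super().__init__(f"non-finite training loss {loss!r} at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class NetConfig:
    """Architecture + optimizer hyperparameters.

    channels: feature maps of conv1/conv2/conv3 (must increase, mirroring
    the design intent of progressively richer features).
    lr/momentum/weight_decay/batch_size: momentum-SGD settings.
    """

    channels: tuple[int, int, int] = (8, 16, 32)
    lr: float = 1e-4
    momentum: float = 0.9
    weight_decay: float = 5e-4
    batch_size: int = 128
    plateau_rel_tol: float = 0.01  # lr cut to 10% when epoch loss improves < 1%


@dataclass(frozen=True)
class PatchPair:
    """A labeled pair of co-located 16x16 patches.

    label 1 means p1 is the clear patch (p2 blurred); label 0 the reverse.
    """

    p1: np.ndarray
    p2: np.ndarray
    label: int


def softmax2(scores: np.ndarray) -> np.ndarray:
    """Stabilized softmax over the last axis: e^{p_i} / sum_j e^{p_j}."""
    s = np.asarray(scores, dtype=float)
    s = s - s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


def make_blur_stack(img: np.ndarray, n_levels: int = 5) -> list[np.ndarray]:
    """Iterated Gaussian blur: sigma 2, 7x7 support, each level blurring the
    previous. Returns ``[original, blur_1, ..., blur_n]`` (n_levels + 1 images)."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.shape[0] < PATCH or img.shape[1] < PATCH:
        raise ValueError(f"image must be 2-D and at least {PATCH}x{PATCH}, got {img.shape}")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    # radius 3 -> 7-tap kernel: truncate = radius / sigma
    out = [img]
    for _ in range(n_levels):
        out.append(ndimage.gaussian_filter(out[-1], sigma=2.0, truncate=1.5, mode="mirror"))
    return out


def sample_pairs(
    clear: np.ndarray, blurred: np.ndarray, n: int, seed: int | np.random.Generator
) -> list[PatchPair]:
    """Sample ``n`` co-located 16x16 patch positions; emit each position twice,
    once labeled positive (p1 = clear) and once negative (p1 = blurred)."""
    clear = np.asarray(clear, dtype=float)
    blurred = np.asarray(blurred, dtype=float)
    if clear.shape != blurred.shape:
        raise ValueError(f"shape mismatch: {clear.shape} vs {blurred.shape}")
    if clear.shape[0] < PATCH or clear.shape[1] < PATCH:
        raise ValueError(f"images must be at least {PATCH}x{PATCH}, got {clear.shape}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ys = rng.integers(0, clear.shape[0] - PATCH + 1, size=n)
    xs = rng.integers(0, clear.shape[1] - PATCH + 1, size=n)
    pairs: list[PatchPair] = []
    for y, x in zip(ys, xs):
        pc = clear[y : y + PATCH, x : x + PATCH].copy()
        pb = blurred[y : y + PATCH, x : x + PATCH].copy()
        pairs.append(PatchPair(p1=pc, p2=pb, label=1))
        pairs.append(PatchPair(p1=pb, p2=pc, label=0))
    return pairs


def pairs_to_arrays(pairs: list[PatchPair]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack a pair list into (x1 [M,1,16,16], x2 [M,1,16,16], y [M]) float32."""
    x1 = np.stack([p.p1 for p in pairs]).astype(np.float32)[:, None]
    x2 = np.stack([p.p2 for p in pairs]).astype(np.float32)[:, None]
    y = np.asarray([p.label for p in pairs], dtype=np.int64)
    return x1, x2, y


# ---------------------------------------------------------------------------
# low-level layers (im2col convolution, ReLU, 2x2 max-pool)
# ---------------------------------------------------------------------------


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Valid 3x3 convolution. x [N,C,H,W], w [K,C,3,3] -> out [N,K,H-2,W-2]."""
    n, c, h, wd = x.shape
    k = w.shape[0]
    win = sliding_window_view(x, (3, 3), axis=(2, 3))  # [N,C,H',W',3,3]
    hp, wp = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * hp * wp, c * 9)
    out = cols @ w.reshape(k, c * 9).T + b
    out = out.reshape(n, hp, wp, k).transpose(0, 3, 1, 2)
    return out, (cols, x.shape, hp, wp)


def _conv_backward(dout: np.ndarray, w: np.ndarray, cache):
    cols, xshape, hp, wp = cache
    n, c, h, wd = xshape
    k = w.shape[0]
    dmat = dout.transpose(0, 2, 3, 1).reshape(n * hp * wp, k)
    dw = (dmat.T @ cols).reshape(k, c, 3, 3)
    db = dmat.sum(axis=0)
    dcols = dmat @ w.reshape(k, c * 9)
    dcols = dcols.reshape(n, hp, wp, c, 3, 3)
    dx = np.zeros(xshape, dtype=dout.dtype)
    for ki in range(3):
        for kj in range(3):
            dx[:, :, ki : ki + hp, kj : kj + wp] += dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
    return dx, dw, db


def _relu_forward(x):
    mask = x > 0
    return x * mask, mask


def _pool_forward(x: np.ndarray):
    """2x2 max-pool, stride 2; odd trailing rows/cols are cropped."""
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    xc = x[:, :, : 2 * h2, : 2 * w2]
    r = xc.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def _pool_backward(dout: np.ndarray, cache):
    idx, xshape = cache
    n, c, h, w = xshape
    h2, w2 = h // 2, w // 2
    dr = np.zeros((n, c, h2, w2, 4), dtype=dout.dtype)
    np.put_along_axis(dr, idx[..., None], dout[..., None], axis=-1)
    dx = np.zeros(xshape, dtype=dout.dtype)
    dx[:, :, : 2 * h2, : 2 * w2] = (
        dr.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, 2 * h2, 2 * w2)
    )
    return dx


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------


def _xavier(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class SiameseNet:
    """Two-branch patch classifier with shared branch parameters.

    Parameters live in ``self.params`` (conv1/2/3 weights+biases and the
    fully connected head); ``self.vel`` holds the matching momentum buffers.
    """

    PARAM_NAMES = ("w1", "b1", "w2", "b2", "w3", "b3", "wf", "bf")

    def __init__(self, config: NetConfig = NetConfig(), seed: int = 0):
        self.config = config
        c1, c2, c3 = config.channels
        rng = np.random.default_rng(seed)
        feat = c3 * 4 * 4  # per-branch feature size for a 16x16 patch
        self.params = {
            "w1": _xavier(rng, (c1, 1, 3, 3), 9, c1 * 9),
            "b1": np.zeros(c1, dtype=np.float32),
            "w2": _xavier(rng, (c2, c1, 3, 3), c1 * 9, c2 * 9),
            "b2": np.zeros(c2, dtype=np.float32),
            "w3": _xavier(rng, (c3, c2, 3, 3), c2 * 9, c3 * 9),
            "b3": np.zeros(c3, dtype=np.float32),
            "wf": _xavier(rng, (2, 2 * feat), 2 * feat, 2),
            "bf": np.zeros(2, dtype=np.float32),
        }
        self.vel = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.history: list[float] = []

    # -- forward ----------------------------------------------------------

    def _branch_forward(self, x: np.ndarray):
        p = self.params
        z1, c1 = _conv_forward(x, p["w1"], p["b1"])
        a1, m1 = _relu_forward(z1)
        z2, c2 = _conv_forward(a1, p["w2"], p["b2"])
        a2, m2 = _relu_forward(z2)
        pl, cp = _pool_forward(a2)
        z3, c3 = _conv_forward(pl, p["w3"], p["b3"])
        a3, m3 = _relu_forward(z3)
        return a3, (c1, m1, c2, m2, cp, c3, m3)

    def _branch_backward(self, da3: np.ndarray, cache):
        c1, m1, c2, m2, cp, c3, m3 = cache
        p = self.params
        g: dict[str, np.ndarray] = {}
        dz3 = da3 * m3
        dpl, g["w3"], g["b3"] = _conv_backward(dz3, p["w3"], c3)
        da2 = _pool_backward(dpl, cp)
        dz2 = da2 * m2
        da1, g["w2"], g["b2"] = _conv_backward(dz2, p["w2"], c2)
        dz1 = da1 * m1
        _, g["w1"], g["b1"] = _conv_backward(dz1, p["w1"], c1)
        return g

    def scores(self, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
        """Head scores for batches of patch pairs. x* are [M,1,16,16]."""
        f1, _ = self._branch_forward(np.asarray(x1, dtype=np.float32))
        f2, _ = self._branch_forward(np.asarray(x2, dtype=np.float32))
        n = f1.shape[0]
        feat = np.concatenate([f1.reshape(n, -1), f2.reshape(n, -1)], axis=1)
        return feat @ self.params["wf"].T + self.params["bf"]

    def predict_pair(self, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
        """Softmax class probabilities for one patch pair (component 1 =
        probability that p1 is the clear patch)."""
        s = self.scores(p1[None, None], p2[None, None])
        return softmax2(s)[0]

    # -- one SGD step ------------------------------------------------------

    def _step(self, x1, x2, y, lr: float) -> float:
        p = self.params
        f1, cache1 = self._branch_forward(x1)
        f2, cache2 = self._branch_forward(x2)
        n = f1.shape[0]
        feat = np.concatenate([f1.reshape(n, -1), f2.reshape(n, -1)], axis=1)
        scores = feat @ p["wf"].T + p["bf"]
        prob = softmax2(scores)
        # batch-sum softmax loss
        loss = float(-np.log(np.maximum(prob[np.arange(n), y], 1e-30)).sum())
        dscores = prob.astype(np.float32)
        dscores[np.arange(n), y] -= 1.0
        grads = {
            "wf": dscores.T @ feat,
            "bf": dscores.sum(axis=0),
        }
        dfeat = dscores @ p["wf"]
        half = feat.shape[1] // 2
        df1 = dfeat[:, :half].reshape(f1.shape)
        df2 = dfeat[:, half:].reshape(f2.shape)
        g1 = self._branch_backward(df1, cache1)
        g2 = self._branch_backward(df2, cache2)
        for k in g1:  # shared branches: gradients add
            grads[k] = g1[k] + g2[k]
        mom, wd = self.config.momentum, self.config.weight_decay
        for k in self.params:
            v = self.vel[k]
            v *= mom
            v -= (wd * lr) * self.params[k] + lr * grads[k]
            self.params[k] += v
        return loss

    # -- checkpointing -----------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: named parameter arrays + architecture JSON."""
        meta = json.dumps(
            {
                "channels": list(self.config.channels),
                "lr": self.config.lr,
                "momentum": self.config.momentum,
                "weight_decay": self.config.weight_decay,
                "batch_size": self.config.batch_size,
                "plateau_rel_tol": self.config.plateau_rel_tol,
            }
        )
        np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path) -> "SiameseNet":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__config__"]).decode())
            cfg = NetConfig(
                channels=tuple(meta["channels"]),
                lr=meta["lr"],
                momentum=meta["momentum"],
                weight_decay=meta["weight_decay"],
                batch_size=meta["batch_size"],
                plateau_rel_tol=meta["plateau_rel_tol"],
            )
            net = cls(cfg, seed=0)
            for k in cls.PARAM_NAMES:
                net.params[k] = z[k].copy()
        net.vel = {k: np.zeros_like(v) for k, v in net.params.items()}
        return net


def train(
    net: SiameseNet,
    data: list[PatchPair],
    epochs: int,
    seed: int = 0,
    verbose: bool = False,
) -> SiameseNet:
    """Momentum-SGD training of the patch classifier.

    Shuffles per epoch (seeded), iterates batches of ``config.batch_size``,
    and cuts the learning rate to 10% whenever the mean epoch loss improves
    by less than ``plateau_rel_tol`` relative to the previous epoch.
    ``epochs == 0`` leaves the parameters untouched. Mean per-example epoch
    losses are appended to ``net.history``.
    """
    if not data:
        raise ValueError("training data is empty")
    if not hasattr(net, "history"):
        net.history = []
    if epochs == 0:
        return net
    x1, x2, y = pairs_to_arrays(data)
    m = len(y)
    bs = net.config.batch_size
    lr = net.config.lr
    rng = np.random.default_rng(seed)
    prev_loss = None
    for epoch in range(epochs):
        order = rng.permutation(m)
        total = 0.0
        for start in range(0, m, bs):
            sel = order[start : start + bs]
            loss = net._step(x1[sel], x2[sel], y[sel], lr)
            if not np.isfinite(loss):
                raise DivergenceError(epoch, loss)
            total += loss
        epoch_loss = total / m
        net.history.append(epoch_loss)
        if verbose:
            print(f"epoch {epoch}: mean loss {epoch_loss:.4f}, lr {lr:g}")
        if prev_loss is not None and epoch_loss > prev_loss * (1.0 - net.config.plateau_rel_tol):
            lr *= 0.1
        prev_loss = epoch_loss
    return net


def evaluate_accuracy(net: SiameseNet, data: list[PatchPair], batch: int = 512) -> float:
    """Fraction of pairs whose arg-max score matches the label."""
    x1, x2, y = pairs_to_arrays(data)
    correct = 0
    for start in range(0, len(y), batch):
        s = net.scores(x1[start : start + batch], x2[start : start + batch])
        correct += int((s.argmax(axis=1) == y[start : start + batch]).sum())
    return correct / len(y)


# ---------------------------------------------------------------------------
# dense (fully convolutional) form and the weight map
# ---------------------------------------------------------------------------


class DenseSiameseNet:
    """Fully convolutional form: the head's fully connected layer rewritten
    as one 4x4 convolution per branch (their outputs summed), so any-size
    image pairs yield a dense grid of predictions at stride 2."""

    def __init__(self, net: SiameseNet):
        c3 = net.config.channels[2]
        feat = c3 * 4 * 4
        wf = net.params["wf"]
        if wf.shape != (2, 2 * feat):
            raise ValueError(
                f"head shape {wf.shape} does not match architecture (expected {(2, 2 * feat)})"
            )
        self.net = net
        # flatten order of branch features is (channel, row, col)
        self.head_a = wf[:, :feat].reshape(2, c3, 4, 4).copy()
        self.head_b = wf[:, feat:].reshape(2, c3, 4, 4).copy()
        self.bias = net.params["bf"].copy()

    def _branch_features(self, img: np.ndarray) -> np.ndarray:
        p = self.net.params
        x = np.asarray(img, dtype=np.float32)[None, None]
        z1, _ = _conv_forward(x, p["w1"], p["b1"])
        a1 = np.maximum(z1, 0)
        z2, _ = _conv_forward(a1, p["w2"], p["b2"])
        a2 = np.maximum(z2, 0)
        pl, _ = _pool_forward(a2)
        z3, _ = _conv_forward(pl, p["w3"], p["b3"])
        return np.maximum(z3, 0)

    @staticmethod
    def _conv_nxn(x: np.ndarray, w: np.ndarray) -> np.ndarray:
        """Valid convolution with a [K,C,k,k] kernel; x [1,C,H,W]."""
        k = w.shape[-1]
        win = sliding_window_view(x, (k, k), axis=(2, 3))
        n, c, hp, wp = win.shape[:4]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * hp * wp, c * k * k)
        out = cols @ w.reshape(w.shape[0], -1).T
        return out.reshape(n, hp, wp, w.shape[0]).transpose(0, 3, 1, 2)

    def dense_scores(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Score grid [2, gh, gw]; cell (i, j) scores the 16x16 windows with
        origin (2i, 2j) in each source."""
        a = np.asarray(a, dtype=np.float32)
        b = np.asarray(b, dtype=np.float32)
        if a.shape != b.shape:
            raise ValueError(f"source shapes differ: {a.shape} vs {b.shape}")
        if a.shape[0] < PATCH or a.shape[1] < PATCH:
            raise ValueError(f"sources must be at least {PATCH}x{PATCH}, got {a.shape}")
        fa = self._branch_features(a)
        fb = self._branch_features(b)
        out = self._conv_nxn(fa, self.head_a) + self._conv_nxn(fb, self.head_b)
        return out[0] + self.bias[:, None, None]


def to_dense(net: SiameseNet) -> DenseSiameseNet:
    """Convert the trained classifier to its fully convolutional form."""
    return DenseSiameseNet(net)


def _box_sum(arr: np.ndarray, size: int) -> np.ndarray:
    """s(y, x) = sum of arr over the trailing size x size box ending at (y, x)."""
    c = np.pad(arr, ((size, 0), (size, 0))).cumsum(axis=0).cumsum(axis=1)
    return c[size:, size:] - c[:-size, size:] - c[size:, :-size] + c[:-size, :-size]


def weight_map(net: SiameseNet | DenseSiameseNet, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-pixel weight of source ``a`` in [0, 1], same shape as the sources.

    Each dense prediction is binarized (1 when the "a is clearer" score
    wins) and assigned to its whole 16x16 window; overlapping windows are
    averaged per pixel. Bottom/right margins not covered by any full window
    inherit the nearest covered pixel's weight.
    """
    dense = net if isinstance(net, DenseSiameseNet) else to_dense(net)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    s = dense.dense_scores(a, b)
    win = (s[1] >= s[0]).astype(float)  # class 1: first input is the clear one
    h, w = a.shape
    gh, gw = win.shape
    grid = np.zeros((h, w))
    cnt_grid = np.zeros((h, w))
    grid[: 2 * gh : 2, : 2 * gw : 2] = win
    cnt_grid[: 2 * gh : 2, : 2 * gw : 2] = 1.0
    acc = _box_sum(grid, PATCH)
    cnt = _box_sum(cnt_grid, PATCH)
    wm = np.zeros((h, w))
    covered = cnt > 0
    wm[covered] = acc[covered] / cnt[covered]
    # coverage is the rectangle [0, 2(gh-1)+15] x [0, 2(gw-1)+15]
    cr, cc = 2 * (gh - 1) + PATCH, 2 * (gw - 1) + PATCH
    if cr < h:
        wm[cr:, :cc] = wm[cr - 1 : cr, :cc]
    if cc < w:
        wm[:, cc:] = wm[:, cc - 1 : cc]
    return np.clip(wm, 0.0, 1.0)
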