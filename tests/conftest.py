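"""Shared fixtures and independent loop-based oracles.

The oracles deliberately use naive scalar loops (with the same mirror
boundary convention) so they stay independent of the vectorized
implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from cpfuse import NetConfig, SiameseNet, make_training_corpus
from cpfuse.network import train as train_net


def mirror_index(i: int, n: int) -> int:
    """Reflect an out-of-range index without repeating the edge sample."""
    while i < 0 or i >= n:
        if i < 0:
            i = -i
        if i >= n:
            i = 2 * n - 2 - i
    return i


def reduce_oracle(img: np.ndarray, taps) -> np.ndarray:
    """Direct double-sum REDUCE: out(i,j) = sum w(m)w(n) img(2i+m, 2j+n)."""
    r, c = img.shape
    out = np.zeros(((r + 1) // 2, (c + 1) // 2))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            s = 0.0
            for m in range(-2, 3):
                for n in range(-2, 3):
                    s += (
                        taps[m + 2]
                        * taps[n + 2]
                        * img[mirror_index(2 * i + m, r), mirror_index(2 * j + n, c)]
                    )
            out[i, j] = s
    return out


def expand_oracle(img: np.ndarray, taps, target_shape) -> np.ndarray:
    """Direct double-sum EXPAND: zero-inserted grid, x4 gain, mirror borders.
    Terms contribute only where (m+i)/2 and (n+j)/2 hit integer sample
    positions, which is exactly what the zero-inserted grid encodes."""
    tr, tc = target_shape
    up = np.zeros((tr, tc))
    up[::2, ::2] = img[: (tr + 1) // 2, : (tc + 1) // 2]
    out = np.zeros((tr, tc))
    for i in range(tr):
        for j in range(tc):
            s = 0.0
            for m in range(-2, 3):
                for n in range(-2, 3):
                    s += (
                        taps[m + 2]
                        * taps[n + 2]
                        * up[mirror_index(i + m, tr), mirror_index(j + n, tc)]
                    )
            out[i, j] = 4.0 * s
    return out


def window_sum_oracle(img: np.ndarray, window) -> np.ndarray:
    wh, ww = window
    r, c = img.shape
    out = np.zeros_like(img)
    for y in range(r):
        for x in range(c):
            s = 0.0
            for m in range(-(wh // 2), wh // 2 + 1):
                for n in range(-(ww // 2), ww // 2 + 1):
                    s += img[mirror_index(y + m, r), mirror_index(x + n, c)]
            out[y, x] = s
    return out


def fuse_level_oracle(ca, cb, gw, threshold, window=(3, 3)) -> np.ndarray:
    """Scalar per-pixel restatement of the thresholded fusion rule."""
    ea = window_sum_oracle(ca * ca, window)
    eb = window_sum_oracle(cb * cb, window)
    cross = 2.0 * window_sum_oracle(ca * cb, window)
    out = np.zeros_like(ca)
    for y in range(ca.shape[0]):
        for x in range(ca.shape[1]):
            denom = ea[y, x] + eb[y, x]
            m = cross[y, x] / denom if denom != 0 else 0.0
            if m < threshold:
                out[y, x] = ca[y, x] if ea[y, x] >= eb[y, x] else cb[y, x]
            else:
                out[y, x] = gw[y, x] * ca[y, x] + (1.0 - gw[y, x]) * cb[y, x]
    return out


@pytest.fixture(scope="session")
def trained_net() -> SiameseNet:
    """A patch classifier trained at small scale, good enough to separate
    clear from blurred patches reliably (shared across the session)."""
    net = SiameseNet(NetConfig(), seed=11)
    corpus = make_training_corpus(48, seed=11)
    return train_net(net, corpus, epochs=3, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
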