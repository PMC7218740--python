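"""Region-energy / similarity fusion of contrast-pyramid levels.

Per level the two sources' local region energies

    E(x, y) = sum_{m,n in window} C(x+m, y+n)^2

and a bounded local match measure

    M(x, y) = 2 sum C_A C_B / (E_A + E_B)      in [-1, 1]

drive the rule: where the regions disagree (M < T) the coefficient with the
larger energy wins outright (choose-max); where they agree (M >= T) a
weighted mean is taken, with the CNN weight map (Gaussian-decomposed to the
matching level) supplying the weights: source A's coefficient receives its
CNN support GW and source B the complement 1 - GW, so the weighted mean
leans toward whichever source the classifier judged sharper. The threshold
is T1 = 3 for all levels below the top (with M bounded by 1 this makes them
pure choose-max) and T2 = 0.6 at the top level. Ties E_A = E_B in the
choose-max branch resolve to source A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .network import DenseSiameseNet, SiameseNet, weight_map
from .pyramid import (
    DEFAULT_CENTER_WEIGHT,
    DEFAULT_EPS,
    DEFAULT_OFFSET,
    Kernel1D,
    build_kernel,
    contrast_decompose,
    contrast_reconstruct,
    gaussian_pyramid,
    max_depth,
)

__all__ = [
    "FusionConfig",
    "LevelTriple",
    "local_energy",
    "local_similarity",
    "fuse_level",
    "fuse_images",
]


@dataclass(frozen=True)
class FusionConfig:
    """Knobs of the fusion pipeline.

    depth: requested pyramid depth N (auto-capped so the coarsest level is
    at least ``min_top`` per side). t1 applies to levels 0 <= l < N, t2 to
    the top level N. window is the odd side of the local region.
    ``bounded_similarity`` selects the [-1,1] sum-denominator match measure;
    the literal product-denominator form is kept for comparison.
    """

    depth: int = 4
    t1: float = 3.0
    t2: float = 0.6
    window: tuple[int, int] = (3, 3)
    center_weight: float = DEFAULT_CENTER_WEIGHT
    eps: float = DEFAULT_EPS
    offset: float = DEFAULT_OFFSET
    min_top: int = 8
    bounded_similarity: bool = True
    seed: int = 0

    def __post_init__(self):
        wh, ww = self.window
        if wh % 2 == 0 or ww % 2 == 0 or wh < 1 or ww < 1:
            raise ValueError(f"window dims must be odd and >= 1, got {self.window}")
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if not (np.isfinite(self.t1) and np.isfinite(self.t2)):
            raise ValueError("thresholds must be finite")


@dataclass
class LevelTriple:
    """One pyramid level of each input to the per-level rule: source A's and
    B's contrast coefficients plus the matching weight-map Gaussian level."""

    ca: np.ndarray
    cb: np.ndarray
    gw: np.ndarray

    def __post_init__(self):
        if not (self.ca.shape == self.cb.shape == self.gw.shape):
            raise ValueError(
                f"level shapes differ: ca {self.ca.shape}, cb {self.cb.shape}, gw {self.gw.shape}"
            )


def _window_sum(img: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    kern = np.ones(window, dtype=float)
    return ndimage.correlate(img, kern, mode="mirror")


def local_energy(level: np.ndarray, window: tuple[int, int] = (3, 3)) -> np.ndarray:
    """Windowed sum of squared coefficients, mirror-padded at borders."""
    level = np.asarray(level, dtype=float)
    return _window_sum(level * level, window)


def local_similarity(
    ca: np.ndarray,
    cb: np.ndarray,
    ea: np.ndarray | None = None,
    eb: np.ndarray | None = None,
    window: tuple[int, int] = (3, 3),
    bounded: bool = True,
) -> np.ndarray:
    """Local match measure between two coefficient levels.

    bounded=True (default): ``2 sum(ca*cb) / (E_A + E_B)``, which lies in
    [-1, 1] with 0/0 := 0. bounded=False evaluates the product-denominator
    variant ``2 sum(ca*cb) / (E_A * E_B)`` (unbounded; kept for comparison).
    """
    ca = np.asarray(ca, dtype=float)
    cb = np.asarray(cb, dtype=float)
    if ca.shape != cb.shape:
        raise ValueError(f"shape mismatch: {ca.shape} vs {cb.shape}")
    if ea is None:
        ea = local_energy(ca, window)
    if eb is None:
        eb = local_energy(cb, window)
    cross = 2.0 * _window_sum(ca * cb, window)
    denom = ea + eb if bounded else ea * eb
    out = np.zeros_like(cross)
    np.divide(cross, denom, out=out, where=denom != 0)
    return out


def fuse_level(
    t: LevelTriple,
    threshold: float,
    window: tuple[int, int] = (3, 3),
    bounded_similarity: bool = True,
) -> np.ndarray:
    """Fuse one pyramid level.

    Per pixel: with M < threshold, choose the coefficient of the source with
    the larger local energy (ties to A). With M >= threshold, take the
    weighted mean GW * CA + (1 - GW) * CB — the weight map is the per-pixel
    weight of source A, so the lower-energy source receives whatever support
    the classifier left it.
    """
    gw = np.asarray(t.gw, dtype=float)
    if gw.min() < 0 or gw.max() > 1:
        raise ValueError(
            f"weight-map level values must lie in [0,1], got range "
            f"[{gw.min():.3g}, {gw.max():.3g}]"
        )
    ca = np.asarray(t.ca, dtype=float)
    cb = np.asarray(t.cb, dtype=float)
    ea = local_energy(ca, window)
    eb = local_energy(cb, window)
    m = local_similarity(ca, cb, ea, eb, window, bounded=bounded_similarity)
    choose = np.where(ea >= eb, ca, cb)
    weighted = gw * ca + (1.0 - gw) * cb
    return np.where(m < threshold, choose, weighted)


def fuse_images(
    a: np.ndarray,
    b: np.ndarray,
    net: SiameseNet | DenseSiameseNet,
    cfg: FusionConfig = FusionConfig(),
) -> np.ndarray:
    """Full pipeline: CNN weight map -> Gaussian pyramid of W -> contrast
    pyramids of the sources -> per-level fusion -> reconstruction.

    Returns the fused image clipped to [0, 1].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"source shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValueError(f"sources must be 2-D grayscale, got ndim={a.ndim}")
    kern: Kernel1D = build_kernel(cfg.center_weight)
    depth = min(cfg.depth, max_depth(a.shape, min_size=cfg.min_top))
    if depth < 1:
        raise ValueError(
            f"image {a.shape} too small for any decomposition with coarsest "
            f"level >= {cfg.min_top}x{cfg.min_top}"
        )
    w = weight_map(net, a, b)
    gw = gaussian_pyramid(w, depth, kern)
    cpa = contrast_decompose(a, depth, kern, eps=cfg.eps, offset=cfg.offset)
    cpb = contrast_decompose(b, depth, kern, eps=cfg.eps, offset=cfg.offset)
    fused_levels = [
        fuse_level(
            LevelTriple(cpa.levels[l], cpb.levels[l], np.clip(gw.levels[l], 0.0, 1.0)),
            cfg.t1,
            cfg.window,
            cfg.bounded_similarity,
        )
        for l in range(depth)
    ]
    fused_top = fuse_level(
        LevelTriple(cpa.top, cpb.top, np.clip(gw.levels[depth], 0.0, 1.0)),
        cfg.t2,
        cfg.window,
        cfg.bounded_similarity,
    )
    fused = contrast_reconstruct(
        type(cpa)(levels=fused_levels, top=fused_top, offset=cfg.offset, eps=cfg.eps), kern
    )
    return np.clip(fused, 0.0, 1.0)
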