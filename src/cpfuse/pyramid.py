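"""Gaussian and contrast pyramids with a constrained 5-tap generating kernel.

The multi-scale machinery used by the fusion pipeline: a separable 5-tap
low-pass window built from four classical constraints (separability,
normalization, symmetry, equal odd/even contribution), REDUCE/EXPAND
operators, and the contrast pyramid

    C_l = G_l / EXPAND(G_{l+1}) - 1,      0 <= l < N
    C_N = G_N

which stores local luminance contrast at every scale and is exactly
invertible by ``G_l = (C_l + 1) * EXPAND(G_{l+1})``.

Boundary handling everywhere is mirror reflection without edge repeat
(``scipy.ndimage`` mode ``'mirror'``), so a constant image stays constant
under both REDUCE and EXPAND. Odd dimensions ceil-halve on REDUCE; EXPAND
takes an explicit target shape, making decompose -> reconstruct exact for
any input size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Kernel1D",
    "GaussianPyramid",
    "ContrastPyramid",
    "build_kernel",
    "reduce_image",
    "expand_image",
    "gaussian_pyramid",
    "contrast_decompose",
    "contrast_reconstruct",
    "max_depth",
    "DecompositionDepthError",
]

#: default shift applied before the contrast ratio so denominators stay
#: bounded away from zero on images with black backgrounds
DEFAULT_OFFSET = 1e-2
#: additive guard on the expand() denominator
DEFAULT_EPS = 1e-12
#: default center weight of the 5-tap window; yields (1/16, 1/4, 3/8, 1/4, 1/16)
DEFAULT_CENTER_WEIGHT = 3.0 / 8.0


class DecompositionDepthError(ValueError):
    """Requested pyramid depth is infeasible for the image size."""


@dataclass(frozen=True)
class Kernel1D:
    """Separable 5-tap generating kernel, taps indexed -2..2.

    Constraints: symmetry w(n) = w(-n); normalization sum w = 1; equal
    contribution of odd and even taps w(-2)+w(0)+w(2) = w(-1)+w(1).
    With center weight ``a`` these force w(+-1) = 1/4, w(+-2) = (1/2 - a)/2.
    """

    taps: tuple[float, float, float, float, float]

    @property
    def center_weight(self) -> float:
        return self.taps[2]

    def window2d(self) -> np.ndarray:
        """The 5x5 2-D window w(m, n) = w(m) w(n)."""
        t = np.asarray(self.taps, dtype=float)
        return np.outer(t, t)


def build_kernel(center_weight: float = DEFAULT_CENTER_WEIGHT) -> Kernel1D:
    """Solve the 5-tap constraint system for a given center weight.

    Parameters
    ----------
    center_weight : float
        w(0), must lie in (0, 1/2]. At 1/2 the outer taps vanish; above it
        they would turn negative, below 0 the kernel is degenerate.

    Returns
    -------
    Kernel1D
        taps ``((1/2-a)/2, 1/4, a, 1/4, (1/2-a)/2)``.
    """
    a = float(center_weight)
    if not (0.0 < a <= 0.5):
        raise ValueError(
            f"center_weight must be in (0, 1/2], got {center_weight!r}: "
            "outer taps w(+-2) = (1/2 - a)/2 would be negative or the kernel degenerate"
        )
    outer = (0.5 - a) / 2.0
    return Kernel1D(taps=(outer, 0.25, a, 0.25, outer))


def _as_image(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


def _sep_filter(img: np.ndarray, taps: np.ndarray) -> np.ndarray:
    # mirror = symmetric reflection without repeating the edge sample
    out = ndimage.correlate1d(img, taps, axis=0, mode="mirror")
    out = ndimage.correlate1d(out, taps, axis=1, mode="mirror")
    return out


def reduce_image(img: np.ndarray, k: Kernel1D | None = None) -> np.ndarray:
    """REDUCE: low-pass filter with the 5-tap window, then drop every other
    row and column. Output dimensions are the ceil-half of the input's."""
    img = _as_image(img)
    if img.shape[0] < 4 or img.shape[1] < 4:
        raise DecompositionDepthError(
            f"image {img.shape} too small to reduce (needs >= 4 rows and columns)"
        )
    k = k or build_kernel()
    taps = np.asarray(k.taps, dtype=float)
    return _sep_filter(img, taps)[::2, ::2]


def expand_image(
    img: np.ndarray, k: Kernel1D | None = None, target_shape: tuple[int, int] | None = None
) -> np.ndarray:
    """EXPAND: upsample by zero-insertion, filter with the window, x4 gain.

    ``target_shape`` must be ``2*dim`` or ``2*dim - 1`` per axis (the two
    sizes whose REDUCE gives ``dim``); defaults to doubling.
    """
    img = _as_image(img)
    r, c = img.shape
    if target_shape is None:
        target_shape = (2 * r, 2 * c)
    tr, tc = target_shape
    if tr not in (2 * r, 2 * r - 1) or tc not in (2 * c, 2 * c - 1):
        raise ValueError(
            f"target_shape {target_shape} incompatible with input {img.shape}: "
            f"each axis must be 2*dim or 2*dim-1"
        )
    k = k or build_kernel()
    up = np.zeros((tr, tc), dtype=float)
    up[::2, ::2] = img[: (tr + 1) // 2, : (tc + 1) // 2]
    taps = 2.0 * np.asarray(k.taps, dtype=float)  # x2 gain per axis
    return _sep_filter(up, taps)


def max_depth(shape: tuple[int, int], min_size: int = 4) -> int:
    """Largest N such that every level of an N-deep pyramid is >= min_size."""
    n = 0
    r, c = shape
    while (r + 1) // 2 >= min_size and (c + 1) // 2 >= min_size:
        r, c = (r + 1) // 2, (c + 1) // 2
        n += 1
    return n


@dataclass
class GaussianPyramid:
    """Levels of repeated REDUCE; ``levels[0]`` is the source image."""

    levels: list[np.ndarray]

    @property
    def depth(self) -> int:
        return len(self.levels) - 1


def gaussian_pyramid(img: np.ndarray, depth: int, k: Kernel1D | None = None) -> GaussianPyramid:
    """Build a Gaussian pyramid of the given depth (depth 0 = input only)."""
    img = _as_image(img)
    if depth < 0:
        raise ValueError(f"depth must be >= 0, got {depth}")
    feasible = max_depth(img.shape)
    if depth > feasible:
        raise DecompositionDepthError(
            f"depth {depth} infeasible for image {img.shape}; max feasible depth is {feasible}"
        )
    k = k or build_kernel()
    levels = [img]
    for _ in range(depth):
        levels.append(reduce_image(levels[-1], k))
    return GaussianPyramid(levels=levels)


@dataclass
class ContrastPyramid:
    """Contrast levels ``C_0..C_{N-1}`` plus the coarsest Gaussian level as top.

    ``levels[l] = G_l / EXPAND(G_{l+1}) - 1`` (values may be negative);
    ``top = G_N``. ``offset`` records the shift applied to the source before
    decomposition so reconstruction can undo it.
    """

    levels: list[np.ndarray]
    top: np.ndarray
    offset: float = 0.0
    eps: float = field(default=DEFAULT_EPS)

    @property
    def depth(self) -> int:
        return len(self.levels)

    def shapes(self) -> list[tuple[int, int]]:
        return [lvl.shape for lvl in self.levels] + [self.top.shape]


def contrast_decompose(
    img: np.ndarray,
    depth: int,
    k: Kernel1D | None = None,
    eps: float = DEFAULT_EPS,
    offset: float = DEFAULT_OFFSET,
) -> ContrastPyramid:
    """Decompose an image into its contrast pyramid.

    The input is shifted by ``offset`` first (inputs are [0,1]-normalized,
    so this bounds the ratio's denominator away from zero); the shift is
    stored and undone by :func:`contrast_reconstruct`.
    """
    img = _as_image(img) + offset
    k = k or build_kernel()
    gp = gaussian_pyramid(img, depth, k)
    levels = []
    for l in range(depth):
        g_up = expand_image(gp.levels[l + 1], k, target_shape=gp.levels[l].shape)
        levels.append(gp.levels[l] / (g_up + eps) - 1.0)
    return ContrastPyramid(levels=levels, top=gp.levels[depth].copy(), offset=offset, eps=eps)


def contrast_reconstruct(cp: ContrastPyramid, k: Kernel1D | None = None) -> np.ndarray:
    """Invert the contrast decomposition: ``G_l = (C_l + 1) * EXPAND(G_{l+1})``
    (the EXPAND here includes the same eps guard used in decomposition, so the
    round trip is exact to floating-point precision)."""
    k = k or build_kernel()
    g = cp.top
    for l in range(cp.depth - 1, -1, -1):
        c = cp.levels[l]
        g_up = expand_image(g, k, target_shape=c.shape)
        if g_up.shape != c.shape:
            raise ValueError(f"level {l} shape {c.shape} mismatches expanded {g_up.shape}")
        g = (c + 1.0) * (g_up + cp.eps)
    return g - cp.offset
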