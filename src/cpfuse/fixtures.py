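"""Synthetic multimodal phantoms and clear/blurred training corpora.

Stand-ins for co-registered structural/functional image pairs: parametric
scenes of random ellipses and ribbons sharing one geometry, rendered twice
with complementary contrast — one pseudo-modality emphasizes structure
rims (bone-like), the other interiors (soft-tissue-like) — plus fine
texture assigned to opposite compartments and seeded Gaussian noise. The
phantoms are geometric, not anatomical; fusion behavior is asserted
structurally (per-region detail transfer), which needs complementary local
sharpness, not realism.

The training-corpus builder applies the iterated-blur procedure (sigma 2,
7x7 support, five levels, each level blurring the previous) and samples 20
co-located 16x16 patch positions per clear/blurred combination, labeled
both ways, exactly mirroring how the patch classifier's training set is
manufactured from any grayscale corpus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse

from .network import PatchPair, make_blur_stack, sample_pairs

__all__ = ["PhantomSpec", "make_phantom_pair", "make_training_corpus", "corpus_split"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one reproducible phantom pair."""

    shape: tuple[int, int] = (128, 128)
    n_structures: int = 6
    rim_width: int = 2
    noise_sigma: float = 0.01
    texture_amp: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.shape[0] < 32 or self.shape[1] < 32:
            raise ValueError(f"phantom shape must be >= 32x32, got {self.shape}")


def make_phantom_pair(spec: PhantomSpec = PhantomSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Render one co-registered pseudo-modality pair in [0, 1].

    Both images share the ellipse geometry; image A gets bright rims and
    textured rims, image B bright interiors and textured interiors, so each
    half of the information lives sharply in exactly one source.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    interior = np.zeros((h, w), dtype=bool)
    labels = np.zeros((h, w), dtype=int)
    for i in range(spec.n_structures):
        cy = rng.uniform(0.15 * h, 0.85 * h)
        cx = rng.uniform(0.15 * w, 0.85 * w)
        ry = rng.uniform(0.06, 0.22) * h
        rx = rng.uniform(0.06, 0.22) * w
        rot = rng.uniform(0, np.pi)
        rr, cc = ellipse(cy, cx, ry, rx, shape=(h, w), rotation=rot)
        interior[rr, cc] = True
        labels[rr, cc] = i + 1
    eroded = ndimage.binary_erosion(interior, iterations=spec.rim_width)
    rim = interior & ~eroded
    core = eroded

    # per-structure interior brightness for the soft-tissue-like modality
    levels = rng.uniform(0.35, 0.85, size=spec.n_structures + 1)
    levels[0] = 0.0
    interior_map = levels[labels] * core

    texture = ndimage.gaussian_filter(rng.standard_normal((h, w)), 1.0)
    texture *= spec.texture_amp / max(texture.std(), 1e-12)

    a = 0.9 * rim + 0.25 * core + texture * rim
    b = interior_map + 0.15 * rim + texture * core

    a = a + rng.normal(0.0, spec.noise_sigma, size=(h, w))
    b = b + rng.normal(0.0, spec.noise_sigma, size=(h, w))
    return np.clip(a, 0.0, 1.0), np.clip(b, 0.0, 1.0)


def make_training_corpus(
    n_images: int,
    spec: PhantomSpec = PhantomSpec(),
    seed: int = 0,
    n_blur_levels: int = 5,
    pairs_per_level: int = 20,
) -> list[PatchPair]:
    """Clear/blurred patch corpus from ``n_images`` phantoms.

    Per phantom: an iterated blur stack (``n_blur_levels`` blurred versions
    of the clear image), and for each blurred level ``pairs_per_level``
    co-located 16x16 positions paired with the clear original, each emitted
    as one positive and one negative example — with the defaults 200
    labeled examples per phantom, balanced 50/50.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    rng = np.random.default_rng(seed)
    corpus: list[PatchPair] = []
    for i in range(n_images):
        sub = PhantomSpec(
            shape=spec.shape,
            n_structures=spec.n_structures,
            rim_width=spec.rim_width,
            noise_sigma=spec.noise_sigma,
            texture_amp=spec.texture_amp,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        img_a, img_b = make_phantom_pair(sub)
        # alternate which pseudo-modality feeds the classifier
        img = img_a if i % 2 == 0 else img_b
        stack = make_blur_stack(img, n_blur_levels)
        for blurred in stack[1:]:
            corpus.extend(sample_pairs(stack[0], blurred, pairs_per_level, rng))
    return corpus


def corpus_split(
    n_train_images: int,
    n_test_images: int,
    spec: PhantomSpec = PhantomSpec(),
    seed: int = 0,
) -> tuple[list[PatchPair], list[PatchPair]]:
    """Disjoint-seed train/held-out corpora (the held-out phantoms come from
    an independent seed stream, so no geometry is shared)."""
    train = make_training_corpus(n_train_images, spec, seed=seed)
    test = make_training_corpus(n_test_images, spec, seed=seed + 1_000_003)
    return train, test
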