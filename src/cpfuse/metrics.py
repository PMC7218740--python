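"""Objective fusion-quality metrics: QTE, QAB/F, QMI, QVIF.

Four reference-free fusion indices, each comparing the fused image F with
both sources A and B:

* ``q_te`` — Tsallis (nonextensive, order q) mutual-information index:
  for each source X, I_q(X;F) = H_q(X) - H_q(X|F) with the pseudo-additive
  conditional H_q(X|F) = (H_q(X,F) - H_q(F)) / (1 + (1-q) H_q(F)), each
  term normalized by H_q(X), summed over the two sources. The raw Tsallis
  entropy of F alone is exposed as :func:`tsallis_entropy`.
* ``q_abf`` — Xydeas–Petrović gradient-based edge-preservation index:
  Sobel strength/orientation per source, sigmoid-mapped preservation
  factors weighted by source edge strength. The sigmoid gains are
  normalized so a perfectly preserved edge scores exactly 1.
* ``q_mi`` — MI(A,F) + MI(B,F) in bits from 256-bin joint histograms.
* ``q_vif`` — pixel-domain multi-scale visual information fidelity of F
  w.r.t. each source under the usual Gaussian-channel model, averaged.

All metrics are deterministic. Intensities are assumed in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "MetricsReport",
    "tsallis_entropy",
    "q_te",
    "q_abf",
    "q_mi",
    "q_vif",
    "evaluate_fusion",
]

N_BINS = 256

# QAB/F sigmoid constants; gains chosen so Q(G=1, A=1) = 1 exactly
ABF_KG, ABF_SG = -15.0, 0.5
ABF_KA, ABF_SA = -22.0, 0.8
ABF_GG = 1.0 + np.exp(ABF_KG * (1.0 - ABF_SG))
ABF_GA = 1.0 + np.exp(ABF_KA * (1.0 - ABF_SA))

VIF_SIGMA_N_SQ = 2.0  # channel noise variance on the 0..255 intensity scale
TSALLIS_Q = 1.85


@dataclass(frozen=True)
class MetricsReport:
    """The four fusion scores for one (A, B, F) triple."""

    q_te: float
    q_abf: float
    q_mi: float
    q_vif: float

    def as_dict(self) -> dict[str, float]:
        return {"QTE": self.q_te, "QAB/F": self.q_abf, "QMI": self.q_mi, "QVIF": self.q_vif}

    def to_text(self) -> str:
        return "\n".join(f"{k}\t{v:.6f}" for k, v in self.as_dict().items())

    def as_row(self) -> list[float]:
        return [self.q_te, self.q_abf, self.q_mi, self.q_vif]


def _check_shapes(*imgs: np.ndarray) -> list[np.ndarray]:
    arrs = [np.asarray(im, dtype=float) for im in imgs]
    shape = arrs[0].shape
    for a in arrs[1:]:
        if a.shape != shape:
            raise ValueError(f"image shapes differ: {[a.shape for a in arrs]}")
    return arrs


def _hist2(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    h, _, _ = np.histogram2d(
        x.ravel(), y.ravel(), bins=N_BINS, range=[[0.0, 1.0], [0.0, 1.0]]
    )
    return h / h.sum()


def tsallis_entropy(img: np.ndarray, q: float = TSALLIS_Q) -> float:
    """Tsallis entropy of order q, (1 - sum p^q) / (q - 1), from a 256-bin
    histogram of the image."""
    if q == 1.0:
        raise ValueError("order q must differ from 1 (use Shannon entropy instead)")
    img = np.asarray(img, dtype=float)
    h, _ = np.histogram(img.ravel(), bins=N_BINS, range=(0.0, 1.0))
    p = h / h.sum()
    return float((1.0 - np.sum(p**q)) / (q - 1.0))


def _tsallis_joint(p: np.ndarray, q: float) -> float:
    return float((1.0 - np.sum(p**q)) / (q - 1.0))


def _tsallis_nmi(x: np.ndarray, f: np.ndarray, q: float) -> float:
    """Normalized nonextensive mutual information I_q(X;F) / H_q(X)."""
    pj = _hist2(x, f)
    hx = _tsallis_joint(pj.sum(axis=1), q)
    hf = _tsallis_joint(pj.sum(axis=0), q)
    hxf = _tsallis_joint(pj, q)
    if hx <= 0:
        warnings.warn("degenerate (constant) source image; Tsallis index term is 0")
        return 0.0
    h_cond = (hxf - hf) / (1.0 + (1.0 - q) * hf)
    return (hx - h_cond) / hx


def q_te(a: np.ndarray, b: np.ndarray, f: np.ndarray, q: float = TSALLIS_Q) -> float:
    """Tsallis mutual-information fusion index, summed over the two sources.

    Ranges over [0, 2]ish; 2 when F carries each source's full nonextensive
    information (e.g. F = A = B), near 0 when F is independent of both.
    """
    if q == 1.0:
        raise ValueError("order q must differ from 1")
    a, b, f = _check_shapes(a, b, f)
    return _tsallis_nmi(a, f, q) + _tsallis_nmi(b, f, q)


def q_mi(a: np.ndarray, b: np.ndarray, f: np.ndarray) -> float:
    """MI(A, F) + MI(B, F) in bits (256-bin joint histograms)."""
    a, b, f = _check_shapes(a, b, f)

    def mi(x, y):
        p = _hist2(x, y)
        px = p.sum(axis=1, keepdims=True)
        py = p.sum(axis=0, keepdims=True)
        nz = p > 0
        return float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))

    return mi(a, f) + mi(b, f)


def _sobel(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gx = ndimage.sobel(img, axis=1, mode="mirror")
    gy = ndimage.sobel(img, axis=0, mode="mirror")
    g = np.hypot(gx, gy)
    alpha = np.arctan2(gy, gx)
    # fold orientation into [-pi/2, pi/2): edges are undirected
    alpha = np.where(alpha >= np.pi / 2, alpha - np.pi, alpha)
    alpha = np.where(alpha < -np.pi / 2, alpha + np.pi, alpha)
    return g, alpha


def _edge_preservation(gs: np.ndarray, als: np.ndarray, gf: np.ndarray, alf: np.ndarray):
    """Per-pixel Q^{XF} edge preservation of source (gs, als) in F."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(gs > gf, gf / gs, gs / gf)
    both_zero = (gs == 0) & (gf == 0)
    ratio = np.where(both_zero, 1.0, np.nan_to_num(ratio))
    dalpha = np.abs(als - alf)
    dalpha = np.minimum(dalpha, np.pi - dalpha)
    afac = 1.0 - dalpha / (np.pi / 2)
    qg = ABF_GG / (1.0 + np.exp(ABF_KG * (ratio - ABF_SG)))
    qa = ABF_GA / (1.0 + np.exp(ABF_KA * (afac - ABF_SA)))
    return qg * qa


def q_abf(a: np.ndarray, b: np.ndarray, f: np.ndarray) -> float:
    """Xydeas–Petrović QAB/F edge-preservation index in [0, 1]."""
    a, b, f = _check_shapes(a, b, f)
    ga, ala = _sobel(a)
    gb, alb = _sobel(b)
    gf, alf = _sobel(f)
    qaf = _edge_preservation(ga, ala, gf, alf)
    qbf = _edge_preservation(gb, alb, gf, alf)
    denom = float((ga + gb).sum())
    if denom == 0:
        warnings.warn("all-flat source images; QAB/F is 0 by convention")
        return 0.0
    return float((qaf * ga + qbf * gb).sum() / denom)


def _vifp(ref: np.ndarray, dist: np.ndarray, sigma_n_sq: float = VIF_SIGMA_N_SQ) -> float:
    """Pixel-domain multi-scale VIF of ``dist`` against ``ref`` (0..255 scale)."""
    eps = 1e-10
    num = den = 0.0
    for scale in range(1, 5):
        n = 2 ** (4 - scale + 1) + 1
        sd = n / 5.0
        if scale > 1:
            ref = ndimage.gaussian_filter(ref, sd)[::2, ::2]
            dist = ndimage.gaussian_filter(dist, sd)[::2, ::2]
        mu1 = ndimage.gaussian_filter(ref, sd)
        mu2 = ndimage.gaussian_filter(dist, sd)
        s1 = ndimage.gaussian_filter(ref * ref, sd) - mu1 * mu1
        s2 = ndimage.gaussian_filter(dist * dist, sd) - mu2 * mu2
        s12 = ndimage.gaussian_filter(ref * dist, sd) - mu1 * mu2
        s1 = np.maximum(s1, 0.0)
        s2 = np.maximum(s2, 0.0)
        g = s12 / (s1 + eps)
        sv = s2 - g * s12
        g = np.where(s1 < eps, 0.0, g)
        sv = np.where(s1 < eps, s2, sv)
        sv = np.where(s2 < eps, 0.0, np.maximum(sv, 0.0))
        g = np.where(s2 < eps, 0.0, np.maximum(g, 0.0))
        num += float(np.log10(1.0 + g * g * s1 / (sv + sigma_n_sq)).sum())
        den += float(np.log10(1.0 + s1 / sigma_n_sq).sum())
    if den == 0:
        warnings.warn("constant reference image; VIF term is 0 by convention")
        return 0.0
    return num / den


def q_vif(a: np.ndarray, b: np.ndarray, f: np.ndarray) -> float:
    """Multi-scale VIF of the fused image against each source, averaged.

    Requires min dimension >= 32 (four dyadic scales)."""
    a, b, f = _check_shapes(a, b, f)
    if min(a.shape) < 32:
        raise ValueError(f"q_vif needs images with min dimension >= 32, got {a.shape}")
    return 0.5 * (_vifp(a * 255.0, f * 255.0) + _vifp(b * 255.0, f * 255.0))


def evaluate_fusion(a: np.ndarray, b: np.ndarray, f: np.ndarray) -> MetricsReport:
    """All four metrics for one fusion result."""
    return MetricsReport(
        q_te=q_te(a, b, f), q_abf=q_abf(a, b, f), q_mi=q_mi(a, b, f), q_vif=q_vif(a, b, f)
    )
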