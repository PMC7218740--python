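# Methods

`cpfuse` fuses two co-registered grayscale images — typically two medical
modalities of the same anatomy (MR/CT, MR/PET slices) — into one image that
keeps, at every location and scale, the information of whichever source is
locally the more informative. The design combines a *learned* per-pixel
activity comparison (a Siamese patch classifier) with a *fixed* multi-scale
decomposition (the contrast pyramid) and hand-designed per-level fusion
rules. This note records the model, its assumptions, every tunable that
matters, and the choices made where the design was genuinely open.

## 1. Pipeline overview

Given sources `A`, `B` (2-D, intensities normalized to [0, 1]):

1. The Siamese classifier, run fully convolutionally over the pair,
   produces a same-size weight map `W` with `W = 1` where `A` is judged
   locally sharper/clearer and `0` where `B` is.
2. `W` is decomposed by a Gaussian pyramid; `A` and `B` by contrast
   pyramids — all with the same depth `N` and the same 5-tap kernel.
3. Each level is fused by a thresholded region-energy rule (below).
4. The fused contrast pyramid is reconstructed and clipped to [0, 1].

## 2. Pyramid machinery

**Generating kernel.** A separable 5-tap window `w(m, n) = w(m) w(n)` whose
1-D taps satisfy four classical constraints — symmetry, normalization to 1,
equal contribution of odd and even taps — leaving one degree of freedom,
the center weight `a = w(0)`:

    w(0) = a,  w(±1) = 1/4,  w(±2) = (1/2 − a)/2,  a ∈ (0, 1/2].

The default `a = 3/8` gives the binomial-like taps (1/16, 1/4, 3/8, 1/4,
1/16); at `a = 1/2` the outer taps vanish. Outside (0, 1/2] the outer taps
would be negative and the kernel is rejected.

**REDUCE / EXPAND.** REDUCE filters with the separable window and drops
every other row/column (ceil-halving for odd sizes). EXPAND zero-inserts
onto a caller-specified target grid (either `2d` or `2d − 1` per axis),
filters, and multiplies by 4 — the gain exactly compensates the inserted
zeros, so a constant image stays constant. Borders use mirror reflection
without edge repeat everywhere; with a normalized kernel this avoids
darkening at image edges.

**Contrast pyramid.** Levels store local luminance contrast,

    C_l = G_l / EXPAND(G_{l+1}) − 1   (0 ≤ l < N),     C_N = G_N,

inverted exactly by `G_l = (C_l + 1) ⊙ EXPAND(G_{l+1})`. Because the level
is a *ratio*, the denominator must stay away from zero: inputs are shifted
by `offset = 1e−2` before decomposition (undone after reconstruction) and
an additive `eps = 1e−12` guards the denominator. A fixed shift — rather
than per-image min/max rescaling — is used deliberately: both sources must
live in the same affine frame, otherwise the inverse map of the *fused*
pyramid would be ill-defined. The round trip decompose → reconstruct is
exact to ~1e−15 for any input size and any feasible depth. Default depth
is `N = 4`, auto-capped so the coarsest level is at least 8×8 per side.

## 3. The Siamese patch classifier

**Task.** Given two co-located 16×16 patches, decide which is the clear
one. Class 1 means "the first patch is clear". This sharpness comparator,
trained only on synthetic blur, is what replaces a hand-designed activity
measure.

**Architecture.** Two parameter-sharing branches: conv 3×3 → ReLU →
conv 3×3 → ReLU → max-pool 2×2 (stride 2) → conv 3×3 → ReLU, all valid
padding, so a 16×16 patch maps to a 4×4 feature block. The branch outputs
are flattened, concatenated, and one fully connected layer yields two
scores read through a softmax. Channel widths are configuration, not
doctrine; the defaults (8, 16, 32) keep the feature-map count increasing
with depth and train in minutes on one CPU core. ReLU is likewise a
configuration choice (any standard saturating/non-saturating nonlinearity
would serve); biases start at 0 and weights use Xavier (Glorot-uniform)
initialization.

**Training data.** From any grayscale corpus: each image is blurred
iteratively (Gaussian, σ = 2, 7×7 support; each level blurs the previous)
into five fuzzy versions; for every (clear, blurred-level) combination, 20
random co-located 16×16 positions are sampled, each emitted twice — once
as a positive example (clear patch first) and once, operands swapped, as a
negative — giving 200 balanced examples per image. Patches are used as-is
in [0, 1], with no per-patch standardization.

**Optimization.** Momentum SGD on the batch-sum softmax loss
`L = Σ −log f(p_label)`, batch size 128:

    v ← 0.9 v − 0.0005 α w − α ∂L/∂w,     w ← w + v,

with initial rate α = 1e−4. The rate is cut to 10% whenever the mean epoch
loss improves by less than 1% relative — an automated stand-in for a
manual "cut when the loss plateaus" schedule, required for reproducible
tests. Training is deterministic given a seed. A non-finite loss raises a
divergence error naming the epoch. At the package's reference scale (200
phantom images → 40 000 labeled pairs) the classifier reaches perfect
held-out accuracy on unseen-seed fixtures within a single epoch; the
property suite trains for three.

**Dense application.** The fully connected head is rewritten as one 4×4
convolution per branch (their responses summed, plus the head bias), so
the network runs fully convolutionally over any-size pair and emits one
prediction per 16×16 window at stride 2 (the single pooling stage sets
the stride). Dense and patchwise scores agree to ~1e−7. Each window's
prediction is binarized — weight 1 to the whole window when the "first
source is clear" score wins, 0 otherwise — and overlapping windows are
averaged per pixel. Bottom/right margins not covered by a complete window
inherit the nearest covered pixel's weight. The result is the weight map
`W ∈ [0, 1]`, the per-pixel weight of source A.

## 4. Fusion rules

Per level `l`, over an odd local window (default 3×3, mirror-padded):

    E_X(x, y) = Σ_window C_X²                      (region energy)
    M(x, y)   = 2 Σ_window C_A C_B / (E_A + E_B)   (match measure, [−1, 1])

with `0/0 := 0`. The *sum* denominator is the standard match measure and
is what bounds `M` to [−1, 1]; the product-denominator variant (which is
unbounded) is kept behind a flag for comparison only.

The rule, per pixel, with threshold `T`:

* `M < T` (regions disagree): choose-max — take the coefficient of the
  source with larger region energy; ties go to A (deterministic).
* `M ≥ T` (regions agree): weighted mean `C_F = GW·C_A + (1 − GW)·C_B`,
  where `GW` is the weight map's Gaussian level — each source's
  coefficient is weighted by its own classifier support. (Assigning the
  *smaller* weight to the higher-energy source instead demonstrably pulls
  the fusion toward the blurrier source on directional fixtures, and a
  weight defined relative to the per-pixel energy ordering could not be
  pre-decomposed into a single pyramid; both points force this form.)

Thresholds: `T1 = 3` for levels `0 ≤ l < N` and `T2 = 0.6` for the top
level. Since `M ≤ 1`, `T1 = 3` makes every non-top level pure choose-max;
`T1` remains exposed in configuration rather than hard-coded. The top
(coarse Gaussian) level uses the weighted mean wherever the sources'
coarse content agrees, which is where the learned weights matter most.
Sweeping `T2` from below −1 to above 1 moves the top level continuously
from pure weighted mean to pure choose-max.

## 5. Quality metrics

All four are deterministic, operate on [0, 1] images, and use 256-bin
histograms where histograms are needed.

* **QTE** (Tsallis index, order `q = 1.85`): for each source `X`, the
  nonextensive mutual information `I_q(X;F) = H_q(X) − H_q(X|F)` with the
  pseudo-additive conditional `H_q(X|F) = (H_q(X,F) − H_q(F)) /
  (1 + (1 − q) H_q(F))`, normalized by `H_q(X)` and summed over both
  sources (maximum 2, attained at `F = A = B`; ≈ 0 for `F` independent of
  the sources). This entropy-difference form was chosen over a plug-in
  Tsallis-divergence estimator because the latter's sparse-histogram bias
  at 256 bins is of order 1 on desk-scale images, destroying the
  independence limit; plug-in `Σ p^q` for `q ≈ 2` is nearly unbiased. The
  raw Tsallis entropy of `F` alone, `(1 − Σ p^q)/(q − 1)`, is exposed
  separately.
* **QAB/F** (Xydeas–Petrović): Sobel strength/orientation per source,
  sigmoid-mapped strength- and orientation-preservation factors
  multiplied and weighted by source edge strength. Slopes and offsets are
  the classical (−15, 0.5) and (−22, 0.8); the gains are normalized as
  `Γ = 1 + exp(κ(1 − σ))` so a perfectly preserved edge scores exactly 1
  (the classical gains top out near 0.975, which makes "perfect fusion"
  scores needlessly opaque). All-flat inputs return 0 with a warning.
* **QMI**: `MI(A,F) + MI(B,F)` in bits. Note the plug-in estimator's
  positive bias grows with occupied-histogram sparsity; comparisons are
  meaningful between fusions of the *same* source pair.
* **QVIF**: pixel-domain multi-scale visual information fidelity (four
  dyadic scales, Gaussian windows, channel noise variance 2 on the 0–255
  scale) of `F` against each source, averaged. Requires min dimension 32.

On fixtures, all four rank perfect fusion (`F = A = B`) above the 50/50
average above an independent-noise "fusion".

## 6. Synthetic fixtures

The phantom generator emulates co-registered structural/functional pairs:
random ellipses sharing one geometry, rendered twice — modality A bright
and textured on structure *rims* (bone-like), modality B bright and
textured in *interiors* with per-structure intensity levels
(soft-tissue-like) — plus Gaussian pixel noise (σ = 0.01 default). Each
half of the scene's detail thus lives sharply in exactly one source, which
is the property the fusion tests assert (per-region gradient-energy
transfer ≥ 95% of the sharper source). The training-corpus builder applies
the iterated-blur/patch-sampling procedure of section 3 above to these
phantoms.

What the phantoms do **not** emulate: anatomical shape statistics, imaging
physics (partial volume, bias fields, Rician noise), inter-modality
misregistration, or pseudo-color functional maps. Passing tests therefore
demonstrate the pipeline's mechanics — exact invertibility, rule
correctness, learned-comparator trainability and directional transfer —
not clinical image quality, which requires real registered studies.

## 7. Problem sizes and numerical choices

The reference scale used by the property suite: 200 phantoms → 40 000
labeled pairs, ≤ 10 epochs (three suffice), held-out accuracy ≥ 0.9 on
unseen-seed fixtures; 1 000 random images for the round-trip bound
(≤ 1e−9 max abs error); 100 random triples against the scalar rule
oracle (exact equality); 50 random pairs for dense/patchwise equivalence
(≤ 1e−6). Float32 is used inside the network (BLAS throughput), float64
everywhere else. Degenerate inputs: images smaller than 4×4 cannot be
reduced; requested depths beyond feasibility raise an error naming the
maximum; non-finite pixels are rejected on entry.

## 8. Known limitations

* Color (PET/SPECT pseudo-color) handling is a convention, not a model:
  fuse the luminance channel, re-attach chroma externally if desired.
* The weight map is piecewise-constant at window granularity (stride 2,
  16×16 support); very fine focus boundaries are smoothed by the overlap
  averaging and the Gaussian decomposition of `W`.
* The classifier is trained on Gaussian blur only; other degradations
  (motion smear, noise, contrast loss) are judged only insofar as they
  resemble blur.
* `QMI`/`QTE` plug-in histogram estimators carry finite-sample bias;
  absolute values depend on image size.
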