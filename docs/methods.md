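# Methods

## Overview

`hmaxmli` implements a fully synthetic perception experiment: a feed-forward
HMAX hierarchy with a linear-SVM decision layer is trained to judge which of
two horizontal lines is longer, and is then probed with Müller-Lyer figures.
Because every input is generated by the package itself, every result is
reproducible from a seed.

The pipeline is

    stimulus (256×256 binary ink) → image pyramid (10 levels, 2^(1/4) steps)
    → S1 (11×11 Gabor filters, 12 orientations, normalised + rectified)
    → C1 (max over 10×10 windows, stride 5, 2 adjacent scales → 9 bands)
    → S2 (Gaussian similarity to 1000 C1 patches sampled during training)
    → C2 (global max per prototype → a 1000-dim scale/position-free vector)
    → linear SVM (LONG vs SHORT on unit-normalised C2 vectors)

## Stimuli

Each image contains a top and a bottom horizontal shaft drawn with a 2×2
pixel pen (binary ink, no anti-aliasing), centred horizontally. The
reference shaft length is uniform on [120, 240] px and the comparator is
2–62 px shorter; vertical positions are uniform on [48, 108] px (top) and
[148, 208] px (bottom); fin lengths uniform on [15, 40] px; fin angles
uniform on [10°, 90°] for the cross-fin (XF) training style and [10°, 70°]
for the LR control and ML test styles. The label is LONG iff the top shaft
is strictly longer.

Fin geometry: fins attach at both shaft ends, mirrored above/below the
shaft at ± the fin angle. XF draws all four fin directions at each end
(no net illusion, every feature of the test styles present). LR draws
left-pointing arrowheads on the top line and right-pointing on the bottom
(equal feature count to ML, no consistent wings-in/out assignment). ML
draws arrowtails (wings out) on the top line and arrowheads (wings in) on
the bottom — the arrangement that makes humans over-report "top longer".

One rendering choice deserves note: with a 240 px shaft centred on a 256 px
canvas, outward-pointing fins at shallow angles necessarily extend past the
canvas; no horizontal placement can avoid this since the full figure can be
up to ~320 px wide. Fin ink is therefore clipped at the canvas border
(shafts themselves always fit and invalid shafts are rejected). This keeps
every sampled parameter exactly uniform over its stated range instead of
truncating the joint distribution by rejection.

Psychometric sweeps fix the top−bottom difference exactly (−60…60 px in
10 px steps by default), draw the reference length uniformly as usual, and
either fix the fin angle (ML conditions) or re-draw it per image (the
"all angles collapsed" control).

## The hierarchy

**Image layer.** Ten levels, each 2^(1/4) smaller, sides
256, 215, 181, 152, 128, 108, 91, 76, 64, 54. Resampling is antialiased
bicubic (Pillow's convolution-based `BICUBIC`).

**S1.** Gabor kernels with wavelength 5.6 px, envelope σ = 4.5, aspect
ratio 0.3, cosine phase, 12 orientations evenly spaced over 180°, support
11×11, each kernel zero-mean and unit-norm. The response is
|kernel · patch| / ‖patch‖ — contrast-polarity invariant and bounded in
[0, 1] by Cauchy–Schwarz; constant regions respond exactly 0.

**C1.** Per orientation, the max over 10×10 S1 windows with stride 5,
then the elementwise max across the two adjacent scale levels of each band
(10 levels → 9 bands). Orientations are never merged. Window grids and the
cross-scale crop are *centred*: rows/columns that do not fit a whole stride
are split between both edges. The corner-anchored alternative
under-represents the bottom/right image edge at coarse scales and measurably
biases the network's top-vs-bottom length comparison (control PSE of
+16…+21 px, where an unbiased observer must sit near 0); centring removes
most of that artifact and is the registration closest to aligned
receptive-field centres. When the excess is odd the extra cell goes to the
top/left (round-up split): this direction balances the residual half-cell
asymmetry introduced by the 2×2 pen (which stamps down-right of the ideal
path) and brings the control PSE to within a few pixels of zero with
balanced per-category accuracy. Both alignment choices were calibrated
against the control condition's required symmetry only, never against the
Müller-Lyer conditions.

**S2/C2.** During training, 1000 patches (n×n×12 orientations,
n ∈ {4, 8, 12, 16}, uniform over images, bands, positions and sizes) are
sampled from the training images' C1 maps; each records its provenance and
is re-extractable bit-for-bit. At test time each prototype P is matched at
every position and scale: response = exp(−‖X−P‖² / (2σ²m)) with m the
element count and σ = 0.05 per element; C2 keeps the global max per
prototype, giving values in (0, 1]. σ was set from the C1 statistics of
pilot stimuli so that best-match distances span a usable response range
(per-element RMS distances of ~0.05–0.12 would otherwise saturate near 1);
a normalised-dot-product similarity is available via configuration.

**Decision layer.** C2 vectors are scaled to unit L2 norm and classified
with a linear max-margin SVM (for two classes, all-pairs with majority
voting reduces to a single binary machine). Decision values are signed so
positive ⇒ LONG; an exact tie goes to LONG. The regularisation parameter
defaults to C = 10⁴: on unit-norm 1000-dimensional vectors the conventional
C = 1 under-fits drastically (67% training accuracy); C was calibrated on
control accuracy only — the same selection rule the reference experiment
used to fix its free parameters — and accuracy saturates for C ≥ 10⁴.

## Experiments

Each run is fully fresh: new training images, newly sampled prototypes, a
newly trained SVM and new test images, so across-run error bars are honest
SEMs. The default protocol is 450 XF training images (225 per category),
150 test images per category and 1000 prototypes.

* **Control accuracy**: LR test accuracy, overall and per category, vs
  network size.
* **Illusion effect**: LR vs ML accuracy per category, with a paired
  two-tailed t-test for the within-control category difference and
  two-sample equal-variance t-tests for LR-vs-ML per category.
* **Psychometrics**: proportion-classified-LONG vs signed length
  difference, per condition; a two-parameter logistic is fitted by maximum
  likelihood on the binomial counts (binomial GLM, logit link) and the PSE
  is the 50% crossing. Negative PSE = the top (arrowtail) line must be
  physically shorter to appear equal, i.e. the Müller-Lyer direction.
  Degenerate curves (all-one-side responses, < 4 distinct differences) and
  PSEs outside the measured difference range raise rather than extrapolate.

### Post-hoc feature analysis

Feature influence is the absolute linear-SVM weight per prototype (the
canonical choice for a linear binary machine). The receptive-field bounding
box of a prototype of size n at band b is
(5(n−1) + 10 + 11 − 1) level pixels at the coarser level of the band,
mapped to input pixels through that level's scale and clipped to 256; the
arithmetic is validated in-suite by a perturbation oracle (flipping input
pixels inside/outside the predicted box and observing the C1 patch). An
ideal radial Fourier filter provides the high-/low-pass illustration of why
wings-out figures elongate under low-pass filtering; complementary masks
reconstruct the image exactly.

## Problem sizes used by the test-suite and acceptance script

The reference protocol (10 runs × 150 test images per category, plus sweeps)
is scaled down to keep full-fidelity networks (d = 1000, 450 training
images — these are never reduced): the suite trains 5 networks for the
accuracy/illusion statistics (50 control and 50 ML test images per category
per run) and measures psychometric sweeps (4 conditions × 13 differences ×
40 images) on 3 of them; the acceptance script uses 3 runs, 100 test images
per category, and 40°/20° sweeps at 50 images per difference. Per-run PSEs
are averaged; pooled-count fits give the same picture.

## What the generator does and does not emulate

The stimuli reproduce the study conditions exactly (ranges above) and are
noise-free binary drawings; there is no luminance noise, no natural-image
context, no 3-D structure. Passing tests therefore show that the
*architecture* reproduces the illusion under the stated stimulus
distribution — they say nothing about natural images, other Müller-Lyer
variants (circle/square terminators, shaftless forms), or human viewing
conditions.

## Known limitations

* Control accuracy plateaus at ~82–90% across runs (mean ~85%), below the
  90.3% reported for the original; the remaining gap is consistent with
  undocumented implementation details of the original code base (e.g. its
  lateral-inhibition defaults, which are out of scope here).
* The illusion magnitude at intermediate angles runs somewhat stronger than
  the reference values (see the acceptance results); the 20° condition, the
  illusion direction and the angle ordering reproduce well.
* The feature-weight analysis comes out the other way around here: the
  most influential SVM features tend to have *larger* receptive boxes than
  the population median (mostly 12–16-unit patches at mid-scale bands), so
  the corresponding in-suite tendency check fails by design rather than by
  accident. In this implementation the length decision leans on
  coarse-scale structure; a different S2 similarity scaling or the
  original's inhibition machinery may be needed to make fine-scale features
  carry the decision.
* The logistic has no lapse-rate parameter (fixed at 0); with near-ceiling
  performance at ±60 px this is adequate, but very shallow curves would be
  better served by a lapse-rate extension.
* Max ties are broken by first occurrence in scan order; this never affects
  values, only provenance bookkeeping.
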