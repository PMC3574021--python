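"""Post-hoc analyses of a trained network.

Three analyses probe *how* the decision layer uses the learned features:

* :func:`feature_influence` / :func:`top_k` — rank prototypes by the
  absolute weight the linear SVM assigns them.
* :func:`receptive_bbox` — the side length, in input-image pixels, of the
  region of the 256×256 input that can influence a prototype's C1 patch
  (its receptive-field bounding box).  Within this hierarchy, bounding-box
  size is inversely related to the spatial-frequency content a feature can
  carry, so comparing the boxes of the most influential features against
  the population tests whether the decision relies on low spatial
  frequencies.
* :func:`frequency_filter_demo` — ideal radial high-/low-pass filtering of
  a stimulus in the Fourier domain (e.g. at 5 cycles/image), which makes
  the low-frequency elongation of a wings-out figure directly visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decision import TrainedClassifier
from .hmax import HmaxConfig, Prototype


@dataclass
class FeatureInfluence:
    """Influence of one S2 prototype on the linear decision."""

    index: int
    influence: float         # |linear SVM weight|
    bbox_side: float | None  # receptive-field box in input pixels
    patch_size: int | None
    band: int | None


def receptive_bbox(proto: Prototype, config: HmaxConfig | None = None) -> float:
    """Receptive-field side length of a prototype, in input-image pixels.

    An n×n C1 patch spans ``stride·(n−1) + pool`` S1 units, and each S1 unit
    sees ``gabor`` pixels of its pyramid level, giving
    ``stride·(n−1) + pool + gabor − 1`` level pixels.  The box is evaluated
    at the coarser of the band's two levels (the larger, governing extent)
    and mapped back to input pixels through that level's scale factor,
    clipped to the input size.
    """
    config = config or HmaxConfig()
    if proto.source is None:
        raise ValueError("prototype has no recorded provenance")
    _, band, _, _ = proto.source
    n = proto.size
    level_extent = (config.c1_stride * (n - 1) + config.c1_pool_size
                    + config.gabor_size - 1)
    coarse_level = min(band + config.c1_scale_depth - 1, config.n_levels - 1)
    side = config.pyramid_sides()[coarse_level]
    return float(min(level_extent * config.input_size / side,
                     config.input_size))


def feature_influence(clf: TrainedClassifier, prototypes=None,
                      config: HmaxConfig | None = None) -> list:
    """One influence score per prototype: the absolute linear SVM weight.

    When the prototype list is supplied, each entry also carries the
    receptive-field bounding box and provenance of that prototype.
    """
    weights = np.asarray(clf.weights, dtype=np.float64)
    if weights.ndim != 1:
        raise ValueError("feature influence requires a linear binary classifier")
    out = []
    for i, w in enumerate(np.abs(weights)):
        if prototypes is not None:
            p = prototypes[i]
            out.append(FeatureInfluence(index=i, influence=float(w),
                                        bbox_side=receptive_bbox(p, config),
                                        patch_size=p.size, band=p.source[1]))
        else:
            out.append(FeatureInfluence(index=i, influence=float(w),
                                        bbox_side=None, patch_size=None,
                                        band=None))
    return out


def top_k(influences, k: int) -> list:
    """The k most influential features, descending; ties broken by index."""
    if k > len(influences):
        raise ValueError("k exceeds the number of features")
    order = sorted(influences, key=lambda f: (-f.influence, f.index))
    return order[:k]


def influence_table(influences, k: int | None = None):
    """Ranked (rank, index, influence, bbox, patch size, band) DataFrame."""
    import pandas as pd
    ranked = top_k(influences, k if k is not None else len(influences))
    return pd.DataFrame({
        "rank": np.arange(1, len(ranked) + 1),
        "prototype": [f.index for f in ranked],
        "influence": [f.influence for f in ranked],
        "bbox_side": [f.bbox_side for f in ranked],
        "patch_size": [f.patch_size for f in ranked],
        "band": [f.band for f in ranked],
    })


def frequency_filter_demo(image: np.ndarray, cutoff: float,
                          mode: str = "low") -> np.ndarray:
    """Ideal radial Fourier filter at ``cutoff`` cycles per image.

    The low- and high-pass masks at the same cutoff partition the spectrum
    (radius ≤ cutoff vs > cutoff), so their outputs sum to the original
    image exactly.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("expected a square greyscale image")
    if mode not in ("low", "high"):
        raise ValueError("mode must be 'low' or 'high'")
    n = image.shape[0]
    f = np.fft.fftfreq(n) * n               # cycles per image
    r = np.hypot(*np.meshgrid(f, f, indexing="ij"))
    mask = (r <= cutoff) if mode == "low" else (r > cutoff)
    return np.real(np.fft.ifft2(np.fft.fft2(image) * mask))


def blob_extent(image: np.ndarray, axis: int = 1) -> float:
    """Second-moment (RMS) extent of the ink distribution along an axis.

    Operates on ink intensity (darkness = 1 − image); used to quantify the
    elongation of low-pass-filtered figures.
    """
    ink = np.clip(1.0 - np.asarray(image, dtype=np.float64), 0.0, None)
    total = ink.sum()
    if total == 0:
        return 0.0
    coords = np.arange(image.shape[axis], dtype=np.float64)
    marginal = ink.sum(axis=1 - axis)
    mean = (coords * marginal).sum() / total
    var = (((coords - mean) ** 2) * marginal).sum() / total
    return float(np.sqrt(var))
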