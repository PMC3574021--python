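"""Feed-forward HMAX feature hierarchy.

The hierarchy alternates template-matching ("simple") and max-pooling
("complex") stages, mirroring the simple/complex cell organisation of the
ventral visual stream:

    image pyramid  →  S1 (Gabor filtering)  →  C1 (local max pooling)
                   →  S2 (learned prototype matching)  →  C2 (global max)

* **Image layer** — a 10-level pyramid, each level 2^(1/4) smaller than the
  previous, built with bicubic interpolation from the 256×256 input.
* **S1** — 11×11 Gabor filters at 12 orientations applied at every position
  of every level; responses are divided by the local patch norm and
  rectified, so they are contrast-polarity invariant and lie in [0, 1].
* **C1** — per orientation, the max over 10×10 spatial windows (stride 5)
  spanning 2 adjacent scale levels; 10 levels therefore give 9 scale bands.
* **S2** — Gaussian similarity between every C1 patch and a bank of
  prototype patches randomly sampled from the C1 layers of training images.
* **C2** — the global max of each prototype's S2 response over all positions
  and scales: a d-dimensional, position- and scale-invariant "bag of
  features" vector, entries in (0, 1].

The heavy inner loops (Gabor filtering via cached FFTs, patch matching via
BLAS matrix products) run in float32; ``apply_s2``/``pool_c2`` provide the
explicit per-prototype response maps and ``encode`` a fused fast path that
is tested to agree with them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.fft
from numpy.lib.stride_tricks import sliding_window_view
from PIL import Image
from scipy.ndimage import uniform_filter

DTYPE = np.float32


@dataclass(frozen=True)
class HmaxConfig:
    """All layer parameters of the hierarchy.

    The Gabor parameters are the published defaults for 11×11 filters
    (wavelength ≈ 5.6 px, envelope σ ≈ 4.5, aspect ratio 0.3, cosine phase).
    ``s2_sigma`` is the per-element width of the Gaussian similarity: the
    response to a patch X for prototype P with m elements is
    ``exp(-||X-P||² / (2·s2_sigma²·m))``.  The default 0.05 matches the
    per-element RMS distance of well-matching C1 patches on these sparse
    line stimuli, so responses span the full (0, 1] range instead of
    saturating near 1.
    """

    input_size: int = 256
    n_levels: int = 10
    scale_factor: float = 2.0 ** 0.25
    gabor_size: int = 11
    n_orientations: int = 12
    gabor_wavelength: float = 5.6
    gabor_sigma: float = 4.5
    gabor_aspect: float = 0.3
    c1_pool_size: int = 10
    c1_stride: int = 5
    c1_scale_depth: int = 2
    prototype_sizes: tuple = (4, 8, 12, 16)
    s2_sigma: float = 0.05
    s2_similarity: str = "gaussian"     # "gaussian" or "dot"

    def pyramid_sides(self) -> list[int]:
        return [int(round(self.input_size * self.scale_factor ** (-k)))
                for k in range(self.n_levels)]

    @property
    def n_bands(self) -> int:
        return self.n_levels - self.c1_scale_depth + 1


@dataclass
class ImagePyramid:
    """Multi-scale greyscale representation of one input image."""

    levels: list
    config: HmaxConfig


@dataclass
class GaborBank:
    """12 oriented, zero-mean, unit-norm 11×11 Gabor kernels."""

    kernels: np.ndarray          # (n_orientations, size, size)
    thetas: np.ndarray           # radians
    config: HmaxConfig
    _fft_cache: dict = field(default_factory=dict, repr=False)


@dataclass
class Prototype:
    """A C1 sub-patch sampled during feature learning (an S2 template).

    ``patch`` has shape (n_orientations, n, n); ``source`` records where it
    was cut from: (training-image index, scale band, row, col).
    """

    patch: np.ndarray
    size: int
    source: tuple


# ---------------------------------------------------------------------------
# image layer

def build_pyramid(image: np.ndarray, config: HmaxConfig | None = None) -> ImagePyramid:
    """Bicubic 10-level pyramid; level sides 256, 215, 181, ..., 54."""
    config = config or HmaxConfig()
    image = np.asarray(image, dtype=np.float64)
    if image.shape != (config.input_size, config.input_size):
        raise ValueError(
            f"expected a {config.input_size}×{config.input_size} image, "
            f"got {image.shape}")
    base = image.astype(DTYPE)
    pim = Image.fromarray(base, mode="F")
    levels = [base]
    for side in config.pyramid_sides()[1:]:
        # Pillow's BICUBIC resampling is convolution-based (antialiased)
        levels.append(np.asarray(pim.resize((side, side), Image.BICUBIC),
                                 dtype=DTYPE))
    return ImagePyramid(levels=levels, config=config)


# ---------------------------------------------------------------------------
# S1: Gabor filtering

def make_gabor_bank(config: HmaxConfig | None = None) -> GaborBank:
    """Build the oriented filter bank; each kernel zero-mean and unit-norm."""
    config = config or HmaxConfig()
    half = config.gabor_size // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(np.float64)
    thetas = np.arange(config.n_orientations) * np.pi / config.n_orientations
    kernels = np.empty((config.n_orientations,) + x.shape)
    for i, th in enumerate(thetas):
        xr = x * np.cos(th) + y * np.sin(th)
        yr = -x * np.sin(th) + y * np.cos(th)
        g = (np.exp(-(xr ** 2 + (config.gabor_aspect * yr) ** 2)
                    / (2.0 * config.gabor_sigma ** 2))
             * np.cos(2.0 * np.pi * xr / config.gabor_wavelength))
        g -= g.mean()
        g /= np.linalg.norm(g)
        kernels[i] = g
    return GaborBank(kernels=kernels.astype(DTYPE), thetas=thetas, config=config)


def apply_s1(pyramid: ImagePyramid, bank: GaborBank) -> list:
    """Normalised, rectified Gabor responses at every level.

    Returns one array of shape (n_orientations, m-g+1, m-g+1) per level
    (``None`` for levels smaller than the kernel support).  The response is
    |filter · patch| / ||patch||, which lies in [0, 1] because the kernels
    are unit-norm, and is identically 0 on constant image regions because
    they are zero-mean.
    """
    cfg = pyramid.config
    g = cfg.gabor_size
    out = []
    for level in pyramid.levels:
        m = level.shape[0]
        if m < g:
            out.append(None)
            continue
        fshape = tuple(scipy.fft.next_fast_len(m + g - 1, real=True)
                       for _ in range(2))
        key = (m, fshape)
        if key not in bank._fft_cache:
            # kernels are even-symmetric, so convolution equals correlation
            bank._fft_cache[key] = scipy.fft.rfft2(bank.kernels, s=fshape,
                                                   axes=(-2, -1))
        lf = scipy.fft.rfft2(level, s=fshape)
        full = scipy.fft.irfft2(lf[None] * bank._fft_cache[key], s=fshape,
                                axes=(-2, -1))
        resp = full[:, g - 1:m, g - 1:m]
        np.abs(resp, out=resp)
        # local L2 norm of each g×g patch
        sq = uniform_filter(level.astype(np.float64) ** 2, size=g,
                            mode="constant") * (g * g)
        half = g // 2
        norms = np.sqrt(np.clip(sq[half:m - half, half:m - half], 0.0, None))
        resp /= np.where(norms > 1e-9, norms, np.inf).astype(DTYPE)[None]
        np.clip(resp, 0.0, 1.0, out=resp)
        out.append(np.ascontiguousarray(resp))
    return out


# ---------------------------------------------------------------------------
# C1: local max pooling

def _blockwise_pairmax(a: np.ndarray, stride: int, axis: int,
                       offset: int) -> np.ndarray:
    """Max over windows of 2·stride with step stride along one axis."""
    a = np.moveaxis(a, axis, -1)[..., offset:]
    nb = a.shape[-1] // stride
    blocks = a[..., :nb * stride].reshape(a.shape[:-1] + (nb, stride)).max(-1)
    out = np.maximum(blocks[..., :-1], blocks[..., 1:])
    return np.moveaxis(out, -1, axis)


def _pool_offset(m: int, size: int, stride: int) -> int:
    """Centre the window grid so leftover rows split between both edges."""
    return ((m - size) % stride) // 2


def _spatial_maxpool(s1_level: np.ndarray, size: int, stride: int) -> np.ndarray:
    if s1_level.shape[1] < size or s1_level.shape[2] < size:
        return None
    off1 = _pool_offset(s1_level.shape[1], size, stride)
    off2 = _pool_offset(s1_level.shape[2], size, stride)
    if size == 2 * stride:
        # separable two-block decomposition of the strided max window
        return _blockwise_pairmax(
            _blockwise_pairmax(s1_level, stride, 1, off1), stride, 2, off2)
    win = sliding_window_view(s1_level, (size, size), axis=(1, 2))
    return np.ascontiguousarray(
        win[:, off1::stride, off2::stride]).max(axis=(-2, -1))


def pool_c1(s1_maps: list, config: HmaxConfig | None = None) -> list:
    """Max over 10×10 spatial windows (stride 5) and 2 adjacent scales.

    Orientations are never merged; output is one (n_orientations, h, w)
    array per scale band (9 bands for 10 levels).
    """
    config = config or HmaxConfig()
    pooled = [None if s is None else
              _spatial_maxpool(s, config.c1_pool_size, config.c1_stride)
              for s in s1_maps]
    bands = []
    for b in range(len(pooled) - config.c1_scale_depth + 1):
        group = [p for p in pooled[b:b + config.c1_scale_depth] if p is not None]
        if not group:
            bands.append(None)
            continue
        h = min(p.shape[1] for p in group)
        w = min(p.shape[2] for p in group)
        acc = None
        for p in group:
            # centre-crop so excess rows/cols split between both edges,
            # keeping the cross-scale merge free of a bottom/right bias;
            # round-up split empirically balances the residual half-cell
            # asymmetry of the 2x2 pen (anchored down-right)
            r0 = (p.shape[1] - h + 1) // 2
            c0 = (p.shape[2] - w + 1) // 2
            cut = p[:, r0:r0 + h, c0:c0 + w]
            acc = cut.copy() if acc is None else np.maximum(acc, cut, out=acc)
        bands.append(acc)
    return bands


def compute_c1(image: np.ndarray, bank: GaborBank) -> list:
    """Image → C1 bands (the shared front end of training and testing)."""
    return pool_c1(apply_s1(build_pyramid(image, bank.config), bank),
                   bank.config)


# ---------------------------------------------------------------------------
# S2/C2: learned prototype features

def sample_prototypes(c1_sets: Sequence[list], d: int,
                      size_set: Sequence[int] | None = None,
                      rng=None, config: HmaxConfig | None = None,
                      ) -> list[Prototype]:
    """Sample d patches uniformly over images × bands × positions × sizes.

    A draw whose patch does not fit at the sampled band is rejected and
    redrawn.  Each prototype records its provenance so it can be re-extracted
    bit-for-bit from the training C1 maps.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if not len(c1_sets):
        raise ValueError("need at least one training C1 set")
    config = config or HmaxConfig()
    size_set = tuple(size_set or config.prototype_sizes)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    protos = []
    while len(protos) < d:
        img = int(rng.integers(len(c1_sets)))
        n = int(size_set[rng.integers(len(size_set))])
        band_idx = int(rng.integers(len(c1_sets[img])))
        band = c1_sets[img][band_idx]
        if band is None or band.shape[1] < n or band.shape[2] < n:
            continue
        r = int(rng.integers(band.shape[1] - n + 1))
        c = int(rng.integers(band.shape[2] - n + 1))
        patch = np.array(band[:, r:r + n, c:c + n], dtype=DTYPE)
        protos.append(Prototype(patch=patch, size=n, source=(img, band_idx, r, c)))
    return protos


class PrototypeBank:
    """Prototypes grouped by patch size for BLAS-friendly matching."""

    def __init__(self, prototypes: Sequence[Prototype], config: HmaxConfig):
        self.prototypes = list(prototypes)
        self.config = config
        self.groups = {}
        for n in sorted({p.size for p in self.prototypes}):
            idx = np.array([i for i, p in enumerate(self.prototypes)
                            if p.size == n])
            w = np.stack([self.prototypes[i].patch.reshape(-1) for i in idx])
            self.groups[n] = (idx, np.ascontiguousarray(w, dtype=DTYPE),
                              (w.astype(np.float64) ** 2).sum(axis=1))

    def __len__(self):
        return len(self.prototypes)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for p in self.prototypes:
            h.update(np.ascontiguousarray(p.patch, dtype=DTYPE).tobytes())
        return h.hexdigest()[:16]


def _band_patches(band: np.ndarray, n: int):
    """im2col: all n×n×orient patches of a C1 band, plus their square norms."""
    k, h, w = band.shape
    win = sliding_window_view(band, (n, n), axis=(1, 2))     # (k, h', w', n, n)
    x = np.ascontiguousarray(win.transpose(1, 2, 0, 3, 4)).reshape(
        (h - n + 1) * (w - n + 1), k * n * n)
    sq = np.einsum("ij,ij->i", x, x)
    return x, sq


def _similarity(dist_sq: np.ndarray, m: int, config: HmaxConfig) -> np.ndarray:
    return np.exp(-np.clip(dist_sq, 0.0, None)
                  / (2.0 * config.s2_sigma ** 2 * m))


def apply_s2(c1_bands: list, prototypes: Sequence[Prototype],
             config: HmaxConfig | None = None) -> list:
    """Per-prototype response maps at every C1 position and scale.

    Returns, for each prototype, a list with one 2-D response map per band
    (``None`` where the patch does not fit).  Intended for inspection and
    testing; ``encode`` computes only the global maxima and is much faster.
    """
    config = config or HmaxConfig()
    maps = [[None] * len(c1_bands) for _ in prototypes]
    for bi, band in enumerate(c1_bands):
        if band is None:
            continue
        for pi, proto in enumerate(prototypes):
            n = proto.size
            if band.shape[1] < n or band.shape[2] < n:
                continue
            h, w = band.shape[1] - n + 1, band.shape[2] - n + 1
            out = np.empty((h, w))
            p = proto.patch.astype(np.float64)
            if config.s2_similarity == "dot":
                pn = np.linalg.norm(p)
                for r in range(h):
                    for c in range(w):
                        x = band[:, r:r + n, c:c + n].astype(np.float64)
                        xn = np.linalg.norm(x)
                        out[r, c] = (0.0 if xn * pn == 0 else
                                     float((x * p).sum()) / (xn * pn))
            else:
                for r in range(h):
                    for c in range(w):
                        x = band[:, r:r + n, c:c + n].astype(np.float64)
                        out[r, c] = _similarity(((x - p) ** 2).sum(), p.size,
                                                config)
            maps[pi][bi] = out
    return maps


def pool_c2(s2_maps: list) -> np.ndarray:
    """Global max of each prototype's response over all positions and scales."""
    c2 = np.zeros(len(s2_maps))
    for i, per_band in enumerate(s2_maps):
        best = 0.0
        for m in per_band:
            if m is not None and m.size:
                best = max(best, float(m.max()))
        c2[i] = best
    return c2


def c2_from_c1(c1_bands: list, bank: PrototypeBank) -> np.ndarray:
    """Fused S2+C2: the C2 vector straight from C1 bands (BLAS fast path)."""
    cfg = bank.config
    d = len(bank)
    if cfg.s2_similarity == "dot":
        best = np.zeros(d)
        for band in c1_bands:
            if band is None:
                continue
            for n, (idx, w, wsq) in bank.groups.items():
                if band.shape[1] < n or band.shape[2] < n:
                    continue
                x, xsq = _band_patches(band, n)
                dots = x @ w.T
                denom = np.sqrt(xsq)[:, None] * np.sqrt(wsq)[None, :]
                sim = np.where(denom > 0, dots / np.where(denom > 0, denom, 1.0), 0.0)
                best[idx] = np.maximum(best[idx], sim.max(axis=0))
        return best

    # gaussian: track the minimum squared distance per prototype
    dmin = np.full(d, np.inf)
    for band in c1_bands:
        if band is None:
            continue
        for n, (idx, w, wsq) in bank.groups.items():
            if band.shape[1] < n or band.shape[2] < n:
                continue
            x, xsq = _band_patches(band, n)
            dots = x @ w.T
            dots *= -2.0
            dots += xsq[:, None]
            dots += wsq[None, :].astype(DTYPE)
            dmin[idx] = np.minimum(dmin[idx], dots.min(axis=0))
    c2 = np.zeros(d)
    for n, (idx, w, _) in bank.groups.items():
        fit = np.isfinite(dmin[idx])
        vals = _similarity(dmin[idx][fit], w.shape[1], bank.config)
        out = np.zeros(len(idx))
        out[fit] = vals
        c2[idx] = out
    return c2


def encode(image: np.ndarray, bank: GaborBank,
           prototype_bank: PrototypeBank) -> np.ndarray:
    """Full pipeline image → C2 vector (deterministic given the prototypes)."""
    return c2_from_c1(compute_c1(image, bank), prototype_bank)


def encode_dataset(images, bank: GaborBank,
                   prototype_bank: PrototypeBank) -> np.ndarray:
    """Encode a list of TrialImages (or arrays) into an (N, d) C2 matrix."""
    rows = []
    for im in images:
        px = im.pixels if hasattr(im, "pixels") else im
        rows.append(encode(px, bank, prototype_bank))
    return np.asarray(rows)


# ---------------------------------------------------------------------------
# C2 disk cache

def save_c2(path, c2: np.ndarray, dataset_key: str, prototype_key: str) -> None:
    """Cache a C2 matrix keyed by dataset and prototype-set hashes."""
    np.savez(path, c2=c2, dataset_key=np.str_(dataset_key),
             prototype_key=np.str_(prototype_key))


def load_c2(path, dataset_key: str, prototype_key: str) -> np.ndarray | None:
    """Load a cached C2 matrix; None when missing or the keys disagree."""
    try:
        with np.load(path) as f:
            if (str(f["dataset_key"]) == dataset_key
                    and str(f["prototype_key"]) == prototype_key):
                return f["c2"]
    except (FileNotFoundError, KeyError):
        pass
    return None
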