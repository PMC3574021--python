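"""Synthetic two-line stimuli for the length-judgement task.

Every image shows two horizontal lines (shafts) on a white canvas; the task
is to judge whether the top shaft is longer (LONG) or shorter (SHORT) than
the bottom one.  Four fin styles are supported:

* ``XF`` (cross fin) — four fins at every shaft end, used for training;
  contains the features of both test styles and induces no bias.
* ``LR`` — left-pointing arrowheads on the top line, right-pointing on the
  bottom; the neutral control with the same feature count as ``ML``.
* ``ML`` — the Müller-Lyer arrangement: arrowtails (wings out) on the top
  line, arrowheads (wings in) on the bottom, so a human observer sees the
  top line as elongated.
* ``PLAIN`` — bare shafts, used mainly for diagnostics.

All geometric parameters are drawn uniformly from fixed ranges: shaft
lengths 120–240 px with the comparator 2–62 px shorter, vertical positions
48–108 px (top) and 148–208 px (bottom), fin lengths 15–40 px, fin angles
10–90° for XF and 10–70° for LR/ML.  Lines are drawn with a 2×2 pixel pen
(binary ink, no anti-aliasing) on a 256×256 canvas; shafts are centred
horizontally and fin ink that would leave the canvas is clipped at the
border.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from skimage.draw import line as _bresenham

CANVAS = 256
PEN = 2

LONG, SHORT = "LONG", "SHORT"
STYLES = ("XF", "LR", "ML", "PLAIN")

SHAFT_RANGE = (120, 240)        # reference shaft length, inclusive
DIFF_RANGE = (2, 62)            # comparator is this much shorter, inclusive
TOP_Y_RANGE = (48, 108)
BOTTOM_Y_RANGE = (148, 208)
FIN_LENGTH_RANGE = (15, 40)
FIN_ANGLE_RANGE = {"XF": (10.0, 90.0), "LR": (10.0, 70.0), "ML": (10.0, 70.0)}


@dataclass(frozen=True)
class FigureSpec:
    """Parametric description of one two-line figure."""

    category: str               # LONG or SHORT
    style: str                  # XF, LR, ML or PLAIN
    top_length: int             # shaft lengths in pixels
    bottom_length: int
    top_y: int                  # shaft row, measured from the image top
    bottom_y: int
    fin_angle_top: float = 45.0     # degrees between fin and shaft
    fin_angle_bottom: float = 45.0
    fin_length: int = 25            # shaft end to fin tip, pixels
    pen: int = PEN
    canvas: int = CANVAS

    def validate(self) -> None:
        if self.style not in STYLES:
            raise ValueError(f"unknown style {self.style!r}")
        if self.category not in (LONG, SHORT):
            raise ValueError(f"unknown category {self.category!r}")
        if self.top_length <= 0 or self.bottom_length <= 0:
            raise ValueError("shaft lengths must be positive")
        if self.style != "PLAIN":
            for a in (self.fin_angle_top, self.fin_angle_bottom):
                if not 0.0 < a <= 90.0:
                    raise ValueError(
                        f"fin angle {a} degenerate: must be in (0, 90]")
            if self.fin_length <= 0:
                raise ValueError("fin length must be positive")
        for length in (self.top_length, self.bottom_length):
            x0 = (self.canvas - length) // 2
            if x0 < 0 or x0 + length >= self.canvas:
                raise ValueError(f"shaft of length {length} leaves the canvas")
        for y in (self.top_y, self.bottom_y):
            if y < 0 or y + self.pen > self.canvas:
                raise ValueError(f"shaft row {y} leaves the canvas")
        expected = LONG if self.top_length > self.bottom_length else SHORT
        if self.category != expected and self.top_length != self.bottom_length:
            raise ValueError("category inconsistent with shaft lengths")


@dataclass
class TrialImage:
    """A rendered stimulus: binary ink on white, values in {0, 1}."""

    pixels: np.ndarray
    spec: FigureSpec
    label: str


@dataclass(frozen=True)
class SweepSpec:
    """A psychometric sweep: fixed fin angle, exact length differences.

    ``fin_angle is None`` means the angle is re-drawn uniformly for every
    image (the "all angles collapsed" control condition).
    """

    style: str
    fin_angle: float | None
    diffs: tuple
    images_per_diff: int
    seed: int

    def __post_init__(self):
        if self.style not in ("LR", "ML"):
            raise ValueError("sweeps are defined for LR and ML styles only")
        if self.images_per_diff < 1:
            raise ValueError("images_per_diff must be >= 1")
        ds = sorted(self.diffs)
        if ds != sorted(-d for d in self.diffs):
            raise ValueError("diffs must be symmetric about 0")


# ---------------------------------------------------------------------------
# rendering

def _stamp(img: np.ndarray, rows: np.ndarray, cols: np.ndarray, pen: int) -> None:
    """Stamp a pen×pen square of ink at each path point, clipped to canvas."""
    n = img.shape[0]
    for dr in range(pen):
        for dc in range(pen):
            r = rows + dr
            c = cols + dc
            keep = (r >= 0) & (r < n) & (c >= 0) & (c < n)
            img[r[keep], c[keep]] = 0.0


def _fin_endpoints(style: str, end: str) -> list[int]:
    """Horizontal fin directions (+1 away from shaft centre is end-dependent).

    Returns signs sx where the fin tip column is ``anchor + sx*len*cos(a)``.
    """
    if style == "XF":
        return [-1, 1]
    if style == "PLAIN":
        return []
    raise ValueError(style)


def render_figure(spec: FigureSpec) -> TrialImage:
    """Deterministically rasterise a figure spec into a 256×256 image.

    Shafts are horizontal, centred, drawn with a square pen (Bresenham
    stamping, no anti-aliasing).  Fins attach at both shaft ends, mirrored
    above and below the shaft at ±fin_angle.  Fin ink is clipped at the
    canvas border; an invalid shaft or a degenerate fin angle raises.
    """
    spec.validate()
    img = np.ones((spec.canvas, spec.canvas), dtype=np.float64)

    for which in ("top", "bottom"):
        length = spec.top_length if which == "top" else spec.bottom_length
        y = spec.top_y if which == "top" else spec.bottom_y
        angle = spec.fin_angle_top if which == "top" else spec.fin_angle_bottom
        x0 = (spec.canvas - length) // 2
        x1 = x0 + length - 1
        rr, cc = _bresenham(y, x0, y, x1)
        _stamp(img, rr, cc, spec.pen)

        if spec.style == "PLAIN":
            continue
        # horizontal fin direction at (left end, right end):
        #   +1 = toward the right.  Wings-in at an end means the fins extend
        #   over the shaft; wings-out means they extend away from it.
        if spec.style == "XF":
            dirs = {"left": (-1, 1), "right": (-1, 1)}
        elif spec.style == "LR":
            sx = 1 if which == "top" else -1     # left- vs right-pointing
            dirs = {"left": (sx,), "right": (sx,)}
        else:  # ML: arrowtails on top (wings out), arrowheads on bottom
            if which == "top":
                dirs = {"left": (-1,), "right": (1,)}
            else:
                dirs = {"left": (1,), "right": (-1,)}

        a = math.radians(angle)
        dx = spec.fin_length * math.cos(a)
        dy = spec.fin_length * math.sin(a)
        for end, anchors in (("left", x0), ("right", x1)):
            for sx in dirs[end]:
                for sy in (-1, 1):
                    tip_r = int(round(y + sy * dy))
                    tip_c = int(round(anchors + sx * dx))
                    rr, cc = _bresenham(y, anchors, tip_r, tip_c)
                    _stamp(img, rr, cc, spec.pen)

    label = LONG if spec.top_length > spec.bottom_length else SHORT
    return TrialImage(pixels=img, spec=spec, label=label)


# ---------------------------------------------------------------------------
# sampling

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_spec(category: str, style: str, rng) -> FigureSpec:
    """Draw one figure spec uniformly from the task's parameter ranges."""
    if category not in (LONG, SHORT):
        raise ValueError(f"unknown category {category!r}")
    if style not in ("XF", "LR", "ML"):
        raise ValueError(f"unknown style {style!r}")
    rng = _as_rng(rng)
    ref = int(rng.integers(SHAFT_RANGE[0], SHAFT_RANGE[1] + 1))
    diff = int(rng.integers(DIFF_RANGE[0], DIFF_RANGE[1] + 1))
    if category == LONG:
        top_len, bottom_len = ref, ref - diff
    else:
        top_len, bottom_len = ref - diff, ref
    lo, hi = FIN_ANGLE_RANGE[style]
    return FigureSpec(
        category=category,
        style=style,
        top_length=top_len,
        bottom_length=bottom_len,
        top_y=int(rng.integers(TOP_Y_RANGE[0], TOP_Y_RANGE[1] + 1)),
        bottom_y=int(rng.integers(BOTTOM_Y_RANGE[0], BOTTOM_Y_RANGE[1] + 1)),
        fin_angle_top=float(rng.uniform(lo, hi)),
        fin_angle_bottom=float(rng.uniform(lo, hi)),
        fin_length=int(rng.integers(FIN_LENGTH_RANGE[0], FIN_LENGTH_RANGE[1] + 1)),
    )


def generate_dataset(style: str, n_per_category: int, seed) -> list[TrialImage]:
    """Balanced LONG/SHORT dataset of rendered images with specs retained."""
    if n_per_category < 0:
        raise ValueError("n_per_category must be >= 0")
    rng = _as_rng(seed)
    images = []
    for category in (LONG, SHORT):
        for _ in range(n_per_category):
            images.append(render_figure(sample_spec(category, style, rng)))
    return images


def generate_sweep(sweep: SweepSpec) -> list[TrialImage]:
    """Images with exact top−bottom length differences for psychometrics.

    For each signed difference d the reference (longer) shaft length is drawn
    from U[120, 240] and the comparator is |d| shorter; all other parameters
    are randomised as usual except the fin angle, which is fixed at
    ``sweep.fin_angle`` for both lines (or re-drawn per image when None).
    """
    rng = _as_rng(sweep.seed)
    lo, hi = FIN_ANGLE_RANGE[sweep.style]
    images = []
    for d in sweep.diffs:
        if abs(d) >= SHAFT_RANGE[0]:
            raise ValueError(f"|diff|={abs(d)} exceeds the shortest reference shaft")
        for _ in range(sweep.images_per_diff):
            ref = int(rng.integers(SHAFT_RANGE[0], SHAFT_RANGE[1] + 1))
            top_len = ref if d >= 0 else ref + d
            bottom_len = ref - d if d >= 0 else ref
            angle = (float(rng.uniform(lo, hi)) if sweep.fin_angle is None
                     else float(sweep.fin_angle))
            spec = FigureSpec(
                category=LONG if d > 0 else SHORT,
                style=sweep.style,
                top_length=top_len,
                bottom_length=bottom_len,
                top_y=int(rng.integers(TOP_Y_RANGE[0], TOP_Y_RANGE[1] + 1)),
                bottom_y=int(rng.integers(BOTTOM_Y_RANGE[0], BOTTOM_Y_RANGE[1] + 1)),
                fin_angle_top=angle,
                fin_angle_bottom=angle,
                fin_length=int(rng.integers(FIN_LENGTH_RANGE[0],
                                            FIN_LENGTH_RANGE[1] + 1)),
            )
            images.append(render_figure(spec))
    return images


# ---------------------------------------------------------------------------
# disk I/O

def save_dataset(images: Sequence[TrialImage], outdir, seed=None) -> None:
    """Write PNGs plus a JSON sidecar with every spec (and the seed used)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sidecar = {"seed": seed, "images": []}
    for i, im in enumerate(images):
        name = f"{i:05d}_{im.label}.png"
        arr = (im.pixels * 255).round().astype(np.uint8)
        Image.fromarray(arr, mode="L").save(outdir / name)
        sidecar["images"].append({"file": name, "label": im.label,
                                  "spec": asdict(im.spec)})
    (outdir / "dataset.json").write_text(json.dumps(sidecar, indent=1))


def load_dataset(indir) -> list[TrialImage]:
    indir = Path(indir)
    sidecar = json.loads((indir / "dataset.json").read_text())
    images = []
    for entry in sidecar["images"]:
        arr = np.asarray(Image.open(indir / entry["file"]), dtype=np.float64) / 255.0
        images.append(TrialImage(pixels=arr, spec=FigureSpec(**entry["spec"]),
                                 label=entry["label"]))
    return images
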