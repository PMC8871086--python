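"""Synthetic H&E-like dermis images with per-pixel ground truth.

The generator emulates the structure of an H&E-stained dermis section:

* a near-white background (unstained glass / sparse tissue),
* eosin-pink collagen fibers drawn as thick anti-aliased segments whose axial
  angles follow a von Mises distribution on doubled angles (the standard
  axial construction; concentration κ = 0 gives isotropic fibers),
* hematoxylin-purple structures: large ellipses for hair follicles and glands
  plus small ellipses for nuclei,
* i.i.d. Gaussian pixel noise.

Ground truth records, per pixel, the last-drawn class (background / collagen /
structure) and — on collagen — the drawing angle of the fiber, which is what
the orientation-estimation stage tries to recover.

Three presets mirror the normal / mixed / scar regions of a thermal-injury
dermis: normal tissue has sparse isotropic collagen with follicles, glands and
nuclei; scar tissue has dense, aligned collagen with no follicles or glands
but with nuclei still scattered through the tissue; mixed is a left-scar /
right-normal composite.

The module also carries the dataset utilities used around the images: lossless
right-angle rotation augmentation and a seeded train/validate/test split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from skimage.color import rgb2lab
from skimage.draw import ellipse as draw_ellipse
from skimage.transform import rotate as _interp_rotate

from .errors import ParameterError

__all__ = [
    "CLASS_BACKGROUND",
    "CLASS_COLLAGEN",
    "CLASS_STRUCTURE",
    "SyntheticSpec",
    "MixedSpec",
    "GroundTruth",
    "generate_image",
    "preset",
    "rotate_augment",
    "split_dataset",
    "sample_axial_angles",
    "fiber_count_for_coverage",
]

CLASS_BACKGROUND = 0
CLASS_COLLAGEN = 1
CLASS_STRUCTURE = 2

#: sRGB stain palette: background near-white, collagen eosin pink, structures
#: hematoxylin purple.  Pairwise (a*, b*) distances exceed 40 units, and mean
#: lightness orders background > collagen > structure, as in real H&E.
DEFAULT_COLORS = {
    "background": (246, 242, 244),
    "collagen": (232, 130, 160),
    "structure": (96, 64, 150),
}

#: Mean frame-chord length of a long fiber, as a fraction of the geometric
#: mean side — calibrated once against Monte-Carlo coverage of the drawing
#: routine (see fiber_count_for_coverage).
_CHORD_FRACTION = 0.85


def _ab(color: Sequence[int]) -> np.ndarray:
    lab = rgb2lab(np.asarray(color, dtype=np.float64).reshape(1, 1, 3) / 255.0)
    return lab[0, 0, 1:]


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of one synthetic dermis image."""

    height: int = 512
    width: int = 512
    fiber_count: int = 90
    fiber_width_px: float = 3.0
    orientation_mean_deg: float = 90.0  # axial, [0, 180)
    orientation_kappa: float = 0.0  # von Mises concentration on doubled angles
    ellipse_count: int = 6  # hair follicles / glands (large)
    nucleus_count: int = 150  # nuclei (small); persist even in scar tissue
    colors: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ParameterError(f"frame {self.height}x{self.width} is degenerate")
        if min(self.fiber_count, self.ellipse_count, self.nucleus_count) < 0:
            raise ParameterError("counts must be non-negative")
        if self.orientation_kappa < 0:
            raise ParameterError(f"kappa must be >= 0, got {self.orientation_kappa}")
        if self.fiber_width_px <= 0:
            raise ParameterError(f"fiber width must be positive, got {self.fiber_width_px}")
        names = list(self.colors)
        for i, ni in enumerate(names):
            for nj in names[i + 1 :]:
                d = float(np.linalg.norm(_ab(self.colors[ni]) - _ab(self.colors[nj])))
                if d < 15.0:
                    raise ParameterError(
                        f"colors {ni!r} and {nj!r} are only {d:.1f} (a*,b*) units "
                        "apart (< 15); segmentation would be untestable"
                    )


@dataclass(frozen=True)
class MixedSpec:
    """Composite scene: left half rendered from one spec, right half from another."""

    left: SyntheticSpec
    right: SyntheticSpec

    def __post_init__(self) -> None:
        if self.left.height != self.right.height:
            raise ParameterError("mixed halves must share a height")

    @property
    def height(self) -> int:
        return self.left.height

    @property
    def width(self) -> int:
        return self.left.width + self.right.width


@dataclass
class GroundTruth:
    """Per-pixel provenance of a generated scene."""

    class_map: np.ndarray  # (H, W) int8 in {0, 1, 2}; last drawn wins
    theta_map: np.ndarray  # (H, W) float64 degrees, NaN off-collagen
    spec: SyntheticSpec | MixedSpec


def sample_axial_angles(
    rng: np.random.Generator,
    n: int,
    mean_deg: float,
    kappa: float,
) -> np.ndarray:
    """Draw n axial angles in [0, 180) via von Mises on doubled angles.

    κ = 0 yields the uniform (isotropic) distribution; larger κ concentrates
    the fibers around ``mean_deg`` (mod 180).
    """
    if kappa == 0.0:
        return rng.uniform(0.0, 180.0, size=n)
    doubled = rng.vonmises(np.deg2rad(2.0 * mean_deg), kappa, size=n)
    return (np.rad2deg(doubled) / 2.0) % 180.0


def fiber_count_for_coverage(
    height: int,
    width: int,
    target_coverage: float,
    fiber_width_px: float = 3.0,
) -> int:
    """Fiber count giving an expected collagen coverage near ``target_coverage``.

    Fibers are long strips through uniformly placed centers, so each covers an
    in-frame area of roughly (mean chord) × width and coverage follows the
    Poisson-overlap law 1 − exp(−N·chord·w / area).
    """
    if not 0.0 < target_coverage < 1.0:
        raise ParameterError(f"target coverage must be in (0, 1), got {target_coverage}")
    area = height * width
    chord = _CHORD_FRACTION * math.sqrt(area)
    return max(1, round(-math.log(1.0 - target_coverage) * area / (chord * fiber_width_px)))


def _paint_fiber(
    canvas: np.ndarray,
    class_map: np.ndarray,
    theta_map: np.ndarray,
    center: np.ndarray,
    angle_deg: float,
    length: float,
    width: float,
    color: np.ndarray,
) -> None:
    """Alpha-blend one thick anti-aliased segment; hard core updates ground truth."""
    h, w = class_map.shape
    rad = np.deg2rad(angle_deg)
    d = np.array([-np.sin(rad), np.cos(rad)])  # (drow, dcol)
    p0 = center - 0.5 * length * d
    p1 = center + 0.5 * length * d
    pad = width / 2.0 + 1.5
    r0 = max(0, int(np.floor(min(p0[0], p1[0]) - pad)))
    r1 = min(h, int(np.ceil(max(p0[0], p1[0]) + pad)) + 1)
    c0 = max(0, int(np.floor(min(p0[1], p1[1]) - pad)))
    c1 = min(w, int(np.ceil(max(p0[1], p1[1]) + pad)) + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    # distance from each pixel center to the segment p0-p1
    vr, vc = p1 - p0
    seg_len2 = vr * vr + vc * vc
    t = ((rr - p0[0]) * vr + (cc - p0[1]) * vc) / seg_len2
    t = np.clip(t, 0.0, 1.0)
    dist = np.hypot(rr - (p0[0] + t * vr), cc - (p0[1] + t * vc))
    alpha = np.clip(width / 2.0 + 0.5 - dist, 0.0, 1.0)
    sub = canvas[r0:r1, c0:c1]
    sub += alpha[:, :, None] * (color - sub)
    core = alpha >= 0.5
    class_map[r0:r1, c0:c1][core] = CLASS_COLLAGEN
    theta_map[r0:r1, c0:c1][core] = angle_deg % 180.0


def _paint_ellipses(
    canvas: np.ndarray,
    class_map: np.ndarray,
    theta_map: np.ndarray,
    rng: np.random.Generator,
    count: int,
    axis_range: tuple[float, float],
    color: np.ndarray,
) -> None:
    h, w = class_map.shape
    for _ in range(count):
        cr, cc_ = rng.uniform(0, h), rng.uniform(0, w)
        a_ax = rng.uniform(*axis_range)
        b_ax = rng.uniform(*axis_range)
        rot = rng.uniform(0, np.pi)
        rr, cc = draw_ellipse(cr, cc_, a_ax, b_ax, shape=(h, w), rotation=rot)
        canvas[rr, cc] = color
        class_map[rr, cc] = CLASS_STRUCTURE
        theta_map[rr, cc] = np.nan


def generate_image(spec: SyntheticSpec | MixedSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a synthetic H&E scene and its ground truth; deterministic per seed."""
    if isinstance(spec, MixedSpec):
        img_l, gt_l = generate_image(spec.left)
        img_r, gt_r = generate_image(spec.right)
        image = np.concatenate([img_l, img_r], axis=1)
        gt = GroundTruth(
            class_map=np.concatenate([gt_l.class_map, gt_r.class_map], axis=1),
            theta_map=np.concatenate([gt_l.theta_map, gt_r.theta_map], axis=1),
            spec=spec,
        )
        return image, gt

    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    canvas = np.empty((h, w, 3), dtype=np.float64)
    canvas[:] = np.asarray(spec.colors["background"], dtype=np.float64)
    class_map = np.full((h, w), CLASS_BACKGROUND, dtype=np.int8)
    theta_map = np.full((h, w), np.nan)

    fiber_color = np.asarray(spec.colors["collagen"], dtype=np.float64)
    length = 1.5 * math.hypot(h, w)  # fibers span the frame
    angles = sample_axial_angles(
        rng, spec.fiber_count, spec.orientation_mean_deg, spec.orientation_kappa
    )
    for angle in angles:
        center = np.array([rng.uniform(0, h), rng.uniform(0, w)])
        _paint_fiber(
            canvas, class_map, theta_map, center, float(angle),
            length, spec.fiber_width_px, fiber_color,
        )

    structure_color = np.asarray(spec.colors["structure"], dtype=np.float64)
    scale = math.sqrt(h * w) / 512.0  # structure sizes track the frame
    _paint_ellipses(
        canvas, class_map, theta_map, rng, spec.ellipse_count,
        (max(6.0, 14.0 * scale), max(10.0, 30.0 * scale)), structure_color,
    )
    _paint_ellipses(
        canvas, class_map, theta_map, rng, spec.nucleus_count,
        (2.0, 4.0), structure_color,
    )

    if spec.noise_sd > 0:
        canvas += rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    image = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return image, GroundTruth(class_map=class_map, theta_map=theta_map, spec=spec)


def preset(
    name: str,
    seed: int = 0,
    height: int = 512,
    width: int = 512,
) -> SyntheticSpec | MixedSpec:
    """Build the spec for one of the three tissue presets.

    * ``normal`` — sparse isotropic collagen (target coverage ~50%, κ = 0)
      with follicle/gland ellipses and nuclei;
    * ``scar`` — dense aligned collagen (target coverage ~90%, κ = 8), no
      follicles or glands, but nuclei persisting throughout the tissue;
    * ``mixed`` — left half scar, right half normal.
    """
    area_scale = (height * width) / (512.0 * 512.0)
    if name == "normal":
        return SyntheticSpec(
            height=height,
            width=width,
            fiber_count=fiber_count_for_coverage(height, width, 0.5),
            orientation_kappa=0.0,
            ellipse_count=max(2, round(6 * area_scale)),
            nucleus_count=max(20, round(150 * area_scale)),
            seed=seed,
        )
    if name == "scar":
        mean = float(np.random.default_rng(seed).uniform(0.0, 180.0))
        return SyntheticSpec(
            height=height,
            width=width,
            fiber_count=fiber_count_for_coverage(height, width, 0.9),
            orientation_mean_deg=mean,
            orientation_kappa=8.0,
            ellipse_count=0,
            nucleus_count=max(20, round(100 * area_scale)),
            seed=seed,
        )
    if name == "mixed":
        left = preset("scar", seed=seed, height=height, width=width // 2)
        right = preset("normal", seed=seed + 1, height=height, width=width - width // 2)
        return MixedSpec(left=left, right=right)
    raise ParameterError(f"unknown preset {name!r}; valid: normal, scar, mixed")


def rotate_augment(
    images: Sequence[np.ndarray],
    angles: Sequence[float] = (0, 90, 180, 270),
    interpolate: bool = False,
) -> list[np.ndarray]:
    """Every image at every angle, order-preserving (all angles of image 0 first).

    Right-angle rotations are lossless (pure pixel rearrangement); any other
    angle requires ``interpolate=True`` and uses bilinear resampling.
    """
    if len(angles) == 0:
        raise ParameterError("angles must be non-empty")
    for a in angles:
        if a % 90 != 0 and not interpolate:
            raise ParameterError(
                f"rotation by {a} deg is not lossless; pass interpolate=True"
            )
    out: list[np.ndarray] = []
    for img in images:
        img = np.asarray(img)
        for a in angles:
            if a % 90 == 0:
                out.append(np.rot90(img, k=int(a // 90) % 4).copy())
            else:
                rot = _interp_rotate(
                    img.astype(np.float64), a, resize=False, preserve_range=True, order=1
                )
                out.append(np.clip(np.rint(rot), 0, 255).astype(img.dtype))
    return out


def split_dataset(
    n_items: int,
    fractions: tuple[float, float, float],
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded disjoint train/validate/test index split.

    Sizes follow the floor-on-validate/test rule with the remainder going to
    train: n_val = ⌊n·f_val⌋, n_test = ⌊n·f_test⌋, n_train = n − n_val − n_test
    (e.g. 372 items at (0.64, 0.16, 0.20) → 239/59/74).
    """
    if n_items < 3:
        raise ParameterError(f"need >= 3 items to split, got {n_items}")
    f_train, f_val, f_test = fractions
    if min(fractions) <= 0:
        raise ParameterError(f"fractions must be positive, got {fractions}")
    if abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise ParameterError(f"fractions must sum to 1, got {fractions}")
    n_val = int(n_items * f_val)
    n_test = int(n_items * f_test)
    n_train = n_items - n_val - n_test
    if min(n_train, n_val, n_test) == 0:
        raise ParameterError(
            f"split of {n_items} at {fractions} leaves an empty part "
            f"({n_train}/{n_val}/{n_test})"
        )
    perm = np.random.default_rng(seed).permutation(n_items)
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]
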