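"""Collagen density and directional variance of fiber orientation.

Given a binary collagen mask (CAS), this module computes:

1. a **collagen density map** ``m(x, y)`` — the mask convolved with a
   normalized airy-disk kernel, giving the local fraction of collagen-positive
   pixels in a smooth, rotationally symmetric neighborhood;
2. a **pixel-wise fiber orientation** field — for each collagen-positive pixel
   the axial angle θ ∈ [0°, 180°) whose line segment through the pixel passes
   through the most collagen-positive pixels;
3. the **directional variance** map

       V(x, y) = 1 − R(x, y) / m(x, y)

   where ``R`` is the magnitude of the kernel-weighted vector sum of the
   doubled-angle orientation unit vectors (cos 2θ, sin 2θ).  Doubling the
   angles identifies θ with θ + 180° — a fiber has no head or tail — and makes
   the axial angles vector-summable, so V is a local circular variance:
   0 for perfectly aligned fibers, 1 for an isotropic mix.

Angles are measured counter-clockwise from the +column axis with the row index
increasing downward, i.e. a fiber along direction (Δrow, Δcol) = (−sin θ, cos θ);
θ = 0° is a horizontal fiber.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import j1

from .errors import DimensionError, ParameterError

__all__ = [
    "AiryKernel",
    "OrientationField",
    "VarianceMap",
    "airy_kernel",
    "collagen_density",
    "estimate_orientation",
    "directional_variance",
]

#: First zero of the Bessel function J1, which places the airy pattern's first
#: dark ring at radius ``radius_px``.
AIRY_FIRST_ZERO = 3.8317059702075125


@dataclass(frozen=True)
class AiryKernel:
    """Normalized airy-disk convolution kernel truncated at its first zero."""

    weights: np.ndarray  # (2r+1, 2r+1), non-negative, unit sum
    radius_px: int

    @property
    def size(self) -> int:
        return 2 * self.radius_px + 1


@dataclass
class OrientationField:
    """Per-pixel axial fiber angle with a validity mask.

    ``theta`` is in degrees, [0, 180); meaningful only where ``valid``.
    """

    theta: np.ndarray  # (H, W) float64, degrees
    valid: np.ndarray  # (H, W) bool

    @property
    def shape(self) -> tuple[int, int]:
        return self.theta.shape


@dataclass
class VarianceMap:
    """Directional variance V = 1 − R/m with its ingredients.

    ``m`` here is the kernel-smoothed density of *orientation-valid* pixels, so
    that R ≤ m holds exactly and V ∈ [0, 1]; pixels with m = 0 are invalid.
    """

    v: np.ndarray  # (H, W) float64 in [0, 1]
    r: np.ndarray  # (H, W) resultant magnitude
    m: np.ndarray  # (H, W) density of orientation-valid pixels
    valid: np.ndarray  # (H, W) bool, m > 0


def airy_kernel(radius_px: int) -> AiryKernel:
    """Build the airy-disk kernel ``[2·J1(x)/x]²`` with first zero at ``radius_px``.

    The weight at pixel offset ρ is ``[2·J1(x)/x]²`` with
    ``x = 3.8317·ρ/radius_px`` (central value 1 at ρ = 0), truncated at the
    first zero ρ = radius_px and normalized to unit sum.
    """
    if radius_px < 1:
        raise ParameterError(f"kernel radius must be >= 1 pixel, got {radius_px}")
    r = int(radius_px)
    rows, cols = np.mgrid[-r : r + 1, -r : r + 1]
    rho = np.hypot(rows, cols)
    x = AIRY_FIRST_ZERO * rho / r
    w = np.ones_like(x)
    nz = rho > 0
    w[nz] = (2.0 * j1(x[nz]) / x[nz]) ** 2
    w[rho > r] = 0.0
    w /= w.sum()
    return AiryKernel(weights=w, radius_px=r)


def _check_kernel_fits(kernel: AiryKernel, shape: tuple[int, int]) -> None:
    if kernel.size > min(shape):
        raise ParameterError(
            f"kernel of size {kernel.size} does not fit image frame {shape}"
        )


def collagen_density(cas: np.ndarray, kernel: AiryKernel) -> np.ndarray:
    """Convolve the {0,1} collagen mask with the airy kernel.

    Borders use reflect padding, so an all-ones mask maps to 1 everywhere
    (up to the kernel's unit-sum rounding).  Output is clipped to [0, 1].
    """
    cas = np.asarray(cas, dtype=bool)
    _check_kernel_fits(kernel, cas.shape)
    m = ndimage.convolve(cas.astype(np.float64), kernel.weights, mode="reflect")
    return np.clip(m, 0.0, 1.0)


def _shifted(mask: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """``out[r, c] = mask[r + dr, c + dc]`` with zeros outside the frame."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    src_r = slice(max(dr, 0), min(h + dr, h))
    src_c = slice(max(dc, 0), min(w + dc, w))
    dst_r = slice(max(-dr, 0), max(-dr, 0) + (src_r.stop - src_r.start))
    dst_c = slice(max(-dc, 0), max(-dc, 0) + (src_c.stop - src_c.start))
    if src_r.stop > src_r.start and src_c.stop > src_c.start:
        out[dst_r, dst_c] = mask[src_r, src_c]
    return out


def candidate_angles(n_angles: int) -> np.ndarray:
    """The evenly spaced axial candidate angles k·180°/n, k = 0..n−1."""
    return np.arange(n_angles) * (180.0 / n_angles)


def estimate_orientation(
    cas: np.ndarray,
    window_radius: int = 8,
    n_angles: int = 18,
) -> OrientationField:
    """Estimate the fiber orientation at every collagen-positive pixel.

    For each candidate angle the mask is sampled (nearest pixel) along the
    line segment of length ``2·window_radius + 1`` through the pixel; the
    angle's score is the number of collagen-positive samples.  θ is the
    arg-max score, ties broken toward the smallest angle.  A pixel whose best
    score is ≤ 1 (no support beyond the pixel itself — an isolated point) is
    marked invalid, as is every collagen-negative pixel.
    """
    if window_radius < 2:
        raise ParameterError(f"window_radius must be >= 2, got {window_radius}")
    if n_angles < 4:
        raise ParameterError(f"n_angles must be >= 4, got {n_angles}")
    cas = np.asarray(cas, dtype=bool)
    mask16 = cas.astype(np.int16)
    ts = np.arange(-window_radius, window_radius + 1)
    best_score = np.full(cas.shape, -1, dtype=np.int16)
    best_angle = np.zeros(cas.shape, dtype=np.float64)
    for ang in candidate_angles(n_angles):
        rad = np.deg2rad(ang)
        drs = np.rint(-ts * np.sin(rad)).astype(int)
        dcs = np.rint(ts * np.cos(rad)).astype(int)
        score = np.zeros(cas.shape, dtype=np.int16)
        for dr, dc in zip(drs, dcs):
            score += _shifted(mask16, dr, dc)
        improved = score > best_score  # strict: ties keep the smaller angle
        best_angle[improved] = ang
        best_score[improved] = score[improved]
    valid = cas & (best_score > 1)
    theta = np.where(valid, best_angle, 0.0)
    return OrientationField(theta=theta, valid=valid)


def directional_variance(
    field: OrientationField,
    kernel: AiryKernel,
    density: np.ndarray | None = None,
) -> VarianceMap:
    """Directional variance V = 1 − R/m from a fiber-orientation field.

    The doubled-angle components X = cos 2θ, Y = sin 2θ are set on valid
    pixels (zero elsewhere) and convolved with the same airy kernel as the
    density map; R = √(Xc² + Yc²).  The denominator m is the kernel-smoothed
    validity mask, which guarantees R ≤ m pointwise (triangle inequality of
    the weighted vector sum) and hence V ∈ [0, 1].  Where m = 0 the pixel is
    invalid — never a division error.  V is clipped against floating-point
    overshoot.

    ``density`` (a collagen density map) is accepted for frame validation
    only; the variance's denominator is recomputed from the validity mask.
    """
    theta = np.asarray(field.theta, dtype=np.float64)
    valid = np.asarray(field.valid, dtype=bool)
    if theta.shape != valid.shape:
        raise DimensionError(f"theta frame {theta.shape} != valid frame {valid.shape}")
    if density is not None and np.asarray(density).shape != theta.shape:
        raise DimensionError(
            f"density frame {np.asarray(density).shape} != orientation frame {theta.shape}"
        )
    _check_kernel_fits(kernel, theta.shape)
    two_theta = np.deg2rad(2.0 * theta)
    x = np.where(valid, np.cos(two_theta), 0.0)
    y = np.where(valid, np.sin(two_theta), 0.0)
    xc = ndimage.convolve(x, kernel.weights, mode="reflect")
    yc = ndimage.convolve(y, kernel.weights, mode="reflect")
    m = ndimage.convolve(valid.astype(np.float64), kernel.weights, mode="reflect")
    r = np.hypot(xc, yc)
    out_valid = m > 0
    v = np.zeros_like(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        v[out_valid] = 1.0 - r[out_valid] / m[out_valid]
    v = np.clip(v, 0.0, 1.0)
    return VarianceMap(v=v, r=r, m=m, valid=out_valid)
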