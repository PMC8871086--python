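"""Color segmentation of H&E-stained tissue in CIE L*a*b* space.

The pipeline converts the sRGB image to CIE 1976 L*a*b* (D65), clusters the
pixels into exactly three groups with K-means on the chromatic ``(a*, b*)``
coordinates only — the color information of an H&E stain lives in those two
opponent axes, while ``L*`` carries lightness — and then names the clusters by
their mean lightness:

* **background** — highest mean L* (near-white glass / unstained regions),
* **foreground** — lowest mean L* (hematoxylin-dark nuclei, glands, follicles),
* **collagen** — the remaining cluster (eosin-pink fibers).

The three resulting masks (CAS, FS, BS) partition the frame exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2lab
from sklearn.cluster import KMeans

from .errors import AmbiguousRolesError, DegenerateInputError, DimensionError

__all__ = [
    "ClusterModel",
    "SegmentationResult",
    "rgb_to_lab",
    "kmeans_cluster",
    "assign_roles",
    "segment_tissue",
    "render_overlay",
]

ROLES = ("background", "collagen", "foreground")

#: Overlay rendering colors, following the usual H&E figure conventions:
#: foreground structures purple, collagen magenta, background untouched white.
_OVERLAY_COLORS = {
    "foreground": (128, 0, 192),
    "collagen": (255, 0, 255),
    "background": (255, 255, 255),
}


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """Convert an ``(H, W, 3) uint8`` sRGB image to CIE 1976 L*a*b* (D65).

    Returns an ``(H, W, 3) float64`` array with channels (L*, a*, b*);
    L* in [0, 100].
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise DimensionError(f"expected (H, W, 3) RGB image, got shape {image.shape}")
    return rgb2lab(image.astype(np.float64) / 255.0)


@dataclass
class ClusterModel:
    """A fitted 3-cluster K-means model over the (a*, b*) plane."""

    k: int
    centroids: np.ndarray  # (k, 2) in (a*, b*)
    labels: np.ndarray  # (H, W) int in {0..k-1}
    seed: int
    inertia: float


@dataclass
class SegmentationResult:
    """Role-named binary masks partitioning the frame."""

    cas: np.ndarray  # collagen area segmentation, (H, W) bool
    fs: np.ndarray  # foreground (nuclei/glands/follicles), (H, W) bool
    bs: np.ndarray  # background, (H, W) bool
    role_map: dict[int, str] = field(default_factory=dict)  # cluster index -> role

    def mask_for(self, role: str) -> np.ndarray:
        return {"collagen": self.cas, "foreground": self.fs, "background": self.bs}[role]


def kmeans_cluster(
    lab: np.ndarray,
    seed: int = 0,
    restarts: int = 10,
    tol: float = 1e-4,
) -> ClusterModel:
    """Cluster pixels into 3 groups by K-means on (a*, b*) only.

    Runs Lloyd's algorithm with k-means++ initialization, keeping the best of
    ``restarts`` runs by inertia; deterministic for a fixed ``seed``.

    Raises
    ------
    DegenerateInputError
        If the image has fewer than 3 distinct (a*, b*) values.
    """
    lab = np.asarray(lab, dtype=np.float64)
    if lab.ndim != 3 or lab.shape[2] != 3:
        raise DimensionError(f"expected (H, W, 3) Lab image, got shape {lab.shape}")
    h, w = lab.shape[:2]
    ab = lab[:, :, 1:].reshape(-1, 2)
    n_distinct = np.unique(ab, axis=0).shape[0]
    if n_distinct < 3:
        raise DegenerateInputError(
            f"K-means needs >= 3 distinct (a*, b*) values, found {n_distinct}"
        )
    km = KMeans(
        n_clusters=3,
        init="k-means++",
        n_init=restarts,
        tol=tol,
        max_iter=300,
        random_state=seed,
        algorithm="lloyd",
    ).fit(ab)
    return ClusterModel(
        k=3,
        centroids=km.cluster_centers_.copy(),
        labels=km.labels_.reshape(h, w).astype(np.int64),
        seed=seed,
        inertia=float(km.inertia_),
    )


def assign_roles(model: ClusterModel, lab: np.ndarray) -> SegmentationResult:
    """Name the three clusters by mean L*: highest → background, lowest →
    foreground, remaining → collagen, and assemble the CAS/FS/BS masks.

    Raises
    ------
    AmbiguousRolesError
        If two clusters have mean L* within 1e-6 of each other.
    """
    lab = np.asarray(lab, dtype=np.float64)
    if lab.shape[:2] != model.labels.shape:
        raise DimensionError(
            f"labels frame {model.labels.shape} does not match Lab frame {lab.shape[:2]}"
        )
    lightness = lab[:, :, 0]
    mean_l = np.array(
        [
            lightness[model.labels == i].mean() if np.any(model.labels == i) else -np.inf
            for i in range(model.k)
        ]
    )
    order = np.argsort(mean_l)  # ascending: darkest first
    if np.min(np.diff(mean_l[order])) < 1e-6:
        raise AmbiguousRolesError(
            f"cluster mean L* values {mean_l} are not separable; centroids {model.centroids}"
        )
    role_map = {
        int(order[0]): "foreground",
        int(order[1]): "collagen",
        int(order[2]): "background",
    }
    masks = {role: model.labels == idx for idx, role in role_map.items()}
    return SegmentationResult(
        cas=masks["collagen"],
        fs=masks["foreground"],
        bs=masks["background"],
        role_map=role_map,
    )


def segment_tissue(
    image: np.ndarray,
    seed: int = 0,
    restarts: int = 10,
    tol: float = 1e-4,
) -> SegmentationResult:
    """End-to-end tissue segmentation: RGB → Lab → K-means → role-named masks."""
    lab = rgb_to_lab(image)
    model = kmeans_cluster(lab, seed=seed, restarts=restarts, tol=tol)
    return assign_roles(model, lab)


def render_overlay(seg: SegmentationResult) -> np.ndarray:
    """Render a segmentation as an RGB overlay (foreground purple, collagen
    magenta, background white) for visual inspection."""
    h, w = seg.cas.shape
    out = np.zeros((h, w, 3), dtype=np.uint8)
    for role, color in _OVERLAY_COLORS.items():
        out[seg.mask_for(role)] = color
    return out
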