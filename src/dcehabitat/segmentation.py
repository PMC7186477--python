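"""Semi-automatic lesion delineation on subtraction images.

Spatial fuzzy C-means (sFCM) inside a rectangular ROI, hard labeling of
the brightest cluster, and morphological refinement. The spatial step
re-weights memberships by the summed membership of the 3x3 neighborhood
(weights p, q); q = 0 degrades to plain FCM.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateClusterError,
    DimensionError,
    EmptyRegionError,
    TooSmallLesionError,
)

DEFAULT_MIN_LESION_PIXELS = 16
_STRUCT_3X3 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ROIBox:
    """Half-open [min, max) pixel box, 0-based, row-major."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if self.row_min >= self.row_max or self.col_min >= self.col_max:
            raise DimensionError(f"empty ROI box {self}")
        if self.row_min < 0 or self.col_min < 0:
            raise DimensionError(f"negative ROI coordinates {self}")

    def validate_within(self, shape: tuple[int, int]) -> None:
        if self.row_max > shape[0] or self.col_max > shape[1]:
            raise DimensionError(f"ROI {self} exceeds image bounds {shape}")

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.row_min, self.row_max), slice(self.col_min, self.col_max)

    @classmethod
    def around_mask(cls, mask: np.ndarray, margin: int = 4) -> "ROIBox":
        """Programmatic ROI: the mask bounding box expanded by a margin."""
        rows, cols = np.nonzero(mask)
        if rows.size == 0:
            raise EmptyRegionError("cannot build an ROI around an empty mask")
        return cls(
            row_min=max(int(rows.min()) - margin, 0),
            row_max=min(int(rows.max()) + 1 + margin, mask.shape[0]),
            col_min=max(int(cols.min()) - margin, 0),
            col_max=min(int(cols.max()) + 1 + margin, mask.shape[1]),
        )


@dataclass
class LesionMask:
    mask: np.ndarray  # (H, W) bool

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


def subtract_phases(pre: np.ndarray, post: np.ndarray) -> np.ndarray:
    """Elementwise post - pre; negative values preserved."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise DimensionError(f"shape mismatch {pre.shape} vs {post.shape}")
    return post - pre


def sfcm_cluster(
    image: np.ndarray,
    n_clusters: int = 2,
    fuzzifier: float = 2.0,
    spatial_window: int = 3,
    spatial_weights: tuple[float, float] = (1.0, 1.0),
    tol: float = 1e-5,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Spatial fuzzy C-means on a 2-D intensity image.

    Returns ``(memberships, centers)`` where memberships has shape
    ``(n_clusters, H, W)`` and sums to 1 per pixel. Centers are
    initialized at evenly spaced intensity percentiles between the 10th
    and 90th (deterministic, no random init).
    """
    if n_clusters < 2:
        raise DegenerateClusterError("n_clusters must be >= 2")
    if fuzzifier <= 1:
        raise DegenerateClusterError("fuzzifier must be > 1")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise DimensionError("sfcm_cluster expects a 2-D image")
    flat = img.ravel()
    if np.ptp(flat) == 0:
        raise DegenerateClusterError("constant image: cluster centers coincide")

    p, q = spatial_weights
    m = fuzzifier
    centers = np.percentile(flat, np.linspace(10, 90, n_clusters))
    if np.unique(centers).size < n_clusters:
        raise DegenerateClusterError("initial cluster centers coincide")

    prev_objective = np.inf
    u = None
    for _ in range(max_iter):
        d2 = (flat[None, :] - centers[:, None]) ** 2 + 1e-12
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=0)

        objective = float((u**m * d2).sum())
        # Alternating FCM optimization is strictly non-increasing at q=0;
        # the spatial re-weighting perturbs the center update, so only a
        # bounded relative wobble (1%) is tolerated there.
        wobble = 1e-6 if q == 0 else 1e-2
        if objective > prev_objective * (1 + wobble) + 1e-9:
            raise AssertionError(
                f"sFCM objective increased: {prev_objective} -> {objective}"
            )
        prev_objective = objective

        if q != 0:
            u_img = u.reshape(n_clusters, *img.shape)
            window_area = spatial_window * spatial_window
            h = (
                ndimage.uniform_filter(
                    u_img, size=(1, spatial_window, spatial_window), mode="constant"
                )
                * window_area
            ).reshape(n_clusters, -1)
            u = (u**p) * (h**q)
            u = u / u.sum(axis=0)

        um = u**m
        new_centers = um @ flat / um.sum(axis=1)
        shift = float(np.max(np.abs(new_centers - centers)))
        centers = new_centers
        if shift < tol:
            break

    if np.min(np.diff(np.sort(centers))) < 1e-9:
        raise DegenerateClusterError("converged cluster centers coincide")
    return u.reshape(n_clusters, *img.shape), centers


def refine_mask(
    raw: np.ndarray, min_lesion_pixels: int = DEFAULT_MIN_LESION_PIXELS
) -> LesionMask:
    """Largest 8-connected component, hole filling, one 3x3 binary opening."""
    raw = np.asarray(raw, dtype=bool)
    if not raw.any():
        raise EmptyRegionError("raw mask is empty")
    mask = _largest_component(raw)
    mask = ndimage.binary_fill_holes(mask)
    mask = ndimage.binary_opening(mask, structure=_STRUCT_3X3)
    if not mask.any():
        raise TooSmallLesionError("mask vanished during morphological opening")
    mask = _largest_component(mask)  # opening can disconnect thin bridges
    if int(mask.sum()) < min_lesion_pixels:
        raise TooSmallLesionError(
            f"refined lesion has {int(mask.sum())} px < {min_lesion_pixels}"
        )
    return LesionMask(mask=mask)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labeled, n = ndimage.label(mask, structure=_STRUCT_3X3)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
    return labeled == (int(np.argmax(sizes)) + 1)


def segment_lesion(
    subtraction: np.ndarray,
    roi: ROIBox,
    mask_override: np.ndarray | None = None,
    min_lesion_pixels: int = DEFAULT_MIN_LESION_PIXELS,
    min_separation: float = 4.0,
    **sfcm_kwargs,
) -> LesionMask:
    """sFCM on the ROI crop, brightest cluster hard-labeled, then refined.

    ``mask_override`` bypasses segmentation entirely and returns the
    supplied mask unchanged, so downstream stages can be exercised
    independently of segmentation quality. ``min_separation`` guards
    against ROIs with no enhancing pixels: splitting unimodal noise gives
    a center gap below ~3 pooled within-cluster SDs, while a genuine
    enhancing lesion against background is far better separated.
    """
    subtraction = np.asarray(subtraction, dtype=float)
    if mask_override is not None:
        return LesionMask(mask=np.asarray(mask_override, dtype=bool))
    roi.validate_within(subtraction.shape)
    crop = subtraction[roi.slices]
    memberships, centers = sfcm_cluster(crop, **sfcm_kwargs)
    lesion_cluster = int(np.argmax(centers))
    hard = np.argmax(memberships, axis=0) == lesion_cluster

    gap = float(np.max(centers) - np.min(centers))
    spread = np.concatenate(
        [crop[hard] - np.max(centers), crop[~hard] - np.min(centers)]
    )
    pooled_sd = float(np.sqrt(np.mean(spread**2))) if spread.size else 0.0
    if pooled_sd > 0 and gap < min_separation * pooled_sd:
        raise TooSmallLesionError(
            "ROI contains no enhancing cluster "
            f"(center gap {gap:.2f} < {min_separation} x SD {pooled_sd:.2f})"
        )
    refined = refine_mask(hard, min_lesion_pixels=min_lesion_pixels)
    full = np.zeros(subtraction.shape, dtype=bool)
    full[roi.slices] = refined.mask
    return LesionMask(mask=full)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks."""
    a = np.asarray(getattr(a, "mask", a), dtype=bool)
    b = np.asarray(getattr(b, "mask", b), dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(a, b).sum()) / float(denom)
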