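"""Bilateral mammographic density/asymmetry features.

Six global features are computed per breast side and fused as absolute
left-right differences (dF_i = |F_i^L - F_i^R|), the inputs of the
short-term breast-cancer risk model: mean density, fibroglandular
(dense-tissue) area, size of the largest focal region in the
difference-of-Gaussian map, mean local pixel-value fluctuation, mean
DoG response, and an ordinal 4-level overall-density category.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from gifa.errors import EmptySegmentationError, InvalidParameterError

#: percent-dense upper bin edges for the 4-level ordinal density category
DENSITY_BIN_EDGES = (0.10, 0.25, 0.50)

DEFAULT_SIGMA_FINE = 2.0
DEFAULT_SIGMA_COARSE = 8.0
DEFAULT_FLUCTUATION_WINDOW = 9
FOCAL_PERCENTILE = 99.0

FEATURE_NAMES = (
    "mean_density",
    "fibroglandular_area",
    "focal_region_size",
    "fluctuation_mean",
    "dog_mean",
    "density_category",
)


@dataclass(frozen=True)
class SideFeatureSet:
    """The six per-side global features of one breast."""

    mean_density: float
    fibroglandular_area: float
    focal_region_size: float
    fluctuation_mean: float
    dog_mean: float
    density_category: int

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], float)


@dataclass(frozen=True)
class BilateralFeatureSet:
    """Absolute left-right differences of the six side features."""

    deltas: tuple[float, ...]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.deltas, float)


def segment_breast(image: np.ndarray, pixel_area: float = 1.0) -> np.ndarray:
    """Segment the breast as the largest connected component above an
    automatic (Otsu) background threshold.

    The threshold is histogram-derived, so the mask is invariant to a
    constant intensity offset.
    """
    image = np.asarray(image, float)
    if image.ndim != 2:
        raise InvalidParameterError("expected a 2D image")
    if np.ptp(image) == 0:
        raise EmptySegmentationError("image has no foreground contrast")
    thr = threshold_otsu(image)
    fg = image > thr
    if not fg.any():
        raise EmptySegmentationError("no pixels above the background threshold")
    labels, n = ndimage.label(fg)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def dog_map(
    image: np.ndarray,
    sigma_fine: float = DEFAULT_SIGMA_FINE,
    sigma_coarse: float = DEFAULT_SIGMA_COARSE,
) -> np.ndarray:
    """Difference-of-Gaussian band-pass map: G(fine)*I - G(coarse)*I."""
    if not (0 < sigma_fine < sigma_coarse):
        raise InvalidParameterError("require 0 < sigma_fine < sigma_coarse")
    image = np.asarray(image, float)
    fine = ndimage.gaussian_filter(image, sigma_fine, mode="reflect")
    coarse = ndimage.gaussian_filter(image, sigma_coarse, mode="reflect")
    return fine - coarse


def fluctuation_map(image: np.ndarray, window: int = DEFAULT_FLUCTUATION_WINDOW) -> np.ndarray:
    """Local pixel-value fluctuation map: per-pixel SD over a sliding
    window (reflect padding)."""
    if window < 3 or window % 2 == 0:
        raise InvalidParameterError("window must be an odd integer >= 3")
    image = np.asarray(image, float)
    mean = ndimage.uniform_filter(image, window, mode="reflect")
    sq_mean = ndimage.uniform_filter(image * image, window, mode="reflect")
    var = np.maximum(sq_mean - mean * mean, 0.0)
    return np.sqrt(var)


def density_category(percent_dense: float, edges=DENSITY_BIN_EDGES) -> int:
    """Map percent-dense breast area to the 4-level ordinal category."""
    return 1 + int(np.searchsorted(np.asarray(edges), percent_dense, side="right"))


def compute_side_features(
    image: np.ndarray,
    mask: np.ndarray,
    *,
    pixel_area: float = 1.0,
    sigma_fine: float = DEFAULT_SIGMA_FINE,
    sigma_coarse: float = DEFAULT_SIGMA_COARSE,
    window: int = DEFAULT_FLUCTUATION_WINDOW,
    focal_percentile: float = FOCAL_PERCENTILE,
) -> SideFeatureSet:
    """Compute the six global features of one breast side.

    The dense-tissue threshold is Otsu computed within the breast mask
    only; a constant-intensity breast (no within-mask contrast) is
    treated as fully dense.
    """
    image = np.asarray(image, float)
    mask = np.asarray(mask, bool)
    if mask.shape != image.shape:
        raise InvalidParameterError("mask shape must match image")
    if not mask.any():
        raise EmptySegmentationError("empty breast mask")

    in_mask = image[mask]
    mean_density = float(in_mask.mean())

    if np.ptp(in_mask) == 0:
        dense = mask.copy()
    else:
        dense = mask & (image > threshold_otsu(in_mask))
    fibroglandular_area = float(dense.sum()) * pixel_area

    dog = dog_map(image, sigma_fine, sigma_coarse)
    dog_mean = float(dog[mask].mean())
    thr = np.percentile(dog[mask], focal_percentile)
    focal = mask & (dog >= thr)
    if np.ptp(dog[mask]) == 0:
        focal_region_size = 0.0
    else:
        # 8-connectivity for focal components
        labels, n = ndimage.label(focal, structure=np.ones((3, 3), int))
        if n == 0:
            focal_region_size = 0.0
        else:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
            focal_region_size = float(sizes.max()) * pixel_area

    # average the local-SD map away from the mask boundary so the
    # breast/background edge does not count as tissue fluctuation
    fluct = fluctuation_map(image, window)
    core = ndimage.binary_erosion(mask, iterations=window // 2)
    fluctuation_mean = float(fluct[core if core.any() else mask].mean())

    percent_dense = float(dense.sum()) / float(mask.sum())
    category = density_category(percent_dense)

    return SideFeatureSet(
        mean_density=mean_density,
        fibroglandular_area=fibroglandular_area,
        focal_region_size=focal_region_size,
        fluctuation_mean=fluctuation_mean,
        dog_mean=dog_mean,
        density_category=category,
    )


def bilateral_difference(left: SideFeatureSet, right: SideFeatureSet) -> BilateralFeatureSet:
    """Absolute elementwise difference |F^L - F^R|; symmetric in sides."""
    if left is None or right is None:
        raise InvalidParameterError("both side feature sets are required")
    deltas = tuple(np.abs(left.as_array() - right.as_array()))
    return BilateralFeatureSet(deltas=deltas)


def extract_bilateral_features(left_image, right_image, **kwargs) -> BilateralFeatureSet:
    """Segment both sides and compute the six bilateral deltas in one call."""
    lmask = segment_breast(left_image)
    rmask = segment_breast(right_image)
    lf = compute_side_features(left_image, lmask, **kwargs)
    rf = compute_side_features(right_image, rmask, **kwargs)
    return bilateral_difference(lf, rf)
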