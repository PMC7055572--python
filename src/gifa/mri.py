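"""Global kinetic features from paired pre/post-contrast breast MRI.

The pipeline subtracts a registered pre-contrast volume from the
post-contrast volume inside a segmented breast region, then summarizes
the enhancement distribution per breast (mean, SD, skewness, mean of
the top 1% / 5% of sorted values) and as bilateral left-right absolute
differences, without any tumor segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from itertools import product

import numpy as np
from skimage.filters import threshold_otsu

from gifa.errors import (
    EmptySegmentationError,
    InvalidInputError,
    InvalidParameterError,
)


@dataclass(frozen=True)
class KineticFeatureSet:
    """Per-breast enhancement statistics and their bilateral deltas."""

    left: dict[str, float]
    right: dict[str, float]
    deltas: dict[str, float]


STAT_NAMES = ("mean", "sd", "skewness", "top1_mean", "top5_mean")


def segment_breast_region(
    volume: np.ndarray, chest_wall: int | None = None
) -> np.ndarray:
    """Segment the breast by removing air background and all tissue at or
    posterior to the chest-wall line.

    Air is removed by an automatic (Otsu) threshold. The chest wall is a
    straight per-volume separation line along the anterior-posterior
    (second) axis: when ``chest_wall`` is None it is fitted as the
    posterior edge of the largest anterior foreground slab (the first
    row index from which foreground occupies nearly the full transverse
    extent); a fixed index can be supplied for phantoms.
    """
    volume = np.asarray(volume, float)
    if volume.ndim != 3:
        raise InvalidParameterError("expected a 3D volume")
    if np.ptp(volume) == 0:
        raise EmptySegmentationError("volume has no foreground contrast")
    fg = volume > threshold_otsu(volume)
    if not fg.any():
        raise EmptySegmentationError("no foreground above the air threshold")

    if chest_wall is None:
        # Row-wise foreground occupancy along the AP axis; the chest wall is
        # where occupancy jumps to (near-)full width — tissue behind the wall
        # spans the whole transverse plane, breasts do not.
        occupancy = fg.mean(axis=(0, 2))
        full = occupancy >= 0.95 * occupancy.max()
        candidates = np.flatnonzero(full)
        chest_wall = int(candidates[0]) if len(candidates) else volume.shape[1]

    mask = fg.copy()
    mask[:, chest_wall:, :] = False
    if not mask.any():
        raise EmptySegmentationError("no breast tissue anterior to the chest wall")
    return mask


def register_translation(
    pre: np.ndarray, post: np.ndarray, max_shift: int = 5
) -> tuple[int, ...]:
    """Integer-translation registration: the shift of ``post`` (applied via
    np.roll) that maximizes correlation with ``pre``, searched exhaustively
    over ±max_shift per axis."""
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    best, best_corr = (0,) * pre.ndim, -np.inf
    pre_c = pre - pre.mean()
    for shift in product(range(-max_shift, max_shift + 1), repeat=pre.ndim):
        rolled = np.roll(post, shift, axis=tuple(range(pre.ndim)))
        corr = float(np.dot(pre_c.ravel(), rolled.ravel()))
        if corr > best_corr:
            best_corr, best = corr, shift
    return best


def enhancement_map(
    pre: np.ndarray,
    post: np.ndarray,
    mask: np.ndarray,
    align: bool = False,
    max_shift: int = 5,
) -> np.ndarray:
    """Contrast-enhancement map: (registered) post − pre inside the mask.

    Values outside the mask are set to 0 and carry no meaning.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    mask = np.asarray(mask, bool)
    if pre.shape != post.shape or mask.shape != pre.shape:
        raise InvalidInputError("pre/post/mask geometry mismatch")
    if not mask.any():
        raise EmptySegmentationError("empty breast mask")
    if align:
        shift = register_translation(pre, post, max_shift)
        post = np.roll(post, shift, axis=tuple(range(pre.ndim)))
    out = np.where(mask, post - pre, 0.0)
    return out


def _side_stats(values: np.ndarray) -> dict[str, float]:
    n = values.size
    mean = float(values.mean())
    sd = float(values.std())  # population SD
    if sd == 0:
        skew = 0.0
    else:
        m3 = float(((values - mean) ** 3).mean())
        skew = m3 / sd**3
    s = np.sort(values)[::-1]
    k1 = int(np.ceil(0.01 * n))
    k5 = int(np.ceil(0.05 * n))
    return {
        "mean": mean,
        "sd": sd,
        "skewness": skew,
        "top1_mean": float(s[:k1].mean()),
        "top5_mean": float(s[:k5].mean()),
    }


def kinetic_features(
    emap: np.ndarray, mask_left: np.ndarray, mask_right: np.ndarray
) -> KineticFeatureSet:
    """Per-breast kinetic statistics and bilateral absolute differences.

    Skewness uses population moments (m3/m2^{3/2}), reported as 0 for a
    degenerate (zero-SD) distribution; top-k% means average the
    ceil(k% · N) largest in-mask values so the set is never empty.
    """
    emap = np.asarray(emap, float)
    mask_left = np.asarray(mask_left, bool)
    mask_right = np.asarray(mask_right, bool)
    if (mask_left & mask_right).any():
        raise InvalidInputError("left and right masks overlap")
    for name, m in (("left", mask_left), ("right", mask_right)):
        if not m.any():
            raise EmptySegmentationError(f"empty {name} breast mask")
    left = _side_stats(emap[mask_left])
    right = _side_stats(emap[mask_right])
    deltas = {k: abs(left[k] - right[k]) for k in STAT_NAMES}
    return KineticFeatureSet(left=left, right=right, deltas=deltas)
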