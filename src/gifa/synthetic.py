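"""Synthetic phantoms and feature tables with known ground truth.

Every generator here is deterministic given its seed, and returns the
ground-truth masks or parameters next to the data, so each downstream
stage (segmentation, feature extraction, modeling, evaluation) can be
tested against a planted truth without any external dataset.

Hounsfield-unit phantoms keep a guard band of at least 30 HU between
tissue classes and the segmentation thresholds (−950 HU for emphysema,
−140..40 HU for fat), so threshold operators are unambiguous by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from gifa.errors import InvalidSpecError

# HU placement constants: each tissue sits >= 30 HU away from the
# thresholds it must not cross.
AIR_HU = -1000.0
LUNG_PARENCHYMA_HU = -850.0
EMPHYSEMA_HU = -985.0
SOFT_TISSUE_HU = 45.0
FAT_HU = -90.0
ORGAN_HU = 85.0


@dataclass(frozen=True)
class Blob:
    """A spherical/circular lesion descriptor: center (voxels), radius, value."""

    center: tuple[float, ...]
    radius: float
    value: float


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, noise and seeding for one phantom image or volume."""

    seed: int
    shape: tuple[int, ...]
    noise_sd: float = 0.0
    background: float = 0.0
    blobs: tuple[Blob, ...] = ()
    spacing: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if any(s < 4 for s in self.shape):
            raise InvalidSpecError(f"phantom shape too small: {self.shape}")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        for blob in self.blobs:
            if len(blob.center) != len(self.shape):
                raise InvalidSpecError("blob center dimensionality mismatch")
            if any(not (0 <= c < s) for c, s in zip(blob.center, self.shape)):
                raise InvalidSpecError(f"blob center {blob.center} outside domain")

    def voxel_spacing(self) -> tuple[float, ...]:
        if self.spacing is None:
            return (1.0,) * len(self.shape)
        return self.spacing


@dataclass(frozen=True)
class FeatureTableSpec:
    """Two-class Gaussian feature-table specification.

    Informative features have a standardized class-mean shift of
    ``effect_size`` (Cohen's d); with a single informative feature the
    theoretical AUC is Phi(d/sqrt(2)). ``correlation`` is the
    within-class equicorrelation of the features.
    """

    n_pos: int
    n_neg: int
    n_features: int = 6
    n_informative: int = 1
    effect_size: float = 0.0
    correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1 or self.n_features < 1:
            raise InvalidSpecError("counts must be >= 1")
        if self.n_informative > self.n_features or self.n_informative < 0:
            raise InvalidSpecError("n_informative must be in [0, n_features]")
        if self.effect_size < 0:
            raise InvalidSpecError("effect_size must be >= 0")
        if not (0 <= self.correlation < 1):
            raise InvalidSpecError("correlation must be in [0, 1)")


@dataclass
class LabeledVolume:
    """A scalar field in HU (or enhancement units) plus geometry and masks."""

    voxels: np.ndarray
    spacing: tuple[float, ...]
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise InvalidSpecError("spacing must be positive per axis")
        for name, mask in self.masks.items():
            if mask.shape != self.voxels.shape:
                raise InvalidSpecError(f"mask {name!r} does not match voxel geometry")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


def gen_feature_table(spec: FeatureTableSpec) -> pd.DataFrame:
    """Generate a two-class case table with a planted effect size.

    Returns a CaseTable DataFrame with columns
    ``case_id, f1..fn, label, synthetic``; class-1 rows have their
    informative columns shifted by ``effect_size`` within-class SDs.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    labels = np.concatenate([np.ones(spec.n_pos, int), np.zeros(spec.n_neg, int)])

    if spec.correlation > 0:
        shared = rng.standard_normal((n, 1))
        noise = rng.standard_normal((n, spec.n_features))
        x = np.sqrt(spec.correlation) * shared + np.sqrt(1 - spec.correlation) * noise
    else:
        x = rng.standard_normal((n, spec.n_features))
    x[labels == 1, : spec.n_informative] += spec.effect_size

    table = pd.DataFrame(x, columns=[f"f{i + 1}" for i in range(spec.n_features)])
    table.insert(0, "case_id", [f"case_{i:05d}" for i in range(n)])
    table["label"] = labels
    table["synthetic"] = False
    return table


def _paint_blobs(image: np.ndarray, blobs: tuple[Blob, ...]) -> None:
    grids = np.ogrid[tuple(slice(0, s) for s in image.shape)]
    for blob in blobs:
        dist2 = sum((g - c) ** 2 for g, c in zip(grids, blob.center))
        image[dist2 <= blob.radius**2] = blob.value


def _disc_mask(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return dist2 <= radius**2


def gen_bilateral_pair(spec: PhantomSpec, asymmetry: float):
    """Generate a (left, right, label) mammogram-like bilateral pair.

    The right image is the left-right mirror of the left image's
    structure; ``asymmetry > 0`` plants extra dense blobs and inflates
    local noise variance on the right side only, emulating bilateral
    tissue-pattern asymmetry. label = 1 iff asymmetry > 0.

    Returns ``(left, right, label, truth)`` where truth carries the
    breast masks of both sides.
    """
    if asymmetry < 0:
        raise InvalidSpecError("asymmetry must be >= 0")
    if len(spec.shape) != 2:
        raise InvalidSpecError("bilateral pair requires a 2D shape")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape

    # Breast as a half-disc against the left edge (chest wall at edge).
    structure = np.full(spec.shape, spec.background, float)
    breast_center = (h / 2.0, 0.0)
    breast_radius = 0.85 * min(h / 2.0, w)
    breast = _disc_mask(spec.shape, breast_center, breast_radius)
    structure[breast] = spec.background + 0.35
    _paint_blobs(structure, spec.blobs)

    right_structure = structure[:, ::-1].copy()
    right_breast = breast[:, ::-1]

    if asymmetry > 0:
        # Extra dense blobs inside the right breast.
        n_extra = 1 + int(round(3 * min(asymmetry, 1.0)))
        coords = np.argwhere(right_breast)
        for _ in range(n_extra):
            cy, cx = coords[rng.integers(len(coords))]
            r = 0.05 * breast_radius + 0.12 * breast_radius * min(asymmetry, 1.0)
            extra = _disc_mask(spec.shape, (float(cy), float(cx)), r) & right_breast
            right_structure[extra] += 0.4 * asymmetry

    left = structure + rng.normal(0.0, spec.noise_sd, spec.shape)
    noise_r = rng.normal(0.0, spec.noise_sd, spec.shape)
    if asymmetry > 0:
        # Local variance inflation in a random in-breast patch.
        coords = np.argwhere(right_breast)
        cy, cx = coords[rng.integers(len(coords))]
        patch = _disc_mask(spec.shape, (float(cy), float(cx)), 0.3 * breast_radius)
        noise_r = np.where(patch & right_breast, noise_r * (1.0 + asymmetry), noise_r)
    right = right_structure + noise_r

    label = int(asymmetry > 0)
    truth = {"breast_left": breast, "breast_right": right_breast}
    return left, right, label, truth


def _fill_count(rng, candidate_mask: np.ndarray, target: int, radii=(3, 7)) -> np.ndarray:
    """Select exactly ``target`` voxels of ``candidate_mask`` as blob-shaped
    regions: spheres are accumulated until the count is exceeded, then the
    last sphere is trimmed voxel-wise to land exactly on target."""
    out = np.zeros_like(candidate_mask)
    if target <= 0:
        return out
    available = int(candidate_mask.sum())
    if target >= available:
        return candidate_mask.copy()
    coords = np.argwhere(candidate_mask)
    guard = 0
    while out.sum() < target:
        guard += 1
        if guard > 10_000:  # pragma: no cover - degenerate geometry
            raise InvalidSpecError("cannot place requested blob volume")
        center = coords[rng.integers(len(coords))]
        r = float(rng.uniform(*radii))
        sphere = _disc_mask(candidate_mask.shape, tuple(map(float, center)), r)
        new = sphere & candidate_mask & ~out
        overshoot = int(out.sum()) + int(new.sum()) - target
        if overshoot > 0:
            new_idx = np.argwhere(new)
            drop = new_idx[rng.permutation(len(new_idx))[:overshoot]]
            new[tuple(drop.T)] = False
        out |= new
    return out


def gen_lung_volume(spec: PhantomSpec, emphysema_fraction: float) -> LabeledVolume:
    """Generate a chest-CT-like volume with planted emphysema.

    The lung field is an ellipsoid of parenchyma around −850 HU inside
    soft tissue; a fraction ``emphysema_fraction`` of lung voxels is
    planted below −950 HU as blob-shaped regions. The planted fraction
    is exact to one voxel.

    Returns a LabeledVolume with masks ``lung`` and ``emphysema``.
    """
    if not (0 <= emphysema_fraction <= 1):
        raise InvalidSpecError("emphysema_fraction must be in [0, 1]")
    if len(spec.shape) != 3:
        raise InvalidSpecError("lung volume requires a 3D shape")
    rng = np.random.default_rng(spec.seed)

    vol = np.full(spec.shape, SOFT_TISSUE_HU, float)
    center = tuple((s - 1) / 2.0 for s in spec.shape)
    semi = tuple(0.38 * s for s in spec.shape)
    grids = np.ogrid[tuple(slice(0, s) for s in spec.shape)]
    lung = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi)) <= 1.0

    sd = min(spec.noise_sd, 20.0)
    parenchyma = rng.normal(LUNG_PARENCHYMA_HU, sd, spec.shape)
    vol[lung] = np.clip(parenchyma, -915.0, -760.0)[lung]

    target = int(round(emphysema_fraction * int(lung.sum())))
    emph = _fill_count(rng, lung, target)
    emph_hu = rng.normal(EMPHYSEMA_HU, sd, spec.shape)
    vol[emph] = np.clip(emph_hu, AIR_HU, -981.0)[emph]

    return LabeledVolume(
        voxels=vol,
        spacing=spec.voxel_spacing(),
        masks={"lung": lung, "emphysema": emph},
    )


def gen_abdominal_slice(spec: PhantomSpec, sfa_area: float, vfa_area: float) -> LabeledVolume:
    """Generate an abdominal-CT-like 2D slice with planted fat compartments.

    Subcutaneous fat (SFA) is drawn as a ring hugging the body boundary,
    visceral fat (VFA) as interior blobs, both in the −140..40 HU fat
    band; other organs are placed above 40 HU with a guard band. Areas
    are in mm² and honored exactly to one pixel.

    Returns a LabeledVolume with masks ``body``, ``sfa`` and ``vfa``.
    """
    if sfa_area < 0 or vfa_area < 0:
        raise InvalidSpecError("fat areas must be >= 0")
    if len(spec.shape) != 2:
        raise InvalidSpecError("abdominal slice requires a 2D shape")
    rng = np.random.default_rng(spec.seed)
    spacing = spec.voxel_spacing()
    pixel_area = spacing[0] * spacing[1]

    center = tuple((s - 1) / 2.0 for s in spec.shape)
    semi = tuple(0.42 * s for s in spec.shape)
    grids = np.ogrid[tuple(slice(0, s) for s in spec.shape)]
    body = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi)) <= 1.0

    sfa_px = int(round(sfa_area / pixel_area))
    vfa_px = int(round(vfa_area / pixel_area))

    # SFA ring: the sfa_px body pixels nearest the outer boundary.
    depth = ndimage.distance_transform_edt(body, sampling=spacing)
    if sfa_px > int(body.sum()):
        raise InvalidSpecError("requested SFA exceeds body area")
    sfa = np.zeros_like(body)
    if sfa_px > 0:
        order = np.argsort(depth[body], kind="stable")
        idx = np.argwhere(body)[order[:sfa_px]]
        sfa[tuple(idx.T)] = True
        ring_depth = float(depth[body][order[sfa_px - 1]])
    else:
        ring_depth = 0.0

    # VFA blobs in the deep interior, kept clear of the ring.
    interior = body & (depth > ring_depth + 15.0)
    if vfa_px > int(interior.sum()):
        raise InvalidSpecError("requested VFA does not fit inside body interior")
    vfa = _fill_count(rng, interior, vfa_px, radii=(4, 10))

    vol = np.full(spec.shape, AIR_HU, float)
    sd = min(spec.noise_sd, 12.0)
    organ = np.clip(rng.normal(ORGAN_HU, sd, spec.shape), 72.0, 110.0)
    fat = np.clip(rng.normal(FAT_HU, sd, spec.shape), -135.0, -45.0)
    vol[body] = organ[body]
    vol[sfa | vfa] = fat[sfa | vfa]

    return LabeledVolume(
        voxels=vol,
        spacing=spacing,
        masks={"body": body, "sfa": sfa, "vfa": vfa},
    )


@dataclass(frozen=True)
class EnhancementSpec:
    """Planted contrast-enhancement field for MRI pair phantoms.

    kind: 'none', 'uniform' (constant ``magnitude``) or 'skewed'
    (right-skewed lognormal with mean ``magnitude``).
    """

    kind: str = "uniform"
    magnitude: float = 100.0
    sigma: float = 0.8  # lognormal shape for the skewed field

    def __post_init__(self) -> None:
        if self.kind not in ("none", "uniform", "skewed"):
            raise InvalidSpecError(f"unknown enhancement kind {self.kind!r}")
        if self.magnitude < 0:
            raise InvalidSpecError("magnitude must be >= 0")


def gen_mri_pair(spec: PhantomSpec, enhancement: EnhancementSpec):
    """Generate pre/post-contrast breast MRI volume phantoms.

    The breast is two half-ellipsoids anterior to a flat chest-wall
    plane with pectoral tissue behind it; the post volume adds the
    planted enhancement field inside the breast mask plus noise.

    Returns ``(pre, post, truth)`` where truth holds the breast mask,
    the left/right side masks, the chest-wall plane index, and the
    planted enhancement field.
    """
    if len(spec.shape) != 3:
        raise InvalidSpecError("MRI pair requires a 3D shape")
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape

    wall = int(0.65 * ny)  # axial rows >= wall are chest / pectoral tissue
    grids = np.ogrid[0:nz, 0:ny, 0:nx]
    breast_mask = np.zeros(spec.shape, bool)
    side_masks = {}
    for name, cx in (("left", 0.27 * nx), ("right", 0.73 * nx)):
        c = (nz / 2.0, float(wall), cx)
        semi = (0.42 * nz, 0.58 * wall, 0.21 * nx)
        ellip = sum(((g - ci) / a) ** 2 for g, ci, a in zip(grids, c, semi)) <= 1.0
        ellip &= grids[1] < wall
        side_masks[name] = ellip
        breast_mask |= ellip

    pre = np.zeros(spec.shape, float)
    pre[breast_mask] = 200.0
    pre[:, wall:, :] = 300.0  # pectoral/chest tissue behind the wall

    if enhancement.kind == "none":
        enh = np.zeros(spec.shape)
    elif enhancement.kind == "uniform":
        enh = np.where(breast_mask, enhancement.magnitude, 0.0)
    else:  # skewed: lognormal scaled to the requested mean
        raw = rng.lognormal(0.0, enhancement.sigma, spec.shape)
        raw *= enhancement.magnitude / np.exp(enhancement.sigma**2 / 2.0)
        enh = np.where(breast_mask, raw, 0.0)

    pre = pre + rng.normal(0.0, spec.noise_sd, spec.shape)
    post = pre + enh + rng.normal(0.0, spec.noise_sd, spec.shape)

    truth = {
        "breast": breast_mask,
        "left": side_masks["left"],
        "right": side_masks["right"],
        "wall": wall,
        "enhancement": enh,
    }
    return pre, post, truth
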