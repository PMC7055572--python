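"""File formats and pipeline configuration.

Case tables are RFC-4180 CSV with header ``case_id,<features...>,label,
synthetic``; 2D phantoms are 16-bit PNG/TIFF; volumes and masks are
NIfTI with voxel spacing in the header; configuration and results
round-trip as JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from gifa.errors import ParseError
from gifa.evaluation import EvaluationResult

REQUIRED_COLUMNS = ("case_id", "label")


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the end-to-end pipeline, with defaults matching
    the published operating points where one exists."""

    emphysema_threshold_hu: float = -950.0
    fat_range_hu: tuple[float, float] = (-140.0, 40.0)
    glcm_levels: int = 32
    shell_mm: float = 10.0
    dog_sigma_fine: float = 2.0
    dog_sigma_coarse: float = 8.0
    fluctuation_window: int = 9
    knn_k: int = 15
    smote_ratio: float | None = 1.0
    smote_k: int = 5
    select: bool = True
    classifier: str = "knn"
    cv: str = "loco"
    threshold: float = 0.5
    n_bins: int = 5
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        if "fat_range_hu" in data:
            data["fat_range_hu"] = tuple(data["fat_range_hu"])
        return cls(**data)


def read_case_table(path) -> pd.DataFrame:
    """Read and validate a case-table CSV."""
    table = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ParseError(f"missing required column {col!r}")
    if "synthetic" not in table.columns:
        table["synthetic"] = False
    table["synthetic"] = table["synthetic"].astype(bool)
    dup = table["case_id"][table["case_id"].duplicated()]
    if len(dup):
        raise ParseError(f"duplicate case_id {dup.iloc[0]!r}")
    feats = [c for c in table.columns if c not in ("case_id", "label", "synthetic")]
    bad = table[feats + ["label"]].isna()
    if bad.any().any():
        row = int(np.flatnonzero(bad.any(axis=1))[0])
        raise ParseError(f"missing value in row {row}")
    labels = set(table["label"].unique())
    if not labels <= {0, 1}:
        raise ParseError(f"labels must be binary 0/1, got {sorted(labels)}")
    return table


def write_case_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_volume(volume: np.ndarray, spacing, path) -> None:
    """Write a volume (or 2D slice) as NIfTI with spacing in the header."""
    arr = np.asarray(volume)
    if arr.ndim == 2:
        arr = arr[..., None]
        spacing = tuple(spacing) + (1.0,)
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(arr, np.float32), affine), str(path))


def read_volume(path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
    return data, spacing


def write_image(image: np.ndarray, path) -> None:
    """Write a 2D phantom as 16-bit PNG/TIFF, scaled over its own range."""
    import imageio.v3 as iio

    arr = np.asarray(image, float)
    lo, hi = arr.min(), arr.max()
    scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    iio.imwrite(str(path), (scaled * 65535).astype(np.uint16))


def read_image(path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(str(path)), float)


def result_to_dict(result: EvaluationResult) -> dict:
    return {
        "auc": result.auc,
        "auc_se": result.auc_se,
        "threshold": result.threshold,
        "confusion": asdict(result.confusion),
        "metrics": result.metrics,
        "or_table": [asdict(r) for r in result.or_table],
        "trend_z": result.trend_z,
        "trend_p": result.trend_p,
        "scores": [float(s) for s in result.scores],
    }


def write_result(result: EvaluationResult, path) -> None:
    Path(path).write_text(json.dumps(result_to_dict(result), indent=2, sort_keys=True))


def format_report(result: EvaluationResult) -> str:
    """Text report mirroring the layout of the published tables:
    subgroup ORs, the confusion matrix, and the derived percentages."""
    lines = [
        f"AUC = {result.auc:.2f} +/- {result.auc_se:.2f}",
        "",
        "Risk-subgroup odds ratios (baseline = lowest subgroup)",
        f"{'Subgroup':>8} {'Pos':>5} {'Neg':>5} {'OR':>6} {'95% CI':>16}",
    ]
    for row in result.or_table:
        ci = "-" if row.baseline else f"[{row.ci_low:.3g}, {row.ci_high:.3g}]"
        lines.append(
            f"{row.subgroup:>8} {row.positives:>5} {row.negatives:>5} "
            f"{row.odds_ratio:>6.2f} {ci:>16}"
        )
    lines += [
        f"Trend test: z = {result.trend_z:.2f}, p = {result.trend_p:.3g}",
        "",
        f"Confusion matrix at T = {result.threshold}",
        f"{'':>16} {'Actual +':>9} {'Actual -':>9}",
        f"{'Predicted +':>16} {result.confusion.tp:>9} {result.confusion.fp:>9}",
        f"{'Predicted -':>16} {result.confusion.fn:>9} {result.confusion.tn:>9}",
        "",
    ]
    for name, value in result.metrics.items():
        shown = "undefined" if value is None else f"{value:.1f}%"
        lines.append(f"{name:>12}: {shown}")
    return "\n".join(lines) + "\n"
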