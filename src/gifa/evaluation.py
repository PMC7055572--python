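"""Model evaluation: SMOTE-embedded LOCO cross-validation and the risk
stratification statistics.

The leave-one-case-out (LOCO) protocol holds one original case out at a
time and performs *every* data-dependent step — feature
standardization, SMOTE oversampling, feature selection, classifier
training — on the remaining cases only, so no information from the
held-out case (or from any synthetic case derived while it was held
in) can leak into its score. Synthetic cases are used for training
only and are never scored.

Performance is summarized by the Mann-Whitney AUC with Hanley-McNeil
SE, a confusion matrix at a fixed operating threshold (default
T = 0.5, score >= T predicts positive), quintile odds ratios versus the
lowest-risk subgroup with Woolf 95% CIs, and a Cochran-Armitage trend
test across the ordered subgroups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from gifa import modeling
from gifa.errors import (
    InvalidInputError,
    InvalidParameterError,
    UndefinedMetricError,
)

DEFAULT_THRESHOLD = 0.5
DEFAULT_BINS = 5


@dataclass(frozen=True)
class LocoConfig:
    """Per-fold pipeline configuration for LOCO cross-validation."""

    smote_ratio: float | None = 1.0  # minority:majority target; None disables
    smote_multiplier: float | None = None
    smote_k: int = 5
    select: bool = True  # CFS feature selection inside the loop
    classifier: str = "knn"
    k: int = modeling.DEFAULT_K
    seed: int = 0


def loco_cv(
    table: pd.DataFrame,
    config: LocoConfig = LocoConfig(),
    indices=None,
) -> np.ndarray:
    """Leave-one-case-out scores, one per original case, in table order.

    SMOTE and feature selection are re-run inside every fold on the
    training cases only; synthetic rows never reach the scoring step.
    ``indices`` restricts scoring to a subset of folds (each still
    trained on all other cases); the returned array then follows the
    order of ``indices``.
    """
    if table["synthetic"].astype(bool).any():
        raise InvalidInputError("loco_cv expects a table of original cases only")
    labels = table["label"].to_numpy().astype(int)
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise InvalidInputError("need >= 2 cases per class")
    n = len(table)
    feats = modeling.feature_columns(table)
    fold_seeds = np.random.default_rng(config.seed).integers(0, 2**31 - 1, n)

    folds = range(n) if indices is None else list(indices)
    scores = np.empty(len(folds))
    for out_pos, i in enumerate(folds):
        train = table.drop(table.index[i]).reset_index(drop=True)
        train_labels = train["label"].to_numpy()
        if train_labels.min() == train_labels.max():
            raise InvalidInputError(
                f"fold for case {table.iloc[i]['case_id']!r} lost one class"
            )
        if config.smote_multiplier is not None:
            train = modeling.smote(
                train,
                multiplier=config.smote_multiplier,
                k_neighbors=config.smote_k,
                seed=int(fold_seeds[i]),
            )
        elif config.smote_ratio is not None:
            train = modeling.smote(
                train,
                target_ratio=config.smote_ratio,
                k_neighbors=config.smote_k,
                seed=int(fold_seeds[i]),
            )
        selected = feats
        if config.select:
            chosen = modeling.cfs_select(train)
            if chosen:
                selected = chosen
        k = min(config.k, len(train))
        scorer = modeling.train_classifier(
            train,
            kind=config.classifier,
            k=k,
            seed=int(fold_seeds[i]),
            features=selected,
        )
        q = table.iloc[[i]][selected].to_numpy(float)
        scores[out_pos] = scorer.score(q, [table.iloc[i]["case_id"]])[0]
    return scores


def auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney AUC (ties count 1/2) and its Hanley-McNeil SE."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("AUC needs both classes")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    a = u / (n1 * n0)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n0 - 1) * (q2 - a * a)) / (n1 * n0)
    return float(a), float(np.sqrt(max(var, 0.0)))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_at_threshold(
    scores: np.ndarray, labels: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> ConfusionMatrix:
    """Confusion matrix at a fixed operating threshold; score >= T is a
    positive prediction."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionMatrix(
        tp=int((pred & pos).sum()),
        fp=int((pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
        tn=int((~pred & ~pos).sum()),
    )


def matrix_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Sensitivity, specificity, PPV, NPV, accuracy as percentages.

    A metric with a zero denominator is reported as None (undefined),
    never as 0.
    """

    def pct(num, den):
        return 100.0 * num / den if den > 0 else None

    return {
        "sensitivity": pct(cm.tp, cm.tp + cm.fn),
        "specificity": pct(cm.tn, cm.tn + cm.fp),
        "ppv": pct(cm.tp, cm.tp + cm.fp),
        "npv": pct(cm.tn, cm.tn + cm.fn),
        "accuracy": pct(cm.tp + cm.tn, cm.total),
    }


def quantile_bins(scores: np.ndarray, k: int = DEFAULT_BINS) -> np.ndarray:
    """Rank-based subgroup index (1..k, 1 = lowest scores) per case.

    Bin sizes differ by at most one; ties are resolved by stable case
    order, so the binning depends only on score ranks (invariant to any
    monotone transform of the scores).
    """
    scores = np.asarray(scores, float)
    n = len(scores)
    if k < 2:
        raise InvalidParameterError("k must be >= 2")
    if n < k:
        raise InvalidParameterError("need at least k scores")
    order = np.argsort(scores, kind="stable")
    bins = np.empty(n, int)
    for g, chunk in enumerate(np.array_split(order, k), start=1):
        bins[chunk] = g
    return bins


@dataclass(frozen=True)
class ORRow:
    subgroup: int
    positives: int
    negatives: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    baseline: bool = False
    corrected: bool = False  # Haldane-Anscombe 0.5 applied


def odds_ratio_from_counts(
    pos: np.ndarray, neg: np.ndarray, baseline: int = 0
) -> list[ORRow]:
    """Odds ratios of each subgroup versus the baseline subgroup, with
    Woolf 95% CIs; zero cells get the Haldane-Anscombe 0.5 correction
    (flagged on the affected rows)."""
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    if pos[baseline] == 0 or neg[baseline] == 0:
        raise InvalidInputError("baseline subgroup must contain both classes")
    rows = []
    for g in range(len(pos)):
        if g == baseline:
            rows.append(
                ORRow(g + 1, int(pos[g]), int(neg[g]), 1.0, 1.0, 1.0, baseline=True)
            )
            continue
        a, b, c, d = pos[g], neg[g], pos[baseline], neg[baseline]
        corrected = False
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            corrected = True
        or_ = (a * d) / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo, hi = np.exp(np.log(or_) - 1.96 * se), np.exp(np.log(or_) + 1.96 * se)
        rows.append(
            ORRow(
                g + 1, int(pos[g]), int(neg[g]), float(or_), float(lo), float(hi),
                corrected=corrected,
            )
        )
    return rows


def odds_ratio_table(
    bins: np.ndarray, labels: np.ndarray, baseline: int = 1
) -> list[ORRow]:
    """Per-subgroup odds ratios from case-level bins and labels.

    ``baseline`` is a subgroup index as produced by
    :func:`quantile_bins` (1 = lowest-risk bin).
    """
    bins = np.asarray(bins, int)
    labels = np.asarray(labels).astype(int)
    groups = np.unique(bins)
    pos = np.array([(labels[bins == g] == 1).sum() for g in groups], float)
    neg = np.array([(labels[bins == g] == 0).sum() for g in groups], float)
    base_idx = int(np.flatnonzero(groups == baseline)[0])
    return odds_ratio_from_counts(pos, neg, baseline=base_idx)


def trend_test_from_counts(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """Cochran-Armitage trend test on a k x 2 table with integer scores
    1..k; returns (z statistic, two-sided p)."""
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    k = len(pos)
    if k < 3:
        raise InvalidParameterError("need >= 3 ordered subgroups")
    n_g = pos + neg
    big_n = n_g.sum()
    big_r = pos.sum()
    if big_r == 0 or big_r == big_n or big_n == 0:
        raise UndefinedMetricError("degenerate table for the trend test")
    s = np.arange(1, k + 1, dtype=float)
    t = float((s * (pos - n_g * big_r / big_n)).sum())
    p_bar = big_r / big_n
    var = p_bar * (1 - p_bar) * float((n_g * s**2).sum() - ((n_g * s).sum()) ** 2 / big_n)
    if var <= 0:
        raise UndefinedMetricError("degenerate table for the trend test")
    z = t / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def trend_test(bins: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Cochran-Armitage trend test from case-level bins and labels."""
    bins = np.asarray(bins, int)
    labels = np.asarray(labels).astype(int)
    groups = np.unique(bins)
    pos = np.array([(labels[bins == g] == 1).sum() for g in groups], float)
    neg = np.array([(labels[bins == g] == 0).sum() for g in groups], float)
    return trend_test_from_counts(pos, neg)


@dataclass
class EvaluationResult:
    """Everything the evaluation protocol reports for one score vector."""

    scores: np.ndarray
    auc: float
    auc_se: float
    confusion: ConfusionMatrix
    metrics: dict[str, float | None]
    or_table: list[ORRow]
    trend_z: float
    trend_p: float
    threshold: float = DEFAULT_THRESHOLD
    n_bins: int = DEFAULT_BINS
    selected_features: list = field(default_factory=list)


def evaluate_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    n_bins: int = DEFAULT_BINS,
) -> EvaluationResult:
    """Bundle AUC, confusion metrics, quintile ORs and the trend test."""
    a, se = auc(scores, labels)
    cm = confusion_at_threshold(scores, labels, threshold)
    bins = quantile_bins(scores, n_bins)
    ors = odds_ratio_table(bins, labels)
    z, p = trend_test(bins, labels)
    return EvaluationResult(
        scores=np.asarray(scores, float),
        auc=a,
        auc_se=se,
        confusion=cm,
        metrics=matrix_metrics(cm),
        or_table=ors,
        trend_z=z,
        trend_p=p,
        threshold=threshold,
        n_bins=n_bins,
    )
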