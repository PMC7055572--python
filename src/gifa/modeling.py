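"""Risk modeling: distance-weighted KNN score, SMOTE, CFS selection.

The native risk model is a k-nearest-neighbor scheme over a reference
library of cases: a query case y_q is compared to each reference x_i by
Euclidean distance in the (standardized) feature space,

    d(y_q, x_i) = sqrt(sum_r [f_r(y_q) - f_r(x_i)]^2),

each of the K nearest references votes with a distance weight
w_i = 1 / d(y_q, x_i)^2, and the risk score is the positive fraction of
the total weight,

    P_risk = sum(w+) / (sum(w+) + sum(w-)),    K = N + M = 15 by default,

which lies in [0, 1] by construction. Class imbalance is handled by
SMOTE interpolation of minority cases; feature subsets are chosen by
correlation-based feature selection (CFS) with a best-first search.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from gifa.errors import (
    InsufficientMinorityError,
    InvalidInputError,
    InvalidParameterError,
)

DEFAULT_K = 15
WEIGHT_EPS = 1e-6  # d below this gets the capped weight 1/eps^2

RESERVED_COLUMNS = ("case_id", "label", "synthetic")


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature columns of a case table (everything not reserved)."""
    return [c for c in table.columns if c not in RESERVED_COLUMNS]


def knn_distance(query: np.ndarray, reference: np.ndarray) -> float:
    """Euclidean distance between two feature vectors."""
    query = np.asarray(query, float)
    reference = np.asarray(reference, float)
    if query.shape != reference.shape:
        raise InvalidInputError("feature dimension mismatch")
    return float(np.sqrt(((query - reference) ** 2).sum()))


def knn_weight(d: float, eps: float = WEIGHT_EPS) -> float:
    """Distance weight w = 1/d²; an (near-)exact match is capped at 1/eps²
    to keep the inverse-square rule finite at d = 0."""
    if d < 0:
        raise InvalidParameterError("distance must be >= 0")
    return 1.0 / max(d, eps) ** 2


@dataclass
class KNNModel:
    """Distance-weighted KNN risk scorer over a reference case table.

    Features are z-score standardized with parameters learned from the
    reference cases (toggle with ``standardize``). Neighbors are ranked
    by distance with ties broken by reference order (case_id-sorted);
    a query sharing a case_id with a reference is excluded from its own
    neighborhood (leave-one-case-out semantics).
    """

    reference: pd.DataFrame
    k: int = DEFAULT_K
    standardize: bool = True
    eps: float = WEIGHT_EPS
    features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.features:
            self.features = feature_columns(self.reference)
        ref = self.reference.sort_values("case_id", kind="stable").reset_index(drop=True)
        if self.k > len(ref):
            raise InvalidInputError(
                f"K={self.k} exceeds the {len(ref)} reference cases"
            )
        labels = ref["label"].to_numpy()
        if labels.min() == labels.max():
            raise InvalidInputError("reference set must contain both classes")
        self._ids = ref["case_id"].to_numpy()
        self._labels = labels.astype(int)
        x = ref[self.features].to_numpy(float)
        if self.standardize:
            self.mean_ = x.mean(axis=0)
            sd = x.std(axis=0)
            self.sd_ = np.where(sd > 0, sd, 1.0)
        else:
            self.mean_ = np.zeros(x.shape[1])
            self.sd_ = np.ones(x.shape[1])
        self._x = (x - self.mean_) / self.sd_

    def _transform(self, features: np.ndarray) -> np.ndarray:
        return (np.asarray(features, float) - self.mean_) / self.sd_

    def risk_score(self, features: np.ndarray, case_id: str | None = None) -> float:
        """P_risk of a single query case (Eqs. of the module docstring)."""
        return float(self.risk_scores(np.atleast_2d(features), [case_id])[0])

    def risk_scores(self, features: np.ndarray, case_ids=None) -> np.ndarray:
        """Vectorized P_risk for a batch of query cases."""
        q = self._transform(np.atleast_2d(features))
        if q.shape[1] != self._x.shape[1]:
            raise InvalidInputError("feature dimension mismatch")
        if case_ids is None:
            case_ids = [None] * len(q)
        d2 = ((q[:, None, :] - self._x[None, :, :]) ** 2).sum(axis=2)
        d = np.sqrt(d2)
        out = np.empty(len(q))
        for i, cid in enumerate(case_ids):
            di = d[i]
            valid = np.ones(len(di), bool)
            if cid is not None:
                valid &= self._ids != cid
            if valid.sum() < self.k:
                raise InvalidInputError("fewer than K references after exclusion")
            idx = np.flatnonzero(valid)
            order = idx[np.argsort(di[idx], kind="stable")[: self.k]]
            w = 1.0 / np.maximum(di[order], self.eps) ** 2
            pos = self._labels[order] == 1
            out[i] = w[pos].sum() / w.sum()
        return out


def knn_risk_score(
    query: np.ndarray,
    model: KNNModel,
    case_id: str | None = None,
) -> float:
    """Functional form of :meth:`KNNModel.risk_score`."""
    return model.risk_score(query, case_id)


def smote(
    table: pd.DataFrame,
    multiplier: float | None = None,
    target_ratio: float | None = None,
    k_neighbors: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """SMOTE: interpolate synthetic minority cases toward class balance.

    Each synthetic case is x + u·(x_nn − x) with u ~ Uniform(0, 1) and
    x_nn one of x's ``k_neighbors`` nearest minority neighbors. Pass
    ``multiplier`` (e.g. 2 doubles the minority class) or
    ``target_ratio`` (desired minority:majority ratio, e.g. 1.0).
    Original rows are returned untouched, first, in input order;
    synthetic rows are flagged ``synthetic=True``.
    """
    if (multiplier is None) == (target_ratio is None):
        raise InvalidParameterError("specify exactly one of multiplier/target_ratio")
    if k_neighbors < 1:
        raise InvalidParameterError("k_neighbors must be >= 1")
    labels = table["label"].to_numpy().astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    minority = 1 if n_pos <= n_neg else 0
    n_min = min(n_pos, n_neg)
    n_maj = max(n_pos, n_neg)

    if multiplier is not None:
        if multiplier < 1:
            raise InvalidParameterError("multiplier must be >= 1")
        n_syn = int(round((multiplier - 1) * n_min))
    else:
        n_syn = max(int(round(target_ratio * n_maj)) - n_min, 0)
    if n_syn == 0:
        return table.copy()
    if n_min < 2:
        raise InsufficientMinorityError("minority class needs >= 2 cases for SMOTE")

    feats = feature_columns(table)
    x_min = table.loc[labels == minority, feats].to_numpy(float)
    k = min(k_neighbors, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x_min)
    neigh = nn.kneighbors(x_min, return_distance=False)[:, 1:]  # drop self

    rng = np.random.default_rng(seed)
    base = rng.integers(0, n_min, n_syn)
    pick = rng.integers(0, k, n_syn)
    u = rng.uniform(0.0, 1.0, n_syn)
    x0 = x_min[base]
    x1 = x_min[neigh[base, pick]]
    synth = x0 + u[:, None] * (x1 - x0)

    syn_table = pd.DataFrame(synth, columns=feats)
    syn_table.insert(0, "case_id", [f"syn_{i:05d}" for i in range(n_syn)])
    syn_table["label"] = minority
    syn_table["synthetic"] = True
    out = pd.concat([table, syn_table[table.columns]], ignore_index=True)
    return out


def remove_synthetic(table: pd.DataFrame) -> pd.DataFrame:
    """Drop SMOTE rows, recovering the original table."""
    return table.loc[~table["synthetic"].astype(bool)].reset_index(drop=True)


def _cfs_correlations(x: np.ndarray, y: np.ndarray):
    """|feature-class| and |feature-feature| Pearson correlations;
    constant features get correlation 0 throughout."""
    n, p = x.shape
    xm = x - x.mean(axis=0)
    sd = x.std(axis=0)
    ym = y - y.mean()
    ysd = y.std()
    ok = sd > 0
    r_cf = np.zeros(p)
    if ysd > 0:
        r_cf[ok] = np.abs((xm[:, ok] * ym[:, None]).mean(axis=0) / (sd[ok] * ysd))
    r_ff = np.zeros((p, p))
    if ok.any():
        xs = np.zeros_like(xm)
        xs[:, ok] = xm[:, ok] / sd[ok]
        r_ff = np.abs(xs.T @ xs / n)
        r_ff[~ok, :] = 0.0
        r_ff[:, ~ok] = 0.0
    np.fill_diagonal(r_ff, 1.0)
    return r_cf, r_ff


def cfs_merit(subset, r_cf: np.ndarray, r_ff: np.ndarray) -> float:
    """CFS merit of a feature subset:
    k·mean|r_cf| / sqrt(k + k(k−1)·mean|r_ff|)."""
    k = len(subset)
    if k == 0:
        return 0.0
    idx = np.asarray(sorted(subset))
    rcf = r_cf[idx].mean()
    if k == 1:
        return float(rcf)
    sub = r_ff[np.ix_(idx, idx)]
    rff = (sub.sum() - k) / (k * (k - 1))
    return float(k * rcf / np.sqrt(k + k * (k - 1) * rff))


def cfs_select(
    table: pd.DataFrame | np.ndarray,
    labels: np.ndarray | None = None,
    max_fails: int = 5,
) -> list:
    """Correlation-based feature selection by best-first search.

    Searches subsets maximizing the CFS merit, expanding the best open
    subset by one feature at a time and stopping after ``max_fails``
    consecutive non-improving expansions. Ties break toward the lower
    feature index. Returns the selected features in order of addition
    (column names for a case table, indices for an array).
    """
    if isinstance(table, pd.DataFrame):
        feats = feature_columns(table)
        x = table[feats].to_numpy(float)
        y = table["label"].to_numpy(float) if labels is None else np.asarray(labels, float)
        names: list = feats
    else:
        x = np.asarray(table, float)
        if labels is None:
            raise InvalidParameterError("labels required with an array input")
        y = np.asarray(labels, float)
        names = list(range(x.shape[1]))
    if x.shape[1] < 2:
        raise InvalidParameterError("need >= 2 features")
    if np.unique(y).size < 2:
        raise InvalidInputError("both classes must be present")

    r_cf, r_ff = _cfs_correlations(x, y)
    p = x.shape[1]

    # best-first over subsets; heap keyed by (-merit, subset) so equal-merit
    # ties pop the lexicographically smallest (lowest-index) subset first
    start: tuple[int, ...] = ()
    heap = [(-0.0, start)]
    best_merit, best_subset = -1.0, start
    addition_order: dict[tuple[int, ...], list[int]] = {start: []}
    seen = {start}
    fails = 0
    # a candidate must beat the incumbent by more than FP jitter, so a
    # redundant duplicate never displaces the smaller subset
    tol = 1e-9
    while heap and fails < max_fails:
        neg_m, subset = heapq.heappop(heap)
        if -neg_m > best_merit + tol:
            best_merit, best_subset = -neg_m, subset
            fails = 0
        else:
            fails += 1
        for j in range(p):
            if j in subset:
                continue
            child = tuple(sorted(subset + (j,)))
            if child in seen:
                continue
            seen.add(child)
            addition_order[child] = addition_order[subset] + [j]
            heapq.heappush(heap, (-cfs_merit(child, r_cf, r_ff), child))

    return [names[j] for j in addition_order[best_subset]]


@dataclass
class Scorer:
    """A fitted model mapping feature matrices to risk scores in [0, 1]."""

    kind: str
    _predict: object
    features: list[str]

    def score(self, x: np.ndarray, case_ids=None) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float))
        return self._predict(x, case_ids)

    def score_table(self, table: pd.DataFrame) -> np.ndarray:
        return self.score(
            table[self.features].to_numpy(float), table["case_id"].to_numpy()
        )


def train_classifier(
    table: pd.DataFrame,
    kind: str = "knn",
    k: int = DEFAULT_K,
    seed: int = 0,
    features: list[str] | None = None,
) -> Scorer:
    """Fit a risk scorer on a case table.

    ``kind='knn'`` is the native distance-weighted KNN of this package;
    'random_forest', 'svm' and 'ann' delegate to scikit-learn behind the
    same interface, with seeds fixed for determinism.
    """
    feats = features if features is not None else feature_columns(table)
    labels = table["label"].to_numpy().astype(int)
    if labels.min() == labels.max():
        raise InvalidInputError("both classes must be present")
    x = table[feats].to_numpy(float)

    if kind == "knn":
        model = KNNModel(reference=table, k=k, features=feats)

        def predict(q, case_ids=None):
            return model.risk_scores(q, case_ids)

    elif kind in ("random_forest", "svm", "ann"):
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.neural_network import MLPClassifier
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        if kind == "random_forest":
            clf = RandomForestClassifier(n_estimators=200, random_state=seed)
        elif kind == "svm":
            from sklearn.calibration import CalibratedClassifierCV

            clf = make_pipeline(
                StandardScaler(),
                CalibratedClassifierCV(SVC(random_state=seed), ensemble=False, cv=3),
            )
        else:
            clf = make_pipeline(
                StandardScaler(),
                MLPClassifier(
                    hidden_layer_sizes=(16,), max_iter=2000, random_state=seed
                ),
            )
        clf.fit(x, labels)

        def predict(q, case_ids=None):
            return clf.predict_proba(q)[:, 1]

    else:
        raise InvalidParameterError(f"unknown classifier kind {kind!r}")

    return Scorer(kind=kind, _predict=predict, features=feats)
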