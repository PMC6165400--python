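"""Transductive conformal prediction with a KNN nonconformity measure.

For a bag of labelled examples, the nonconformity score of member (x, y) is

    alpha = sum of distances to its k nearest same-label neighbours
            / sum of distances to its k nearest different-label neighbours,

both neighbour sets taken within the bag excluding the member itself.  Small
alpha means x sits among its own class; large alpha means rival classes are
closer.

To score a new object x under a hypothesized label y, the bag is augmented
with (x, y), every member of the augmented bag (size n) is re-scored
leave-one-out, and the p-value is a rank statistic of alpha_new among all
alphas.  Two counting conventions are provided:

* ``strict``   : p_y = #{i : alpha_i >  alpha_new} / n  (strict inequality);
* ``standard``: p_y = #{i : alpha_i >= alpha_new} / n, the conventional
  transductive p-value, which includes the test member itself (so
  p >= 1/n) and carries the finite-sample coverage guarantee
  P(y_true not in prediction set at level eps) <= eps under exchangeability.

The prediction set at significance eps is {y : p_y > eps}; these sets are
nested across eps.  Forced (point) prediction outputs argmax_y p_y together
with confidence = 1 - second-largest p-value and credibility = largest
p-value.

Degenerate neighbourhoods: missing neighbour distances are padded with +inf,
so a member with fewer than k same-label companions scores alpha = +inf
(nothing nearby shares its label), one with fewer than k different-label
companions scores 0 unless its numerator is also infinite (then 1, neutral);
a zero numerator always gives alpha = 0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .features import FeatureMatrix

__all__ = [
    "CPConfig",
    "CPModel",
    "ConformalPrediction",
    "PredictionSet",
    "InsufficientDataError",
    "knn_nonconformity",
    "p_values",
    "prediction_set",
    "forced_prediction",
    "loo_evaluate",
    "calibration_curve",
    "format_prediction_row",
]


class InsufficientDataError(ValueError):
    """Raised when a neighbour query cannot be satisfied."""


@dataclass(frozen=True)
class CPConfig:
    k: int = 1
    distance_metric: str = "euclidean"
    p_value_mode: str = "standard"   # "standard" or "strict"
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.p_value_mode not in ("strict", "standard"):
            raise ValueError("p_value_mode must be 'strict' or 'standard'")


class CPModel:
    """Training bag (features, labels) plus conformal-predictor settings.

    With ``config.standardize`` each feature is centred/scaled using moments
    fitted on this training bag only.  At least two classes are required; for
    every p-value to be backed by k true neighbours each class should have at
    least k + 2 members (smaller classes are handled by the +inf padding
    convention described in the module docstring).
    """

    def __init__(self, features, labels, config: CPConfig | None = None):
        self.config = config or CPConfig()
        X = np.asarray(features, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("features must be a 2-D array with >= 2 rows")
        y = np.asarray(labels)
        if y.shape != (X.shape[0],):
            raise ValueError("labels must have one entry per feature row")
        self.label_space = np.unique(y)
        if self.label_space.size < 2:
            raise ValueError("need at least 2 classes")
        self.features = X
        self.labels = y
        if self.config.standardize:
            self._mu = X.mean(axis=0)
            sd = X.std(axis=0)
            self._sd = np.where(sd == 0, 1.0, sd)
        else:
            self._mu = None
            self._sd = None
        self._X = self.transform(X)
        self._D = cdist(self._X, self._X, metric=self.config.distance_metric)

    @property
    def n(self) -> int:
        return self.features.shape[0]

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self._mu is None:
            return X
        return (X - self._mu) / self._sd


@dataclass(frozen=True)
class PredictionSet:
    epsilon: float
    members: frozenset

    def __contains__(self, label) -> bool:
        return label in self.members

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ConformalPrediction:
    p_values: dict
    forced_label: object
    confidence: float
    credibility: float


def _alpha_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """alpha = num/den with the documented degenerate-case conventions."""
    with np.errstate(divide="ignore", invalid="ignore"):
        a = num / den
    a = np.where(np.isnan(a), 1.0, a)               # inf/inf -> neutral
    a = np.where((den == 0) & (num > 0), np.inf, a)
    a = np.where(num == 0, 0.0, a)
    return a


def _ksum(rows: np.ndarray, k: int) -> np.ndarray:
    """Sum of the k smallest entries per row, summed in ascending order.

    Ascending-order summation makes the result independent of row element
    ordering, which keeps optimized and naive code paths bit-identical.
    """
    part = np.partition(rows, k - 1, axis=1)[:, :k]
    part.sort(axis=1)
    return part.sum(axis=1)


def _bag_alphas(D: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Leave-one-out KNN nonconformity for every member of a bag.

    ``D`` is the full symmetric distance matrix of the bag; member i's
    neighbours are all other members.
    """
    n = labels.shape[0]
    alphas = np.empty(n)
    all_idx = np.arange(n)
    for lab in np.unique(labels):
        mask = labels == lab
        idx = all_idx[mask]
        m = idx.size
        if m - 1 >= k:
            same = D[np.ix_(idx, idx)].copy()
            np.fill_diagonal(same, np.inf)
            num = _ksum(same, k)
        else:
            num = np.full(m, np.inf)
        other = all_idx[~mask]
        if other.size >= k:
            den = _ksum(D[np.ix_(idx, other)], k)
        else:
            den = np.full(m, np.inf)
        alphas[idx] = _alpha_ratio(num, den)
    return alphas


def knn_nonconformity(
    model: CPModel,
    candidate_features,
    candidate_label,
    exclude_index: int | None = None,
) -> float:
    """Nonconformity of (x, y) against the model's bag.

    ``exclude_index`` removes one training member from the neighbour pool
    (used when the candidate is itself a bag member).  Requires at least k
    same-label and k different-label points after exclusion.
    """
    x = model.transform(candidate_features)
    d = cdist(x, model._X, metric=model.config.distance_metric)[0]
    labels = model.labels
    keep = np.ones(model.n, dtype=bool)
    if exclude_index is not None:
        keep[exclude_index] = False
    same = np.sort(d[keep & (labels == candidate_label)])
    diff = np.sort(d[keep & (labels != candidate_label)])
    k = model.config.k
    if same.size < k or diff.size < k:
        raise InsufficientDataError(
            f"need k={k} same- and different-label points "
            f"(have {same.size} and {diff.size})"
        )
    num = float(same[:k].sum())
    den = float(diff[:k].sum())
    return float(_alpha_ratio(np.array([num]), np.array([den]))[0])


def _count_p(alphas: np.ndarray, a_new: float, n: int, mode: str) -> float:
    if mode == "strict":
        return float(np.count_nonzero(alphas > a_new)) / n
    return float(np.count_nonzero(alphas >= a_new)) / n


def p_values(model: CPModel, x_new) -> dict:
    """Conformal p-value of x_new under every label in the model's space.

    For each candidate label the bag is augmented with (x_new, label), all
    n + 1 members are re-scored leave-one-out within the augmented bag, and
    the p-value is computed under ``model.config.p_value_mode``.
    """
    x = model.transform(x_new)
    n = model.n
    d_new = cdist(x, model._X, metric=model.config.distance_metric)[0]
    D = np.empty((n + 1, n + 1))
    D[:n, :n] = model._D
    D[:n, n] = d_new
    D[n, :n] = d_new
    D[n, n] = 0.0
    out = {}
    labels_aug = np.empty(n + 1, dtype=model.labels.dtype)
    labels_aug[:n] = model.labels
    for lab in model.label_space:
        labels_aug[n] = lab
        alphas = _bag_alphas(D, labels_aug, model.config.k)
        out[lab.item() if hasattr(lab, "item") else lab] = _count_p(
            alphas, alphas[n], n + 1, model.config.p_value_mode
        )
    return out


def prediction_set(p: dict, epsilon: float) -> PredictionSet:
    """Gamma^eps = {y : p_y > eps}; may be empty at large eps."""
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must lie in (0, 1)")
    return PredictionSet(
        epsilon=epsilon,
        members=frozenset(y for y, pv in p.items() if pv > epsilon),
    )


def forced_prediction(p: dict) -> ConformalPrediction:
    """Point prediction: argmax_y p_y, confidence and credibility.

    Ties at the maximal p-value are broken toward the smallest label in
    sorted label order.  Requires at least two labels (confidence is the
    complement of the runner-up p-value).
    """
    if len(p) < 2:
        raise ValueError("need p-values for at least 2 labels")
    labels = sorted(p)
    pv = np.array([p[lab] for lab in labels])
    best = int(np.argmax(pv))  # first occurrence = smallest label on ties
    order = np.sort(pv)[::-1]
    return ConformalPrediction(
        p_values=dict(p),
        forced_label=labels[best],
        confidence=float(1.0 - order[1]),
        credibility=float(order[0]),
    )


def _loo_pmaps_fast(X, y, config: CPConfig):
    """All-sample LOO p-value maps sharing one full distance matrix.

    Holding out sample i and augmenting the remaining bag with (x_i, y_cand)
    is exactly the full bag with label i replaced, so one n x n distance
    matrix serves every fold.  Bit-identical to the naive per-fold path.
    """
    D = cdist(X, X, metric=config.distance_metric)
    n = X.shape[0]
    label_space = np.unique(y)
    pmaps = []
    work = y.copy()
    for i in range(n):
        true = work[i]
        pmap = {}
        for lab in label_space:
            work[i] = lab
            alphas = _bag_alphas(D, work, config.k)
            pmap[lab.item() if hasattr(lab, "item") else lab] = _count_p(
                alphas, alphas[i], n, config.p_value_mode
            )
        work[i] = true
        pmaps.append(pmap)
    return pmaps


def _loo_pmaps_naive(X, y, config: CPConfig):
    """Reference LOO path: rebuild a CPModel per held-out sample."""
    n = X.shape[0]
    pmaps = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        model = CPModel(X[keep], y[keep], config)
        pmaps.append(p_values(model, X[i]))
    return pmaps


def loo_evaluate(
    features: FeatureMatrix, config: CPConfig | None = None, *, naive: bool = False
):
    """Leave-one-out conformal prediction of every sample.

    Returns ``(predictions, accuracy)`` where predictions is one
    :class:`ConformalPrediction` per sample (in row order) and accuracy is
    the forced-prediction hit rate.  The default path reuses one full
    pairwise distance matrix; ``naive=True`` (or ``config.standardize``,
    whose per-fold scaler invalidates the shared matrix) rebuilds a model
    per fold.
    """
    config = config or CPConfig()
    X = np.asarray(features.values, dtype=float)
    y = np.asarray(features.labels)
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes")
    if naive or config.standardize:
        pmaps = _loo_pmaps_naive(X, y, config)
    else:
        pmaps = _loo_pmaps_fast(X, y, config)
    preds = [forced_prediction(p) for p in pmaps]
    hits = sum(pred.forced_label == lab for pred, lab in zip(preds, y.tolist()))
    return preds, hits / len(preds)


def calibration_curve(
    features: FeatureMatrix,
    config: CPConfig | None = None,
    epsilons: Sequence[float] = (0.05, 0.1, 0.2),
) -> np.ndarray:
    """Empirical error of LOO prediction sets at each significance level.

    The error at eps is the fraction of samples whose true label is excluded
    from Gamma^eps, i.e. whose true-label p-value is <= eps.  In ``standard``
    mode this is guaranteed (up to LOO coupling) to stay below eps on
    exchangeable data; ``strict`` mode carries no such guarantee.
    """
    config = config or CPConfig()
    X = np.asarray(features.values, dtype=float)
    y = np.asarray(features.labels)
    if config.standardize:
        pmaps = _loo_pmaps_naive(X, y, config)
    else:
        pmaps = _loo_pmaps_fast(X, y, config)
    p_true = np.array(
        [pmap[lab] for pmap, lab in zip(pmaps, y.tolist())]
    )
    return np.array([float(np.mean(p_true <= eps)) for eps in epsilons])


def format_prediction_row(
    sample_index: int,
    true_label,
    prediction: ConformalPrediction,
    label_names: dict | None = None,
) -> str:
    """Human-readable per-sample report row.

    With ``label_names = {1: 'Astragalus', ...}`` a correct prediction of
    class 1 with confidence 0.9950 and credibility 0.7433 renders as
    ``"5, 1 (Astragalus), 1 (Astragalus), 0.9950, 0.7433"``.
    """

    def fmt(lab) -> str:
        if label_names and lab in label_names:
            return f"{lab} ({label_names[lab]})"
        return str(lab)

    return (
        f"{sample_index}, {fmt(true_label)}, {fmt(prediction.forced_label)}, "
        f"{prediction.confidence:.4f}, {prediction.credibility:.4f}"
    )
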