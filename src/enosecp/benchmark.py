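"""Leave-one-out classifier benchmark harness and PCA dimension sweep.

The harness wraps off-the-shelf scikit-learn classifiers (decision tree, KNN,
LDA, SVM, Gaussian naive Bayes, back-propagation MLP) behind a declarative
:class:`ClassifierSpec`, evaluates each with leave-one-out cross-validation,
optionally after PCA dimensionality reduction, and reports accuracy,
wall-clock time (informational only; hardware-dependent) and cumulative
explained variance per run.

By default PCA is fitted once on the full feature matrix before the LOO loop,
mirroring the common chemometrics protocol this harness reproduces; pass
``pca_in_fold=True`` to refit the projection inside every fold (no
information leakage from the held-out sample).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix

__all__ = [
    "ClassifierSpec",
    "BenchmarkReport",
    "make_classifier",
    "loo_accuracy",
    "pca_reduce",
    "run_benchmark",
    "FAMILIES",
]

FAMILIES = (
    "decision_tree",
    "knn",
    "lda",
    "svm",
    "naive_bayes",
    "neural_net",
)


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus its hyperparameters.

    ``standardize`` wraps the estimator in a per-fold standard scaler (fitted
    on the training fold only).  Family-specific keys: ``k`` for knn,
    ``kernel``/``C``/``gamma``/``degree`` for svm, ``hidden_layer_sizes`` /
    ``max_iter`` for neural_net; anything else is passed through.
    """

    family: str
    hyperparameters: dict = field(default_factory=dict)
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )

    @property
    def name(self) -> str:
        hp = ",".join(f"{k}={v}" for k, v in sorted(self.hyperparameters.items()))
        return f"{self.family}({hp})" if hp else self.family


def make_classifier(spec: ClassifierSpec, seed: int = 0):
    """Instantiate the scikit-learn estimator described by ``spec``."""
    hp = dict(spec.hyperparameters)
    if spec.family == "decision_tree":
        est = DecisionTreeClassifier(random_state=seed, **hp)
    elif spec.family == "knn":
        est = KNeighborsClassifier(n_neighbors=hp.pop("k", 1), **hp)
    elif spec.family == "lda":
        est = LinearDiscriminantAnalysis(**hp)
    elif spec.family == "svm":
        hp.setdefault("kernel", "linear")
        est = SVC(**hp)
    elif spec.family == "naive_bayes":
        est = GaussianNB(**hp)
    elif spec.family == "neural_net":
        hp.setdefault("hidden_layer_sizes", (50,))
        hp.setdefault("max_iter", 500)
        est = MLPClassifier(random_state=seed, **hp)
    else:  # pragma: no cover - guarded by ClassifierSpec
        raise ValueError(spec.family)
    if spec.standardize:
        est = Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def loo_accuracy(features: FeatureMatrix, spec: ClassifierSpec, seed: int = 0) -> float:
    """Leave-one-out accuracy: refit on n-1 samples, predict the held-out one."""
    X = features.values
    y = features.labels
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes")
    base = make_classifier(spec, seed=seed)
    hits = 0
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        est = clone(base)
        est.fit(X[keep], y[keep])
        hits += int(est.predict(X[i : i + 1])[0] == y[i])
    return hits / n


def pca_reduce(features: FeatureMatrix, n_components: int):
    """Mean-centred PCA projection with a deterministic sign convention.

    Returns ``(reduced FeatureMatrix, explained-variance fractions)``.  Each
    component is flipped, if necessary, so its largest-magnitude loading is
    positive, removing the eigenvector sign ambiguity.
    """
    X = features.values
    max_dim = min(X.shape)
    if not 1 <= n_components <= max_dim:
        raise ValueError(f"n_components must lie in 1..{max_dim}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    comps = pca.components_
    for r in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[r])))
        if comps[r, j] < 0:
            comps[r] = -comps[r]
            scores[:, r] = -scores[:, r]
    names = [f"pc{j + 1:02d}" for j in range(n_components)]
    reduced = FeatureMatrix(scores, names, features.labels)
    return reduced, pca.explained_variance_ratio_.copy()


def _loo_accuracy_pca_in_fold(
    features: FeatureMatrix, spec: ClassifierSpec, n_components: int, seed: int
) -> float:
    X = features.values
    y = features.labels
    n = X.shape[0]
    base = make_classifier(spec, seed=seed)
    hits = 0
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        pca = PCA(n_components=n_components, svd_solver="full").fit(X[keep])
        est = clone(base)
        est.fit(pca.transform(X[keep]), y[keep])
        hits += int(est.predict(pca.transform(X[i : i + 1]))[0] == y[i])
    return hits / n


@dataclass
class BenchmarkReport:
    """Accuracy/time/explained-variance table, one row per (spec, dims) run."""

    table: pd.DataFrame

    COLUMNS = ("classifier", "params", "dims", "accuracy", "time_s", "explained_variance")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"report table missing columns {sorted(missing)}")
        acc = self.table["accuracy"].to_numpy(dtype=float)
        if len(acc) and (acc.min() < 0 or acc.max() > 1):
            raise ValueError("accuracies must lie in [0, 1]")


def run_benchmark(
    features: FeatureMatrix,
    specs: Sequence[ClassifierSpec],
    pca_dims: Sequence[int] = (),
    seed: int = 0,
    pca_in_fold: bool = False,
) -> BenchmarkReport:
    """Evaluate every spec at full dimension and at each PCA dimension.

    Explained variance is the cumulative fraction retained by the projection
    (1.0 for the full-dimension run).  Wall time covers the whole LOO loop of
    a run and is reported for orientation only.
    """
    rows = []
    dim_runs: list[tuple[str, int | None]] = [("full", None)]
    dim_runs += [(str(d), int(d)) for d in pca_dims]
    for spec in specs:
        for dims_label, dims in dim_runs:
            t0 = time.perf_counter()
            if dims is None:
                acc = loo_accuracy(features, spec, seed=seed)
                ev = 1.0
            elif pca_in_fold:
                acc = _loo_accuracy_pca_in_fold(features, spec, dims, seed)
                _, evr = pca_reduce(features, dims)
                ev = float(evr.sum())
            else:
                reduced, evr = pca_reduce(features, dims)
                acc = loo_accuracy(reduced, spec, seed=seed)
                ev = float(evr.sum())
            elapsed = time.perf_counter() - t0
            rows.append(
                {
                    "classifier": spec.family,
                    "params": ";".join(
                        f"{k}={v}" for k, v in sorted(spec.hyperparameters.items())
                    ),
                    "dims": dims_label,
                    "accuracy": acc,
                    "time_s": elapsed,
                    "explained_variance": ev,
                }
            )
    table = pd.DataFrame(rows, columns=list(BenchmarkReport.COLUMNS))
    return BenchmarkReport(table)
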