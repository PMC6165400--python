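"""Independent brute-force reference implementations used only by tests.

Pure-Python / pure-loop re-implementations of the conformal p-value, the EMA
recurrence and PCA variances.  They share no code with the package paths they
check (all-pairs lists, explicit sorts, explicit recurrences).
"""

from __future__ import annotations

import math

import numpy as np

INF = float("inf")


def euclidean(a, b) -> float:
    return float(math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b))))


def naive_alpha(points, labels, i, k) -> float:
    """KNN nonconformity of bag member i, neighbours = all other members.

    Missing neighbours are padded with +inf; alpha follows the conventions:
    numerator 0 -> 0; positive/zero -> +inf; inf/inf -> 1.
    """
    same = sorted(
        euclidean(points[i], points[j])
        for j in range(len(points))
        if j != i and labels[j] == labels[i]
    )
    diff = sorted(
        euclidean(points[i], points[j])
        for j in range(len(points))
        if labels[j] != labels[i]
    )
    same += [INF] * max(0, k - len(same))
    diff += [INF] * max(0, k - len(diff))
    num = sum(same[:k])
    den = sum(diff[:k])
    if num == 0:
        return 0.0
    if den == 0:
        return INF
    if math.isinf(num) and math.isinf(den):
        return 1.0
    return num / den


def naive_p_values(train_x, train_y, x_new, k, mode) -> dict:
    """Transductive CP p-values by full augmented-bag recomputation."""
    label_space = sorted(set(train_y))
    out = {}
    for lab in label_space:
        pts = [list(p) for p in train_x] + [list(x_new)]
        ys = list(train_y) + [lab]
        n = len(ys)
        alphas = [naive_alpha(pts, ys, i, k) for i in range(n)]
        a_new = alphas[-1]
        if mode == "strict":
            count = sum(1 for a in alphas if a > a_new)
        else:
            count = sum(1 for a in alphas if a >= a_new)
        out[lab] = count / n
    return out


def naive_ema(signal, a):
    """The EMA-of-first-difference recurrence as an explicit loop."""
    v = list(signal)
    y = [a * v[0]]
    for kk in range(1, len(v)):
        y.append((1 - a) * y[-1] + a * (v[kk] - v[kk - 1]))
    return y


def naive_pca_variances(X):
    """Eigenvalues of the sample covariance (denominator n-1), descending."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    vals = np.linalg.eigvalsh(cov)[::-1]
    return np.clip(vals, 0.0, None)
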