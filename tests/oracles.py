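"""Independent brute-force oracles used by the test suite.

Everything here is written as plain nested loops over the defining
constructions (pair enumeration, run scanning, flood fill, neighbour
counting, concordant-pair counting) and deliberately shares no code with
the package implementation.
"""

from __future__ import annotations

import numpy as np

DIRS = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) > (0, 0, 0)
]
NB26 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]


def inside(shape, v):
    return all(0 <= v[k] < shape[k] for k in range(3))


def glcm_oracle(levels: np.ndarray, g: int) -> np.ndarray:
    """Direction-averaged symmetric normalized co-occurrence matrix."""
    mats = []
    shape = levels.shape
    for d in DIRS:
        m = np.zeros((g, g))
        for v in np.ndindex(shape):
            w = tuple(v[k] + d[k] for k in range(3))
            if not inside(shape, w):
                continue
            a, b = levels[v], levels[w]
            if a > 0 and b > 0:
                m[a - 1, b - 1] += 1
                m[b - 1, a - 1] += 1  # symmetric
        if m.sum() > 0:
            mats.append(m / m.sum())
    return np.mean(mats, axis=0)


def glrlm_oracle(levels: np.ndarray, g: int, max_run: int) -> np.ndarray:
    """Direction-averaged run-length count matrix by explicit line scanning."""
    shape = levels.shape
    mats = []
    for d in DIRS:
        m = np.zeros((g, max_run))
        for v in np.ndindex(shape):
            lev = levels[v]
            if lev == 0:
                continue
            prev = tuple(v[k] - d[k] for k in range(3))
            if inside(shape, prev) and levels[prev] == lev:
                continue  # not a run start
            run = 1
            w = tuple(v[k] + d[k] for k in range(3))
            while inside(shape, w) and levels[w] == lev:
                run += 1
                w = tuple(w[k] + d[k] for k in range(3))
            m[lev - 1, run - 1] += 1
        mats.append(m)
    return np.mean(mats, axis=0)


def glszm_oracle(levels: np.ndarray, g: int, max_size: int) -> np.ndarray:
    """Zone matrix by breadth-first flood fill over 26-connected equal levels."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    m = np.zeros((g, max_size))
    for v in np.ndindex(shape):
        if levels[v] == 0 or seen[v]:
            continue
        lev = levels[v]
        stack, zone = [v], 0
        seen[v] = True
        while stack:
            u = stack.pop()
            zone += 1
            for d in NB26:
                w = tuple(u[k] + d[k] for k in range(3))
                if inside(shape, w) and not seen[w] and levels[w] == lev:
                    seen[w] = True
                    stack.append(w)
        m[lev - 1, zone - 1] += 1
    return m


def gldm_oracle(levels: np.ndarray, g: int, alpha: int = 0) -> np.ndarray:
    """Dependence matrix; column = (number of dependent 26-neighbours) + 1."""
    shape = levels.shape
    m = np.zeros((g, 27))
    for v in np.ndindex(shape):
        lev = levels[v]
        if lev == 0:
            continue
        dep = 0
        for d in NB26:
            w = tuple(v[k] + d[k] for k in range(3))
            if inside(shape, w) and levels[w] > 0 and abs(int(levels[w]) - int(lev)) <= alpha:
                dep += 1
        m[lev - 1, dep] += 1
    cols = np.nonzero(m.sum(axis=0))[0]
    return m[:, : cols[-1] + 1]


def first_order_oracle(x: np.ndarray) -> dict:
    """Direct formula-by-formula statistics of a flat intensity sample."""
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    mu = x.sum() / n
    var = ((x - mu) ** 2).sum() / n
    sd = np.sqrt(var)
    out = {
        "Mean": mu,
        "Energy": (x**2).sum(),
        "Variance": var,
        "Minimum": x.min(),
        "Maximum": x.max(),
        "Range": x.max() - x.min(),
        "Median": float(np.median(x)),
        "RootMeanSquared": np.sqrt((x**2).sum() / n),
        "MeanAbsoluteDeviation": np.abs(x - mu).sum() / n,
        "Skewness": (((x - mu) / sd) ** 3).sum() / n if sd > 0 else 0.0,
        "Kurtosis": (((x - mu) / sd) ** 4).sum() / n if sd > 0 else 0.0,
    }
    return out


def auc_pair_count_oracle(scores, labels) -> float:
    """AUC = fraction of concordant positive/negative pairs, ties half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def svm_rfe_exhaustive_oracle(X, y, cost, gamma):
    """One-at-a-time backward elimination with the kernel margin criterion.

    Independent implementation: refits sklearn SVC at each stage and
    recomputes W^2 for every candidate removal by rebuilding the RBF kernel
    on the reduced data with explicit loops.
    """
    from sklearn.svm import SVC

    X = np.asarray(X, dtype=float)
    y2 = 2.0 * np.asarray(y, dtype=float) - 1.0

    def w2_of(cols, alpha_beta, sv_rows):
        Xs = X[np.ix_(sv_rows, cols)]
        total = 0.0
        for i in range(len(sv_rows)):
            for j in range(len(sv_rows)):
                d2 = float(((Xs[i] - Xs[j]) ** 2).sum())
                total += alpha_beta[i] * alpha_beta[j] * np.exp(-gamma * d2)
        return total

    remaining = list(range(X.shape[1]))
    order = []
    while len(remaining) > 1:
        clf = SVC(kernel="rbf", C=cost, gamma=gamma)
        clf.fit(X[:, remaining], y2)
        beta = clf.dual_coef_[0]
        sv = clf.support_
        w2 = w2_of(remaining, beta, sv)
        crits = []
        for pos, col in enumerate(remaining):
            cols = [c for c in remaining if c != col]
            crits.append((abs(w2 - w2_of(cols, beta, sv)), -col))
        worst = min(range(len(crits)), key=lambda i: crits[i])
        order.append(remaining.pop(worst))
    order.append(remaining.pop())
    order.reverse()
    return order
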