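"""Independent brute-force oracles used to cross-check the implementations.

Everything here is written from first principles (enumeration, closed
forms, plain Newton iteration) and deliberately avoids the code paths
under test.
"""

import numpy as np


def auc_pair_count(pos: np.ndarray, neg: np.ndarray) -> float:
    """Probability a random positive out-scores a random negative; ties 1/2.

    Scores must already be oriented so that larger = more disease-leaning.
    """
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def ols_closed_form(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and intercept from the normal equations."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def logistic_newton(X: np.ndarray, y: np.ndarray, tol: float = 1e-12,
                    max_iter: int = 200) -> np.ndarray:
    """Plain Newton-Raphson MLE for logistic regression.

    ``X`` must already include any intercept column.  Returns the
    coefficient vector.
    """
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        hess = X.T @ (X * w[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta
    raise RuntimeError("Newton iteration did not converge")


def greedy_match_replay(
    logit_scores: np.ndarray, is_case: np.ndarray, caliper: float
) -> tuple[list[tuple[int, int]], list[int]]:
    """Literal replay of the stated matching rule.

    Cases in descending propensity order; nearest available control by
    absolute logit distance; equidistant ties to the lowest index; pairs
    beyond the caliper discarded.
    """
    order = sorted(
        np.flatnonzero(is_case), key=lambda i: (-logit_scores[i], i)
    )
    available = list(np.flatnonzero(~is_case))
    pairs, unmatched = [], []
    for ci in order:
        dists = [(abs(logit_scores[ci] - logit_scores[j]), j) for j in available]
        if dists:
            d, j = min(dists)
            if d <= caliper:
                pairs.append((ci, j))
                available.remove(j)
                continue
        unmatched.append(ci)
    return pairs, unmatched + available
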