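"""Independent reference implementations used only by tests.

Everything here is deliberately slow and simple: a proximal-gradient solver
for the penalised precision matrix, exhaustive modularity search, numerical
integration for ordinalized correlations.  None of it shares code with the
package.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import multivariate_normal, norm


def slow_glasso(S: np.ndarray, lam: float, tol: float = 1e-10,
                max_iter: int = 200_000) -> np.ndarray:
    """Proximal gradient (ISTA) on -log det T + tr(S T) + lam * |offdiag(T)|_1."""
    p = S.shape[0]
    T = np.linalg.inv(S + lam * np.eye(p))
    step = 1.0 / (np.linalg.eigvalsh(S)[-1] ** 2 + 1.0)
    off = ~np.eye(p, dtype=bool)

    def prox(M: np.ndarray, s: float) -> np.ndarray:
        M = M.copy()
        M[off] = np.sign(M[off]) * np.maximum(np.abs(M[off]) - s * lam, 0.0)
        return 0.5 * (M + M.T)

    for _ in range(max_iter):
        G = S - np.linalg.inv(T)
        s = step
        Tn = prox(T - s * G, s)
        while np.linalg.eigvalsh(Tn)[0] <= 1e-12:
            s *= 0.5
            Tn = prox(T - s * G, s)
        if np.max(np.abs(Tn - T)) < tol:
            return Tn
        T = Tn
    return T


def all_partitions(n: int):
    """All set partitions of range(n) as membership tuples (restricted growth)."""

    def rec(i: int, max_label: int, cur: list[int]):
        if i == n:
            yield tuple(cur)
            return
        for lab in range(max_label + 1):
            cur.append(lab)
            yield from rec(i + 1, max(max_label, lab + 1), cur)
            cur.pop()

    yield from rec(0, 0, [])


def modularity(A: np.ndarray, membership) -> float:
    """Weighted Newman modularity of a partition (A symmetric, zero diag)."""
    m2 = A.sum()
    if m2 == 0:
        return 0.0
    k = A.sum(axis=1)
    q = 0.0
    n = len(membership)
    for i in range(n):
        for j in range(n):
            if membership[i] == membership[j]:
                q += A[i, j] - k[i] * k[j] / m2
    return q / m2


def max_modularity(A: np.ndarray) -> float:
    """Exhaustive search over all partitions (n <= 10 or so)."""
    return max(modularity(A, mem) for mem in all_partitions(A.shape[0]))


def ordinal_corr_oracle(rho: float, thr_x: np.ndarray, thr_y: np.ndarray) -> float:
    """Pearson correlation of two ordinalized standard-normal latents.

    X = #(thresholds below x) with corr(x, y) = rho; moments by numerical
    integration of the bivariate normal over threshold rectangles.
    """

    def moments(thr: np.ndarray) -> tuple[float, float]:
        sf = 1.0 - norm.cdf(thr)
        mean = sf.sum()
        # E[X^2] = sum_{k,l} P(x > t_k, x > t_l) = sum_k sf_k + 2 sum_{k<l} sf_l
        ex2 = sf.sum() + 2.0 * sum(
            sf[l] for k in range(len(thr)) for l in range(k + 1, len(thr))
        )
        return mean, ex2 - mean**2

    cov_mat = np.array([[1.0, rho], [rho, 1.0]])
    exy = 0.0
    for tk in thr_x:
        for tl in thr_y:
            # P(x > tk, y > tl) by inclusion-exclusion on the CDF
            exy += (
                1.0
                - norm.cdf(tk)
                - norm.cdf(tl)
                + multivariate_normal.cdf([tk, tl], cov=cov_mat)
            )
    mx, vx = moments(thr_x)
    my, vy = moments(thr_y)
    return (exy - mx * my) / np.sqrt(vx * vy)


def ordinal_moments_oracle(thr: np.ndarray) -> tuple[float, float]:
    """Analytic (mean, sd) of an ordinalized standard-normal latent."""
    edges = np.concatenate(([-np.inf], thr, [np.inf]))
    probs = np.diff(norm.cdf(edges))
    cats = np.arange(len(probs))
    mean = float(np.sum(cats * probs))
    var = float(np.sum((cats - mean) ** 2 * probs))
    return mean, np.sqrt(var)


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson formula, written out."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    den = (
        sum((xi - mx) ** 2 for xi in x) * sum((yi - my) ** 2 for yi in y)
    ) ** 0.5
    return num / den
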