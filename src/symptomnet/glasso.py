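"""Gaussian graphical model estimation with an L1-penalised precision matrix.

The estimator maximises

    log det(Theta) - tr(S Theta) - lambda * sum_{i != j} |theta_ij|

over positive-definite matrices Theta (the diagonal is unpenalised), using
block coordinate descent: each column of the working covariance W is updated
by solving a lasso regression on the remaining variables (coordinate descent
on the dual), which yields exact zeros in the precision matrix.  Edge
weights of the resulting network are the partial correlations

    p_ij = -theta_ij / sqrt(theta_ii * theta_jj)

Model selection along a logarithmic lambda path uses the extended Bayesian
information criterion (EBIC), which adds a gamma-weighted complexity term to
the BIC so that spurious edges are suppressed in wide models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import spearmanr

from .data import ResponseMatrix

__all__ = [
    "CorrMatrix",
    "Network",
    "correlation",
    "glasso_fit",
    "glasso_objective",
    "partial_correlations",
    "ebic",
    "ebic_glasso",
]


@dataclass
class CorrMatrix:
    """A p x p correlation matrix together with the sample size behind it."""

    values: np.ndarray
    n: int
    item_codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        S = np.asarray(self.values, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(S), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(S)[0] < -1e-8:
            raise ValueError("correlation matrix is not positive semidefinite")
        self.values = 0.5 * (S + S.T)
        if not self.item_codes:
            self.item_codes = tuple(f"v{i}" for i in range(S.shape[0]))
        self.item_codes = tuple(self.item_codes)

    @property
    def p(self) -> int:
        return self.values.shape[0]


@dataclass
class Network:
    """Partial-correlation network: edge weights, precision, penalty."""

    weights: np.ndarray
    precision: Optional[np.ndarray]
    lambda_: float
    node_codes: tuple[str, ...]
    path: Optional[pd.DataFrame] = None  # (lambda, n_edges, ebic) table

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(W, W.T, atol=1e-8):
            raise ValueError("weights must be symmetric")
        if np.any(np.abs(np.diag(W)) > 1e-12):
            raise ValueError("weights must have zero diagonal")
        if np.any(np.abs(W) >= 1.0):
            raise ValueError("partial correlations must lie in (-1, 1)")
        self.weights = W
        self.node_codes = tuple(self.node_codes)
        if len(self.node_codes) != W.shape[0]:
            raise ValueError("node_codes length mismatch")

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def edge_list(self) -> pd.DataFrame:
        """Weighted edge list (upper triangle, nonzero edges only)."""
        i_idx, j_idx = np.nonzero(np.triu(self.weights, 1))
        return pd.DataFrame(
            {
                "node_i": [self.node_codes[i] for i in i_idx],
                "node_j": [self.node_codes[j] for j in j_idx],
                "partial_correlation": self.weights[i_idx, j_idx],
            }
        )


def correlation(
    m: ResponseMatrix, method: str = "pearson"
) -> CorrMatrix:
    """Item correlation matrix (Pearson by default, Spearman optional)."""
    X = m.values
    if np.isnan(X).any():
        raise ValueError("missing values present; apply complete_cases first")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = m.codes[int(np.flatnonzero(sds == 0)[0])]
        raise ValueError(f"item {bad!r} has zero variance")
    if method == "pearson":
        S = np.corrcoef(X, rowvar=False)
    elif method == "spearman":
        S, _ = spearmanr(X)
        S = np.atleast_2d(S)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    np.fill_diagonal(S, 1.0)
    return CorrMatrix(S, n=m.n_subjects, item_codes=m.codes)


# ---------------------------------------------------------------------------
# Solver


@njit(cache=True)
def _glasso_cd(S, lam, tol, max_outer, inner_tol, max_inner):  # pragma: no cover
    # lam is a full penalty matrix so the same kernel solves both the
    # uniformly penalised problem and the support-restricted ML refit
    p = S.shape[0]
    W = S.copy()
    B = np.zeros((p, p))
    converged = False
    n_outer = 0
    for _ in range(max_outer):
        n_outer += 1
        max_d = 0.0
        for j in range(p):
            for _ in range(max_inner):
                d_in = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    r = S[k, j]
                    for l in range(p):
                        if l == j or l == k:
                            continue
                        r -= W[k, l] * B[l, j]
                    b_old = B[k, j]
                    lkj = lam[k, j]
                    if r > lkj:
                        b_new = (r - lkj) / W[k, k]
                    elif r < -lkj:
                        b_new = (r + lkj) / W[k, k]
                    else:
                        b_new = 0.0
                    B[k, j] = b_new
                    d = abs(b_new - b_old)
                    if d > d_in:
                        d_in = d
                if d_in < inner_tol:
                    break
            for k in range(p):
                if k == j:
                    continue
                v = 0.0
                for l in range(p):
                    if l == j:
                        continue
                    v += W[k, l] * B[l, j]
                d = abs(v - W[k, j])
                if d > max_d:
                    max_d = d
                W[k, j] = v
                W[j, k] = v
        if max_d < tol:
            converged = True
            break
    Theta = np.zeros((p, p))
    for j in range(p):
        s = 0.0
        for l in range(p):
            if l != j:
                s += W[j, l] * B[l, j]
        t_jj = 1.0 / (W[j, j] - s)
        Theta[j, j] = t_jj
        for k in range(p):
            if k != j:
                Theta[k, j] = -B[k, j] * t_jj
    for i in range(p):
        for k in range(i + 1, p):
            if Theta[i, k] == 0.0 and Theta[k, i] == 0.0:
                continue
            v = 0.5 * (Theta[i, k] + Theta[k, i])
            Theta[i, k] = v
            Theta[k, i] = v
    return Theta, W, n_outer, converged


def partial_correlations(precision: np.ndarray) -> np.ndarray:
    """P with p_ij = -theta_ij / sqrt(theta_ii theta_jj), zero diagonal."""
    d = np.sqrt(np.diag(precision))
    P = -precision / np.outer(d, d)
    np.fill_diagonal(P, 0.0)
    # exact zeros in Theta stay exact zeros in P
    P[precision == 0.0] = 0.0
    np.fill_diagonal(P, 0.0)
    return P


def glasso_objective(
    precision: np.ndarray, S: np.ndarray, lam: float
) -> float:
    """Penalised log-likelihood the solver maximises."""
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        return -np.inf
    off = precision - np.diag(np.diag(precision))
    return float(logdet - np.sum(S * precision) - lam * np.sum(np.abs(off)))


def glasso_fit(
    S: CorrMatrix | np.ndarray,
    lam: float,
    *,
    n: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> Network:
    """Fit the graphical lasso at a single penalty value.

    At ``lam = 0`` the estimate is the unpenalised MLE ``inv(S)`` (requires
    an invertible correlation matrix).
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if isinstance(S, CorrMatrix):
        codes, n_obs, Sv = S.item_codes, S.n, S.values
    else:
        Sv = np.asarray(S, dtype=float)
        codes = tuple(f"v{i}" for i in range(Sv.shape[0]))
        n_obs = n
    if lam == 0.0:
        if np.linalg.eigvalsh(Sv)[0] <= 1e-12:
            raise np.linalg.LinAlgError(
                "correlation matrix is singular; lambda = 0 has no MLE"
            )
        Theta = np.linalg.inv(Sv)
        Theta = 0.5 * (Theta + Theta.T)
    else:
        lam_mat = np.full_like(Sv, float(lam))
        Theta, _, n_outer, converged = _glasso_cd(
            Sv, lam_mat, tol, max_iter, tol * 1e-2, max_iter
        )
        if not converged:
            raise RuntimeError(
                f"graphical lasso did not converge in {n_outer} outer "
                f"iterations (lambda={lam:g}, tol={tol:g})"
            )
        if np.linalg.eigvalsh(Theta)[0] <= 0:
            raise RuntimeError(
                f"graphical lasso produced a non-PD precision at lambda={lam:g}"
            )
    return Network(
        weights=partial_correlations(Theta),
        precision=Theta,
        lambda_=float(lam),
        node_codes=codes,
    )


def restricted_mle(
    S: np.ndarray,
    support: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> np.ndarray:
    """Maximum-likelihood precision matrix constrained to a given edge set.

    Classical covariance selection: maximise log det Theta - tr(S Theta)
    subject to theta_ij = 0 off the support.  Solved with the same block
    coordinate descent, using a per-edge penalty of zero on the support and
    a prohibitive penalty (> max |s_ij|) elsewhere.
    """
    Sv = np.asarray(S, dtype=float)
    support = np.asarray(support, dtype=bool)
    lam_mat = np.where(support | np.eye(Sv.shape[0], dtype=bool), 0.0, 2.0)
    Theta, _, n_outer, converged = _glasso_cd(
        Sv, lam_mat, tol, max_iter, tol * 1e-2, max_iter
    )
    if not converged:
        raise RuntimeError(
            f"restricted ML refit did not converge in {n_outer} iterations"
        )
    return Theta


# ---------------------------------------------------------------------------
# Model selection


def ebic(
    network: Network, S: CorrMatrix | np.ndarray, n: int, gamma: float
) -> float:
    """Extended BIC of a fitted network.

    EBIC = -2 l(Theta) + E log(n) + 4 gamma E log(p), with the Gaussian
    log-likelihood l = (n/2)(log det Theta - tr(S Theta)) and E the number
    of nonzero upper-triangle edges.  gamma = 0 reduces to the BIC.
    """
    Sv = S.values if isinstance(S, CorrMatrix) else np.asarray(S, dtype=float)
    Theta = network.precision
    sign, logdet = np.linalg.slogdet(Theta)
    ll = 0.5 * n * (logdet - float(np.sum(Sv * Theta)))
    E = network.n_edges
    p = network.p
    return float(-2.0 * ll + E * np.log(n) + 4.0 * gamma * E * np.log(p))


def ebic_glasso(
    S: CorrMatrix,
    n: Optional[int] = None,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.1,
    refit_selection: bool = True,
) -> Network:
    """EBIC-selected graphical lasso over a logarithmic penalty path.

    The path runs from ``lambda_max`` (the largest absolute off-diagonal
    correlation, where the network is empty) down to
    ``lambda_max * lambda_min_ratio``.  By default each candidate edge set is
    scored by the EBIC of its support-restricted ML refit (relaxed
    selection): scoring the penalised estimate itself lets the shrinkage
    bias of strong edges dominate the edge penalty as n grows, which drives
    the selector to the densest end of the path.  The refit is used only for
    scoring; the returned network is the penalised fit at the winning
    penalty, with conventionally shrunken partial correlations.
    ``refit_selection=False`` scores the penalised fits directly.

    Ties go to the sparser fit.  The (lambda, edges, EBIC) table of the full
    path is attached to the returned network as ``.path``.
    """
    if n_lambda < 2:
        raise ValueError("n_lambda must be >= 2")
    n_obs = S.n if n is None else n
    Sv = S.values
    p = S.p
    lam_max = float(np.max(np.abs(Sv - np.diag(np.diag(Sv)))))
    if lam_max == 0.0:  # already diagonal: empty network at any penalty
        net = glasso_fit(S, 1.0)
        net.path = pd.DataFrame(
            {"lambda": [1.0], "n_edges": [0], "ebic": [ebic(net, S, n_obs, gamma)]}
        )
        return net
    lams = np.exp(
        np.linspace(np.log(lam_max), np.log(lam_max * lambda_min_ratio), n_lambda)
    )
    rows = []
    best: Optional[tuple[float, int, Network]] = None
    crit_cache: dict[bytes, float] = {}
    n_failed = 0
    for lam in lams:
        try:
            net = glasso_fit(S, float(lam))
            if refit_selection:
                support = net.weights != 0
                key = support.tobytes()
                if key not in crit_cache:
                    theta_r = restricted_mle(Sv, support)
                    refit = Network(
                        weights=partial_correlations(theta_r),
                        precision=theta_r,
                        lambda_=float(lam),
                        node_codes=net.node_codes,
                    )
                    crit_cache[key] = ebic(refit, S, n_obs, gamma)
                crit = crit_cache[key]
            else:
                crit = ebic(net, S, n_obs, gamma)
        except (RuntimeError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        rows.append((float(lam), net.n_edges, crit))
        if (
            best is None
            or crit < best[0] - 1e-12
            or (abs(crit - best[0]) <= 1e-12 and net.n_edges < best[1])
        ):
            best = (crit, net.n_edges, net)
    if best is None:
        raise RuntimeError(f"all {n_failed} graphical lasso fits failed")
    net = best[2]
    net.path = pd.DataFrame(rows, columns=["lambda", "n_edges", "ebic"])
    return net
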