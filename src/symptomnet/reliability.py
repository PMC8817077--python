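"""Internal-consistency coefficients: Cronbach's alpha and McDonald's omega.

Alpha is the classical variance-ratio coefficient.  Omega (total) is
computed from a one-factor maximum-likelihood fit on the item correlation
scale:

    omega = (sum |lambda_i|)^2 / ((sum |lambda_i|)^2 + sum psi_i)

where lambda are the standardised loadings and psi the uniquenesses.
Absolute loadings make the coefficient invariant to item reflection.  The
confidence interval is a non-parametric percentile bootstrap over subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.decomposition import FactorAnalysis
from sklearn.exceptions import ConvergenceWarning

from .data import ResponseMatrix

__all__ = ["ReliabilityResult", "cronbach_alpha", "one_factor_fit", "mcdonald_omega"]


@dataclass
class ReliabilityResult:
    alpha: float
    omega: float
    omega_ci: Optional[tuple[float, float]]
    n_boot: int

    def __post_init__(self) -> None:
        if self.omega_ci is not None:
            low, high = self.omega_ci
            if not low <= self.omega <= high:
                raise ValueError("omega must lie inside its CI")


def _values(m: ResponseMatrix | np.ndarray) -> np.ndarray:
    X = m.values if isinstance(m, ResponseMatrix) else np.asarray(m, dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values present; apply complete_cases first")
    return X


def cronbach_alpha(m: ResponseMatrix | np.ndarray) -> float:
    """alpha = p/(p-1) * (1 - sum of item variances / variance of the total)."""
    X = _values(m)
    p = X.shape[1]
    if p < 2:
        raise ValueError("alpha needs at least 2 items")
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance")
    return float(p / (p - 1) * (1.0 - item_var.sum() / total_var))


def one_factor_fit(
    X: np.ndarray, max_iter: int = 2000
) -> tuple[np.ndarray, np.ndarray]:
    """ML one-factor fit on standardised items -> (loadings, uniquenesses).

    Uniquenesses that hit the optimiser's lower bound (Heywood cases) are
    clamped to zero with a warning.
    """
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    fa = FactorAnalysis(n_components=1, max_iter=max_iter, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            fa.fit(Z)
        except ConvergenceWarning as e:
            raise RuntimeError(
                f"one-factor ML fit did not converge within {max_iter} "
                f"iterations: {e}"
            ) from None
    loadings = fa.components_[0].copy()
    if loadings.sum() < 0:
        loadings = -loadings
    psi = fa.noise_variance_.copy()
    heywood = psi < 1e-6
    if heywood.any():
        warnings.warn(
            f"{int(heywood.sum())} Heywood case(s): uniqueness clamped to 0"
        )
        psi[heywood] = 0.0
    return loadings, psi


def _omega_total(loadings: np.ndarray, psi: np.ndarray) -> float:
    s = np.abs(loadings).sum()
    return float(s**2 / (s**2 + psi.sum()))


def mcdonald_omega(
    m: ResponseMatrix | np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> ReliabilityResult:
    """Omega total with a percentile-bootstrap 95% CI (``n_boot = 0`` skips it)."""
    X = _values(m)
    if X.shape[1] < 3:
        raise ValueError("omega needs at least 3 items")
    loadings, psi = one_factor_fit(X)
    omega = _omega_total(loadings, psi)
    alpha = cronbach_alpha(X)
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = X.shape[0]
        reps = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                l_b, p_b = one_factor_fit(X[idx])
            except (RuntimeError, FloatingPointError):
                continue
            reps.append(_omega_total(l_b, p_b))
        if len(reps) < max(10, n_boot // 2):
            raise RuntimeError(
                f"too many bootstrap failures ({n_boot - len(reps)}/{n_boot})"
            )
        low, high = np.percentile(reps, [2.5, 97.5])
        ci = (min(float(low), omega), max(float(high), omega))
    return ReliabilityResult(alpha=alpha, omega=omega, omega_ci=ci, n_boot=n_boot)
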