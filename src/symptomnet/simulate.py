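"""Ordinal questionnaire simulation with known community structure.

Responses are generated from a correlated common-factor model: latent
factors are multivariate normal with a given correlation matrix, each item's
latent response is ``loadings @ factors`` plus unique normal noise
(total variance normalised to 1), and the ordinal category is obtained by
counting fixed thresholds below the latent value (a graded-response-style
discretization, which preserves the strong skew typical of symptom items).

Redundant item pairs are injected by letting two items share a fraction of
their unique variance, so their correlation exceeds what the factors alone
produce - the ground truth for redundancy detection.

``default_study_spec`` reproduces the study conditions every downstream
stage is tested against: 22 items in four communities of sizes 7/5/3/7,
primary loadings 0.65, small cross-loadings between the two interrelated
demoralisation communities, factor correlations 0.45 within the
demoralisation block and 0.30 with the depressive block, and thresholds
calibrated so analytic item means match the published reference moments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .data import ItemMeta, ResponseMatrix, Scale
from .instruments import (
    DS2_PHQ9_ITEMS,
    NODE_MOMENTS,
    REFERENCE_MOMENTS,
    STUDY_COMMUNITIES,
    STUDY_COMPOSITES,
)

__all__ = [
    "SynthSpec",
    "generate",
    "thresholds_for_target",
    "community_spec",
    "default_study_spec",
    "default_raw_study_spec",
]


@dataclass
class SynthSpec:
    """Parameters of the generative factor model.

    ``thresholds[i]`` are the strictly increasing cut-points of item ``i``
    on its standard-normal latent scale; an item with m thresholds yields
    categories 0..m.  ``redundant_pairs`` entries are
    ``(item_index_i, item_index_j, extra_shared_variance)`` where the last
    component is the fraction of unique variance the pair shares.
    """

    loadings: np.ndarray
    factor_corr: np.ndarray
    thresholds: tuple[np.ndarray, ...]
    item_meta: tuple[ItemMeta, ...]
    n: int
    seed: int
    redundant_pairs: tuple[tuple[int, int, float], ...] = ()
    mcar_rate: float = 0.0
    membership: Optional[np.ndarray] = None  # ground-truth community per item

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.factor_corr = np.asarray(self.factor_corr, dtype=float)
        self.thresholds = tuple(np.asarray(t, dtype=float) for t in self.thresholds)
        self.item_meta = tuple(self.item_meta)
        p, k = self.loadings.shape
        if self.factor_corr.shape != (k, k):
            raise ValueError("factor_corr shape does not match loadings")
        if not np.allclose(self.factor_corr, self.factor_corr.T):
            raise ValueError("factor_corr must be symmetric")
        if not np.allclose(np.diag(self.factor_corr), 1.0):
            raise ValueError("factor_corr must have unit diagonal")
        try:
            np.linalg.cholesky(self.factor_corr)
        except np.linalg.LinAlgError as e:
            raise ValueError("factor_corr is not positive definite") from e
        if len(self.thresholds) != p or len(self.item_meta) != p:
            raise ValueError("thresholds/item_meta length must equal n items")
        for i, t in enumerate(self.thresholds):
            if t.size and np.any(np.diff(t) <= 0):
                raise ValueError(f"thresholds of item {i} not strictly increasing")
        comm = self.communalities
        if np.any(comm >= 1.0):
            raise ValueError("communality >= 1; reduce loadings")
        used: set[int] = set()
        for i, j, frac in self.redundant_pairs:
            if not 0.0 < frac < 1.0:
                raise ValueError("extra_shared_variance must be in (0, 1)")
            if i == j or i in used or j in used:
                raise ValueError("redundant pairs must be disjoint")
            used.update((i, j))
        if not 0.0 <= self.mcar_rate < 1.0:
            raise ValueError("mcar_rate must be in [0, 1)")
        if self.membership is not None:
            self.membership = np.asarray(self.membership, dtype=int)

    @property
    def n_items(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    @property
    def communalities(self) -> np.ndarray:
        """Variance of each item latent explained by the common factors."""
        return np.einsum(
            "ik,kl,il->i", self.loadings, self.factor_corr, self.loadings
        )

    def latent_corr(self) -> np.ndarray:
        """Model-implied correlation matrix of the item latents."""
        R = self.loadings @ self.factor_corr @ self.loadings.T
        u = 1.0 - self.communalities
        np.fill_diagonal(R, 1.0)
        for i, j, frac in self.redundant_pairs:
            extra = frac * np.sqrt(u[i] * u[j])
            R[i, j] += extra
            R[j, i] += extra
        return R


def generate(spec: SynthSpec) -> ResponseMatrix:
    """Draw ``spec.n`` i.i.d. subjects from the factor model.

    Deterministic given ``spec.seed``.  Constant (degenerate) columns are
    flagged with a warning.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.n_items
    u = 1.0 - spec.communalities
    F = rng.multivariate_normal(
        np.zeros(spec.n_factors), spec.factor_corr, size=spec.n, method="cholesky"
    )
    E = rng.standard_normal((spec.n, p))
    X = F @ spec.loadings.T
    shared_frac = np.zeros(p)
    for i, j, frac in spec.redundant_pairs:
        s = rng.standard_normal(spec.n)
        X[:, i] += np.sqrt(frac * u[i]) * s
        X[:, j] += np.sqrt(frac * u[j]) * s
        shared_frac[i] = shared_frac[j] = frac
    X += E * np.sqrt(u * (1.0 - shared_frac))

    values = np.empty((spec.n, p), dtype=float)
    for i in range(p):
        base = spec.item_meta[i].min_score if spec.item_meta[i].is_ordinal else 0
        values[:, i] = base + np.searchsorted(
            spec.thresholds[i], X[:, i], side="right"
        )
    if spec.mcar_rate > 0.0:
        mask = rng.random((spec.n, p)) < spec.mcar_rate
        values[mask] = np.nan
    for i in range(p):
        col = values[:, i]
        col = col[~np.isnan(col)]
        if col.size and np.all(col == col[0]):
            warnings.warn(
                f"degenerate simulated item {spec.item_meta[i].code!r}: "
                "constant column",
                stacklevel=2,
            )
    return ResponseMatrix(values, spec.item_meta)


# ---------------------------------------------------------------------------
# Threshold calibration


def analytic_mean(thresholds: np.ndarray) -> float:
    """Expected ordinal score (0-based) of a standard-normal latent."""
    return float(np.sum(1.0 - norm.cdf(thresholds)))


def thresholds_for_target(
    mean: float, sd: float, n_categories: int
) -> np.ndarray:
    """Thresholds whose discretized standard normal has the target mean.

    Base cut-points place category k at ``(k - 0.5 - mean) / sd`` (a rounded
    normal with the target moments); a common location shift is then solved
    so the analytic ordinal mean matches ``mean`` exactly.
    """
    if n_categories < 2:
        raise ValueError("need >= 2 categories")
    if not 0 < mean < n_categories - 1:
        raise ValueError("target mean must lie inside the score range")
    base = (np.arange(1, n_categories) - 0.5 - mean) / sd

    def gap(delta: float) -> float:
        return analytic_mean(base + delta) - mean

    delta = brentq(gap, -8.0, 8.0, xtol=1e-12)
    return base + delta


# ---------------------------------------------------------------------------
# Ready-made specifications


def _factor_corr_matrix(k: int, rho) -> np.ndarray:
    Phi = np.asarray(rho, dtype=float)
    if Phi.ndim == 0:
        Phi = np.full((k, k), float(rho))
        np.fill_diagonal(Phi, 1.0)
    return Phi


def community_spec(
    sizes: Sequence[int],
    n: int,
    seed: int,
    loading: float = 0.65,
    factor_corr: float | np.ndarray = 0.3,
    cross_loading: float = 0.0,
    n_categories: int = 5,
    mean: float = 1.0,
    sd: float = 1.0,
) -> SynthSpec:
    """Simple-structure spec: one factor per community, equal loadings.

    ``cross_loading`` (if nonzero) adds a secondary loading of each item of
    community c on factor c+1 (cyclically), producing mildly overlapping
    communities.  All items share the same marginal target moments.
    """
    sizes = tuple(int(s) for s in sizes)
    k = len(sizes)
    p = sum(sizes)
    membership = np.repeat(np.arange(k), sizes)
    L = np.zeros((p, k))
    for i, c in enumerate(membership):
        L[i, c] = loading
        if cross_loading and k > 1:
            L[i, (c + 1) % k] = cross_loading
    Phi = _factor_corr_matrix(k, factor_corr)
    thr = thresholds_for_target(mean, sd, n_categories)
    meta = tuple(
        ItemMeta(f"item{i + 1:02d}", Scale.COMPOSITE, 0, n_categories - 1)
        for i in range(p)
    )
    return SynthSpec(
        loadings=L,
        factor_corr=Phi,
        thresholds=tuple(thr.copy() for _ in range(p)),
        item_meta=meta,
        n=n,
        seed=seed,
        membership=membership,
    )


_STUDY_SIZES = (7, 5, 3, 7)
_PRIMARY_LOADING = 0.65
_CROSS_LOADING = 0.10  # between the hope/meaning and entrapment communities
_RHO_DEMORAL = 0.45  # among communities 1-3
_RHO_DEPRESS = 0.30  # between each of 1-3 and community 4


def _study_phi() -> np.ndarray:
    Phi = np.eye(4)
    Phi[:3, :3] = _RHO_DEMORAL
    np.fill_diagonal(Phi, 1.0)
    Phi[3, :3] = Phi[:3, 3] = _RHO_DEPRESS
    return Phi


def _study_loadings(
    codes: Sequence[str], membership: np.ndarray
) -> np.ndarray:
    p = len(codes)
    L = np.zeros((p, 4))
    for i, c in enumerate(membership):
        L[i, c] = _PRIMARY_LOADING
        if c == 0:
            L[i, 2] = _CROSS_LOADING
        elif c == 2:
            L[i, 0] = _CROSS_LOADING
    return L


def _node_meta(code: str) -> ItemMeta:
    composite_codes = {s.new_code for s in STUDY_COMPOSITES}
    if code in composite_codes:
        return ItemMeta(code, Scale.COMPOSITE, 0, 4, False, "latent composite")
    raw = next(m for m in DS2_PHQ9_ITEMS if m.code == code)
    # generated items are already in scored orientation
    return ItemMeta(raw.code, raw.scale, raw.min_score, raw.max_score, False, raw.label)


def default_study_spec(n: int, seed: int) -> SynthSpec:
    """The 22-node, four-community study stand-in.

    Items are grouped by community (sizes 7/5/3/7); thresholds are
    calibrated so each item's analytic mean equals its reference moment.
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    codes = [c for items in STUDY_COMMUNITIES.values() for c in items]
    membership = np.repeat(np.arange(4), _STUDY_SIZES)
    meta = tuple(_node_meta(c) for c in codes)
    thresholds = tuple(
        thresholds_for_target(*NODE_MOMENTS[c], m.n_categories)
        for c, m in zip(codes, meta)
    )
    return SynthSpec(
        loadings=_study_loadings(codes, membership),
        factor_corr=_study_phi(),
        thresholds=thresholds,
        item_meta=meta,
        n=n,
        seed=seed,
        membership=membership,
    )


def default_raw_study_spec(
    n: int,
    seed: int,
    extra_shared_variance: float = 0.5,
) -> SynthSpec:
    """The 25-raw-item stand-in with three injected redundant pairs.

    Each member of a merged composite (helplessness, worthlessness,
    death/suicide ideation) loads like its composite node and additionally
    shares ``extra_shared_variance`` of its unique variance with its partner,
    so redundancy detection has ground truth; merging the pairs reduces the
    25 items back to 22 nodes.  Items are emitted in instrument order, in
    scored orientation (no reverse-coded columns).
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    node_of = {}
    for s in STUDY_COMPOSITES:
        for m in s.member_codes:
            node_of[m] = s.new_code
    comm_of_node = {
        c: k
        for k, items in enumerate(STUDY_COMMUNITIES.values())
        for c in items
    }
    meta = tuple(
        ItemMeta(m.code, m.scale, m.min_score, m.max_score, False, m.label)
        for m in DS2_PHQ9_ITEMS
    )
    codes = [m.code for m in meta]
    membership = np.array(
        [comm_of_node[node_of.get(c, c)] for c in codes], dtype=int
    )
    thresholds = tuple(
        thresholds_for_target(*REFERENCE_MOMENTS[c], m.n_categories)
        for c, m in zip(codes, meta)
    )
    pairs = tuple(
        (codes.index(s.member_codes[0]), codes.index(s.member_codes[1]),
         float(extra_shared_variance))
        for s in STUDY_COMPOSITES
    )
    return SynthSpec(
        loadings=_study_loadings(codes, membership),
        factor_corr=_study_phi(),
        thresholds=thresholds,
        item_meta=meta,
        n=n,
        seed=seed,
        redundant_pairs=pairs,
        membership=membership,
    )
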