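"""Node centrality and its robustness to dropping cases or nodes.

Node strength - the sum of absolute partial correlations incident to a node
- is the centrality index used throughout.  Community loadings generalise
it: the raw loading of node i on community c sums i's absolute edges into c
(with the sign of the dominant edge restored), and each column is scaled by
the square root of the summed absolute raw loadings of the community's own
members, which puts them on a factor-loading-like scale.

Stability is assessed by case-dropping (subsample without replacement,
re-estimate, correlate node strengths with the full-sample values) and
node-dropping (remove a random node subset, re-estimate on the remainder).
The CS coefficient is the largest drop fraction at which at least 95% of
subsamples still correlate >= 0.7 with the full-sample strengths.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .data import ResponseMatrix
from .ega import EGAConfig, Partition, ega
from .glasso import Network

__all__ = [
    "CentralityResult",
    "StabilityCurve",
    "node_strength",
    "node_loadings",
    "centrality",
    "case_drop_stability",
    "node_drop_stability",
]

logger = logging.getLogger(__name__)

DEFAULT_DROP_FRACTIONS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)


@dataclass
class CentralityResult:
    strength: pd.Series
    loadings: pd.DataFrame


@dataclass
class StabilityCurve:
    """Distribution of strength correlations per drop fraction."""

    drop_fractions: np.ndarray
    mean_corr: np.ndarray
    q025: np.ndarray
    q975: np.ndarray
    prop_above: np.ndarray  # P(correlation >= corr_threshold) per fraction
    cs_coefficient: float
    corr_threshold: float = 0.7
    certainty: float = 0.95

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drop_fraction": self.drop_fractions,
                "mean_corr": self.mean_corr,
                "q025": self.q025,
                "q975": self.q975,
                "prop_above_threshold": self.prop_above,
            }
        )


def node_strength(network: Network) -> pd.Series:
    """s_i = sum_j |p_ij| per node."""
    s = np.abs(network.weights).sum(axis=1)
    return pd.Series(s, index=list(network.node_codes), name="strength")


def node_loadings(network: Network, partition: Partition) -> pd.DataFrame:
    """Standardised loadings of each node on each community."""
    codes = list(network.node_codes)
    membership = partition.membership(network.node_codes)
    K = partition.n_communities
    W = network.weights
    raw = np.zeros((len(codes), K))
    for c in range(1, K + 1):
        members = membership == c
        if not members.any():
            raise ValueError(f"community {c} has no members")
        for i in range(len(codes)):
            block = W[i, members & (np.arange(len(codes)) != i)]
            mag = np.abs(block).sum()
            sign = 1.0 if block.sum() >= 0 else -1.0
            raw[i, c - 1] = sign * mag
    std = raw.copy()
    for c in range(1, K + 1):
        members = membership == c
        denom = np.sqrt(np.abs(raw[members, c - 1]).sum())
        if denom > 0:
            std[:, c - 1] = raw[:, c - 1] / denom
    return pd.DataFrame(std, index=codes, columns=[str(c) for c in range(1, K + 1)])


def centrality(network: Network, partition: Partition) -> CentralityResult:
    """Node strengths together with standardised community loadings."""
    return CentralityResult(
        strength=node_strength(network),
        loadings=node_loadings(network, partition),
    )


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    if method == "pearson":
        return float(pearsonr(x, y)[0])
    if method == "spearman":
        return float(spearmanr(x, y)[0])
    raise ValueError(f"unknown correlation method {method!r}")


def _summarise(
    fractions: list[float],
    corrs_per_fraction: list[np.ndarray],
    corr_threshold: float,
    certainty: float,
) -> StabilityCurve:
    mean_corr, q025, q975, prop = [], [], [], []
    for cs in corrs_per_fraction:
        cs = cs[~np.isnan(cs)]
        mean_corr.append(cs.mean() if cs.size else float("nan"))
        q025.append(np.percentile(cs, 2.5) if cs.size else float("nan"))
        q975.append(np.percentile(cs, 97.5) if cs.size else float("nan"))
        prop.append(
            float((cs >= corr_threshold).mean()) if cs.size else float("nan")
        )
    cs_coef = 0.0
    for f, pr in zip(fractions, prop):
        if not np.isnan(pr) and pr >= certainty and f > cs_coef:
            cs_coef = f
    return StabilityCurve(
        drop_fractions=np.asarray(fractions),
        mean_corr=np.asarray(mean_corr),
        q025=np.asarray(q025),
        q975=np.asarray(q975),
        prop_above=np.asarray(prop),
        cs_coefficient=cs_coef,
        corr_threshold=corr_threshold,
        certainty=certainty,
    )


def case_drop_stability(
    m: ResponseMatrix,
    n_iter: int = 2500,
    drop_fractions: Sequence[float] = DEFAULT_DROP_FRACTIONS,
    seed: int = 0,
    config: Optional[EGAConfig] = None,
    corr_method: str = "pearson",
    corr_threshold: float = 0.7,
    certainty: float = 0.95,
) -> StabilityCurve:
    """Case-dropping stability of node strength.

    ``n_iter`` subsamples per drop fraction, each retaining (1-f)*n rows
    drawn without replacement.  At f = 0 the subsample is the full sample,
    so the correlation is exactly 1 and is recorded without re-estimation.
    Fractions leaving fewer than 10 rows per node are skipped with a warning.
    """
    fractions = [float(f) for f in drop_fractions]
    if any(f < 0 or f >= 1 for f in fractions):
        raise ValueError("drop fractions must lie in [0, 1)")
    cfg = config or EGAConfig()
    full = ega(m, cfg, compute_layout=False)
    s_full = node_strength(full.network).to_numpy()
    n, p = m.n_subjects, m.n_items

    kept_fractions, corrs_all = [], []
    for fi, f in enumerate(fractions):
        if f == 0.0:
            kept_fractions.append(f)
            corrs_all.append(np.ones(n_iter))
            continue
        n_keep = int(round((1.0 - f) * n))
        if n_keep < 10 * p:
            warnings.warn(
                f"drop fraction {f:g} leaves {n_keep} rows (< 10 per node); "
                "skipped"
            )
            continue
        corrs = np.full(n_iter, np.nan)
        for it in range(n_iter):
            rng = np.random.default_rng((seed + 100_003 * fi + it) % 2**31)
            idx = rng.choice(n, size=n_keep, replace=False)
            sub = ResponseMatrix(m.values[idx], m.item_meta)
            try:
                res = ega(sub, cfg, compute_layout=False)
            except Exception as e:  # noqa: BLE001
                logger.warning("case-drop iteration failed at f=%g: %s", f, e)
                continue
            corrs[it] = _corr(
                node_strength(res.network).to_numpy(), s_full, corr_method
            )
        kept_fractions.append(f)
        corrs_all.append(corrs)
    return _summarise(kept_fractions, corrs_all, corr_threshold, certainty)


def node_drop_stability(
    m: ResponseMatrix,
    n_iter: int = 2500,
    drop_fractions: Sequence[float] = DEFAULT_DROP_FRACTIONS,
    seed: int = 0,
    config: Optional[EGAConfig] = None,
    corr_method: str = "pearson",
    corr_threshold: float = 0.7,
    certainty: float = 0.95,
) -> StabilityCurve:
    """Node-dropping stability: re-estimate on random node subsets.

    Retained nodes' strengths are correlated with their full-network values.
    Fractions leaving fewer than 3 nodes are skipped.
    """
    fractions = [float(f) for f in drop_fractions]
    if any(f < 0 or f >= 1 for f in fractions):
        raise ValueError("drop fractions must lie in [0, 1)")
    cfg = config or EGAConfig()
    full = ega(m, cfg, compute_layout=False)
    s_full = pd.Series(
        node_strength(full.network).to_numpy(), index=list(m.codes)
    )
    p = m.n_items

    kept_fractions, corrs_all = [], []
    for fi, f in enumerate(fractions):
        if f == 0.0:
            kept_fractions.append(f)
            corrs_all.append(np.ones(n_iter))
            continue
        p_keep = int(round((1.0 - f) * p))
        if p_keep < 3:
            warnings.warn(
                f"drop fraction {f:g} leaves {p_keep} nodes (< 3); skipped"
            )
            continue
        corrs = np.full(n_iter, np.nan)
        for it in range(n_iter):
            rng = np.random.default_rng((seed + 100_003 * fi + it) % 2**31)
            keep = np.sort(rng.choice(p, size=p_keep, replace=False))
            sub = ResponseMatrix(
                m.values[:, keep], tuple(m.item_meta[j] for j in keep)
            )
            try:
                res = ega(sub, cfg, compute_layout=False)
            except Exception as e:  # noqa: BLE001
                logger.warning("node-drop iteration failed at f=%g: %s", f, e)
                continue
            s_sub = node_strength(res.network)
            corrs[it] = _corr(
                s_sub.to_numpy(),
                s_full.loc[s_sub.index].to_numpy(),
                corr_method,
            )
        kept_fractions.append(f)
        corrs_all.append(corrs)
    return _summarise(kept_fractions, corrs_all, corr_threshold, certainty)
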