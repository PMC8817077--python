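"""Item redundancy: weighted topological overlap, flagging, and merging.

Two items that measure the same thing contribute no unique information and
inflate the apparent dimensionality of a network, so redundancy is assessed
before network estimation.  The weighted topological overlap (wTO) of nodes
i and j compares their connection profiles on the absolute partial
correlations a_uv:

    wto_ij = (sum_{u != i,j} a_iu * a_ju + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with connectivity k_i = sum_u a_iu.  High-overlap pairs are flagged by a
quantile or mean+SD rule; whether flagged items truly measure the same
construct is a conceptual judgement, so merging is an explicit user step via
``CompositeSpec`` lists.  Merged items are replaced by a single composite
column: either a one-factor latent score (Thurstone regression method,
standardised) or the mean of the standardised members.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data import (
    CombineMethod,
    CompositeSpec,
    ItemMeta,
    ResponseMatrix,
    Scale,
)
from .glasso import Network
from .reliability import one_factor_fit

__all__ = [
    "RedundancyReport",
    "weighted_topological_overlap",
    "detect_redundant",
    "redundancy_report",
    "combine_items",
]


@dataclass
class RedundancyReport:
    wto: np.ndarray
    node_codes: tuple[str, ...]
    flagged_pairs: list[tuple[str, str, float]]  # sorted by descending wTO
    applied_composites: tuple[CompositeSpec, ...] = ()


def weighted_topological_overlap(network: Network) -> np.ndarray:
    """p x p wTO matrix of the network (diagonal set to 0, ignored)."""
    A = np.abs(network.weights)
    k = A.sum(axis=1)
    shared = A @ A  # (A@A)_ij = sum_u a_iu a_uj, includes u in {i, j}
    p = A.shape[0]
    wto = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            num = shared[i, j] - A[i, i] * A[i, j] - A[i, j] * A[j, j] + A[i, j]
            den = min(k[i], k[j]) + 1.0 - A[i, j]
            wto[i, j] = num / den
    return wto


def detect_redundant(
    wto: np.ndarray,
    node_codes: Sequence[str],
    method: str = "quantile",
    threshold: Optional[float] = None,
) -> list[tuple[str, str, float]]:
    """Flag high-overlap pairs.

    ``method="quantile"`` flags pairs strictly above the given upper
    quantile (default 0.95) of all off-diagonal wTO values;
    ``method="sd"`` flags pairs above mean + threshold * SD (default 2).
    Returns (code_i, code_j, wto) sorted by descending overlap.
    """
    wto = np.asarray(wto, dtype=float)
    p = wto.shape[0]
    iu, ju = np.triu_indices(p, k=1)
    vals = wto[iu, ju]
    if method == "quantile":
        q = 0.95 if threshold is None else float(threshold)
        cut = np.quantile(vals, q)
    elif method == "sd":
        t = 2.0 if threshold is None else float(threshold)
        cut = vals.mean() + t * vals.std(ddof=1)
    else:
        raise ValueError(f"unknown redundancy method {method!r}")
    flagged = [
        (node_codes[i], node_codes[j], float(wto[i, j]))
        for i, j in zip(iu, ju)
        if wto[i, j] > cut
    ]
    flagged.sort(key=lambda t: -t[2])
    return flagged


def redundancy_report(
    network: Network,
    method: str = "quantile",
    threshold: Optional[float] = None,
    applied_composites: Sequence[CompositeSpec] = (),
) -> RedundancyReport:
    """Compute the wTO matrix and flag high-overlap pairs in one step."""
    wto = weighted_topological_overlap(network)
    flagged = detect_redundant(wto, network.node_codes, method, threshold)
    return RedundancyReport(
        wto=wto,
        node_codes=network.node_codes,
        flagged_pairs=flagged,
        applied_composites=tuple(applied_composites),
    )


def _standardise(col: np.ndarray) -> np.ndarray:
    sd = col.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance member item")
    return (col - col.mean()) / sd


def _latent_score(X: np.ndarray) -> np.ndarray:
    """Thurstone regression factor scores of a one-factor fit, standardised.

    A one-factor model is not identified for two items, so the two-item
    case uses the symmetric (tau-equivalent) solution lambda = sqrt(r),
    which makes the score proportional to the members' mean.
    """
    Z = np.column_stack([_standardise(X[:, j]) for j in range(X.shape[1])])
    R = np.corrcoef(Z, rowvar=False)
    if X.shape[1] == 2:
        r = R[0, 1]
        if r <= 0:
            raise ValueError(
                "two-item composite requires positively correlated members"
            )
        loadings = np.array([np.sqrt(r), np.sqrt(r)])
    else:
        loadings, _ = one_factor_fit(X)
    scores = Z @ np.linalg.solve(R, loadings)
    return _standardise(scores)


def combine_items(
    m: ResponseMatrix, specs: Sequence[CompositeSpec]
) -> ResponseMatrix:
    """Replace each spec's member items by one composite column.

    Member columns are removed; composites are appended (scale COMPOSITE,
    continuous).  Output item count is p - sum(members - 1).
    """
    specs = tuple(specs)
    all_members = [c for s in specs for c in s.member_codes]
    if len(set(all_members)) != len(all_members):
        raise ValueError("composite specs share member items")
    codes = m.codes
    for s in specs:
        for c in s.member_codes:
            if c not in codes:
                raise ValueError(f"composite member {c!r} not in matrix")
    if np.isnan(m.values).any():
        raise ValueError("missing values present; apply complete_cases first")

    member_set = set(all_members)
    keep_idx = [j for j, c in enumerate(codes) if c not in member_set]
    new_values = [m.values[:, keep_idx]]
    new_meta = [m.item_meta[j] for j in keep_idx]
    for s in specs:
        idx = [codes.index(c) for c in s.member_codes]
        X = m.values[:, idx]
        if s.method is CombineMethod.LATENT_SCORE:
            col = _latent_score(X)
        else:
            col = np.mean(
                [_standardise(X[:, j]) for j in range(X.shape[1])], axis=0
            )
        new_values.append(col[:, None])
        new_meta.append(
            ItemMeta(
                code=s.new_code,
                scale=Scale.COMPOSITE,
                min_score=None,
                max_score=None,
                label=f"composite of {', '.join(s.member_codes)}",
            )
        )
    return ResponseMatrix(
        np.hstack(new_values), tuple(new_meta), subject_ids=m.subject_ids
    )
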