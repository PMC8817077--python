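"""Bootstrap replication of the network: community-count distribution,
median network, structural consistency and item stability.

Each replicate resamples subjects with replacement and reruns the full
estimation (correlation -> EBIC graphical lasso -> walktrap).  Replicate
communities are matched to the original partition by solving the assignment
problem on the contingency table of shared items; replicate communities left
unmatched (a split-off fragment, or a surplus community when a replicate
finds more than the original) count towards an "extra" column.

Derived metrics:

* item stability - the proportion of replicates in which each item lands in
  each (aligned) original community;
* structural consistency - the proportion of replicates in which the
  replicate community aligned to an original community has exactly that
  community's item set.  By construction it can never exceed the smallest
  item stability of the community's members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .data import ResponseMatrix
from .ega import EGAConfig, Partition, ega
from .glasso import Network

__all__ = [
    "NEW_COMMUNITY",
    "BootResult",
    "align_communities",
    "item_stability",
    "structural_consistency",
    "boot_ega",
]

logger = logging.getLogger(__name__)

#: Sentinel id for replicate communities with no matching original community.
NEW_COMMUNITY = -1

_EXTRA_COLUMN = "extra"


@dataclass
class BootResult:
    n_iter: int
    n_failed: int
    replicate_k: np.ndarray
    k_median: float
    k_ci_normal: tuple[float, float]  # mean +/- 1.96 SD
    k_ci_percentile: tuple[float, float]  # 2.5 / 97.5 percentiles
    median_network: Network
    item_stability: pd.DataFrame  # items x (communities 1..K + "extra")
    structural_consistency: dict[int, float]

    def __post_init__(self) -> None:
        sums = self.item_stability.sum(axis=1).to_numpy()
        if np.any(sums > 1.0 + 1e-9):
            raise ValueError("item stability rows must sum to <= 1")
        for c, v in self.structural_consistency.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"structural consistency of {c} outside [0,1]")
        own = {
            c: float(
                self.item_stability.loc[list(items), str(c)].min()
            )
            for c, items in self._original_items.items()
        }
        for c, v in self.structural_consistency.items():
            if v > own[c] + 1e-9:
                raise AssertionError(
                    "structural consistency exceeds minimum item stability"
                )

    _original_items: dict[int, frozenset[str]] = field(default_factory=dict)


def align_communities(
    original: Partition, replicate: Partition
) -> dict[int, int]:
    """Map replicate community ids to original ids (or ``NEW_COMMUNITY``).

    The mapping maximises the total number of shared items, solved as an
    assignment problem on the K_orig x K_rep contingency table.
    """
    orig_set = set(original.assignment)
    if set(replicate.assignment) != orig_set:
        raise ValueError("partitions cover different node sets")
    k_o, k_r = original.n_communities, replicate.n_communities
    table = np.zeros((k_o, k_r))
    for code, c_rep in replicate.assignment.items():
        table[original.assignment[code] - 1, c_rep - 1] += 1
    rows, cols = linear_sum_assignment(-table)
    mapping = {c: NEW_COMMUNITY for c in range(1, k_r + 1)}
    for r, c in zip(rows, cols):
        if table[r, c] > 0:
            mapping[c + 1] = r + 1
    return mapping


def item_stability(
    replicates: Sequence[Partition], original: Partition
) -> pd.DataFrame:
    """Items x (original communities + extra) proportion table."""
    codes = list(original.assignment)
    k = original.n_communities
    cols = [str(c) for c in range(1, k + 1)] + [_EXTRA_COLUMN]
    counts = pd.DataFrame(0.0, index=codes, columns=cols)
    for rep in replicates:
        mapping = align_communities(original, rep)
        for code in codes:
            target = mapping[rep.assignment[code]]
            col = _EXTRA_COLUMN if target == NEW_COMMUNITY else str(target)
            counts.loc[code, col] += 1.0
    return counts / max(len(replicates), 1)


def structural_consistency(
    replicates: Sequence[Partition], original: Partition
) -> dict[int, float]:
    """Proportion of replicates reproducing each community's exact item set."""
    k = original.n_communities
    orig_items = {c: original.items_in(c) for c in range(1, k + 1)}
    hits = {c: 0 for c in range(1, k + 1)}
    for rep in replicates:
        mapping = align_communities(original, rep)
        inverse = {v: c for c, v in mapping.items() if v != NEW_COMMUNITY}
        for c in range(1, k + 1):
            if c in inverse and rep.items_in(inverse[c]) == orig_items[c]:
                hits[c] += 1
    n = max(len(replicates), 1)
    return {c: hits[c] / n for c in hits}


def boot_ega(
    m: ResponseMatrix,
    n_iter: int,
    seed: int,
    config: Optional[EGAConfig] = None,
    original: Optional[Partition] = None,
) -> BootResult:
    """Non-parametric bootstrap of the EGA pipeline.

    Per-iteration seeds derive deterministically from the master seed, so
    results do not depend on execution order.  Failed iterations are logged
    and excluded; more than 20% failures is fatal.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    cfg = config or EGAConfig()
    if original is None:
        original = ega(m, cfg, compute_layout=False).partition
    n = m.n_subjects
    partitions: list[Partition] = []
    weight_stack: list[np.ndarray] = []
    n_failed = 0
    for it in range(n_iter):
        rng = np.random.default_rng((seed + it) % 2**31)
        idx = rng.integers(0, n, size=n)
        boot_m = ResponseMatrix(m.values[idx], m.item_meta)
        try:
            res = ega(boot_m, cfg, compute_layout=False)
        except Exception as e:  # noqa: BLE001 - any stage may fail on a resample
            n_failed += 1
            logger.warning("bootstrap iteration %d failed: %s", it, e)
            continue
        partitions.append(res.partition)
        weight_stack.append(res.network.weights)
    if n_failed > 0.2 * n_iter:
        raise RuntimeError(
            f"{n_failed}/{n_iter} bootstrap iterations failed"
        )

    ks = np.array([p.n_communities for p in partitions], dtype=float)
    mean, sd = ks.mean(), ks.std(ddof=1)
    lo_p, hi_p = np.percentile(ks, [2.5, 97.5])
    median_net = Network(
        weights=np.median(np.stack(weight_stack), axis=0),
        precision=None,
        lambda_=float("nan"),
        node_codes=m.codes,
    )
    stab = item_stability(partitions, original)
    consistency = structural_consistency(partitions, original)
    return BootResult(
        n_iter=n_iter,
        n_failed=n_failed,
        replicate_k=ks.astype(int),
        k_median=float(np.median(ks)),
        k_ci_normal=(float(mean - 1.96 * sd), float(mean + 1.96 * sd)),
        k_ci_percentile=(float(lo_p), float(hi_p)),
        median_network=median_net,
        item_stability=stab,
        structural_consistency=consistency,
        _original_items={
            c: original.items_in(c)
            for c in range(1, original.n_communities + 1)
        },
    )
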