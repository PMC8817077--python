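"""End-to-end analysis pipeline and report bundle.

Stage order follows the standard workflow: complete-case filter ->
reverse scoring -> reliability -> redundancy reduction -> network estimation
with community detection -> bootstrap replication -> centrality and
(optionally) case-/node-dropping stability.  Every numeric output is a
deterministic function of the manifest (inputs, configuration, seeds):
rerunning with the same manifest reproduces each JSON/CSV byte for byte.
Logs and timings go to stderr and are never mixed with machine outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bootstrap import boot_ega
from .centrality import (
    DEFAULT_DROP_FRACTIONS,
    case_drop_stability,
    centrality,
    node_drop_stability,
)
from .data import (
    CompositeSpec,
    ResponseMatrix,
    complete_cases,
    load_item_meta,
    load_responses,
    reverse_score,
)
from .ega import EGAConfig, EGAResult, ega
from .glasso import correlation, ebic_glasso
from .instruments import STUDY_COMPOSITES, study_item_meta
from .redundancy import combine_items, redundancy_report

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Full configuration of a pipeline run (YAML-serialisable)."""

    input_csv: str
    out_dir: str
    meta: str = "study"  # "study" or a path to a metadata sidecar
    corr_method: str = "pearson"
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.1
    walktrap_steps: int = 4
    redundancy_method: str = "quantile"
    redundancy_threshold: Optional[float] = None
    composites: str | Sequence[CompositeSpec] = "study"
    boot_iters: int = 10_000
    boot_seed: int = 1
    stability_iters: int = 2500
    drop_fractions: tuple[float, ...] = DEFAULT_DROP_FRACTIONS
    stability_seed: int = 2
    layout_seed: int = 0
    run_stability: bool = True
    make_plots: bool = False

    def __post_init__(self) -> None:
        self.drop_fractions = tuple(float(f) for f in self.drop_fractions)
        if any(f < 0 or f > 0.9 for f in self.drop_fractions):
            raise ValueError("drop fractions must lie in [0, 0.9]")
        for name in ("boot_seed", "stability_seed", "layout_seed"):
            if not isinstance(getattr(self, name), int):
                raise ValueError(f"{name} must be an integer")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if isinstance(raw.get("composites"), list):
            raw["composites"] = tuple(
                CompositeSpec(
                    c["new_code"], tuple(c["member_codes"]), c.get("method", "LATENT_SCORE")
                )
                for c in raw["composites"]
            )
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if not isinstance(self.composites, str):
            d["composites"] = [
                {
                    "new_code": c.new_code,
                    "member_codes": list(c.member_codes),
                    "method": c.method.value,
                }
                for c in self.composites
            ]
        d["drop_fractions"] = list(self.drop_fractions)
        return d

    def ega_config(self) -> EGAConfig:
        return EGAConfig(
            corr_method=self.corr_method,
            gamma=self.gamma,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            steps=self.walktrap_steps,
            layout_seed=self.layout_seed,
        )


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _write_graphml(result: EGAResult, path: Path) -> None:
    import networkx as nx

    G = nx.Graph()
    for i, code in enumerate(result.network.node_codes):
        G.add_node(
            code,
            community=int(result.partition.assignment[code]),
            x=float(result.layout[i, 0]) if result.layout is not None else 0.0,
            y=float(result.layout[i, 1]) if result.layout is not None else 0.0,
        )
    for _, row in result.network.edge_list().iterrows():
        G.add_edge(
            row["node_i"], row["node_j"], weight=float(row["partial_correlation"])
        )
    nx.write_graphml(G, path)


def _descriptives(m: ResponseMatrix) -> pd.DataFrame:
    df = m.to_frame()
    return pd.DataFrame(
        {
            "item": df.columns,
            "mean": df.mean().to_numpy(),
            "sd": df.std(ddof=1).to_numpy(),
        }
    )


def _plot_network(result: EGAResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xy = result.layout
    W = result.network.weights
    fig, ax = plt.subplots(figsize=(7, 7))
    p = result.network.p
    for i in range(p):
        for j in range(i + 1, p):
            if W[i, j] != 0:
                ax.plot(
                    [xy[i, 0], xy[j, 0]],
                    [xy[i, 1], xy[j, 1]],
                    color="green" if W[i, j] > 0 else "red",
                    lw=6 * abs(W[i, j]),
                    alpha=0.6,
                    zorder=1,
                )
    membership = result.partition.membership(result.network.node_codes)
    ax.scatter(
        xy[:, 0], xy[:, 1], c=membership, cmap="tab10", s=420, zorder=2,
        edgecolors="black",
    )
    for i, code in enumerate(result.network.node_codes):
        ax.annotate(code, xy[i], ha="center", va="center", fontsize=5, zorder=3)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def _plot_centrality(strength: pd.Series, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = strength.sort_values()
    fig, ax = plt.subplots(figsize=(5, 7))
    ax.barh(s.index, s.to_numpy(), color="steelblue")
    ax.set_xlabel("node strength")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write the report bundle to ``config.out_dir``.

    Returns a dict of in-memory stage results keyed by stage name.
    """
    input_path = Path(config.input_csv)
    if not input_path.exists():
        raise FileNotFoundError(f"input CSV not found: {input_path}")
    if config.meta != "study" and not Path(config.meta).exists():
        raise FileNotFoundError(f"metadata file not found: {config.meta}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage %s ...", name)
        return time.perf_counter()

    def done(name, t0):
        logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)

    meta = (
        study_item_meta() if config.meta == "study" else load_item_meta(config.meta)
    )

    t0 = stage("load")
    raw = load_responses(input_path, meta)
    filtered, n_removed = complete_cases(raw)
    scored = reverse_score(filtered)
    _descriptives(scored).to_csv(out / "descriptives.csv", index=False)
    done("load", t0)
    logger.info(
        "%d subjects retained (%d removed as incomplete), %d items",
        scored.n_subjects, n_removed, scored.n_items,
    )

    t0 = stage("reliability")
    from .reliability import mcdonald_omega

    rel = mcdonald_omega(scored, n_boot=0)
    reliability_block = {
        "alpha": rel.alpha,
        "omega": rel.omega,
        "omega_ci": rel.omega_ci,
        "n_boot": rel.n_boot,
    }
    _dump_json({"reliability": reliability_block}, out / "reliability.json")
    done("reliability", t0)

    t0 = stage("redundancy")
    cfg = config.ega_config()
    raw_net = ebic_glasso(
        correlation(scored, cfg.corr_method),
        gamma=cfg.gamma,
        n_lambda=cfg.n_lambda,
        lambda_min_ratio=cfg.lambda_min_ratio,
    )
    composites = (
        STUDY_COMPOSITES if config.composites == "study" else tuple(config.composites)
    )
    applicable = tuple(
        s for s in composites if all(c in scored.codes for c in s.member_codes)
    )
    report = redundancy_report(
        raw_net,
        method=config.redundancy_method,
        threshold=config.redundancy_threshold,
        applied_composites=applicable,
    )
    flagged = report.flagged_pairs
    pd.DataFrame(flagged, columns=["item_i", "item_j", "wto"]).to_csv(
        out / "redundancy_flagged.csv", index=False
    )
    reduced = combine_items(scored, applicable) if applicable else scored
    done("redundancy", t0)
    logger.info(
        "%d pairs flagged; %d composites applied; %d -> %d nodes",
        len(flagged), len(applicable), scored.n_items, reduced.n_items,
    )

    t0 = stage("ega")
    result = ega(reduced, cfg)
    result.network.edge_list().to_csv(out / "network_edges.csv", index=False)
    result.network.path.to_csv(out / "lambda_path.csv", index=False)
    _write_graphml(result, out / "network.graphml")
    _dump_json(
        {
            "assignment": result.partition.assignment,
            "n_communities": result.partition.n_communities,
            "modularity": result.partition.modularity,
            "lambda": result.network.lambda_,
            "n_edges": result.network.n_edges,
        },
        out / "partition.json",
    )
    done("ega", t0)
    logger.info("%d communities found", result.partition.n_communities)

    t0 = stage("bootstrap")
    boot = boot_ega(
        reduced, config.boot_iters, config.boot_seed, cfg,
        original=result.partition,
    )
    boot.item_stability.rename_axis("item").to_csv(out / "item_stability.csv")
    _dump_json(
        {
            "k_median": boot.k_median,
            "k_ci_normal": list(boot.k_ci_normal),
            "k_ci_percentile": list(boot.k_ci_percentile),
            "replicate_k_counts": {
                str(k): int(c)
                for k, c in zip(*np.unique(boot.replicate_k, return_counts=True))
            },
            "structural_consistency": {
                str(c): v for c, v in boot.structural_consistency.items()
            },
            "n_failed": boot.n_failed,
        },
        out / "bootstrap.json",
    )
    boot.median_network.edge_list().to_csv(out / "median_network_edges.csv", index=False)
    done("bootstrap", t0)

    t0 = stage("centrality")
    cent = centrality(result.network, result.partition)
    strength, loadings = cent.strength, cent.loadings
    strength.rename_axis("item").to_csv(out / "centrality.csv")
    loadings.rename_axis("item").to_csv(out / "loadings.csv")
    done("centrality", t0)

    curves = {}
    if config.run_stability:
        t0 = stage("stability")
        for mode, fn in (("cases", case_drop_stability), ("nodes", node_drop_stability)):
            curve = fn(
                reduced,
                n_iter=config.stability_iters,
                drop_fractions=config.drop_fractions,
                seed=config.stability_seed,
                config=cfg,
            )
            curve.to_frame().to_csv(out / f"stability_{mode}.csv", index=False)
            curves[mode] = curve
        _dump_json(
            {mode: curves[mode].cs_coefficient for mode in curves},
            out / "cs_coefficients.json",
        )
        done("stability", t0)

    if config.make_plots:
        t0 = stage("plots")
        _plot_network(result, out / "network.png")
        _plot_centrality(strength, out / "centrality.png")
        done("plots", t0)

    config_dict = config.to_dict()
    # the manifest describes the computation, not where this run put it
    config_dict.pop("out_dir", None)
    manifest = {
        "package": "symptomnet",
        "version": __version__,
        "input_sha256": hashlib.sha256(input_path.read_bytes()).hexdigest(),
        "config": config_dict,
        "n_subjects": scored.n_subjects,
        "n_removed_incomplete": n_removed,
        "n_raw_items": scored.n_items,
        "n_nodes": reduced.n_items,
    }
    _dump_json(manifest, out / "manifest.json")

    summary = {
        "reliability": reliability_block,
        "n_flagged_pairs": len(flagged),
        "n_nodes": reduced.n_items,
        "n_communities": result.partition.n_communities,
        "structural_consistency": {
            str(c): v for c, v in boot.structural_consistency.items()
        },
        "k_median": boot.k_median,
        "most_central": strength.sort_values(ascending=False).index[:5].tolist(),
        "cs_coefficients": {m: c.cs_coefficient for m, c in curves.items()},
    }
    _dump_json(summary, out / "summary.json")

    return {
        "responses": reduced,
        "reliability": rel,
        "flagged": flagged,
        "ega": result,
        "boot": boot,
        "strength": strength,
        "loadings": loadings,
        "stability": curves,
        "manifest": manifest,
    }
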