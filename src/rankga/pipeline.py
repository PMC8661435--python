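"""Config-driven pipeline: preprocess -> GA (whole data or per cluster) ->
optional lineage -> optional subsample consensus for large N.

The configuration is a YAML (or plain dict) of the form::

    seed: 7
    input:                 # either a file or a simulation block
      expression: counts.tsv
      clusters: labels.tsv     # optional
    # simulate: {n_cells: 300, n_genes: 100, dropout_scenario: 1}
    filter: {enabled: true, n_top: 2000}
    cluster: {enabled: false, k: auto}
    mode: order            # order | lineage | big
    ga: {pop_size: 100, min_generations: 30}
    big: {B: 30, M: 100, r: 5}
    root: null             # cluster id or cell id, lineage mode only
    output_dir: results/

All configuration problems are collected and reported together before the
run aborts.  Outputs: ``pseudotime.tsv``, optionally ``tree.tsv``, and a
``provenance.json`` recording the seed, config hash and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import fields as dc_fields
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .containers import ClusterAssignment, ExpressionMatrix
from .bigdata import pseudotime_large
from .evaluate import abs_spearman
from .ga import GAConfig, evolve
from .io import read_clusters, read_expression, write_pseudotime, write_tree
from .lineage import build_tree, order_all_clusters, root_tree
from .preprocess import cluster_cells, filter_genes
from .rank_cost import ordering_to_pseudotime, rank_transform
from .simulate import SimConfig, simulate_trajectory

__all__ = ["run_pipeline", "ConfigError", "load_config"]

logger = logging.getLogger(__name__)

_MODES = ("order", "lineage", "big")


class ConfigError(ValueError):
    """Raised with every configuration problem listed."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in problems))


def load_config(source) -> dict:
    if isinstance(source, dict):
        return source
    with open(source) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(["config file must contain a mapping"])
    return cfg


def _validate(cfg: dict) -> list[str]:
    problems = []
    if "input" not in cfg and "simulate" not in cfg:
        problems.append("one of 'input' or 'simulate' is required")
    if "input" in cfg and "simulate" in cfg:
        problems.append("'input' and 'simulate' are mutually exclusive")
    mode = cfg.get("mode", "order")
    if mode not in _MODES:
        problems.append(f"mode must be one of {_MODES} (got {mode!r})")
    if not isinstance(cfg.get("seed", 0), int):
        problems.append("seed must be an integer")
    ga_keys = {f.name for f in dc_fields(GAConfig)}
    for key in cfg.get("ga", {}) or {}:
        if key not in ga_keys:
            problems.append(f"unknown ga option {key!r}")
    sim_keys = {f.name for f in dc_fields(SimConfig)}
    for key in cfg.get("simulate", {}) or {}:
        if key not in sim_keys:
            problems.append(f"unknown simulate option {key!r}")
    for key in cfg.get("big", {}) or {}:
        if key not in ("B", "M", "r"):
            problems.append(f"unknown big option {key!r}")
    if "input" in cfg and "expression" not in (cfg["input"] or {}):
        problems.append("input.expression path is required")
    return problems


def run_pipeline(config, output_dir=None) -> dict:
    """Execute the pipeline; returns a dict of in-memory results."""
    cfg = load_config(config)
    problems = _validate(cfg)
    if problems:
        raise ConfigError(problems)

    seed = int(cfg.get("seed", 0))
    mode = cfg.get("mode", "order")
    out_dir = Path(output_dir or cfg.get("output_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)

    truth = None
    clusters = None
    if "simulate" in cfg:
        sim_cfg = SimConfig(**{**(cfg["simulate"] or {}), "seed": seed})
        truth = simulate_trajectory(sim_cfg)
        expr = truth.counts
        logger.info("simulated %d genes x %d cells", expr.n_genes, expr.n_cells)
    else:
        expr = read_expression(cfg["input"]["expression"], cfg["input"].get("format"))
        if cfg["input"].get("clusters"):
            clusters = read_clusters(cfg["input"]["clusters"], expr.cell_ids)

    cl_cfg = cfg.get("cluster", {}) or {}
    if clusters is None and (cl_cfg.get("enabled") or mode == "lineage"):
        k = cl_cfg.get("k", "auto")
        clusters = cluster_cells(expr, None if k in ("auto", None) else int(k), seed=seed)
        logger.info("clustered cells into k=%d groups", clusters.k)

    f_cfg = cfg.get("filter", {}) or {}
    if f_cfg.get("enabled"):
        n_top = min(int(f_cfg.get("n_top", 2000)), expr.n_genes)
        expr = filter_genes(expr, clusters, n_top)
        logger.info("kept %d genes after filtering", expr.n_genes)

    ga_config = GAConfig(**{**(cfg.get("ga", {}) or {}), "seed": seed})
    result: dict = {"expr": expr, "clusters": clusters, "truth": truth, "mode": mode}

    if mode == "order":
        res = evolve(rank_transform(expr), ga_config)
        ranks_pt = ordering_to_pseudotime(res.ordering)
        write_pseudotime(out_dir / "pseudotime.tsv", expr.cell_ids, ranks_pt,
                         cluster=clusters.labels if clusters else None)
        result.update(ordering=res.ordering, pseudotime=ranks_pt, ga=res)
    elif mode == "lineage":
        paths = order_all_clusters(expr, clusters, ga_config)
        tree = build_tree(paths, expr)
        if cfg.get("root") is not None:
            tree = root_tree(tree, cfg["root"])
        pt = np.zeros(expr.n_cells)
        for p in tree.paths.values():
            pt[p.cells] = np.arange(1, len(p) + 1)
        write_pseudotime(out_dir / "pseudotime.tsv", expr.cell_ids, pt, cluster=clusters.labels)
        write_tree(tree, out_dir / "tree.tsv")
        result.update(tree=tree, pseudotime=pt)
    else:  # big
        big = cfg.get("big", {}) or {}
        res = pseudotime_large(expr, B=int(big.get("B", 30)), M=int(big.get("M", 100)),
                               r=int(big.get("r", 5)), config=ga_config)
        pt = ordering_to_pseudotime(res.ordering)
        write_pseudotime(out_dir / "pseudotime.tsv", expr.cell_ids, pt, score=res.arc_length)
        result.update(ordering=res.ordering, pseudotime=pt, big=res)

    if truth is not None and "pseudotime" in result:
        result["accuracy"] = abs_spearman(result["pseudotime"], truth.true_pseudotime)
        logger.info("absolute Spearman vs generating pseudotime: %.4f", result["accuracy"])

    canonical = json.dumps(cfg, sort_keys=True, default=str).encode()
    provenance = {
        "seed": seed,
        "config_sha256": hashlib.sha256(canonical).hexdigest(),
        "version": __version__,
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return result
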