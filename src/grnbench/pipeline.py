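"""End-to-end benchmark orchestration on synthetic worlds.

``run_all`` wires every stage together: generate a ground-truth world and
its four expression datasets, build the three nested gold standards from
simulated knockout and binding evidence, run the configured inference
approaches on every dataset, score each inferred network against each
gold standard with Benjamini–Hochberg-adjusted hypergeometric
significance, summarize sensitivity/specificity clouds with a
Pareto-frontier ROC, and count significant TF connectivity–accuracy
correlations.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd

from . import evaluation, gold_standard, inference, subnetwork, synthetic
from .containers import DirectedEdgeSet, UndirectedNetwork
from .io import (
    RunConfig,
    write_binding_tsv,
    write_de_tsv,
    write_edges_tsv,
    write_expression_tsv,
    write_pairs_tsv,
)

__all__ = ["run_all"]

logger = logging.getLogger(__name__)

GOLD_LEVELS = ("conservative", "intermediate", "liberal")
#: (threshold, min_conservation) per stringency level
GOLD_FILTERS = {
    "conservative": (0.001, 2),
    "intermediate": (0.005, 1),
    "liberal": (0.005, 0),
}


def _derive_seed(base: int, *offsets: int) -> int:
    s = base
    for k in offsets:
        s = (s * 1_000_003 + k) % (2**31 - 1)
    return s


def run_all(config: RunConfig) -> dict:
    """Run the full benchmark grid and write every artifact to out_dir."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    world = synthetic.make_world(
        config.n_genes, config.n_tfs, config.mean_out_degree,
        config.noise_sd, _derive_seed(config.seed, 1),
    )
    write_edges_tsv(world.true_network, out / "true_network.tsv")

    datasets = {}
    for di, design in enumerate(synthetic.DESIGNS):
        expr = synthetic.simulate_expression(
            world, design, config.n_samples, _derive_seed(config.seed, 2, di)
        )
        datasets[design] = expr
        write_expression_tsv(expr, out / f"expression_{design}.tsv")
    logger.info("simulated %d datasets (%.1fs)", len(datasets), time.time() - t0)

    de = synthetic.simulate_mutant_pvalues(
        world, config.n_wt, config.n_mut, _derive_seed(config.seed, 3)
    )
    write_de_tsv(de, out / "mutant_de.tsv")
    cons, inter, lib = synthetic.simulate_binding(
        world, config.binding_fnr, config.binding_fpr, _derive_seed(config.seed, 4)
    )
    scores = synthetic.binding_scores_from_networks(cons, inter, lib)
    write_binding_tsv(scores, out / "binding_scores.tsv")

    regulatory = gold_standard.build_regulatory_network(de, config.fdr_level)
    golds: dict[str, DirectedEdgeSet] = {}
    for level in GOLD_LEVELS:
        thr, min_cons = GOLD_FILTERS[level]
        binding = gold_standard.build_binding_network(scores, thr, min_cons)
        gs = gold_standard.intersect_networks(regulatory, binding)
        golds[level] = gs
        write_edges_tsv(gs, out / f"gold_{level}.tsv")
    logger.info(
        "gold standards: %s",
        {lvl: len(gs) for lvl, gs in golds.items()},
    )

    names = config.approaches or list(inference.STANDARD_APPROACHES)
    specs = {name: inference.STANDARD_APPROACHES[name] for name in names}
    inferred: dict[tuple[str, str], UndirectedNetwork] = {}
    for design, expr in datasets.items():
        for name, spec in specs.items():
            t1 = time.time()
            net = inference.run_approach(expr, spec)
            inferred[(name, design)] = net
            write_pairs_tsv(net, out / f"inferred_{design}_{name}.tsv")
            logger.info("inferred %s on %s: %d edges (%.1fs)",
                        name, design, len(net), time.time() - t1)

    # metric grid over gold standards x approaches x datasets
    raw: dict[tuple[str, str, str], evaluation.MetricSet] = {}
    pvals: dict[tuple[str, str, str], float] = {}
    for level, gs in golds.items():
        if len(gs) == 0:
            logger.warning("gold standard %s is empty; skipping", level)
            continue
        for (name, design), net in inferred.items():
            c = evaluation.confusion(net, gs)
            ms = evaluation.core_metrics(c)
            p = evaluation.network_significance(c)
            raw[(level, name, design)] = ms
            pvals[(level, name, design)] = p
    flags = evaluation.batch_adjust(pvals, alpha=config.alpha_level)
    grid = {
        key: evaluation.MetricSet(
            ms.sensitivity, ms.specificity, ms.ppv, ms.npv, ms.undefined,
            significance_p=pvals[key], significant=flags[key],
        )
        for key, ms in raw.items()
    }
    cells = pd.DataFrame(
        [
            (lvl, name, design, ms.sensitivity, ms.specificity, ms.ppv, ms.npv,
             ms.d_ss, ms.d_pn, ms.d_rp, ms.significance_p, ms.significant)
            for (lvl, name, design), ms in sorted(grid.items())
        ],
        columns=["gold", "approach", "dataset", "sensitivity", "specificity",
                 "ppv", "npv", "d_ss", "d_pn", "d_rp", "p_value", "significant"],
    )
    cells.to_csv(out / "metrics_grid.tsv", sep="\t", index=False)

    design_types = {d: d for d in datasets}  # one dataset per design here
    primary = GOLD_LEVELS[0] if GOLD_LEVELS[0] in {k[0] for k in grid} else None
    tables = {}
    if primary is not None:
        sub = {(n, d): ms for (lvl, n, d), ms in grid.items() if lvl == primary}
        for metric in ("d_ss", "d_pn", "d_rp"):
            tbl = evaluation.metrics_table(
                sub, metric, list(specs), list(datasets), dataset_types=design_types
            )
            tbl["pairs"].to_csv(out / f"table_{metric}_pairs.tsv", sep="\t")
            dist = tbl["distances"].copy()
            dist["Method Average"] = tbl["method_average"]
            dist.loc["Dataset Average"] = tbl["dataset_average"]
            dist.to_csv(out / f"table_{metric}_distance.tsv", sep="\t")
            tables[metric] = tbl

        points = [
            (ms.sensitivity, ms.specificity) for ms in sub.values()
            if not ("sensitivity" in ms.undefined or "specificity" in ms.undefined)
        ]
        gs = golds[primary]
        n_pos = len(gs)
        n_neg = len(evaluation.default_universe(gs)) - n_pos
        roc = evaluation.pareto_roc(points, n_pos=n_pos, n_neg=n_neg)
        pd.DataFrame(roc.frontier, columns=["fpr", "tpr"]).to_csv(
            out / "pareto_frontier.tsv", sep="\t", index=False
        )
        (out / "pareto_summary.tsv").write_text(
            f"auroc\tp_value\n{roc.auroc:.6g}\t{roc.p_value:.6g}\n"
        )
        tables["pareto"] = roc

    # TF connectivity vs sub-network accuracy counts
    counts = None
    if primary is not None and len(golds[primary].regulators) >= 3:
        rows = []
        run_idx = 0
        for (name, design), net in sorted(inferred.items()):
            for metric in ("d_ss", "d_pn", "d_rp"):
                for which in ("gold", "inferred"):
                    run_idx += 1
                    try:
                        rep = subnetwork.connectivity_accuracy_correlation(
                            net, golds[primary], which=which, metric=metric,
                            n_perm=config.n_perm,
                            seed=_derive_seed(config.seed, 5, run_idx),
                        )
                    except ValueError:
                        continue
                    rows.append((name, metric, which, design, rep.rho, rep.perm_p))
        if rows:
            perm = pd.DataFrame(
                rows, columns=["approach", "metric", "which", "dataset", "rho", "perm_p"]
            )
            perm.to_csv(out / "subnet_correlations.tsv", sep="\t", index=False)
            counts = subnetwork.significance_count_table(
                perm, n_datasets=len(datasets), alpha=config.alpha_level
            )
            counts.to_csv(out / "subnet_significant_counts.tsv", sep="\t")

    logger.info("full grid finished in %.1fs", time.time() - t0)
    return {
        "world": world,
        "golds": golds,
        "inferred": inferred,
        "grid": grid,
        "cells": cells,
        "tables": tables,
        "subnet_counts": counts,
    }
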