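"""Per-TF sub-network accuracy and its relation to TF connectivity.

Even when a whole-network reconstruction is poor, the sub-network around
an individual transcription factor can be recovered well.  This module
scores each TF's sub-network (candidate pairs with that TF as regulator),
measures TF connectivity (degree) in either the gold-standard or the
inferred network, and tests whether connectivity correlates with
sub-network accuracy using Spearman's rho with an exact permutation null:
gene identifiers are shuffled on a fixed network topology, because TFs
are not independent observations and a parametric null would be invalid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DirectedEdgeSet, UndirectedNetwork
from .evaluation import MetricSet, batch_adjust, confusion, core_metrics

__all__ = [
    "TFSubnetReport",
    "tf_subnetwork_accuracy",
    "connectivity",
    "connectivity_accuracy_correlation",
    "significance_count_table",
]


def tf_subnetwork_accuracy(
    inferred: UndirectedNetwork, gold: DirectedEdgeSet, tf: str
) -> MetricSet:
    """Accuracy metrics restricted to candidates regulated by one TF."""
    if tf not in gold.regulators:
        raise ValueError(f"{tf!r} is not a regulator of the gold standard")
    universe = {(tf, g) for g in gold.universe if g != tf}
    c = confusion(inferred, gold, universe=universe, universe_spec=f"targets of {tf}")
    ms = core_metrics(c)
    return ms


def connectivity(network: DirectedEdgeSet | UndirectedNetwork, node: str) -> int:
    """Degree of a node: incident edges (in- plus out-degree if directed)."""
    return network.degree(node)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass(frozen=True)
class TFSubnetReport:
    """Connectivity–accuracy correlation result for one inferred network."""

    table: pd.DataFrame  # per-TF rows: connectivity and metric value
    rho: float
    perm_p: float
    n_perm: int
    which: str
    metric: str


def connectivity_accuracy_correlation(
    inferred: UndirectedNetwork,
    gold: DirectedEdgeSet,
    which: str = "inferred",
    metric: str = "d_pn",
    n_perm: int = 1000,
    seed: int = 0,
    recompute_metrics: bool = True,
) -> TFSubnetReport:
    """Spearman correlation of TF connectivity with sub-network accuracy.

    ``which`` selects the network in which connectivity (and, when
    permuting, topology) is assessed.  The exact null is built by
    relabeling the gene identifiers of that network uniformly at random
    with structure fixed; per-TF connectivity and — when
    ``recompute_metrics`` is set — sub-network metrics are recomputed for
    every permutation.  When ``recompute_metrics`` is off only the
    connectivity vector is permuted (a cheaper variant of the same null).

    The permutation p-value is add-one smoothed,
    ``(1 + #{|rho_perm| >= |rho_obs|}) / (n_perm + 1)``, a two-sided test
    on the magnitude of the correlation.
    """
    if which not in ("gold", "inferred"):
        raise ValueError("which must be 'gold' or 'inferred'")
    if metric not in ("d_ss", "d_pn", "d_rp"):
        raise ValueError("metric must be one of d_ss, d_pn, d_rp")
    if n_perm < 1:
        raise ValueError("need n_perm >= 1")
    tfs = sorted(gold.regulators)

    def per_tf(infer_net: UndirectedNetwork, gold_net: DirectedEdgeSet,
               conn_net) -> tuple[list[str], np.ndarray, np.ndarray]:
        kept, conns, vals = [], [], []
        for tf in tfs:
            ms = tf_subnetwork_accuracy(infer_net, gold_net, tf)
            v = ms.distance(metric)
            if np.isnan(v):
                continue
            kept.append(tf)
            conns.append(connectivity(conn_net, tf))
            vals.append(v)
        return kept, np.asarray(conns, float), np.asarray(vals, float)

    conn_net = gold if which == "gold" else inferred
    kept, conns, vals = per_tf(inferred, gold, conn_net)
    if len(kept) < 3:
        raise ValueError("need at least 3 TFs with defined metrics")
    rho_obs = _spearman(conns, vals)
    table = pd.DataFrame(
        {"tf": kept, "connectivity": conns.astype(int), metric: vals}
    )
    if np.isnan(rho_obs):
        return TFSubnetReport(table, float("nan"), float("nan"), n_perm, which, metric)

    rng = np.random.default_rng(seed)
    universe = sorted(conn_net.universe)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(universe))
        mapping = {universe[i]: universe[perm[i]] for i in range(len(universe))}
        if which == "inferred":
            perm_inferred = inferred.relabel(mapping)
            perm_gold = gold
            perm_conn = perm_inferred
        else:
            perm_gold = DirectedEdgeSet(
                edges={(mapping[r], mapping[t]): s for (r, t), s in gold.edges.items()},
                regulators=frozenset(mapping[r] for r in gold.regulators),
                universe=frozenset(mapping[g] for g in gold.universe),
            )
            perm_inferred = inferred
            perm_conn = perm_gold
        if recompute_metrics:
            p_tfs = sorted(perm_gold.regulators)
            p_kept, p_conns, p_vals = [], [], []
            for tf in p_tfs:
                ms = tf_subnetwork_accuracy(perm_inferred, perm_gold, tf)
                v = ms.distance(metric)
                if np.isnan(v):
                    continue
                p_conns.append(connectivity(perm_conn, tf))
                p_vals.append(v)
            if len(p_conns) < 3:
                continue
            rho_p = _spearman(np.asarray(p_conns, float), np.asarray(p_vals, float))
        else:
            # permute only the connectivity vector: degree of each kept TF
            # identifier in the relabeled network
            p_conns = [connectivity(perm_conn, tf) for tf in kept]
            rho_p = _spearman(np.asarray(p_conns, float), vals)
        if not np.isnan(rho_p) and abs(rho_p) >= abs(rho_obs):
            hits += 1
    perm_p = (1 + hits) / (n_perm + 1)
    return TFSubnetReport(table, rho_obs, perm_p, n_perm, which, metric)


def significance_count_table(
    perm_p: pd.DataFrame, n_datasets: int | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Count datasets with significant connectivity–accuracy correlation.

    ``perm_p`` is a long table with columns ``approach``, ``metric``,
    ``which``, ``dataset`` and ``perm_p``.  Benjamini–Hochberg is applied
    globally over every test in the table, and the survivors at ``alpha``
    are counted per (approach, metric, which) cell.
    """
    required = {"approach", "metric", "which", "dataset", "perm_p"}
    if not required <= set(perm_p.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    flags = batch_adjust(
        {i: p for i, p in perm_p["perm_p"].items()}, alpha=alpha
    )
    df = perm_p.assign(significant=[flags[i] for i in perm_p.index])
    counts = (
        df.groupby(["approach", "metric", "which"], sort=True)["significant"]
        .sum()
        .astype(int)
        .unstack(["which", "metric"])
        .fillna(0)
        .astype(int)
    )
    if n_datasets is not None and (counts.to_numpy() > n_datasets).any():
        raise AssertionError("count exceeds number of datasets")
    return counts
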