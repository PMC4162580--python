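"""Accuracy metrics for inferred networks against a gold standard.

Four core metrics (sensitivity, specificity, PPV, NPV) are computed from
confusion counts over a candidate-pair universe, and three combined
metrics measure the Euclidean distance from the optimal operating point
for an antagonistic pair: sensitivity/specificity (``d_ss``), PPV/NPV
(``d_pn``) and recall/precision (``d_rp``), each ranging from 0 (optimal)
to √2 (worst).  Network-level significance uses an upper-tail
hypergeometric test with Benjamini–Hochberg adjustment across the whole
benchmarking grid.  A Pareto-frontier ROC summarizes a cloud of
(sensitivity, specificity) results with a single AUROC.

The candidate universe is a first-class, injectable parameter: by default
it is every (TF, gene) pair with the TF drawn from the gold standard's
regulators and the gene from its universe.  An inferred *unordered* pair
{a, b} predicts every directed candidate it is compatible with.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import DirectedEdgeSet, UndirectedNetwork

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "ParetoROC",
    "default_universe",
    "confusion",
    "core_metrics",
    "combined_distance",
    "network_significance",
    "batch_adjust",
    "pareto_roc",
    "summarize_distances",
    "metrics_table",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    universe_size: int
    universe_spec: str = "gold.regulators x gold.universe"

    def __post_init__(self) -> None:
        if self.tp + self.fp + self.tn + self.fn != self.universe_size:
            raise ValueError("confusion counts must partition the universe")


@dataclass(frozen=True)
class MetricSet:
    """Core and combined accuracy values for one inferred network.

    Metrics with a 0/0 denominator are *undefined* and carried as NaN;
    the ``undefined`` tuple lists them explicitly so they are never
    mistaken for zeros.
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    undefined: tuple[str, ...] = ()
    significance_p: float = float("nan")
    significant: bool = False

    @property
    def d_ss(self) -> float:
        return combined_distance(self.sensitivity, self.specificity)

    @property
    def d_pn(self) -> float:
        return combined_distance(self.ppv, self.npv)

    @property
    def d_rp(self) -> float:
        return combined_distance(self.sensitivity, self.ppv)

    def distance(self, which: str) -> float:
        return {"d_ss": self.d_ss, "d_pn": self.d_pn, "d_rp": self.d_rp}[which]


def default_universe(gold: DirectedEdgeSet) -> set[tuple[str, str]]:
    """All (TF, gene) candidate pairs: gold regulators × gold universe."""
    return {
        (tf, g)
        for tf in gold.regulators
        for g in gold.universe
        if g != tf
    }


def confusion(
    inferred: UndirectedNetwork,
    gold: DirectedEdgeSet,
    universe: Iterable[tuple[str, str]] | None = None,
    universe_spec: str | None = None,
) -> ConfusionCounts:
    """Tally confusion counts of an undirected prediction vs a directed gold.

    An inferred pair {a, b} predicts the directed candidate (a, b) when
    that candidate lies in the universe, and (b, a) likewise (both
    directions count when both genes are regulators).  Inferred pairs
    entirely outside the universe are ignored.
    """
    if universe is None:
        pairs = default_universe(gold)
        spec = "gold.regulators x gold.universe"
    else:
        pairs = set(universe)
        spec = universe_spec or "custom"
    if not pairs:
        raise ValueError("candidate-pair universe is empty")
    predicted = set()
    for a, b in inferred.pairs:
        if (a, b) in pairs:
            predicted.add((a, b))
        if (b, a) in pairs:
            predicted.add((b, a))
    gold_in = {e for e in gold.edges if e in pairs}
    tp = len(predicted & gold_in)
    fp = len(predicted - gold_in)
    fn = len(gold_in) - tp
    tn = len(pairs) - tp - fp - fn
    return ConfusionCounts(tp, fp, tn, fn, len(pairs), spec)


def core_metrics(c: ConfusionCounts) -> MetricSet:
    """Sensitivity, specificity, PPV and NPV with explicit 0/0 handling."""
    if c.universe_size == 0:
        raise ValueError("empty universe")

    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    return MetricSet(
        sensitivity=ratio(c.tp, c.tp + c.fn, "sensitivity"),
        specificity=ratio(c.tn, c.tn + c.fp, "specificity"),
        ppv=ratio(c.tp, c.tp + c.fp, "ppv"),
        npv=ratio(c.tn, c.tn + c.fn, "npv"),
        undefined=tuple(undefined),
    )


def combined_distance(m1: float, m2: float) -> float:
    """Euclidean distance from the optimal point (1, 1) for two metrics.

    Ranges from 0 (both metrics perfect) to √2 (both zero); smaller is
    better.  NaN inputs (undefined metrics) propagate.
    """
    if math.isnan(m1) or math.isnan(m2):
        return float("nan")
    if not (0 <= m1 <= 1 and 0 <= m2 <= 1):
        raise ValueError("metrics must lie in [0, 1]")
    return math.hypot(1 - m1, 1 - m2)


def network_significance(c: ConfusionCounts) -> float:
    """Upper-tail hypergeometric p-value for the recovered edge count.

    Population: the candidate universe.  Successes: gold edges.  Draws:
    predicted edges.  Returns P[X >= tp].
    """
    if c.tp == 0:
        return 1.0
    return float(
        min(1.0, stats.hypergeom.sf(c.tp - 1, c.universe_size, c.tp + c.fn, c.tp + c.fp))
    )


def batch_adjust(
    p_values: Mapping[object, float], alpha: float = 0.05
) -> dict[object, bool]:
    """Benjamini–Hochberg across a grid of network p-values.

    Returns per-cell significance flags at the given FDR level.  Intended
    for the full benchmarking grid (gold standards × approaches ×
    datasets) so that the many reconstruction tests share one adjustment.
    """
    keys = list(p_values)
    if not keys:
        return {}
    flags = multipletests([p_values[k] for k in keys], alpha=alpha, method="fdr_bh")[0]
    return {k: bool(f) for k, f in zip(keys, flags)}


@dataclass(frozen=True)
class ParetoROC:
    frontier: tuple[tuple[float, float], ...]  # (fpr, tpr), staircase
    auroc: float
    p_value: float


def pareto_roc(
    points: Sequence[tuple[float, float]],
    n_pos: int | None = None,
    n_neg: int | None = None,
) -> ParetoROC:
    """Pareto-frontier ROC over a cloud of (sensitivity, specificity) results.

    Each result maps to (fpr = 1−specificity, tpr = sensitivity); points
    dominated by another (no larger fpr, no smaller tpr) are discarded.
    The frontier is anchored at (0, 0) and (1, 1) and its AUROC computed
    by the trapezoid rule.  When effective positive/negative counts are
    supplied, a one-sided p-value for AUROC > 0.5 is obtained from the
    Hanley–McNeil normal approximation of the AUROC standard error.
    """
    if not points:
        raise ValueError("need at least one (sensitivity, specificity) point")
    roc = sorted({(round(1 - spec, 12), round(sens, 12)) for sens, spec in points})
    frontier: list[tuple[float, float]] = []
    best_tpr = -1.0
    # scan in increasing fpr (ties: best tpr first); a point is dominated
    # iff some point with <= fpr already reached >= tpr
    for fpr, tpr in sorted(roc, key=lambda q: (q[0], -q[1])):
        if tpr > best_tpr:
            frontier.append((fpr, tpr))
            best_tpr = tpr
    pts = [(0.0, 0.0)] + [p for p in frontier if p not in ((0.0, 0.0), (1.0, 1.0))] + [(1.0, 1.0)]
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    auroc = float(np.trapezoid(ys, xs))
    p_value = float("nan")
    if n_pos is not None and n_neg is not None and n_pos > 0 and n_neg > 0:
        a = min(max(auroc, 1e-12), 1 - 1e-12)
        q1 = a / (2 - a)
        q2 = 2 * a * a / (1 + a)
        var = (
            a * (1 - a)
            + (n_pos - 1) * (q1 - a * a)
            + (n_neg - 1) * (q2 - a * a)
        ) / (n_pos * n_neg)
        if var <= 0:
            p_value = 0.0 if auroc > 0.5 else 1.0
        else:
            p_value = float(stats.norm.sf((auroc - 0.5) / math.sqrt(var)))
    return ParetoROC(frontier=tuple(pts), auroc=auroc, p_value=p_value)


def summarize_distances(
    pairs: pd.DataFrame,
    dataset_types: Mapping[str, str] | None = None,
) -> dict[str, pd.Series]:
    """Combined-distance averages over a benchmark grid of metric pairs.

    ``pairs`` is a long table with columns ``approach``, ``dataset``,
    ``m1``, ``m2`` (one antagonistic metric pair per cell).  Returns the
    per-cell distances plus the three averaging conventions used in the
    benchmark tables, each rounded to 2 decimals:

    * ``method_average`` — mean over datasets for each approach;
    * ``dataset_average`` — mean over approaches for each dataset;
    * ``data_type_average`` — mean over all cells of member datasets
      (requires ``dataset_types``).
    """
    required = {"approach", "dataset", "m1", "m2"}
    if not required <= set(pairs.columns):
        raise ValueError(f"grid must have columns {sorted(required)}")
    df = pairs.copy()
    df["distance"] = [
        combined_distance(a, b) for a, b in zip(df["m1"], df["m2"])
    ]
    out: dict[str, pd.Series] = {
        "cell": df.set_index(["approach", "dataset"])["distance"],
        "method_average": df.groupby("approach", sort=False)["distance"].mean().round(2),
        "dataset_average": df.groupby("dataset", sort=False)["distance"].mean().round(2),
    }
    if dataset_types is not None:
        df["data_type"] = df["dataset"].map(dict(dataset_types))
        if df["data_type"].isna().any():
            missing = sorted(df.loc[df["data_type"].isna(), "dataset"].unique())
            raise ValueError(f"datasets without a data type: {missing}")
        out["data_type_average"] = (
            df.groupby("data_type", sort=False)["distance"].mean().round(2)
        )
    return out


_PAIR_FIELDS = {
    "d_ss": ("sensitivity", "specificity"),
    "d_pn": ("ppv", "npv"),
    "d_rp": ("sensitivity", "ppv"),
}


def metrics_table(
    grid: Mapping[tuple[str, str], MetricSet],
    metric: str,
    approaches: Sequence[str],
    datasets: Sequence[str],
    dataset_types: Mapping[str, str] | None = None,
) -> dict[str, pd.DataFrame | pd.Series]:
    """Benchmark-table exports for one combined metric.

    ``grid`` maps (approach, dataset) to a :class:`MetricSet`; the grid
    must be complete.  Emits the paired-value cell table (two core metrics
    separated by ``|``, 2 decimals), the distance table with its method
    averages, dataset averages and optional data-type averages, and a
    significance-marker table from the sets' ``significant`` flags.
    """
    if metric not in _PAIR_FIELDS:
        raise ValueError(f"metric must be one of {sorted(_PAIR_FIELDS)}")
    missing = [
        (a, d) for a in approaches for d in datasets if (a, d) not in grid
    ]
    if missing:
        raise ValueError(f"incomplete grid; missing cells: {missing}")
    f1, f2 = _PAIR_FIELDS[metric]
    rows = []
    for a in approaches:
        for d in datasets:
            ms = grid[(a, d)]
            rows.append((a, d, getattr(ms, f1), getattr(ms, f2), ms.significant))
    long = pd.DataFrame(rows, columns=["approach", "dataset", "m1", "m2", "significant"])
    pair_cells = long.assign(
        cell=[f"{m1:.2f}|{m2:.2f}" for m1, m2 in zip(long["m1"], long["m2"])]
    ).pivot(index="approach", columns="dataset", values="cell").loc[approaches, datasets]
    summaries = summarize_distances(long[["approach", "dataset", "m1", "m2"]],
                                    dataset_types=dataset_types)
    dist = summaries["cell"].unstack("dataset").loc[approaches, datasets].round(2)
    sig = long.pivot(index="approach", columns="dataset", values="significant")
    out: dict[str, pd.DataFrame | pd.Series] = {
        "pairs": pair_cells,
        "distances": dist,
        "significant": sig.loc[approaches, datasets],
        "method_average": summaries["method_average"].loc[list(approaches)],
        "dataset_average": summaries["dataset_average"].loc[list(datasets)],
    }
    if dataset_types is not None:
        out["data_type_average"] = summaries["data_type_average"]
    return out
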