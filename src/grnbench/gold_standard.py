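"""Gold-standard network construction from knockout and binding evidence.

A *regulatory* network is read off per-mutant differential-expression
p-values (Benjamini–Hochberg within each mutant profile at a 5% FDR by
default).  A *binding* network is read off TF→gene binding scores filtered
at a significance threshold plus an evolutionary-conservation requirement.
Their intersection — targets supported by both perturbation response and
physical binding — defines the gold standard of direct regulatory
interactions, whose overlap significance is quantified with an upper-tail
hypergeometric test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import DirectedEdgeSet

__all__ = [
    "build_regulatory_network",
    "build_binding_network",
    "intersect_networks",
    "overlap_significance",
]


def build_regulatory_network(de: pd.DataFrame, fdr_level: float = 0.05) -> DirectedEdgeSet:
    """Threshold a differential-expression table into mutant→gene edges.

    ``de`` must have columns ``mutant``, ``gene``, ``p_value``, ``sign``.
    Benjamini–Hochberg step-up is applied *within each mutant profile*
    (each deletion experiment is its own family of tests); the surviving
    (mutant, gene) pairs become signed edges.
    """
    required = {"mutant", "gene", "p_value", "sign"}
    if not required <= set(de.columns):
        raise ValueError(f"DE table must have columns {sorted(required)}")
    if len(de) == 0:
        warnings.warn("empty DE table: regulatory network has no edges")
        return DirectedEdgeSet.from_edges({}, regulators=[], universe=[])
    p = de["p_value"].to_numpy(float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    edges: dict[tuple[str, str], str] = {}
    for mutant, grp in de.groupby("mutant", sort=True):
        keep = multipletests(grp["p_value"].to_numpy(float), alpha=fdr_level,
                             method="fdr_bh")[0]
        for _, row in grp[keep].iterrows():
            edges[(str(mutant), str(row["gene"]))] = str(row["sign"])
    universe = set(de["mutant"].astype(str)) | set(de["gene"].astype(str))
    return DirectedEdgeSet.from_edges(
        edges,
        regulators=set(de["mutant"].astype(str)),
        universe=universe,
    )


def build_binding_network(
    binding_scores: pd.DataFrame,
    threshold: float = 0.001,
    min_conservation: int = 2,
) -> DirectedEdgeSet:
    """Filter binding scores into a TF→gene binding network.

    Keeps (TF, gene) rows with ``p <= threshold`` and
    ``conservation >= min_conservation``.  The conventional operating
    points are (0.001, 2) for the most conservative network, (0.005, 1)
    for the intermediate one and (0.005, 0) for the most liberal one.
    """
    required = {"tf", "gene", "p", "conservation"}
    if not required <= set(binding_scores.columns):
        raise ValueError(f"binding table must have columns {sorted(required)}")
    cons = binding_scores["conservation"].to_numpy(int)
    if np.any((cons < 0) | (cons > 2)):
        raise ValueError("conservation counts must be 0, 1 or 2")
    keep = (binding_scores["p"].to_numpy(float) <= threshold) & (cons >= min_conservation)
    kept = binding_scores[keep]
    edges = {(str(r["tf"]), str(r["gene"])): "?" for _, r in kept.iterrows()}
    universe = set(binding_scores["tf"].astype(str)) | set(binding_scores["gene"].astype(str))
    return DirectedEdgeSet.from_edges(
        edges,
        regulators=set(binding_scores["tf"].astype(str)),
        universe=universe,
    )


def intersect_networks(
    regulatory: DirectedEdgeSet, binding: DirectedEdgeSet
) -> DirectedEdgeSet:
    """Intersect regulatory and binding evidence into a gold standard.

    An edge survives iff present in both inputs; its sign is taken from the
    regulatory (perturbation-derived) network, since binding evidence
    carries no direction of effect.
    """
    common = set(regulatory.edges) & set(binding.edges)
    if not common:
        warnings.warn("regulatory and binding networks share no edges")
    edges = {pair: regulatory.edges[pair] for pair in common}
    return DirectedEdgeSet(
        edges=edges,
        regulators=regulatory.regulators & binding.regulators,
        universe=regulatory.universe & binding.universe,
    )


def overlap_significance(
    regulatory: DirectedEdgeSet, binding: DirectedEdgeSet, universe_pairs: int
) -> float:
    """Upper-tail hypergeometric probability of the observed edge overlap.

    Population: ``universe_pairs`` candidate TF→gene pairs.  Successes:
    regulatory edges.  Draws: binding edges.  Returns P[X ≥ k] for the
    observed intersection size k, summed in log space so that extremely
    small probabilities are still meaningful.
    """
    n_reg, n_bind = len(regulatory), len(binding)
    k = len(set(regulatory.edges) & set(binding.edges))
    if universe_pairs < max(n_reg, n_bind):
        raise ValueError("universe_pairs must be at least max(|regulatory|, |binding|)")
    if k == 0:
        return 1.0
    hg = stats.hypergeom(universe_pairs, n_reg, n_bind)
    upper = min(n_reg, n_bind)
    logs = hg.logpmf(np.arange(k, upper + 1))
    logs = logs[np.isfinite(logs)]
    if logs.size == 0:
        return 0.0
    from scipy.special import logsumexp

    return float(min(1.0, np.exp(logsumexp(logs))))
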