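"""Shared fixtures: hand-built worlds and a d-separation oracle."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from grnbench.containers import DirectedEdgeSet
from grnbench.synthetic import SyntheticWorld


def world_from_weights(
    weights: dict[tuple[str, str], float],
    tfs: list[str],
    genes: list[str],
    noise_sd: float = 0.1,
    seed: int = 0,
) -> SyntheticWorld:
    """Build a synthetic world from explicit edge weights.

    Gene identifiers must sort in a topological order of the graph (the
    simulator evaluates genes in sorted order).
    """
    edges = {p: ("+" if w > 0 else "-") for p, w in weights.items()}
    net = DirectedEdgeSet(
        edges=edges,
        regulators=frozenset(tfs),
        universe=frozenset(genes),
        weights=weights,
    )
    return SyntheticWorld(
        true_network=net,
        n_genes=len(genes),
        tf_ids=tuple(tfs),
        noise_sd=noise_sd,
        seed=seed,
    )


@pytest.fixture
def chain_world() -> SyntheticWorld:
    """a → b → c with unit weights."""
    return world_from_weights(
        {("a", "b"): 1.0, ("b", "c"): 1.0}, tfs=["a", "b"], genes=["a", "b", "c"]
    )


@pytest.fixture
def collider_world() -> SyntheticWorld:
    """a → c ← b with a ⟂ b."""
    return world_from_weights(
        {("a", "c"): 1.0, ("b", "c"): 1.0}, tfs=["a", "b"], genes=["a", "b", "c"]
    )


def dsep_skeleton(edges: set[tuple[str, str]], nodes: list[str]) -> set[tuple[str, str]]:
    """Oracle skeleton by exhaustive d-separation queries on the true DAG.

    Two nodes are adjacent iff no subset of the remaining nodes
    d-separates them.
    """
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    skel = set()
    for i, j in itertools.combinations(sorted(nodes), 2):
        rest = [k for k in nodes if k not in (i, j)]
        separated = False
        for r in range(len(rest) + 1):
            for s in itertools.combinations(rest, r):
                if nx.is_d_separator(g, {i}, {j}, set(s)):
                    separated = True
                    break
            if separated:
                break
        if not separated:
            skel.add((i, j))
    return skel
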