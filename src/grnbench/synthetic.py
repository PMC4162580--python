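"""Synthetic ground truth and data generation.

The generator produces everything the benchmark consumes so that the whole
pipeline is testable without microarray downloads: a ground-truth directed
TF→gene network, expression matrices under four study designs
(wild-type replicates, environment/time series, compendium, targeted
perturbation), knockout differential-expression p-value tables and noisy
TF→gene binding calls at three nested stringency levels.

The expression model is linear-Gaussian and acyclic: genes are evaluated in
topological order as ``x_g = Σ_parents w·x_parent + ε_g`` where exogenous
roots receive unit-variance innovations and regulated genes receive
``ε_g ~ N(0, noise_sd²)``.  Knockouts clamp the deleted gene to a fixed low
value on the standardized scale rather than removing it, which keeps the
matrix rectangular as in real mutant arrays.  All draws flow from a single
seeded generator per call, so identical arguments yield bit-identical
outputs.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DirectedEdgeSet, ExpressionMatrix

__all__ = [
    "SyntheticWorld",
    "generate_true_network",
    "make_world",
    "simulate_expression",
    "simulate_mutant_pvalues",
    "simulate_binding",
    "binding_scores_from_networks",
    "KNOCKOUT_CLAMP",
    "DESIGNS",
]

#: Clamp value (standardized scale) for deleted/knocked-down genes.
KNOCKOUT_CLAMP = -3.0

DESIGNS = ("replicates", "environment_time", "compendium", "perturbation")


@dataclass(frozen=True)
class SyntheticWorld:
    """A ground-truth regulatory network plus simulation parameters."""

    true_network: DirectedEdgeSet
    n_genes: int
    tf_ids: tuple[str, ...]
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for reg, _ in self.true_network.edges:
            if reg not in self.tf_ids:
                raise ValueError(f"edge regulator {reg!r} is not a TF")

    @property
    def genes(self) -> list[str]:
        return sorted(self.true_network.universe)


def _gene_ids(n_genes: int) -> list[str]:
    # zero-padded so lexicographic order equals the acyclic topological order
    return [f"g{i:04d}" for i in range(n_genes)]


def generate_true_network(
    n_genes: int, n_tfs: int, mean_out_degree: float, seed: int
) -> DirectedEdgeSet:
    """Sample a directed acyclic TF→gene network with hub-heavy degrees.

    Exactly ``round(n_tfs * mean_out_degree)`` edges are placed by
    preferential attachment on both ends (a TF's chance of gaining an edge
    and a gene's chance of being targeted grow with current degree), which
    yields the heavy-tailed out-degree profile characteristic of real
    transcription networks.  TF→TF edges only point from earlier to later
    TFs in the fixed gene ordering, so the graph is acyclic by
    construction.  Edge signs are fair coin flips and |weights| are uniform
    on [0.5, 1.5].
    """
    if not (1 <= n_tfs <= n_genes):
        raise ValueError("need 1 <= n_tfs <= n_genes")
    if mean_out_degree < 0:
        raise ValueError("mean_out_degree must be non-negative")
    n_edges = round(n_tfs * mean_out_degree)
    genes = _gene_ids(n_genes)
    tfs = genes[:n_tfs]
    # TF i may target TFs after it plus every non-TF gene
    capacity = [(n_tfs - i - 1) + (n_genes - n_tfs) for i in range(n_tfs)]
    if n_edges > sum(capacity):
        raise ValueError(
            f"cannot place {n_edges} edges: acyclic capacity is {sum(capacity)}"
        )
    rng = np.random.default_rng(seed)
    out_deg = np.zeros(n_tfs)
    in_deg = np.zeros(n_genes)
    edges: dict[tuple[str, str], str] = {}
    weights: dict[tuple[str, str], float] = {}
    placed: set[tuple[int, int]] = set()
    used = np.zeros(n_tfs)
    while len(edges) < n_edges:
        open_tfs = np.flatnonzero(used < capacity)
        w_tf = out_deg[open_tfs] + 1.0
        ti = int(rng.choice(open_tfs, p=w_tf / w_tf.sum()))
        allowed = [
            j
            for j in range(n_genes)
            if j != ti
            and (j >= n_tfs or j > ti)
            and (ti, j) not in placed
        ]
        w_g = in_deg[allowed] + 1.0
        tj = int(rng.choice(allowed, p=w_g / w_g.sum()))
        placed.add((ti, tj))
        used[ti] += 1
        out_deg[ti] += 1
        in_deg[tj] += 1
        sign = "+" if rng.random() < 0.5 else "-"
        mag = rng.uniform(0.5, 1.5)
        edges[(tfs[ti], genes[tj])] = sign
        weights[(tfs[ti], genes[tj])] = mag if sign == "+" else -mag
    return DirectedEdgeSet(
        edges=edges,
        regulators=frozenset(tfs),
        universe=frozenset(genes),
        weights=weights,
    )


def make_world(
    n_genes: int,
    n_tfs: int,
    mean_out_degree: float,
    noise_sd: float,
    seed: int,
) -> SyntheticWorld:
    """Convenience constructor: sample a true network and wrap it."""
    net = generate_true_network(n_genes, n_tfs, mean_out_degree, seed)
    return SyntheticWorld(
        true_network=net,
        n_genes=n_genes,
        tf_ids=tuple(_gene_ids(n_genes)[:n_tfs]),
        noise_sd=noise_sd,
        seed=seed,
    )


def _structural_sample(
    world: SyntheticWorld,
    n_samples: int,
    rng: np.random.Generator,
    clamp: dict[str, np.ndarray] | None = None,
    tf_drive: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Evaluate the linear-Gaussian model in topological order.

    ``clamp`` maps gene → boolean sample mask of entries forced to
    :data:`KNOCKOUT_CLAMP` (applied before children are evaluated).
    ``tf_drive`` maps gene → additive exogenous signal per sample.
    """
    genes = world.genes
    idx = {g: i for i, g in enumerate(genes)}
    parents: dict[str, list[tuple[int, float]]] = {g: [] for g in genes}
    assert world.true_network.weights is not None or not world.true_network.edges
    for (reg, tgt) in world.true_network.edges:
        w = world.true_network.weights[(reg, tgt)]
        parents[tgt].append((idx[reg], w))
    x = np.empty((len(genes), n_samples))
    # draw all innovations up front in a fixed gene order
    eps = rng.normal(size=(len(genes), n_samples))
    for g in genes:  # gene ids sort in topological order
        i = idx[g]
        scale = 1.0 if not parents[g] else world.noise_sd
        row = eps[i] * scale
        for pi, w in parents[g]:
            row = row + w * x[pi]
        if tf_drive and g in tf_drive:
            row = row + tf_drive[g]
        if clamp and g in clamp:
            row = np.where(clamp[g], KNOCKOUT_CLAMP, row)
        x[i] = row
    return pd.DataFrame(x, index=genes)


def simulate_expression(
    world: SyntheticWorld, design: str, n_samples: int, seed: int
) -> ExpressionMatrix:
    """Simulate a genes × samples matrix under one of the four designs.

    * ``replicates`` — i.i.d. steady-state draws, no exogenous variation.
    * ``environment_time`` — a smooth latent condition signal (random-phase
      sinusoid) feeds a random half of the TFs, mimicking environmental or
      time-course variation.
    * ``compendium`` — each sample clamps one random gene to the knockout
      value, mimicking a merged, predominantly perturbation-based corpus.
    * ``perturbation`` — samples cycle through TF knockouts.

    The perturbed gene per sample is recorded in the annotations but is
    never exposed to the inference methods.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
    if n_samples < 2:
        raise ValueError("need n_samples >= 2")
    rng = np.random.default_rng(seed)
    genes = world.genes
    samples = [f"s{i:04d}" for i in range(n_samples)]
    clamp: dict[str, np.ndarray] | None = None
    tf_drive: dict[str, np.ndarray] | None = None
    perturbed: dict[str, str | None] = {s: None for s in samples}

    if design == "environment_time":
        t = np.arange(n_samples) / n_samples
        freq = rng.integers(1, 4)
        phase = rng.uniform(0, 2 * np.pi)
        signal = np.sqrt(2.0) * np.sin(2 * np.pi * freq * t + phase)
        n_driven = max(1, len(world.tf_ids) // 2)
        driven = rng.choice(len(world.tf_ids), size=n_driven, replace=False)
        tf_drive = {world.tf_ids[i]: signal for i in sorted(driven)}
    elif design == "compendium":
        picks = rng.integers(0, len(genes), size=n_samples)
        clamp = {}
        for s_i, g_i in enumerate(picks):
            g = genes[g_i]
            mask = clamp.setdefault(g, np.zeros(n_samples, bool))
            mask[s_i] = True
            perturbed[samples[s_i]] = g
    elif design == "perturbation":
        clamp = {}
        for s_i in range(n_samples):
            tf = world.tf_ids[s_i % len(world.tf_ids)]
            mask = clamp.setdefault(tf, np.zeros(n_samples, bool))
            mask[s_i] = True
            perturbed[samples[s_i]] = tf

    df = _structural_sample(world, n_samples, rng, clamp=clamp, tf_drive=tf_drive)
    df.columns = samples
    return ExpressionMatrix(values=df, design=design, perturbed=perturbed)


def simulate_mutant_pvalues(
    world: SyntheticWorld, n_wt: int, n_mut: int, seed: int
) -> pd.DataFrame:
    """Knockout differential-expression calls for every TF.

    For each TF, ``n_mut`` knockout replicates (TF clamped low) are compared
    against a shared pool of ``n_wt`` wild-type replicates with per-gene
    Welch t-tests.  Returns a long table with columns ``mutant``, ``gene``,
    ``p_value`` and ``sign``, where the recorded sign follows the deletion
    convention: a target that goes *down* when its regulator is removed is
    recorded as excitatory (``+``).

    Genes with degenerate (zero) variance in both groups get ``p = 1``.
    """
    if n_wt < 2 or n_mut < 2:
        raise ValueError("need at least 2 replicates per group")
    rng = np.random.default_rng(seed)
    genes = world.genes
    wt = _structural_sample(world, n_wt, rng).to_numpy()
    rows: list[tuple[str, str, float, str]] = []
    for tf in world.tf_ids:
        mask = {tf: np.ones(n_mut, bool)}
        mut = _structural_sample(world, n_mut, rng, clamp=mask).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            # the clamped TF row is constant in the mutant group by design
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(mut, wt, axis=1, equal_var=False)
        pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        diff = mut.mean(axis=1) - wt.mean(axis=1)
        for gi, g in enumerate(genes):
            if g == tf:
                continue
            sign = "+" if diff[gi] < 0 else "-"
            rows.append((tf, g, float(pvals[gi]), sign))
    return pd.DataFrame(rows, columns=["mutant", "gene", "p_value", "sign"])


# survival probabilities when thinning the liberal binding set down to the
# intermediate and conservative levels; true edges survive preferentially
_TRUE_RETAIN = 0.95
_FALSE_RETAIN = 0.5


def simulate_binding(
    world: SyntheticWorld, fnr: float, fpr: float, seed: int
) -> tuple[DirectedEdgeSet, DirectedEdgeSet, DirectedEdgeSet]:
    """Noisy TF→gene binding calls at three nested stringency levels.

    The liberal set keeps each true edge with probability ``1 - fnr`` and
    adds each possible false TF→gene edge with probability ``fpr``.  The
    intermediate and conservative sets are nested random subsets of the
    liberal set in which true edges survive each thinning step with
    probability 0.95 and false edges with probability 0.5, mirroring how a
    stricter binding threshold plus a conservation requirement prunes
    mostly spurious calls.

    Returns ``(conservative, intermediate, liberal)`` with
    ``conservative ⊆ intermediate ⊆ liberal``.
    """
    if not (0 <= fnr <= 1 and 0 <= fpr <= 1):
        raise ValueError("fnr and fpr must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = world.genes
    true_edges = set(world.true_network.edges)
    liberal: dict[tuple[str, str], str] = {}
    for pair in sorted(true_edges):
        if rng.random() >= fnr:
            liberal[pair] = "?"
    for tf in world.tf_ids:
        for g in genes:
            if g == tf or (tf, g) in true_edges:
                continue
            if rng.random() < fpr:
                liberal[(tf, g)] = "?"

    def thin(edge_map: dict[tuple[str, str], str]) -> dict[tuple[str, str], str]:
        kept = {}
        for pair in sorted(edge_map):
            p_keep = _TRUE_RETAIN if pair in true_edges else _FALSE_RETAIN
            if rng.random() < p_keep:
                kept[pair] = "?"
        return kept

    intermediate = thin(liberal)
    conservative = thin(intermediate)
    regs = frozenset(world.tf_ids)
    univ = frozenset(genes)

    def build(edge_map: dict[tuple[str, str], str]) -> DirectedEdgeSet:
        return DirectedEdgeSet(edges=edge_map, regulators=regs, universe=univ)

    return build(conservative), build(intermediate), build(liberal)


def binding_scores_from_networks(
    conservative: DirectedEdgeSet,
    intermediate: DirectedEdgeSet,
    liberal: DirectedEdgeSet,
) -> pd.DataFrame:
    """Encode three nested binding networks as a score table.

    The output has columns ``tf``, ``gene``, ``p`` and ``conservation`` and
    is constructed so that filtering at (p ≤ 0.001, conservation ≥ 2)
    recovers the conservative set, (p ≤ 0.005, conservation ≥ 1) the
    intermediate set and (p ≤ 0.005, conservation ≥ 0) the liberal set.
    """
    if not (set(conservative.edges) <= set(intermediate.edges)
            <= set(liberal.edges)):
        raise ValueError("binding networks must be nested")
    rows = []
    for (tf, g) in sorted(liberal.edges):
        if (tf, g) in conservative.edges:
            rows.append((tf, g, 0.0005, 2))
        elif (tf, g) in intermediate.edges:
            rows.append((tf, g, 0.003, 1))
        else:
            rows.append((tf, g, 0.004, 0))
    return pd.DataFrame(rows, columns=["tf", "gene", "p", "conservation"])
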