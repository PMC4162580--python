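"""Statistical network reverse-engineering approaches.

Eighteen approaches are benchmarked, the cross product of:

* association test — Fisher's Z on continuous data, or G² on
  ternary-discretized data;
* conditioning — none (bivariate analysis) or a Generalized Local
  Learning (GLL) neighborhood search conditioning on subsets of up to 1,
  2 or 3 genes;
* thresholding/assembly — bivariate: 5% alpha (symmetric, no assembly) or
  per-gene 5% FDR followed by an AND or OR symmetrization; GLL: AND or OR
  symmetrization of the per-gene neighbor sets.

The GLL search is local-to-global ("divide and conquer"): for every gene
a candidate neighbor set is grown in order of unconditional association
strength, with interleaved elimination — a member is dropped as soon as
some reliable test conditioned on a subset of the other current members
(of size at most ``max_k``) fails to reject independence.  The per-gene
sets are then pieced together into an undirected network with the AND rule
(mutual membership) or the OR rule (either membership).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ci_tests import (
    TernaryMatrix,
    TestResult,
    _fisher_from_corr,
    _g2_core,
    _g2_strata,
    discretize,
    g2_test,
)
from .containers import ExpressionMatrix, UndirectedNetwork

__all__ = [
    "InferenceSpec",
    "STANDARD_APPROACHES",
    "bivariate_screen",
    "gll_neighbors",
    "assemble_network",
    "run_approach",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InferenceSpec:
    """Configuration of one reverse-engineering approach.

    ``max_k = 0`` selects bivariate analysis; ``max_k >= 1`` selects GLL
    with conditioning subsets of up to ``max_k`` genes.  ``threshold_rule``
    applies only to bivariate analysis (GLL always thresholds individual
    tests at ``alpha_level``).
    """

    test: str  # "fisher_z" | "g2"
    max_k: int
    threshold_rule: str = "alpha"  # "alpha" | "fdr"
    alpha_level: float = 0.05
    combine: str = "none"  # "AND" | "OR" | "none"

    def __post_init__(self) -> None:
        if self.test not in ("fisher_z", "g2"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.max_k not in (0, 1, 2, 3):
            raise ValueError("max_k must be 0, 1, 2 or 3")
        if self.threshold_rule not in ("alpha", "fdr"):
            raise ValueError(f"unknown threshold rule {self.threshold_rule!r}")
        if not (0 < self.alpha_level < 1):
            raise ValueError("alpha_level must lie in (0, 1)")
        if self.combine not in ("AND", "OR", "none"):
            raise ValueError(f"unknown combine rule {self.combine!r}")
        if self.max_k == 0 and self.threshold_rule == "alpha":
            if self.combine != "none":
                raise ValueError("bivariate alpha thresholding is symmetric: combine must be 'none'")
        elif self.combine == "none":
            raise ValueError("per-gene outputs require an AND or OR assembly rule")
        if self.max_k > 0 and self.threshold_rule != "alpha":
            raise ValueError("GLL thresholds individual tests at alpha")

    @property
    def name(self) -> str:
        """Canonical abbreviation, e.g. BIVARIATE_Z_FDR_AND or GLL_G_2_OR."""
        t = "Z" if self.test == "fisher_z" else "G"
        if self.max_k == 0:
            if self.threshold_rule == "alpha":
                return f"BIVARIATE_{t}_ALPHA"
            return f"BIVARIATE_{t}_FDR_{self.combine}"
        return f"GLL_{t}_{self.max_k}_{self.combine}"


def _standard_approaches() -> tuple[InferenceSpec, ...]:
    specs: list[InferenceSpec] = []
    for test in ("fisher_z", "g2"):
        specs.append(InferenceSpec(test, 0, "fdr", combine="AND"))
        specs.append(InferenceSpec(test, 0, "fdr", combine="OR"))
        specs.append(InferenceSpec(test, 0, "alpha", combine="none"))
        for k in (1, 2, 3):
            specs.append(InferenceSpec(test, k, "alpha", combine="AND"))
            specs.append(InferenceSpec(test, k, "alpha", combine="OR"))
    return tuple(specs)


#: The 18 benchmarked approaches, keyed by their canonical abbreviation.
STANDARD_APPROACHES: dict[str, InferenceSpec] = {
    s.name: s for s in _standard_approaches()
}


def _pairwise_fisher_z(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs unconditional Fisher's Z statistics and p-values."""
    x = df.to_numpy(float)
    n = x.shape[1]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x)
    corr = np.nan_to_num(corr, nan=0.0)  # constant genes carry no association
    np.fill_diagonal(corr, 0.0)
    r = np.clip(corr, -1 + 1e-7, 1 - 1e-7)
    z = 0.5 * np.log((1 + r) / (1 - r))
    stat = np.sqrt(n - 3) * np.abs(z)
    p = 2 * stats.norm.sf(stat)
    np.fill_diagonal(p, 1.0)
    return stat, np.minimum(p, 1.0)


def _pairwise_g2(tern: TernaryMatrix) -> tuple[np.ndarray, np.ndarray]:
    genes = tern.genes
    m = len(genes)
    stat = np.zeros((m, m))
    p = np.ones((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            res = g2_test(tern, genes[a], genes[b])
            stat[a, b] = stat[b, a] = res.statistic
            p[a, b] = p[b, a] = res.p_value
    return stat, p


def _pairwise(data: ExpressionMatrix | TernaryMatrix, test: str) -> tuple[list[str], np.ndarray, np.ndarray]:
    if test == "fisher_z":
        if not isinstance(data, ExpressionMatrix):
            raise TypeError("fisher_z requires continuous expression data")
        return data.genes, *_pairwise_fisher_z(data.values)
    if not isinstance(data, TernaryMatrix):
        raise TypeError("g2 requires ternary-discretized data")
    return data.genes, *_pairwise_g2(data)


class _FisherEngine:
    """Cached Fisher's Z tests from one precomputed correlation matrix.

    Every partial correlation is a function of the full sample correlation
    matrix, so no per-test data access is needed; results are identical to
    :func:`grnbench.ci_tests.fisher_z_test` on the same data.
    """

    def __init__(self, df: pd.DataFrame):
        self.idx = {g: k for k, g in enumerate(df.index)}
        self.n = df.shape[1]
        with np.errstate(invalid="ignore"):
            self.corr = np.corrcoef(df.to_numpy(float))

    def test(self, i: str, j: str, cond: tuple[str, ...]) -> TestResult:
        k = len(cond)
        if self.n <= k + 3:
            raise ValueError(f"need n > |cond| + 3 (n={self.n}, |cond|={k})")
        ids = [self.idx[i], self.idx[j]] + [self.idx[c] for c in cond]
        return _fisher_from_corr(self.corr[np.ix_(ids, ids)], self.n, k)

    def cond_pool(self, candidates: list[str]) -> list[str]:
        return candidates


class _G2Engine:
    """Cached G² tests on a ternary matrix.

    A conditional test whose reliability bound already fails from the
    observed strata count alone is short-circuited (unreliable results
    never influence edge decisions), and identical queries are answered
    from a cache — both pure speedups over :func:`grnbench.ci_tests.g2_test`
    with unchanged elimination decisions.
    """

    def __init__(self, tern: TernaryMatrix):
        self.x = tern.values.to_numpy(np.int64)
        self.idx = {g: k for k, g in enumerate(tern.values.index)}
        self.n = self.x.shape[1]
        self._cats = {g: len(np.unique(self.x[k])) for g, k in self.idx.items()}
        self._strata_counts: dict[tuple[str, ...], int] = {}
        self._cache: dict[tuple, TestResult] = {}

    def _n_strata(self, cond: tuple[str, ...]) -> int:
        if cond not in self._strata_counts:
            xc = self.x[[self.idx[c] for c in cond]]
            self._strata_counts[cond] = len(np.unique(_g2_strata(xc, self.n)))
        return self._strata_counts[cond]

    def test(self, i: str, j: str, cond: tuple[str, ...]) -> TestResult:
        a, b = (i, j) if i <= j else (j, i)
        key = (a, b, cond)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        if cond and self.n < 45 * self._n_strata(cond):
            res = TestResult(0.0, 1.0, self.n, len(cond), reliable=False)
        else:
            xc = self.x[[self.idx[c] for c in cond]] if cond else None
            res = _g2_core(self.x[self.idx[a]], self.x[self.idx[b]], xc, len(cond))
        self._cache[key] = res
        return res

    def cond_pool(self, candidates: list[str]) -> list[str]:
        # any subset containing gene c has at least cats(c) strata, so if
        # n < 45·cats(c) every such subset is unreliable and cannot
        # eliminate; dropping c from the pool changes no decision
        return [c for c in candidates if self.n >= 45 * self._cats[c]]


def _make_engine(data: ExpressionMatrix | TernaryMatrix, test: str):
    if test == "fisher_z":
        if not isinstance(data, ExpressionMatrix):
            raise TypeError("fisher_z requires continuous expression data")
        return _FisherEngine(data.values)
    if not isinstance(data, TernaryMatrix):
        raise TypeError("g2 requires ternary-discretized data")
    return _G2Engine(data)


def bivariate_screen(
    data: ExpressionMatrix | TernaryMatrix, spec: InferenceSpec
) -> UndirectedNetwork:
    """Pairwise association screening (no conditioning).

    Alpha rule: keep pairs with ``p <= alpha_level`` (symmetric).  FDR
    rule: Benjamini–Hochberg within each gene's row of m−1 p-values at
    ``alpha_level``, yielding per-gene neighbor lists which are then
    symmetrized with the AND or OR rule.
    """
    if spec.max_k != 0:
        raise ValueError("bivariate_screen requires max_k = 0")
    if data.n_samples < 4:
        raise ValueError("need at least 4 samples")
    genes, _, p = _pairwise(data, spec.test)
    m = len(genes)
    if spec.threshold_rule == "alpha":
        pairs = [
            (genes[a], genes[b])
            for a in range(m)
            for b in range(a + 1, m)
            if p[a, b] <= spec.alpha_level
        ]
        return UndirectedNetwork.from_pairs(pairs, universe=genes)
    neighbor_map: dict[str, set[str]] = {}
    for a in range(m):
        others = [b for b in range(m) if b != a]
        keep = multipletests(p[a, others], alpha=spec.alpha_level, method="fdr_bh")[0]
        neighbor_map[genes[a]] = {genes[b] for b, k in zip(others, keep) if k}
    return assemble_network(neighbor_map, spec.combine, universe=genes)


def gll_neighbors(
    data: ExpressionMatrix | TernaryMatrix,
    target: str,
    test: str = "fisher_z",
    max_k: int = 1,
    alpha_level: float = 0.05,
    _strength: dict[str, float] | None = None,
    _engine: "_FisherEngine | _G2Engine | None" = None,
) -> set[str]:
    """GLL local neighborhood of ``target``: direct causes and effects.

    Candidates are admitted in descending order of unconditional
    association strength (ties broken by gene identifier).  After each
    admission every current member X is re-examined: X is removed on the
    first *reliable* test of (target ⟂ X | S) with ``p > alpha_level``,
    over subsets S of the other current members with ``|S| <= max_k``
    (including the empty set).  Under faithfulness this returns the genes
    adjacent to the target in the true network.
    """
    if max_k < 1:
        raise ValueError("gll_neighbors requires max_k >= 1")
    df = data.values
    if target not in df.index:
        raise KeyError(f"target {target!r} not in data")
    engine = _engine if _engine is not None else _make_engine(data, test)
    if _strength is None:
        genes, stat, _ = _pairwise(data, test)
        gi = genes.index(target)
        _strength = {g: float(stat[gi, k]) for k, g in enumerate(genes) if g != target}
    ranked = sorted(_strength, key=lambda g: (-_strength[g], g))
    current: list[str] = []
    for cand in ranked:
        current.append(cand)
        for x in list(current):
            others = sorted(set(current) - {x})
            pool = engine.cond_pool(others)
            eliminated = False
            for k in range(0, max_k + 1):
                subsets = [()] if k == 0 else itertools.combinations(pool, k)
                for s in subsets:
                    res = engine.test(target, x, s)
                    if res.reliable and res.p_value > alpha_level:
                        current.remove(x)
                        eliminated = True
                        break
                if eliminated:
                    break
    return set(current)


def assemble_network(
    neighbor_map: dict[str, set[str]],
    combine: str,
    universe: Iterable[str] | None = None,
) -> UndirectedNetwork:
    """Piece per-gene neighbor sets into an undirected network.

    AND rule: X—Y requires mutual membership (Y in X's output and X in
    Y's).  OR rule: either membership suffices.
    """
    if combine not in ("AND", "OR"):
        raise ValueError("combine must be 'AND' or 'OR'")
    pairs = set()
    for x, neigh in neighbor_map.items():
        for y in neigh:
            if combine == "OR" or x in neighbor_map.get(y, set()):
                pairs.add((x, y) if x <= y else (y, x))
    return UndirectedNetwork.from_pairs(
        pairs, universe=universe if universe is not None else neighbor_map.keys()
    )


def run_approach(data: ExpressionMatrix, spec: InferenceSpec) -> UndirectedNetwork:
    """Run one configured approach end to end on an expression matrix.

    G²-based approaches discretize the data first; GLL approaches run the
    per-gene neighborhood search and assemble with the configured rule.
    Per-gene computations are independent, so any execution order yields
    the same network.
    """
    work: ExpressionMatrix | TernaryMatrix = data
    if spec.test == "g2":
        work = discretize(data)
    if spec.max_k == 0:
        net = bivariate_screen(work, spec)
        logger.info("approach %s: %d edges", spec.name, len(net))
        return net
    genes, stat, _ = _pairwise(work, spec.test)
    engine = _make_engine(work, spec.test)
    neighbor_map: dict[str, set[str]] = {}
    for gi, g in enumerate(genes):
        strength = {h: float(stat[gi, k]) for k, h in enumerate(genes) if h != g}
        neighbor_map[g] = gll_neighbors(
            work, g, test=spec.test, max_k=spec.max_k,
            alpha_level=spec.alpha_level, _strength=strength, _engine=engine,
        )
        logger.debug("approach %s: %s -> %d neighbors", spec.name, g, len(neighbor_map[g]))
    net = assemble_network(neighbor_map, spec.combine, universe=genes)
    logger.info("approach %s: %d edges", spec.name, len(net))
    return net
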