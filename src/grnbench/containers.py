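"""Core in-memory containers shared across the pipeline.

Three containers carry the data between pipeline stages:

* :class:`ExpressionMatrix` — a genes × samples table of (log-scale)
  expression values with optional design annotations.
* :class:`DirectedEdgeSet` — a set of regulator→target edges with signs,
  used for regulatory networks, binding networks and gold standards.
* :class:`UndirectedNetwork` — unordered gene pairs, the output format of
  every statistical inference approach in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = ["ExpressionMatrix", "DirectedEdgeSet", "UndirectedNetwork"]

Sign = str  # one of "+", "-", "?"
_VALID_SIGNS = frozenset({"+", "-", "?"})


@dataclass
class ExpressionMatrix:
    """Real-valued genes × samples expression table.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier with sample identifiers as
        columns.  Gene identifiers must be unique.
    design
        Optional study-design label (``replicates``, ``environment_time``,
        ``compendium`` or ``perturbation``).
    perturbed
        Optional mapping from sample identifier to the gene clamped in
        that sample (``None`` for unperturbed samples).  This annotation is
        bookkeeping only: inference methods never see it.
    """

    values: pd.DataFrame
    design: str | None = None
    perturbed: dict[str, str | None] | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups}")
        if self.values.isna().any().any():
            bad = self.values.isna().stack()
            loc = bad[bad].index[0]
            raise ValueError(f"missing value at gene {loc[0]!r}, sample {loc[1]!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.values.equals(other.values)
            and self.design == other.design
            and self.perturbed == other.perturbed
        )


def _norm_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class DirectedEdgeSet:
    """Directed regulator→target edges with per-edge signs.

    ``edges`` maps ``(regulator, target)`` to a sign: ``"+"`` (excitatory),
    ``"-"`` (inhibiting) or ``"?"`` (unknown, e.g. binding evidence only).
    ``weights`` optionally carries real effect sizes (used by the synthetic
    ground-truth networks; absent for data-derived networks).
    """

    edges: Mapping[tuple[str, str], Sign]
    regulators: frozenset[str]
    universe: frozenset[str]
    weights: Mapping[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", dict(self.edges))
        object.__setattr__(self, "regulators", frozenset(self.regulators))
        object.__setattr__(self, "universe", frozenset(self.universe))
        if not self.regulators <= self.universe:
            raise ValueError("regulators must be a subset of the gene universe")
        for (reg, tgt), sign in self.edges.items():
            if reg == tgt:
                raise ValueError(f"self-edge {reg}->{tgt} not allowed")
            if reg not in self.regulators:
                raise ValueError(f"edge regulator {reg!r} not in regulator set")
            if tgt not in self.universe:
                raise ValueError(f"edge target {tgt!r} not in gene universe")
            if sign not in _VALID_SIGNS:
                raise ValueError(f"invalid sign {sign!r} on edge {reg}->{tgt}")
        if self.weights is not None:
            object.__setattr__(self, "weights", dict(self.weights))
            if set(self.weights) != set(self.edges):
                raise ValueError("weights must cover exactly the edge set")

    @classmethod
    def from_edges(
        cls,
        edges: Mapping[tuple[str, str], Sign] | Iterable[tuple[str, str]],
        regulators: Iterable[str] | None = None,
        universe: Iterable[str] | None = None,
        weights: Mapping[tuple[str, str], float] | None = None,
    ) -> "DirectedEdgeSet":
        """Build an edge set, inferring regulators/universe when omitted."""
        if not isinstance(edges, Mapping):
            edges = {pair: "?" for pair in edges}
        regs = set(regulators) if regulators is not None else {r for r, _ in edges}
        univ = set(universe) if universe is not None else set()
        univ |= regs | {t for _, t in edges} | {r for r, _ in edges}
        return cls(edges=dict(edges), regulators=frozenset(regs),
                   universe=frozenset(univ), weights=weights)

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.edges

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(self.edges))

    def sign(self, regulator: str, target: str) -> Sign:
        return self.edges[(regulator, target)]

    def targets_of(self, regulator: str) -> frozenset[str]:
        return frozenset(t for (r, t) in self.edges if r == regulator)

    def degree(self, node: str) -> int:
        """Total connectivity: out-degree plus in-degree."""
        if node not in self.universe:
            raise KeyError(f"unknown node {node!r}")
        return sum(1 for (r, t) in self.edges if r == node or t == node)

    def skeleton(self) -> "UndirectedNetwork":
        """Forget edge directions, yielding the undirected pair set."""
        return UndirectedNetwork.from_pairs(
            (_norm_pair(r, t) for (r, t) in self.edges), universe=self.universe
        )


@dataclass(frozen=True)
class UndirectedNetwork:
    """Symmetric network of unordered gene pairs."""

    pairs: frozenset[tuple[str, str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(self.pairs))
        object.__setattr__(self, "universe", frozenset(self.universe))
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair {a!r} not allowed")
            if a > b:
                raise ValueError(f"pair ({a!r}, {b!r}) not in normalized order")
            if a not in self.universe or b not in self.universe:
                raise ValueError(f"pair ({a!r}, {b!r}) outside gene universe")

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        universe: Iterable[str] | None = None,
    ) -> "UndirectedNetwork":
        norm = frozenset(_norm_pair(a, b) for a, b in pairs)
        univ = set(universe) if universe is not None else set()
        for a, b in norm:
            univ.add(a)
            univ.add(b)
        return cls(pairs=norm, universe=frozenset(univ))

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return _norm_pair(a, b) in self.pairs

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(self.pairs))

    def degree(self, node: str) -> int:
        if node not in self.universe:
            raise KeyError(f"unknown node {node!r}")
        return sum(1 for a, b in self.pairs if node in (a, b))

    def neighbors(self, node: str) -> frozenset[str]:
        return frozenset(b if a == node else a
                         for a, b in self.pairs if node in (a, b))

    def relabel(self, mapping: Mapping[str, str]) -> "UndirectedNetwork":
        """Rename genes while keeping the topology fixed."""
        return UndirectedNetwork.from_pairs(
            ((mapping.get(a, a), mapping.get(b, b)) for a, b in self.pairs),
            universe=(mapping.get(g, g) for g in self.universe),
        )
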