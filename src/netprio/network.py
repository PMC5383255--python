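"""Weighted protein-interaction network and seed-set containers.

The same interaction list is used under two weighting conventions:

* ``raw`` mode keeps the integer confidence score S(p1, p2) on each edge
  (the propagation network): high score = strong tie.
* ``transformed`` mode stores w(e) = 1000 - S(p1, p2) (the shortest-path
  network): strong ties become short edges, so minimum-weight paths follow
  high-confidence interactions.

Scores live in [150, 999], hence transformed weights in [1, 850], and the
two weights of any edge always sum to 1000.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

from .errors import ValidationError

logger = logging.getLogger(__name__)

SCORE_FLOOR = 150
SCORE_CEIL = 999

RAW = "raw"
TRANSFORMED = "transformed"
_MODES = (RAW, TRANSFORMED)


@dataclass(frozen=True, order=True)
class InteractionRecord:
    """One scored interaction between two proteins/genes."""

    node_a: str
    node_b: str
    score: int

    def canonical(self) -> tuple[str, str]:
        """Unordered-pair key: endpoints in lexicographic order."""
        a, b = self.node_a, self.node_b
        return (a, b) if a <= b else (b, a)

    @property
    def is_self_loop(self) -> bool:
        return self.node_a == self.node_b


def transformed_weight(score: int) -> int:
    """Shortest-path edge weight: 1000 minus the confidence score."""
    return 1000 - int(score)


class WeightedNetwork:
    """Undirected weighted graph over opaque string node IDs.

    Wraps a :class:`networkx.Graph` whose edges carry both the raw
    ``score`` and the mode-dependent ``weight`` attribute; ``weight`` is
    what shortest-path and normalization code consumes.
    """

    def __init__(self, graph: nx.Graph, mode: str):
        if mode not in _MODES:
            raise ValidationError(f"unknown network mode {mode!r}; expected one of {_MODES}")
        self._graph = graph
        self.mode = mode
        self._node_order: tuple[str, ...] = tuple(sorted(graph.nodes))
        self._index: dict[str, int] = {n: i for i, n in enumerate(self._node_order)}

    # -- basic accessors ------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def node_order(self) -> tuple[str, ...]:
        """Deterministic (sorted) node ordering used for all vectors/matrices."""
        return self._node_order

    @property
    def n_nodes(self) -> int:
        return len(self._node_order)

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def index(self, node: str) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise ValidationError(f"node {node!r} not in network") from None

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def __iter__(self) -> Iterator[str]:
        return iter(self._node_order)

    def neighbors(self, node: str) -> list[str]:
        self.index(node)
        return sorted(self._graph.neighbors(node))

    def score(self, u: str, v: str) -> int:
        """Raw confidence score of edge (u, v); raises if absent."""
        return int(self._graph.edges[u, v]["score"])

    def has_edge(self, u: str, v: str) -> bool:
        return self._graph.has_edge(u, v)

    def weight(self, u: str, v: str) -> int:
        """Mode-dependent edge weight (score in raw mode, 1000-score otherwise)."""
        return int(self._graph.edges[u, v]["weight"])

    def edges(self) -> Iterator[tuple[str, str, int]]:
        """Yield (u, v, score) with u < v, in deterministic order."""
        for u, v in sorted(tuple(sorted(e)) for e in self._graph.edges):
            yield u, v, self.score(u, v)

    # -- derived views --------------------------------------------------
    def with_mode(self, mode: str) -> "WeightedNetwork":
        """Same topology and scores under the other weighting convention."""
        if mode == self.mode:
            return self
        g = nx.Graph()
        g.add_nodes_from(self._graph.nodes)
        for u, v, data in self._graph.edges(data=True):
            s = int(data["score"])
            w = s if mode == RAW else transformed_weight(s)
            g.add_edge(u, v, score=s, weight=w)
        return WeightedNetwork(g, mode)

    def induced_subgraph(self, nodes: Iterable[str]) -> "WeightedNetwork":
        nodes = set(nodes)
        missing = nodes - set(self._node_order)
        if missing:
            raise ValidationError(f"{len(missing)} node(s) not in network: {sorted(missing)[:5]}")
        return WeightedNetwork(nx.Graph(self._graph.subgraph(nodes)), self.mode)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedNetwork):
            return NotImplemented
        return (
            self.mode == other.mode
            and self._node_order == other._node_order
            and list(self.edges()) == list(other.edges())
        )

    def __repr__(self) -> str:
        return f"<WeightedNetwork mode={self.mode} nodes={self.n_nodes} edges={self.n_edges}>"


def build_network(records: Iterable[InteractionRecord], mode: str = RAW) -> WeightedNetwork:
    """Assemble a :class:`WeightedNetwork` from interaction records.

    Self-loop records are dropped (their count is logged); duplicate
    unordered pairs keep the maximum score. Raises on an empty record list.
    """
    best: dict[tuple[str, str], int] = {}
    n_loops = 0
    for rec in records:
        if rec.is_self_loop:
            n_loops += 1
            continue
        key = rec.canonical()
        prev = best.get(key)
        if prev is None or rec.score > prev:
            best[key] = int(rec.score)
    if n_loops:
        logger.warning("dropped %d self-loop record(s)", n_loops)
    if not best:
        raise ValidationError("no usable interaction records (empty input or all self-loops)")
    g = nx.Graph()
    for (u, v), s in best.items():
        w = s if mode == RAW else transformed_weight(s)
        g.add_edge(u, v, score=s, weight=w)
    return WeightedNetwork(g, mode)


@dataclass(frozen=True)
class SeedSet:
    """Validated disease-gene IDs bound to a network (the walk sources / path endpoints)."""

    ids: tuple[str, ...]
    label: str = "seeds"

    def __post_init__(self):
        if not self.ids:
            raise ValidationError("seed set is empty")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("seed set contains duplicates")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[str]:
        return iter(self.ids)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.ids)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.ids)

    def without(self, gene: str) -> "SeedSet":
        """Leave-one-out fold: the same seeds minus one held-out gene."""
        if gene not in self.ids:
            raise ValidationError(f"{gene!r} is not a seed")
        return SeedSet(tuple(g for g in self.ids if g != gene), label=f"{self.label}-minus-{gene}")


def make_seed_set(ids: Iterable[str], network: WeightedNetwork, label: str = "seeds") -> SeedSet:
    """Bind an ID list to a network: drop IDs absent from the node set.

    Order of first appearance is preserved and duplicates collapse to the
    first occurrence. Raises if no ID survives.
    """
    seen: dict[str, None] = {}
    dropped: list[str] = []
    for gid in ids:
        if gid in seen:
            continue
        if gid in network:
            seen[gid] = None
        else:
            dropped.append(gid)
    if dropped:
        logger.info("discarded %d seed ID(s) absent from the network: %s", len(dropped), dropped)
    if not seen:
        raise ValidationError("no seed ID occurs in the network")
    return SeedSet(tuple(seen), label=label)
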