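"""Shortest-path candidate mining on the transformed-weight network.

All minimum-weight paths between every pair of seed genes are collected
(Dijkstra; edge weights are 1000 - score, so paths follow high-confidence
interactions). Candidates are the non-seed *inner* nodes of those paths,
and each candidate's betweenness is the number of seed-pair shortest
paths that contain it — a seed-restricted count, not classical
betweenness centrality.

Two path modes are supported:

* ``all-ties`` (default): every minimum-weight path per pair counts.
* ``single``: exactly one path per pair, the lexicographically smallest
  node sequence among the ties, so runs are bit-reproducible.
"""

from __future__ import annotations

import heapq
import itertools
import logging
from collections import Counter
from dataclasses import dataclass

import networkx as nx

from .errors import ValidationError
from .network import TRANSFORMED, SeedSet, WeightedNetwork
from .records import CandidateRecord

logger = logging.getLogger(__name__)

ALL_TIES = "all-ties"
SINGLE = "single"
_PATH_MODES = (ALL_TIES, SINGLE)


@dataclass(frozen=True)
class SeedPairPath:
    """One minimum-weight path between two seeds, endpoints excluded from inner_nodes."""

    seed_a: str
    seed_b: str
    total_weight: int
    inner_nodes: tuple[str, ...]


def _check_sp_network(network: WeightedNetwork) -> None:
    if network.mode != TRANSFORMED:
        raise ValidationError("shortest-path search requires the transformed-weight network")


def seed_pair_shortest_paths(
    network: WeightedNetwork,
    seeds: SeedSet,
    path_mode: str = ALL_TIES,
) -> list[SeedPairPath]:
    """Minimum-weight path(s) for every unordered seed pair.

    Disconnected pairs are skipped (their count is logged). Paths are
    returned in deterministic order: pairs sorted lexicographically, then
    node sequences.
    """
    _check_sp_network(network)
    if path_mode not in _PATH_MODES:
        raise ValidationError(f"unknown path_mode {path_mode!r}; expected one of {_PATH_MODES}")
    for gene in seeds:
        network.index(gene)
    g = network.graph
    out: list[SeedPairPath] = []
    n_disconnected = 0
    for a, b in itertools.combinations(sorted(seeds.ids), 2):
        try:
            ties = sorted(nx.all_shortest_paths(g, a, b, weight="weight"))
        except nx.NetworkXNoPath:
            n_disconnected += 1
            continue
        if path_mode == SINGLE:
            ties = ties[:1]
        for path in ties:
            weight = sum(network.weight(u, v) for u, v in zip(path, path[1:]))
            out.append(SeedPairPath(a, b, int(weight), tuple(path[1:-1])))
    if n_disconnected:
        logger.info("skipped %d disconnected seed pair(s)", n_disconnected)
    return out


def betweenness(paths: list[SeedPairPath], seeds: SeedSet) -> dict[str, int]:
    """Count, per non-seed gene, the seed-pair shortest paths containing it.

    Seed genes never enter the table even when they sit inside another
    pair's path; genes on no path are simply absent (betweenness 0).
    """
    seed_ids = seeds.as_set()
    counts: Counter[str] = Counter()
    for path in paths:
        for node in path.inner_nodes:
            if node not in seed_ids:
                counts[node] += 1
    return dict(sorted(counts.items()))


def _dijkstra_with_counts(graph: nx.Graph, source: str) -> tuple[dict[str, int], dict[str, int]]:
    """Single-source distances and shortest-path multiplicities.

    Integer edge weights keep distance comparisons exact, so tie counting
    is well defined.
    """
    dist: dict[str, int] = {}
    sigma: dict[str, int] = {source: 1}
    heap: list[tuple[int, str]] = [(0, source)]
    tentative: dict[str, int] = {source: 0}
    while heap:
        d, u = heapq.heappop(heap)
        if u in dist:
            continue
        dist[u] = d
        for v, data in graph[u].items():
            nd = d + int(data["weight"])
            old = tentative.get(v)
            if old is None or nd < old:
                tentative[v] = nd
                sigma[v] = sigma[u]
                heapq.heappush(heap, (nd, v))
            elif nd == old and v not in dist:
                sigma[v] += sigma[u]
    return dist, sigma


def betweenness_counts(network: WeightedNetwork, seeds: SeedSet) -> dict[str, int]:
    """All-ties betweenness without materializing paths.

    For a pair (s, t) the number of minimum-weight s-t paths through an
    inner node v is sigma_s(v) * sigma_t(v) when
    dist_s(v) + dist_t(v) = dist_s(t). Summing over pairs reproduces the
    enumeration-based count at |seeds| single-source searches, which keeps
    the permutation test tractable.
    """
    _check_sp_network(network)
    g = network.graph
    seed_ids = seeds.as_set()
    present = [s for s in sorted(seeds.ids) if s in network]
    sssp = {s: _dijkstra_with_counts(g, s) for s in present}
    counts: Counter[str] = Counter()
    for a, b in itertools.combinations(present, 2):
        dist_a, sigma_a = sssp[a]
        dist_b, sigma_b = sssp[b]
        if b not in dist_a:
            continue
        d_ab = dist_a[b]
        for v, da in dist_a.items():
            if v == a or v == b or v in seed_ids:
                continue
            db = dist_b.get(v)
            if db is not None and da + db == d_ab:
                counts[v] += sigma_a[v] * sigma_b[v]
    return dict(sorted(counts.items()))


def sp_candidates(table: dict[str, int]) -> list[CandidateRecord]:
    """One record per gene with betweenness >= 1, sorted by descending count then ID."""
    out = [
        CandidateRecord(gene=g, method="sp", statistic=float(c))
        for g, c in table.items()
        if c >= 1
    ]
    out.sort(key=lambda rec: (-rec.statistic, rec.gene))
    return out
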