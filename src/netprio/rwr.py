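"""Random walk with restart on the score-weighted interaction network.

The walker starts from the seed distribution P0 (1/|seeds| on each seed)
and iterates

    P_{t+1} = (1 - r) * A P_t + r * P0

where A is the column-normalized weighted adjacency matrix (the
column-stochastic transition matrix: A[i, j] is the probability of
stepping j -> i) and r the restart probability (default 0.8). Iteration
stops when the L1 change drops below the tolerance (default 1e-6).
Because A's columns sum to one, every iterate remains a probability
distribution; the stationary vector ranks genes by propagated proximity
to the seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.sparse as sp

from .errors import ConvergenceError, ValidationError
from .network import RAW, SeedSet, WeightedNetwork
from .records import CandidateRecord


@dataclass(frozen=True)
class RWRConfig:
    """Solver settings: restart probability, L1 tolerance, iteration guard."""

    restart_prob: float = 0.8
    tolerance: float = 1e-6
    max_iterations: int = 10_000

    def __post_init__(self):
        if not 0.0 < self.restart_prob <= 1.0:
            raise ValidationError(f"restart_prob must be in (0, 1], got {self.restart_prob}")
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")


def initial_vector(network: WeightedNetwork, seeds: SeedSet) -> np.ndarray:
    """Seed distribution P0: 1/|seeds| on each seed node, 0 elsewhere."""
    if len(seeds) == 0:
        raise ValidationError("empty seed set")
    p0 = np.zeros(network.n_nodes)
    for gene in seeds:
        p0[network.index(gene)] = 1.0 / len(seeds)
    return p0


def normalized_adjacency(network: WeightedNetwork) -> sp.csr_matrix:
    """Column-normalized weighted adjacency A: A[i, j] = w(i,j) / sum_k w(k,j).

    Requires the raw-score network with no zero-weighted-degree node.
    """
    if network.mode != RAW:
        raise ValidationError("normalized adjacency requires the raw-score network")
    n = network.n_nodes
    rows, cols, vals = [], [], []
    for u, v, score in network.edges():
        i, j = network.index(u), network.index(v)
        rows += [i, j]
        cols += [j, i]
        vals += [float(score), float(score)]
    w = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    col_sums = np.asarray(w.sum(axis=0)).ravel()
    zero = np.flatnonzero(col_sums == 0)
    if zero.size:
        bad = [network.node_order[i] for i in zero[:5]]
        raise ValidationError(f"cannot column-normalize: zero-degree node(s) {bad}")
    return (w @ sp.diags(1.0 / col_sums)).tocsr()


def propagate(
    A: sp.spmatrix,
    p0: np.ndarray,
    config: RWRConfig | None = None,
    callback: Callable[[np.ndarray], None] | None = None,
) -> tuple[np.ndarray, int]:
    """Iterate the restart recurrence to convergence.

    Returns the converged vector and the number of update steps taken.
    ``callback`` (if given) sees every iterate, including the final one.
    Raises :class:`ConvergenceError` with the last residual if the
    iteration guard is exhausted.
    """
    config = config or RWRConfig()
    if A.shape[0] != A.shape[1] or A.shape[0] != p0.shape[0]:
        raise ValidationError(f"dimension mismatch: A {A.shape}, p0 {p0.shape}")
    r = config.restart_prob
    A = A.tocsr()
    p = p0.copy()
    residual = np.inf
    for step in range(1, config.max_iterations + 1):
        p_next = (1.0 - r) * (A @ p) + r * p0
        if callback is not None:
            callback(p_next)
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < config.tolerance:
            return p, step
    raise ConvergenceError(
        f"no convergence after {config.max_iterations} iterations "
        f"(last L1 residual {residual:.3e})",
        residual=residual,
    )


def closed_form(A: sp.spmatrix, p0: np.ndarray, restart_prob: float = 0.8) -> np.ndarray:
    """Direct linear solve of the stationary equation P = r (I - (1-r) A)^-1 P0.

    Dense; intended for small networks and as an independent check of the
    iterative solver.
    """
    n = p0.shape[0]
    dense = np.asarray(A.todense()) if sp.issparse(A) else np.asarray(A)
    m = np.eye(n) - (1.0 - restart_prob) * dense
    return restart_prob * np.linalg.solve(m, p0)


def rwr_candidates(
    p: np.ndarray,
    network: WeightedNetwork,
    seeds: SeedSet,
    prwrp: float,
) -> list[CandidateRecord]:
    """Non-seed genes whose stationary probability strictly exceeds ``prwrp``.

    Sorted by descending probability, ties broken by gene ID.
    """
    seed_ids = seeds.as_set()
    out = [
        CandidateRecord(gene=g, method="rwr", statistic=float(p[i]))
        for i, g in enumerate(network.node_order)
        if g not in seed_ids and p[i] > prwrp
    ]
    out.sort(key=lambda rec: (-rec.statistic, rec.gene))
    return out
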