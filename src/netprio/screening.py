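"""The three screening rules applied to raw candidates.

1. **Permutation p-value** — the observed statistic (propagation
   probability or betweenness) is compared against the statistics obtained
   from random seed sets of the same size; p-value(g) is the fraction of
   random sets whose statistic strictly exceeds the observed one. Genes
   with p < 0.05 survive.
2. **Maximum interaction score (MIS)** — the candidate's highest
   confidence score to any seed gene; survives when MIS >= p_MIS.
3. **Maximum function score (MFS)** — the candidate's highest cosine
   similarity, over seeds, between term-enrichment-score vectors ES(g);
   survives when MFS > p_MFS.

Comparison directions (strict vs non-strict) follow the method's
pseudo-code wording exactly and are pinned by tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .errors import ValidationError
from .network import RAW, SeedSet, WeightedNetwork
from .records import CandidateRecord
from . import rwr as _rwr
from . import shortest_paths as _sp

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 1000
DEFAULT_P_CUTOFF = 0.05

INDICATOR = "indicator"
NEIGHBORHOOD_HYPERGEOMETRIC = "neighborhood-hypergeometric"
_SCORERS = (INDICATOR, NEIGHBORHOOD_HYPERGEOMETRIC)


@dataclass(frozen=True)
class ScreeningThresholds:
    """Cutoffs for the three rules (p-value, p_MIS, p_MFS)."""

    p_cutoff: float = DEFAULT_P_CUTOFF
    p_mis: int = 400
    p_mfs: float = 0.8

    def __post_init__(self):
        if not 0.0 < self.p_cutoff < 1.0:
            raise ValidationError(f"p_cutoff must be in (0, 1), got {self.p_cutoff}")
        if not 0 <= self.p_mis <= 999:
            raise ValidationError(f"p_mis must be in [0, 999], got {self.p_mis}")
        if not 0.0 <= self.p_mfs <= 1.0:
            raise ValidationError(f"p_mfs must be in [0, 1], got {self.p_mfs}")


# ---------------------------------------------------------------------------
# Rule 1: permutation test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationEntry:
    observed: float
    exceed_count: int
    p_value: float


@dataclass(frozen=True)
class PermutationResult:
    """Per-gene permutation outcome plus the settings that produced it."""

    entries: Mapping[str, PermutationEntry]
    n_perm: int
    rng_seed: int

    def p_value(self, gene: str) -> float:
        return self.entries[gene].p_value

    def genes(self) -> list[str]:
        return list(self.entries)


def draw_permutation_sets(
    network: WeightedNetwork,
    size: int,
    n_perm: int,
    rng_seed: int,
    exclude: Iterable[str] = (),
) -> list[tuple[str, ...]]:
    """n_perm node sets of the given size, uniform without replacement.

    By default the whole node universe (seeds included) is eligible;
    ``exclude`` removes genes from the pool.
    """
    pool = [g for g in network.node_order if g not in set(exclude)]
    if size > len(pool):
        raise ValidationError(f"cannot draw {size} nodes from a pool of {len(pool)}")
    rng = np.random.default_rng(rng_seed)
    sets = []
    for _ in range(n_perm):
        idx = rng.choice(len(pool), size=size, replace=False)
        sets.append(tuple(pool[i] for i in idx))
    return sets


def _rwr_statistic_fn(network: WeightedNetwork, config: _rwr.RWRConfig,
                      genes: Sequence[str]) -> Callable[[tuple[str, ...]], np.ndarray]:
    A = _rwr.normalized_adjacency(network)
    idx = np.array([network.index(g) for g in genes], dtype=int)
    gene_arr = np.array(genes)

    def stat(seed_ids: tuple[str, ...]) -> np.ndarray:
        p0 = _rwr.initial_vector(network, SeedSet(seed_ids, label="perm"))
        p, _ = _rwr.propagate(A, p0, config)
        out = p[idx]
        # a gene drawn into the permuted seed set is not a candidate of
        # that run (seeds are never candidates) and its restart-inflated
        # probability is no candidate statistic: contribute 0, mirroring
        # the betweenness convention for candidates absent from a run
        out[np.isin(gene_arr, seed_ids)] = 0.0
        return out

    return stat


def _sp_statistic_fn(network: WeightedNetwork, path_mode: str,
                     genes: Sequence[str]) -> Callable[[tuple[str, ...]], np.ndarray]:
    def stat(seed_ids: tuple[str, ...]) -> np.ndarray:
        perm_seeds = SeedSet(seed_ids, label="perm")
        if path_mode == _sp.ALL_TIES:
            table = _sp.betweenness_counts(network, perm_seeds)
        else:
            paths = _sp.seed_pair_shortest_paths(network, perm_seeds, path_mode)
            table = _sp.betweenness(paths, perm_seeds)
        return np.array([float(table.get(g, 0)) for g in genes])

    return stat


def permutation_test(
    method: str | Callable[[tuple[str, ...]], np.ndarray],
    network: WeightedNetwork,
    seeds: SeedSet,
    candidates: Sequence[CandidateRecord],
    n_perm: int = DEFAULT_N_PERM,
    rng_seed: int = 0,
    rwr_config: _rwr.RWRConfig | None = None,
    path_mode: str = _sp.ALL_TIES,
    exclude_seeds: bool = False,
) -> PermutationResult:
    """Empirical significance of each candidate's statistic.

    ``method`` selects the statistic re-run per random seed set: ``"rwr"``
    (stationary probability on the raw network), ``"sp"`` (betweenness on
    the transformed network; a candidate absent from a permuted run counts
    as 0), or any callable mapping a seed-ID tuple to the candidates'
    statistics in order — the hook the tests use to pin the counting
    arithmetic independently of the graph algorithms.
    """
    genes = [c.gene for c in candidates]
    observed = np.array([c.statistic for c in candidates], dtype=float)
    if callable(method):
        stat_fn = method
    elif method == "rwr":
        stat_fn = _rwr_statistic_fn(network, rwr_config or _rwr.RWRConfig(), genes)
    elif method == "sp":
        stat_fn = _sp_statistic_fn(network, path_mode, genes)
    else:
        raise ValidationError(f"unknown permutation method {method!r}")

    exclude = seeds.ids if exclude_seeds else ()
    perm_sets = draw_permutation_sets(network, len(seeds), n_perm, rng_seed, exclude=exclude)
    exceed = np.zeros(len(genes), dtype=int)
    for perm in perm_sets:
        stats = np.asarray(stat_fn(perm), dtype=float)
        exceed += stats > observed
    entries = {
        g: PermutationEntry(float(observed[i]), int(exceed[i]), exceed[i] / n_perm)
        for i, g in enumerate(genes)
    }
    return PermutationResult(entries=entries, n_perm=n_perm, rng_seed=rng_seed)


def filter_by_pvalue(result: PermutationResult,
                     cutoff: float = DEFAULT_P_CUTOFF) -> list[str]:
    """Genes with p-value strictly below the cutoff (p = cutoff is removed)."""
    if not 0.0 < cutoff < 1.0:
        raise ValidationError(f"cutoff must be in (0, 1), got {cutoff}")
    return [g for g, e in result.entries.items() if e.p_value < cutoff]


# ---------------------------------------------------------------------------
# Rule 2: maximum interaction score
# ---------------------------------------------------------------------------

def mis(gene: str, seeds: SeedSet, network: WeightedNetwork) -> int:
    """Highest confidence score between the gene and any seed; 0 if none adjacent."""
    if network.mode != RAW:
        raise ValidationError("MIS requires the raw-score network")
    network.index(gene)
    scores = [network.score(gene, s) for s in seeds if network.has_edge(gene, s)]
    return max(scores, default=0)


# ---------------------------------------------------------------------------
# Rule 3: enrichment-score profiles and the maximum function score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationProfile:
    """Per-gene vectors of term enrichment scores over a fixed term universe.

    ``matrix`` is (n_genes x n_terms), rows aligned to ``genes``; all
    scores are nonnegative. Genes whose vector is all-zero are flagged in
    ``zero_genes`` — their cosine associations are defined as 0.
    """

    terms: tuple[str, ...]
    genes: tuple[str, ...]
    matrix: np.ndarray
    scorer: str
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "_index", {g: i for i, g in enumerate(self.genes)})

    def vector(self, gene: str) -> np.ndarray:
        try:
            return self.matrix[self._index[gene]]
        except KeyError:
            raise ValidationError(f"gene {gene!r} not in annotation profile") from None

    @property
    def zero_genes(self) -> tuple[str, ...]:
        norms = np.linalg.norm(self.matrix, axis=1)
        return tuple(g for g, nrm in zip(self.genes, norms) if nrm == 0.0)


def build_annotation_profile(
    term_sets: Mapping[str, Iterable[str]],
    network: WeightedNetwork,
    scorer: str = NEIGHBORHOOD_HYPERGEOMETRIC,
) -> AnnotationProfile:
    """Encode every network gene as an ES vector over the GMT term universe.

    * ``indicator``: ES(g)[t] = 1 if g is annotated to term t, else 0 — a
      transparent membership encoding.
    * ``neighborhood-hypergeometric`` (default): ES(g)[t] is the
      -log10 upper-tail hypergeometric probability of the overlap between
      g's closed neighborhood ({g} plus direct interactors) and term t's
      gene set within the network-node universe, floored at 0. This scores
      how over-represented the term is around the gene, the
      guilt-by-association reading of "enrichment".
    """
    if scorer not in _SCORERS:
        raise ValidationError(f"unknown scorer {scorer!r}; expected one of {_SCORERS}")
    terms = tuple(term_sets)
    if not terms:
        raise ValidationError("term universe is empty")
    genes = network.node_order
    node_set = set(genes)
    members = [frozenset(term_sets[t]) & node_set for t in terms]
    mat = np.zeros((len(genes), len(terms)))
    if scorer == INDICATOR:
        for j, mem in enumerate(members):
            for g in mem:
                mat[network.index(g), j] = 1.0
    else:
        n_universe = len(genes)
        for i, g in enumerate(genes):
            neighborhood = frozenset(network.neighbors(g)) | {g}
            n_draw = len(neighborhood)
            for j, mem in enumerate(members):
                k = len(neighborhood & mem)
                if k == 0:
                    continue  # upper tail is 1, score 0
                tail = float(hypergeom.sf(k - 1, n_universe, len(mem), n_draw))
                mat[i, j] = max(0.0, -np.log10(max(tail, 1e-300)))
    profile = AnnotationProfile(terms=terms, genes=genes, matrix=mat, scorer=scorer)
    if profile.zero_genes:
        logger.info("%d gene(s) have an all-zero enrichment vector", len(profile.zero_genes))
    return profile


def association(gene_a: str, gene_b: str, profile: AnnotationProfile) -> float:
    """Cosine similarity M(g, g') of the two enrichment-score vectors, in [0, 1].

    A zero-norm vector yields 0 with a logged warning rather than an error.
    """
    va, vb = profile.vector(gene_a), profile.vector(gene_b)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        logger.warning("zero-norm enrichment vector for %s or %s; association set to 0",
                       gene_a, gene_b)
        return 0.0
    return float(np.dot(va, vb) / (na * nb))


def mfs(gene: str, seeds: SeedSet, profile: AnnotationProfile) -> float:
    """Maximum function score: max over seeds of association(gene, seed)."""
    return max(association(gene, s, profile) for s in seeds)


def mfs_table(genes: Sequence[str], seeds: SeedSet,
              profile: AnnotationProfile) -> dict[str, float]:
    """Vectorized MFS for many genes at once (matches ``mfs`` gene by gene)."""
    def unit_rows(ids: Sequence[str]) -> np.ndarray:
        rows = np.stack([profile.vector(g) for g in ids])
        norms = np.linalg.norm(rows, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(norms > 0, rows / norms, 0.0)
        return out

    if not genes:
        return {}
    sims = unit_rows(genes) @ unit_rows(list(seeds.ids)).T
    return {g: float(sims[i].max()) for i, g in enumerate(genes)}
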