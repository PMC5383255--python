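"""End-to-end orchestration of the two prioritization routes.

Each route runs its raw search, then the three screening rules in order:

1. raw statistic (propagation probability > pRWRp, or betweenness >= 1),
2. permutation p-value < 0.05,
3. MIS >= p_MIS,
4. MFS > p_MFS,

emitting *every* step-1 candidate with its intermediate values and pass
flags, so failed candidates stay inspectable; the putative set is the
subset passing all four. The integrated result is the union of the two
putative sets, partitioned into both / propagation-only / path-only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import ValidationError
from .network import RAW, SeedSet, TRANSFORMED, WeightedNetwork
from .records import CandidateRecord
from . import evaluation as _eval
from . import rwr as _rwr
from . import screening as _screen
from . import shortest_paths as _sp


def _screen_candidates(
    candidates: Sequence[CandidateRecord],
    perm: _screen.PermutationResult,
    mis_map: dict[str, int],
    mfs_map: dict[str, float],
    thresholds: _screen.ScreeningThresholds,
) -> list[CandidateRecord]:
    """Attach rule values and pass flags to every candidate.

    Pure set intersections: the order the rules are applied in cannot
    change the surviving set.
    """
    out = []
    for rec in candidates:
        p = perm.p_value(rec.gene)
        m = mis_map[rec.gene]
        f = mfs_map[rec.gene]
        out.append(rec.evolve(
            p_value=p,
            mis=m,
            mfs=f,
            passed_pvalue=p < thresholds.p_cutoff,
            passed_mis=m >= thresholds.p_mis,
            passed_mfs=f > thresholds.p_mfs,
        ))
    return out


def _rule_values(
    candidates: Sequence[CandidateRecord],
    network_raw: WeightedNetwork,
    seeds: SeedSet,
    profile: _screen.AnnotationProfile,
) -> tuple[dict[str, int], dict[str, float]]:
    genes = [c.gene for c in candidates]
    mis_map = {g: _screen.mis(g, seeds, network_raw) for g in genes}
    mfs_map = _screen.mfs_table(genes, seeds, profile)
    return mis_map, mfs_map


def run_rwr_method(
    network: WeightedNetwork,
    seeds: SeedSet,
    profile: _screen.AnnotationProfile,
    prwrp: float,
    thresholds: _screen.ScreeningThresholds,
    rng_seed: int = 0,
    n_perm: int = _screen.DEFAULT_N_PERM,
    config: _rwr.RWRConfig | None = None,
) -> list[CandidateRecord]:
    """Propagation route with full provenance; putative genes pass all rules."""
    if network.mode != RAW:
        raise ValidationError("the propagation route needs the raw-score network")
    config = config or _rwr.RWRConfig()
    A = _rwr.normalized_adjacency(network)
    p0 = _rwr.initial_vector(network, seeds)
    p, _ = _rwr.propagate(A, p0, config)
    candidates = _rwr.rwr_candidates(p, network, seeds, prwrp)
    if not candidates:
        return []
    perm = _screen.permutation_test(
        "rwr", network, seeds, candidates,
        n_perm=n_perm, rng_seed=rng_seed, rwr_config=config,
    )
    mis_map, mfs_map = _rule_values(candidates, network, seeds, profile)
    return _screen_candidates(candidates, perm, mis_map, mfs_map, thresholds)


def run_sp_method(
    network: WeightedNetwork,
    seeds: SeedSet,
    profile: _screen.AnnotationProfile,
    thresholds: _screen.ScreeningThresholds,
    rng_seed: int = 0,
    n_perm: int = _screen.DEFAULT_N_PERM,
    path_mode: str = _sp.ALL_TIES,
) -> list[CandidateRecord]:
    """Shortest-path route with full provenance; betweenness is the raw statistic."""
    network_raw = network.with_mode(RAW)
    network_sp = network.with_mode(TRANSFORMED)
    if path_mode == _sp.ALL_TIES:
        table = _sp.betweenness_counts(network_sp, seeds)
    else:
        paths = _sp.seed_pair_shortest_paths(network_sp, seeds, path_mode)
        table = _sp.betweenness(paths, seeds)
    candidates = _sp.sp_candidates(table)
    if not candidates:
        return []
    perm = _screen.permutation_test(
        "sp", network_sp, seeds, candidates,
        n_perm=n_perm, rng_seed=rng_seed, path_mode=path_mode,
    )
    mis_map, mfs_map = _rule_values(candidates, network_raw, seeds, profile)
    return _screen_candidates(candidates, perm, mis_map, mfs_map, thresholds)


def putative_genes(records: Sequence[CandidateRecord]) -> frozenset[str]:
    return frozenset(rec.gene for rec in records if rec.is_putative)


# ---------------------------------------------------------------------------
# Threshold-independent fold statistics (feeds the grid search)
# ---------------------------------------------------------------------------

def compute_rwr_fold_stats(
    network: WeightedNetwork,
    fold_seeds: SeedSet,
    held_out: str,
    profile: _screen.AnnotationProfile,
    min_prwrp: float,
    n_perm: int,
    rng_seed: int,
    config: _rwr.RWRConfig | None = None,
) -> _eval.FoldStats:
    """One fold's candidate statistics for the propagation route.

    Candidates are taken at the *loosest* probability threshold of the
    grid so that every grid point is a pure thresholding of this cache.
    """
    config = config or _rwr.RWRConfig()
    A = _rwr.normalized_adjacency(network)
    p0 = _rwr.initial_vector(network, fold_seeds)
    p, _ = _rwr.propagate(A, p0, config)
    candidates = _rwr.rwr_candidates(p, network, fold_seeds, min_prwrp)
    perm = _screen.permutation_test(
        "rwr", network, fold_seeds, candidates,
        n_perm=n_perm, rng_seed=rng_seed, rwr_config=config,
    )
    mis_map, mfs_map = _rule_values(candidates, network, fold_seeds, profile)
    return _eval.FoldStats(
        held_out=held_out,
        method=_eval.RWR,
        statistics={c.gene: c.statistic for c in candidates},
        p_values={g: e.p_value for g, e in perm.entries.items()},
        mis=mis_map,
        mfs=mfs_map,
    )


def compute_sp_fold_stats(
    network: WeightedNetwork,
    fold_seeds: SeedSet,
    held_out: str,
    profile: _screen.AnnotationProfile,
    n_perm: int,
    rng_seed: int,
    path_mode: str = _sp.ALL_TIES,
) -> _eval.FoldStats:
    """One fold's candidate statistics for the shortest-path route."""
    network_raw = network.with_mode(RAW)
    network_sp = network.with_mode(TRANSFORMED)
    if path_mode == _sp.ALL_TIES:
        table = _sp.betweenness_counts(network_sp, fold_seeds)
    else:
        paths = _sp.seed_pair_shortest_paths(network_sp, fold_seeds, path_mode)
        table = _sp.betweenness(paths, fold_seeds)
    candidates = _sp.sp_candidates(table)
    perm = _screen.permutation_test(
        "sp", network_sp, fold_seeds, candidates,
        n_perm=n_perm, rng_seed=rng_seed, path_mode=path_mode,
    )
    mis_map, mfs_map = _rule_values(candidates, network_raw, fold_seeds, profile)
    return _eval.FoldStats(
        held_out=held_out,
        method=_eval.SP,
        statistics={c.gene: c.statistic for c in candidates},
        p_values={g: e.p_value for g, e in perm.entries.items()},
        mis=mis_map,
        mfs=mfs_map,
    )


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntegratedResult:
    """Union of the two putative sets with its three-way partition."""

    rwr_putative: frozenset[str]
    sp_putative: frozenset[str]

    @property
    def union(self) -> frozenset[str]:
        return self.rwr_putative | self.sp_putative

    @property
    def intersection(self) -> frozenset[str]:
        return self.rwr_putative & self.sp_putative

    @property
    def rwr_only(self) -> frozenset[str]:
        return self.rwr_putative - self.sp_putative

    @property
    def sp_only(self) -> frozenset[str]:
        return self.sp_putative - self.rwr_putative

    def source_of(self, gene: str) -> str:
        if gene in self.intersection:
            return "both"
        if gene in self.rwr_putative:
            return "rwr"
        if gene in self.sp_putative:
            return "sp"
        raise ValidationError(f"{gene!r} is not a putative gene")


def integrate(rwr_set: Sequence[str] | frozenset[str],
              sp_set: Sequence[str] | frozenset[str]) -> IntegratedResult:
    """Combine the two putative gene sets by union."""
    return IntegratedResult(frozenset(rwr_set), frozenset(sp_set))


def extract_subnetwork(network: WeightedNetwork, genes: Sequence[str] | frozenset[str]
                       ) -> WeightedNetwork:
    """Induced subgraph on the given genes (putative plus validated, typically)."""
    return network.induced_subgraph(genes)
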