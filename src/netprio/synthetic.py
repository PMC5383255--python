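"""Synthetic benchmark generator: a planted high-confidence module.

Emulates the statistical structure the prioritizers assume: a sparse
score-weighted interaction network in which one dense module of
high-score edges carries the disease signal, half of the module posing as
validated seed genes and the other half as held-out truth; term
annotations are coherent within the module so the function-score screen
has signal. Everything is reproducible from a single RNG seed, and all
outputs serialize to the exact external formats the readers consume.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .io import write_gmt, write_seed_list, write_string_links
from .network import (InteractionRecord, SCORE_CEIL, SCORE_FLOOR, SeedSet,
                      WeightedNetwork, build_network, make_seed_set)


@dataclass(frozen=True)
class SimulationScenario:
    """Generator settings.

    Defaults describe the benchmark condition used throughout the test
    suite: a 200-gene network with a 20-gene module, dense high-score
    edges inside the module (p=0.6, scores 800-999) against a sparse
    low-score background (p=0.02, scores 150-400), and 20 annotation
    terms of which half are module-enriched.
    """

    n_nodes: int = 200
    module_size: int = 20
    p_in: float = 0.6
    p_out: float = 0.02
    module_score_range: tuple[int, int] = (800, 999)
    background_score_range: tuple[int, int] = (150, 400)
    n_terms: int = 20
    coherence: float = 0.8            # P(module gene carries each module term)
    module_term_leak: float = 0.05    # P(background gene carries a module term)
    background_term_rate: float = 0.1  # P(any gene carries a background term)
    rng_seed: int = 12345

    def __post_init__(self):
        if self.n_nodes < 2:
            raise ValidationError("need at least 2 nodes")
        if not 0 < self.module_size < self.n_nodes:
            raise ValidationError("module_size must be in (0, n_nodes)")
        if not self.p_in > self.p_out:
            raise ValidationError("p_in must exceed p_out")
        for lo, hi in (self.module_score_range, self.background_score_range):
            if not (SCORE_FLOOR <= lo <= hi <= SCORE_CEIL):
                raise ValidationError(
                    f"score range ({lo}, {hi}) must sit inside "
                    f"[{SCORE_FLOOR}, {SCORE_CEIL}]"
                )
        if self.n_terms < 2:
            raise ValidationError("need at least 2 annotation terms")
        for p in (self.p_in, self.p_out, self.coherence,
                  self.module_term_leak, self.background_term_rate):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0, 1]")


@dataclass(frozen=True)
class SyntheticBundle:
    """A generated study: network, seeds, held-out truth and annotations."""

    scenario: SimulationScenario
    records: tuple[InteractionRecord, ...]
    network: WeightedNetwork
    seeds: SeedSet
    held_out: tuple[str, ...]
    module: tuple[str, ...]
    annotations: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def background(self) -> tuple[str, ...]:
        """Non-module genes (includes neither seeds nor held-out truth)."""
        module = set(self.module)
        return tuple(g for g in self.network.node_order if g not in module)


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def generate(scenario: SimulationScenario | None = None) -> SyntheticBundle:
    """Sample one benchmark instance, fully determined by the scenario RNG seed."""
    scenario = scenario or SimulationScenario()
    rng = np.random.default_rng(scenario.rng_seed)
    genes = [_gene_name(i) for i in range(scenario.n_nodes)]
    module = sorted(
        genes[i] for i in rng.choice(scenario.n_nodes, scenario.module_size, replace=False)
    )
    module_set = set(module)

    records: list[InteractionRecord] = []
    degree = {g: 0 for g in genes}

    def add_edge(u: str, v: str, lo: int, hi: int) -> None:
        score = int(rng.integers(lo, hi + 1))
        records.append(InteractionRecord(u, v, score))
        degree[u] += 1
        degree[v] += 1

    for u, v in itertools.combinations(genes, 2):
        within = u in module_set and v in module_set
        p = scenario.p_in if within else scenario.p_out
        if rng.random() < p:
            lo, hi = (scenario.module_score_range if within
                      else scenario.background_score_range)
            add_edge(u, v, lo, hi)

    # every gene must appear in the network with degree >= 1
    lo, hi = scenario.background_score_range
    for g in genes:
        if degree[g] == 0:
            for _ in range(100):
                other = genes[int(rng.integers(scenario.n_nodes))]
                if other != g:
                    add_edge(g, other, lo, hi)
                    break
            else:
                raise ValidationError(f"could not repair isolated node {g}")

    network = build_network(records, mode="raw")

    order = rng.permutation(scenario.module_size)
    n_seeds = scenario.module_size // 2
    seed_ids = tuple(sorted(module[i] for i in order[:n_seeds]))
    held_out = tuple(sorted(module[i] for i in order[n_seeds:]))
    seeds = make_seed_set(seed_ids, network, label="planted-module")

    annotations: dict[str, tuple[str, ...]] = {}
    n_module_terms = scenario.n_terms // 2
    for t in range(scenario.n_terms):
        is_module_term = t < n_module_terms
        name = f"{'MT' if is_module_term else 'BT'}{t:03d}"
        members = []
        for g in genes:
            if is_module_term:
                p = scenario.coherence if g in module_set else scenario.module_term_leak
            else:
                p = scenario.background_term_rate
            if rng.random() < p:
                members.append(g)
        if not members:  # GMT terms must be nonempty
            members.append(genes[int(rng.integers(scenario.n_nodes))])
        annotations[name] = tuple(members)

    return SyntheticBundle(
        scenario=scenario,
        records=tuple(sorted(records)),
        network=network,
        seeds=seeds,
        held_out=held_out,
        module=tuple(module),
        annotations=annotations,
    )


def write_fixture(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Serialize a bundle to the external input formats.

    Returns the paths written: the edge list (STRING links dialect), the
    seed list, the GMT annotations and the held-out truth list (which
    never contains a seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "links": outdir / "network.links.txt",
        "seeds": outdir / "seeds.txt",
        "gmt": outdir / "annotations.gmt",
        "truth": outdir / "truth.txt",
    }
    write_string_links(bundle.records, paths["links"])
    write_seed_list(bundle.seeds.ids, paths["seeds"])
    write_gmt(bundle.annotations, paths["gmt"])
    write_seed_list(bundle.held_out, paths["truth"])
    return paths
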