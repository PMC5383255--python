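"""Shared fixtures: tiny hand-built graphs and the default planted-module benchmark."""

import numpy as np
import pytest

import netprio as npr


@pytest.fixture(scope="session")
def bundle():
    """The default planted-module benchmark (200 genes, 20-gene module)."""
    return npr.generate()


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced instance (60 genes, 10-gene module) for fast pipeline runs."""
    return npr.generate(npr.SimulationScenario(
        n_nodes=60, module_size=10, n_terms=8, rng_seed=2024))


@pytest.fixture(scope="session")
def small_profile(small_bundle):
    return npr.build_annotation_profile(
        small_bundle.annotations, small_bundle.network,
        scorer="neighborhood-hypergeometric",
    )


@pytest.fixture(scope="session")
def indicator_profile(bundle):
    return npr.build_annotation_profile(
        bundle.annotations, bundle.network, scorer="indicator"
    )


@pytest.fixture(scope="session")
def hyper_profile(bundle):
    return npr.build_annotation_profile(
        bundle.annotations, bundle.network, scorer="neighborhood-hypergeometric"
    )


@pytest.fixture
def path_network():
    """Path a-b (score 200), b-c (score 600) in raw mode."""
    return npr.build_network(
        [npr.InteractionRecord("a", "b", 200), npr.InteractionRecord("b", "c", 600)],
        mode="raw",
    )


@pytest.fixture
def star_network():
    """Four leaves around a hub, all scores equal."""
    recs = [npr.InteractionRecord("hub", f"leaf{i}", 500) for i in range(4)]
    return npr.build_network(recs, mode="transformed")


def random_weighted_records(rng: np.random.Generator, n_nodes: int, p_edge: float):
    """Random connected-enough graph: G(n, p) plus a chain so no node is isolated."""
    names = [f"n{i:02d}" for i in range(n_nodes)]
    recs = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                recs.append(npr.InteractionRecord(
                    names[i], names[j], int(rng.integers(150, 1000))))
    for i in range(n_nodes - 1):  # guarantee degree >= 1 everywhere
        recs.append(npr.InteractionRecord(
            names[i], names[i + 1], int(rng.integers(150, 1000))))
    return recs, names
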