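"""Shared fixtures: small deterministic trees, matrices and benchmarks."""

from __future__ import annotations

import numpy as np
import pytest

from panforest import (PAMatrix, PipelineConfig, from_newick,
                       generate_benchmark, simulate_tree)


@pytest.fixture(scope="session")
def balanced4():
    """((a,b),(c,d)) with unit branch lengths everywhere."""
    return from_newick("((a:1,b:1):1,(c:1,d:1):1);")


@pytest.fixture(scope="session")
def tree32():
    return simulate_tree(32, "yule", seed=7)


@pytest.fixture(scope="session")
def tree128():
    return simulate_tree(128, "yule", seed=11)


@pytest.fixture(scope="session")
def fast_config():
    """A cheap screen configuration for unit tests (not the study settings)."""
    return PipelineConfig(n_trees=60, n_d_permutations=100, seed=0)


@pytest.fixture(scope="session")
def small_benchmark():
    """64-tip benchmark with a handful of planted pairs, for pipeline tests."""
    return generate_benchmark(n_tips=64, n_null_genes=60, n_mutualism=2,
                              n_commensal=1, n_competition=1, seed=3)


@pytest.fixture(scope="session")
def default_benchmark():
    """The full default planted benchmark (256 tips, 400 null genes,
    20 + 10 + 10 coupled pairs); shared because it is expensive."""
    return generate_benchmark(seed=0)


def random_binary_tree(n_tips: int, rng: np.random.Generator,
                       prefix: str = "t"):
    """A random rooted binary topology with exponential branch lengths,
    built independently of the package's own simulators (oracle helper)."""
    labels = [f"{prefix}{i}" for i in range(n_tips)]
    nodes = [f"{lab}:{rng.exponential(1.0):.6f}" for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        if len(nodes) == 0:
            nodes.append(f"({a},{b});")
        else:
            nodes.append(f"({a},{b}):{rng.exponential(1.0):.6f}")
    return from_newick(nodes[0]), labels


def star_like_tree(n_tips: int, tip_length: float):
    """Caterpillar with zero internal branches and long terminal branches:
    tip states under a stationary-rooted Markov model are exactly i.i.d."""
    from panforest import from_newick

    nwk = f"t0:{tip_length}"
    for i in range(1, n_tips):
        nwk = f"({nwk},t{i}:{tip_length}):0"
    return from_newick(nwk[:-2] + ";")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def matrix_from_columns(columns: dict[str, np.ndarray],
                        genome_prefix: str = "G") -> PAMatrix:
    genes = sorted(columns)
    values = np.stack([columns[g] for g in genes], axis=1)
    genomes = [f"{genome_prefix}{i:04d}" for i in range(values.shape[0])]
    return PAMatrix(genomes, genes, values)
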