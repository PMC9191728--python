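import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sinescout.synth import FamilySpec, SimConfig, simulate_genome, simulate_reads


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def mutate(rng: np.random.Generator, seq: str, n_sub: int, protect_ends: bool = True) -> str:
    chars = list(seq)
    lo = 1 if protect_ends else 0
    hi = len(seq) - 1 if protect_ends else len(seq)
    for p in rng.choice(np.arange(lo, hi), size=n_sub, replace=False):
        chars[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[p]]
    return "".join(chars)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def small_sim_config(seed: int = 3) -> SimConfig:
    return SimConfig(
        seed=seed,
        genome_length=300_000,
        n_genes=4,
        families=(
            FamilySpec("fA", 8, body_length=220, tail_unit="TTAG",
                       max_divergence=0.06, n_intronic=1),
            FamilySpec("fB", 6, body_length=300, tail_unit="CA",
                       max_divergence=0.05, n_intronic=1),
        ),
        n_sine_reads=120,
        n_background_reads=40,
        n_decoy_reads=25,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small two-family simulation with genes and reads, shared read-only
    across tests."""
    cfg = small_sim_config()
    genome, genes, manifest = simulate_genome(cfg)
    reads = simulate_reads(manifest, cfg, genome, genes)
    return cfg, genome, genes, manifest, reads


@pytest.fixture(scope="session")
def small_sim_models(small_sim):
    from sinescout.discovery import discover

    cfg, genome, genes, manifest, reads = small_sim
    models, clusters, rejects = discover(genome)
    return models, clusters, rejects
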