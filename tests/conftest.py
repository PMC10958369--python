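"""Shared fixtures: one simulated clade reused across the suite."""

from __future__ import annotations

import pytest

from mitocompare.simulate import SimulationConfig, simulate_clade, simulate_mitogenome


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def clade(sim_config):
    """(root, leaves, truth_log) for a 4-taxon clade under default settings."""
    return simulate_clade(sim_config)


@pytest.fixture(scope="session")
def root_genome(clade):
    return clade[0]


@pytest.fixture(scope="session")
def leaf_genomes(clade):
    root, leaves, _ = clade
    return [leaves[k] for k in sorted(leaves)]


@pytest.fixture(scope="session")
def tiny_gene_config():
    """A minimal layout (one 600-codon PCG + control region) for replicated
    selection simulations where the full 37-gene genome would be wasteful."""
    from mitocompare.simulate import GeneSpec

    layout = (
        GeneSpec("cox1", "PCG", "J", 1803, 3),
        GeneSpec("d_loop", "control_region", "J", 0, 0),
    )
    def make(seed: int, omega: float, kappa: float = 1.0) -> SimulationConfig:
        return SimulationConfig(
            seed=seed,
            genome_length=2200,
            layout=layout,
            tree="(a:0.1,b:0.1);",
            kappa=kappa,
            omega=omega,
        )
    return make
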