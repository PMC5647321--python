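import pytest

from paleoploid.simulate import (
    DivergenceEvent,
    SimulationConfig,
    simulate_ancestral_genes,
)

BASES = "ACGT"


@pytest.fixture(scope="session")
def single_wgd_config() -> SimulationConfig:
    """100 ancestral genes through one WGD, no loss."""
    return SimulationConfig(
        n_genes=100,
        codons_per_gene=30,
        genes_per_chromosome=10,
        loss_prob=0.0,
        seed=11,
        events=(DivergenceEvent("wgd", 0.05),),
    )


@pytest.fixture(scope="session")
def long_random_cds() -> str:
    """A single long CDS (100k codons) for Monte-Carlo site statistics."""
    cfg = SimulationConfig(
        n_genes=1, codons_per_gene=100_000, seed=99,
        events=(DivergenceEvent("wgd", 0.05),),
    )
    return next(iter(simulate_ancestral_genes(cfg).values()))


def random_codon_pair_sequences(n_codons: int, tau: float, kappa: float, seed: int):
    """An ungapped in-frame pair: random sense codons and a K2P-evolved copy."""
    from paleoploid.simulate import evolve_k2p

    cfg = SimulationConfig(
        n_genes=1, codons_per_gene=max(n_codons, 10), seed=seed,
        events=(DivergenceEvent("wgd", 0.05),),
    )
    a = next(iter(simulate_ancestral_genes(cfg).values()))
    b = evolve_k2p(a, tau, kappa, seed + 1)
    return a, b
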