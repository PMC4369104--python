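import numpy as np
import pytest

from quadtract import (
    SimulationConfig,
    Variant,
    VariantKind,
    annotate_genome,
    build_toy_genome,
    simulate_line,
)


@pytest.fixture(scope="session")
def toy():
    """Default planted genome (study-condition rates are near zero)."""
    return build_toy_genome(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def toy_annotation(toy):
    genome, _ = toy
    return annotate_genome(genome)


@pytest.fixture(scope="session")
def rich_sim():
    """A simulation with inflated rates so every event type is well populated."""
    cfg = SimulationConfig(
        seed=7,
        genome_length=150_000,
        mu_sbs=1e-6,
        mu_indel=3e-7,
        mu_del_g4=1.5e-3,
        mu_del_nong4=2e-8,
        mu_dup=2e-4,
        n_decoy_calls=15,
    )
    genome, truth = build_toy_genome(cfg)
    tables = simulate_line(genome, truth, cfg)
    return cfg, genome, truth, tables


def make_sbs(pos, ref="A", alt="G", contig="I", generation=None):
    return Variant(contig, pos, ref, alt, VariantKind.SBS,
                   first_generation_observed=generation)


def make_large_del(pos, size, contig="I"):
    return Variant(contig, pos, "<REGION>", "<DEL>", VariantKind.DEL_LARGE,
                   size=size)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
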