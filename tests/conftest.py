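"""Shared fixtures: all inputs are generated programmatically at test time."""

import pytest

from temob import synthetic as syn
from temob.insertion import CallerConfig, call_insertions


@pytest.fixture(scope="session")
def toy_genome():
    """Default toy genome: 2 x 100 kb contigs, 3 families x 2 copies, chrM."""
    return syn.build_toy_genome(syn.GenomeConfig(), seed=1)


@pytest.fixture(scope="session")
def small_genome():
    """Lighter genome for simulation-heavy tests."""
    cfg = syn.GenomeConfig(
        contigs={"chr1": 50_000, "chr2": 50_000},
        families={"ZAMx": 2_000, "GTWx": 2_000, "CTRLx": 2_000},
        copies=2,
        cluster_length=2_000,
        mt_length=5_000,
    )
    return syn.build_toy_genome(cfg, seed=2)


@pytest.fixture(scope="session")
def smallrna_setup(toy_genome):
    """Simulated small-RNA library with a mixed truth profile."""
    profile = {
        ("ZAMx", 25, "antisense"): 500,
        ("ZAMx", 21, "sense"): 200,
        ("GTWx", 26, "sense"): 300,
        ("GTWx", 21, "antisense"): 150,
        ("CTRLx", 24, "sense"): 100,
        ("cluster1", 25, "sense"): 400,
    }
    truth = syn.TruthTable(smallrna_profile=profile)
    reads, records = syn.simulate_smallrna_library(toy_genome, truth, seed=7)
    return toy_genome, truth, reads, records


@pytest.fixture(scope="session")
def planted_wgs(toy_genome):
    """Chimera-free 30x WGS library with 10 planted insertions (2 families)."""
    planted = syn.plant_insertions(toy_genome, ["ZAMx"] * 5 + ["GTWx"] * 5, seed=3)
    truth = syn.TruthTable(planted_insertions=planted)
    records = syn.simulate_wgs_library(toy_genome, truth, coverage=30, seed=4)
    return toy_genome, truth, records


@pytest.fixture(scope="session")
def planted_calls(planted_wgs):
    genome, truth, records = planted_wgs
    return call_insertions(records, genome.te_library, CallerConfig())
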