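"""Shared fixtures: seeded simulated genomes at two problem sizes.

The session-scoped fixtures are expensive (tens of seconds) and shared by
every test that only reads them.
"""

from __future__ import annotations

import pytest

from lrmut.simulate import (
    SimulationConfig,
    generate_reference,
    simulate_read_support,
    spike_background_snps,
    spike_conversions,
    spike_insertions,
)


def build_genome(seed: int, *, error: float = 0.0, chrom_len: int = 300_000,
                 n_conversions: int = 8, n_simple: int = 6, n_complex: int = 4,
                 n_background: int = 60):
    cfg = SimulationConfig(seed=seed, chromosome_length=chrom_len,
                           per_base_error=error)
    genome = generate_reference(cfg)
    genome = spike_insertions(genome, n_simple, n_complex, cfg)
    genome = spike_conversions(genome, n_conversions, cfg)
    genome = spike_background_snps(genome, n_background, cfg)
    return cfg, genome


@pytest.fixture(scope="session")
def small_genome():
    """Small error-free genome: 3 x 300 kb, 8 conversions, 10 insertions."""
    cfg, genome = build_genome(seed=11)
    support = simulate_read_support(genome, cfg)
    return cfg, genome, support


@pytest.fixture(scope="session")
def study_genome():
    """Error-free genome at the study scale used for parameter recovery:
    3 x 5 Mb, 20 planted conversion events, 30 simple + 9 complex
    insertions, 240 background SNPs."""
    cfg, genome = build_genome(seed=23, chrom_len=5_000_000, n_conversions=20,
                               n_simple=30, n_complex=9, n_background=240)
    support = simulate_read_support(genome, cfg)
    return cfg, genome, support
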