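"""Shared fixtures: a small simulated dataset reused across test modules."""

from __future__ import annotations

import pytest

from retroloc.samio import AlignmentRecord, ReadAlignmentGroup
from retroloc.simulate import SimulationConfig, generate_reference, simulate_all


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        depth=12_000,
        n_genes=14,
        n_repeat_elements=12,
        copies_per_element=4,
        replicates=1,
        nuclear_enrichment=4.0,
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_reference(small_config)


@pytest.fixture(scope="session")
def small_samples(small_reference):
    return simulate_all(small_reference)  # nuc1, cyt1


@pytest.fixture(scope="session")
def small_groups(small_samples):
    return {s.name: s.groups() for s in small_samples}


def make_fragment(
    read_id: str,
    placements: list[tuple[str, tuple[tuple[int, int], ...], str]],
) -> ReadAlignmentGroup:
    """Fragment from (chrom, blocks, strand) placements; first is primary."""
    records = [
        AlignmentRecord(read_id, chrom, blocks, strand, is_secondary=i > 0)
        for i, (chrom, blocks, strand) in enumerate(placements)
    ]
    return ReadAlignmentGroup(read_id, records)
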