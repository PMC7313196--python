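"""Shared fixtures: the default synthetic community, mapped once per session."""

from __future__ import annotations

import pytest

from cladebin import profiler, recruitment, synthetic


@pytest.fixture(scope="session")
def default_truth():
    """Default 6-genome community (+host), fragmented, with simulated reads."""
    config = synthetic.default_config(seed=0)
    truth = synthetic.generate_genomes(config)
    synthetic.fragment_genomes(truth)
    truth.r1, truth.r2 = synthetic.simulate_reads(truth)
    return truth


@pytest.fixture(scope="session")
def default_alignments(default_truth):
    """Reads of the default community mapped at a 95% identity floor."""
    index = recruitment.build_index(default_truth.scaffolds)
    reads = dict(default_truth.r1) | dict(default_truth.r2)
    return recruitment.map_reads(reads, index, min_identity=95.0)


@pytest.fixture(scope="session")
def default_profiles(default_truth, default_alignments):
    labels = synthetic.taxonomy_labels(default_truth)
    return profiler.profile_table(default_truth.scaffolds, default_alignments, labels)


@pytest.fixture(scope="session")
def flat_community():
    """Equal-genome-size, single-copy-16S community: 100,000 mapped reads."""
    config = synthetic.default_config(
        n_genomes=4,
        genome_length=100_000,
        gc_targets=(0.35, 0.45, 0.55, 0.65),
        abundances=(0.4, 0.3, 0.2, 0.1),
        depth_total=100.0,
        error_rate=0.0,
        singleton_rate=0.0,
        host_fraction=0.0,
        n_16s_copies=1,
        n_marker_families=20,
        seed=31,
    )
    truth = synthetic.generate_genomes(config)
    synthetic.fragment_genomes(truth)
    r1, r2 = synthetic.simulate_reads(truth)
    index = recruitment.build_index(truth.scaffolds)
    reads = dict(r1) | dict(r2)
    alignments = recruitment.map_reads(reads, index, min_identity=100.0)
    return truth, reads, alignments


@pytest.fixture(scope="session")
def clean_pair_community():
    """Two equal genomes, equal abundance, no errors, no host, no singletons."""
    config = synthetic.default_config(
        n_genomes=2,
        genome_length=100_000,
        gc_targets=(0.40, 0.60),
        abundances=(0.5, 0.5),
        depth_total=20.0,
        error_rate=0.0,
        singleton_rate=0.0,
        host_fraction=0.0,
        n_16s_copies=1,
        seed=11,
    )
    truth = synthetic.generate_genomes(config)
    synthetic.fragment_genomes(truth)
    truth.r1, truth.r2 = synthetic.simulate_reads(truth)
    return truth
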