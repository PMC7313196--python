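"""Abundance estimation and environmental-filter contracts."""

import numpy as np
import pandas as pd
import pytest

from cladebin import abundance as ab
from cladebin import recruitment, synthetic
from cladebin.abundance import (
    MatchFilter,
    amplicon_abundance,
    compare_metrics,
    environmental_match,
    metagenomic_abundance,
)


def genome_bins(truth):
    return {
        gid: {s for s, g in truth.scaffold_origin.items() if g == gid}
        for gid in truth.genome_ids()
    }


def ssu_set(truth, region=(515, 926)):
    out = {}
    for gid in truth.genome_ids():
        genome = truth.genomes[gid]
        out[gid] = [genome[lo:hi] for _, (lo, hi) in truth.ssu_loci_genomic[gid]]
    return out


def test_read_recruitment_recovers_true_abundance(flat_community):
    truth, reads, alignments = flat_community
    assert len(reads) >= 100_000
    table = metagenomic_abundance(alignments, genome_bins(truth), n_total_reads=len(reads))
    classified = table[table["metric"] == "read_recruitment_classified"]
    assert classified["relative_abundance"].sum() == pytest.approx(1.0, abs=1e-6)
    shares = dict(zip(classified["taxon_group"], classified["relative_abundance"]))
    for gid, true in truth.true_abundance.items():
        assert shares[gid] == pytest.approx(true, abs=0.02)
    total = table[table["metric"] == "read_recruitment_total"]
    assert total["relative_abundance"].sum() == pytest.approx(1.0, abs=1e-6)


def test_read_recruitment_underrepresents_small_genomes():
    """Equal per-cell abundance, 50 kb vs 100 kb genomes -> shares 1/3 vs 2/3."""
    config = synthetic.default_config(
        n_genomes=2, genome_length=100_000, gc_targets=(0.40, 0.60),
        abundances=(0.5, 0.5), depth_total=30.0, error_rate=0.0, singleton_rate=0.0,
        host_fraction=0.0, n_16s_copies=1, n_marker_families=20, seed=32,
    )
    truth = synthetic.generate_genomes(config)
    truth.genomes["g1"] = truth.genomes["g1"][:50_000]
    truth.marker_loci_genomic["g1"] = [
        (m, span) for m, span in truth.marker_loci_genomic["g1"] if span[1] <= 50_000
    ]
    truth.ssu_loci_genomic["g1"] = [
        (m, span) for m, span in truth.ssu_loci_genomic["g1"] if span[1] <= 50_000
    ]
    synthetic.fragment_genomes(truth)
    r1, r2 = synthetic.simulate_reads(truth)
    index = recruitment.build_index(truth.scaffolds)
    reads = dict(r1) | dict(r2)
    alignments = recruitment.map_reads(reads, index, min_identity=100.0)
    table = metagenomic_abundance(alignments, genome_bins(truth), n_total_reads=len(reads))
    classified = table[table["metric"] == "read_recruitment_classified"]
    shares = dict(zip(classified["taxon_group"], classified["relative_abundance"]))
    assert shares["g1"] == pytest.approx(1 / 3, abs=0.015)
    assert shares["g2"] == pytest.approx(2 / 3, abs=0.015)


def test_overlapping_bins_rejected(flat_community):
    truth, _, alignments = flat_community
    bins = genome_bins(truth)
    shared = next(iter(bins["g1"]))
    bins["g2"] = bins["g2"] | {shared}
    with pytest.raises(ValueError, match="overlap"):
        metagenomic_abundance(alignments, bins)


def test_amplicon_assignment_and_normalization(flat_community):
    truth, _, _ = flat_community
    asv_table = synthetic.simulate_amplicons(truth, n_reads=100_000)
    table = amplicon_abundance(asv_table, ssu_set(truth))
    shares = dict(zip(table["taxon_group"], table["relative_abundance"]))
    assert sum(shares.values()) == pytest.approx(1.0, abs=1e-6)
    for gid, true in truth.true_abundance.items():
        assert shares[gid] == pytest.approx(true, abs=0.02)


def test_amplicon_below_identity_floor_unassigned(flat_community):
    truth, _, _ = flat_community
    references = ssu_set(truth)
    asv = references["g1"][0]
    # ~4.5% substitutions: best identity ~95.5%, below the 97% floor
    rng = np.random.default_rng(0)
    broken = list(asv)
    for p in rng.choice(len(asv), size=int(0.045 * len(asv)), replace=False):
        broken[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[broken[p]]
    table = amplicon_abundance(
        pd.DataFrame(
            {"sample_id": ["S1", "S1"], "asv_id": ["a1", "a2"],
             "sequence": [asv, "".join(broken)], "count": [90, 10]}
        ),
        references,
    )
    shares = dict(zip(table["taxon_group"], table["relative_abundance"]))
    assert shares["g1"] == pytest.approx(0.9)
    assert shares["unassigned"] == pytest.approx(0.1)


def test_amplicon_empty_table_gives_empty_output():
    empty = pd.DataFrame(columns=["sample_id", "asv_id", "sequence", "count"])
    assert amplicon_abundance(empty, {"g1": "ACGT" * 100}).empty


def test_multicopy_16s_overreports_fourfold():
    """A rare genome with four 16S copies: amplicon share ~4x its
    single-copy expectation."""
    config = synthetic.default_config(
        n_genomes=4, genome_length=100_000, gc_targets=(0.35, 0.45, 0.55, 0.65),
        abundances=(0.01, 0.39, 0.30, 0.30), n_16s_copies=(4, 1, 1, 1),
        host_fraction=0.0, n_marker_families=20, seed=33,
    )
    truth = synthetic.generate_genomes(config)
    asv_table = synthetic.simulate_amplicons(truth, n_reads=200_000)
    table = amplicon_abundance(asv_table, ssu_set(truth))
    shares = dict(zip(table["taxon_group"], table["relative_abundance"]))
    single_copy_expectation = 0.01
    expected_share = 0.04 / (0.04 + 0.99)  # exact copy-weighted expectation
    assert shares["g1"] == pytest.approx(expected_share, rel=0.1)
    assert shares["g1"] / single_copy_expectation == pytest.approx(4.0, rel=0.15)


def test_environmental_match_alignment_length_cutoff():
    rng = np.random.default_rng(1)
    gene = "".join(rng.choice(list("ACGT"), 1_500))
    refs = {"ref": gene}
    kept = environmental_match(gene[100:460], refs)  # 360 nt
    assert len(kept) == 1
    assert kept.loc[0, "align_len"] == 360
    assert kept.loc[0, "identity"] == pytest.approx(100.0)
    assert kept.loc[0, "evalue"] <= 1e-7
    dropped = environmental_match(gene[100:459], refs)  # 359 nt
    assert dropped.empty


def test_environmental_match_identity_tiers():
    rng = np.random.default_rng(2)
    gene = "".join(rng.choice(list("ACGT"), 1_500))
    query = list(gene[200:600])  # 400 nt
    for p in range(10, 400 - 10, 25):  # 16 interior substitutions -> 96%
        query[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[query[p]]
    query = "".join(query)
    refs = {"ref": gene}
    species = environmental_match(query, refs, MatchFilter(min_identity=97.0))
    genus = environmental_match(query, refs, MatchFilter(min_identity=95.0))
    assert species.empty
    assert len(genus) == 1
    assert 95.0 <= genus.loc[0, "identity"] < 97.0


def test_environmental_match_full_length_identical_pair():
    rng = np.random.default_rng(3)
    gene = "".join(rng.choice(list("ACGT"), 1_500))
    out = environmental_match(gene, {"ref": gene})
    assert len(out) == 1
    assert out.loc[0, "align_len"] == 1_500
    assert out.attrs["karlin_altschul"]["lambda"] == pytest.approx(1.28)


def test_compare_metrics_concordant_community(flat_community):
    truth, reads, alignments = flat_community
    read_table = metagenomic_abundance(alignments, genome_bins(truth), n_total_reads=len(reads))
    asv_table = synthetic.simulate_amplicons(truth, n_reads=100_000)
    amplicon_table = amplicon_abundance(asv_table, ssu_set(truth))
    combined = pd.concat([read_table, amplicon_table], ignore_index=True)
    report = compare_metrics(combined)
    assert report["spearman_rho"].to_numpy() == pytest.approx(1.0)
    assert report["difference"].abs().max() < 0.02


def test_compare_metrics_flags_multicopy_taxa(flat_community):
    truth, reads, alignments = flat_community
    read_table = metagenomic_abundance(alignments, genome_bins(truth), n_total_reads=len(reads))
    amplicon_table = amplicon_abundance(
        synthetic.simulate_amplicons(truth, n_reads=50_000), ssu_set(truth)
    )
    combined = pd.concat([read_table, amplicon_table], ignore_index=True)
    report = compare_metrics(combined, ssu_copies={"g1": 4}, genome_sizes={"g1": 100_000, "g2": 100_000})
    flagged = report.set_index("taxon_group")["flags"]
    assert "multi_copy_16s" in flagged["g1"]
    assert flagged["g2"] == ""


def test_compare_metrics_skips_single_metric_samples(flat_community):
    truth, reads, alignments = flat_community
    read_table = metagenomic_abundance(alignments, genome_bins(truth), n_total_reads=len(reads))
    assert compare_metrics(read_table).empty
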