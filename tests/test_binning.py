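"""Binning, screening, refinement, and marker-tally contracts."""

import collections

import numpy as np
import pandas as pd
import pytest

from cladebin import binning, profiler, recruitment, synthetic
from cladebin.binning import (
    Bin,
    ScreenThresholds,
    bin_summary,
    marker_qc,
    preliminary_bins,
    refine,
    screen_scaffolds,
)


def community_profiles(config, labels=None, min_identity=95.0, label_fraction=1.0):
    truth = synthetic.generate_genomes(config)
    synthetic.fragment_genomes(truth)
    r1, r2 = synthetic.simulate_reads(truth)
    index = recruitment.build_index(truth.scaffolds)
    alignments = recruitment.map_reads(dict(r1) | dict(r2), index, min_identity=min_identity)
    kwargs = {"label_fraction": label_fraction}
    if labels:
        kwargs["labels"] = labels
    label_table = synthetic.taxonomy_labels(truth, **kwargs)
    profiles = profiler.profile_table(truth.scaffolds, alignments, label_table)
    return truth, profiles


def assignment_quality(bins, profiles, truth):
    origin = truth.scaffold_origin
    totals = collections.Counter(origin[s] for s in profiles["scaffold_id"])
    quality = {}
    for genome in truth.genome_ids():
        best = max(bins, key=lambda b: sum(origin[s] == genome for s in b.scaffold_ids))
        tp = sum(origin[s] == genome for s in best.scaffold_ids)
        quality[genome] = (tp / len(best.scaffold_ids), tp / totals[genome])
    return quality


def uniform_bin_profiles(n=10, paired=0.95):
    """A tight synthetic bin: identical composition up to multinomial noise."""
    rng = np.random.default_rng(6)
    rows = []
    for i in range(n):
        seq = "".join(rng.choice(list("ACGT"), p=[0.25, 0.25, 0.25, 0.25], size=12_000))
        rows.append({"scaffold_id": f"s{i:02d}", "sequence": seq})
    scaffolds = {r["scaffold_id"]: r["sequence"] for r in rows}
    table = profiler.profile_table(scaffolds, None, None, min_len=1_000)
    table["coverage"] = 10.0
    table["paired_fraction"] = paired
    return table


def test_two_separated_genomes_give_two_clean_bins():
    config = synthetic.default_config(
        n_genomes=2, genome_length=60_000, gc_targets=(0.35, 0.60),
        abundances=(1 / 11, 10 / 11), depth_total=110.0, host_fraction=0.0,
        n_marker_families=20, seed=21,
    )
    truth, profiles = community_profiles(config)
    bins = preliminary_bins(profiles)
    assert len(bins) == 2
    for precision, recall in assignment_quality(bins, profiles, truth).values():
        assert precision >= 0.95 and recall >= 0.95


def test_single_genome_collapses_to_one_bin():
    config = synthetic.default_config(
        n_genomes=1, genome_length=60_000, gc_targets=(0.5,), abundances=(1.0,),
        depth_total=20.0, host_fraction=0.0, n_marker_families=20, seed=22,
    )
    _, profiles = community_profiles(config)
    bins = preliminary_bins(profiles)
    assert len(bins) == 1
    assert len(bins[0].scaffold_ids) == len(profiles)


def test_coverage_alone_separates_identical_composition():
    """Same GC and TNF, same taxonomy label, 20x coverage ratio -> 2 bins."""
    config = synthetic.default_config(
        n_genomes=2, genome_length=60_000, gc_targets=(0.45, 0.45),
        abundances=(1 / 21, 20 / 21), depth_total=42.0, host_fraction=0.0,
        n_marker_families=20, seed=23,
    )
    truth, profiles = community_profiles(config, labels=("SamePhylum", "SamePhylum"))
    bins = preliminary_bins(profiles)
    assert len(bins) == 2
    for precision, recall in assignment_quality(bins, profiles, truth).values():
        assert precision >= 0.95 and recall >= 0.95


def test_all_unlabeled_falls_back_to_density_clustering():
    config = synthetic.default_config(
        n_genomes=2, genome_length=60_000, gc_targets=(0.35, 0.60),
        abundances=(0.5, 0.5), depth_total=40.0, host_fraction=0.0,
        n_marker_families=20, seed=24,
    )
    truth = synthetic.generate_genomes(config)
    synthetic.fragment_genomes(truth)
    r1, r2 = synthetic.simulate_reads(truth)
    index = recruitment.build_index(truth.scaffolds)
    alignments = recruitment.map_reads(dict(r1) | dict(r2), index, min_identity=95.0)
    profiles = profiler.profile_table(truth.scaffolds, alignments, None)
    with pytest.warns(UserWarning, match="unlabeled"):
        bins = preliminary_bins(profiles)
    assert len(bins) == 2


def test_empty_profiles_rejected():
    with pytest.raises(ValueError):
        preliminary_bins(pd.DataFrame())


@pytest.mark.parametrize(
    "fraction, decision",
    [(0.85, "rejected"), (0.90, "rejected"), (0.95, "accepted")],
)
def test_paired_fraction_screen_is_strictly_greater_than_90(fraction, decision):
    profiles = uniform_bin_profiles(paired=0.95)
    profiles.loc[0, "paired_fraction"] = fraction
    bin_ = Bin(bin_id="b1", scaffold_ids=sorted(profiles["scaffold_id"]))
    report = screen_scaffolds(bin_, profiles)
    target = profiles.loc[0, "scaffold_id"]
    if decision == "rejected":
        assert (target, "paired_fraction") in report.rejected
    else:
        assert target in report.accepted


def test_undefined_paired_fraction_fails_screen():
    profiles = uniform_bin_profiles()
    profiles.loc[0, "paired_fraction"] = float("nan")
    bin_ = Bin(bin_id="b1", scaffold_ids=sorted(profiles["scaffold_id"]))
    report = screen_scaffolds(bin_, profiles)
    assert (profiles.loc[0, "scaffold_id"], "paired_fraction") in report.rejected


def test_screen_partitions_input():
    profiles = uniform_bin_profiles()
    profiles.loc[0, "paired_fraction"] = 0.5
    bin_ = Bin(bin_id="b1", scaffold_ids=sorted(profiles["scaffold_id"]))
    report = screen_scaffolds(bin_, profiles)
    rejected_ids = {sid for sid, _ in report.rejected}
    assert set(report.accepted) | rejected_ids == set(bin_.scaffold_ids)
    assert not set(report.accepted) & rejected_ids


def test_gc_and_coverage_outliers_flagged():
    profiles = uniform_bin_profiles()
    profiles.loc[1, "gc_percent"] += 8.0
    profiles.loc[2, "coverage"] *= 5.0
    bin_ = Bin(bin_id="b1", scaffold_ids=sorted(profiles["scaffold_id"]))
    report = screen_scaffolds(bin_, profiles)
    reasons = dict(report.rejected)
    assert reasons[profiles.loc[1, "scaffold_id"]] == "gc_outlier"
    assert reasons[profiles.loc[2, "scaffold_id"]] == "coverage_outlier"


def test_taxonomy_conflict_flagged():
    profiles = uniform_bin_profiles()
    profiles["taxonomy_label"] = "Cyanobacteria"
    profiles.loc[3, "taxonomy_label"] = "Bacteroidetes"
    bin_ = Bin(bin_id="b1", scaffold_ids=sorted(profiles["scaffold_id"]), taxonomy_label="Cyanobacteria")
    report = screen_scaffolds(bin_, profiles)
    assert (profiles.loc[3, "scaffold_id"], "taxonomy_conflict") in report.rejected


@pytest.fixture(scope="module")
def host_contaminated():
    """Bacterial community plus host scaffolds matched in GC and coverage."""
    config = synthetic.default_config(
        n_genomes=2, genome_length=100_000, gc_targets=(0.35, 0.55),
        abundances=(0.5, 0.5), depth_total=20.0, host_fraction=0.3,
        n_marker_families=20, seed=25,
    )
    truth = synthetic.generate_genomes(config)
    synthetic.fragment_genomes(truth)
    r1, r2 = synthetic.simulate_reads(truth)
    index = recruitment.build_index(truth.scaffolds)
    alignments = recruitment.map_reads(dict(r1) | dict(r2), index, min_identity=95.0)
    profiles = profiler.profile_table(truth.scaffolds, alignments, None)
    return truth, profiles


def test_host_scaffold_in_bacterial_bin_is_composition_outlier(host_contaminated):
    truth, profiles = host_contaminated
    g1_scaffolds = sorted(s for s, g in truth.scaffold_origin.items() if g == "g1")
    host_scaffold = sorted(s for s, g in truth.scaffold_origin.items() if g == "host")[0]
    indexed = profiles.set_index("scaffold_id")
    # the planted contaminant matches the bin on GC and coverage...
    assert abs(indexed.loc[host_scaffold, "gc_percent"] - indexed.loc[g1_scaffolds, "gc_percent"].median()) <= 5.0
    bin_ = Bin(bin_id="b1", scaffold_ids=g1_scaffolds + [host_scaffold])
    report = screen_scaffolds(bin_, profiles)
    # ...so only its tetranucleotide composition gives it away
    assert (host_scaffold, "composition_outlier") in report.rejected
    assert set(report.accepted) == set(g1_scaffolds)


def test_refine_removes_contaminants_by_round_two(host_contaminated):
    truth, profiles = host_contaminated
    g1 = sorted(s for s, g in truth.scaffold_origin.items() if g == "g1")
    host = sorted(s for s, g in truth.scaffold_origin.items() if g == "host")[:2]
    bins = [Bin(bin_id="b1", scaffold_ids=g1 + host)]
    refined, _ = refine(bins, profiles, max_rounds=2)
    members = refined[0].scaffold_ids
    purity = sum(truth.scaffold_origin[s] == "g1" for s in members) / len(members)
    assert purity >= 0.99
    assert refined[0].status == "screened"


def test_refine_clean_bin_converges_first_round(host_contaminated):
    truth, profiles = host_contaminated
    g1 = sorted(s for s, g in truth.scaffold_origin.items() if g == "g1")
    bins = [Bin(bin_id="b1", scaffold_ids=g1)]
    refined, reports = refine(bins, profiles, max_rounds=5)
    assert len(reports) == 1
    assert reports[0].rejected == []
    assert refined[0].scaffold_ids == g1


def test_refine_single_round_equals_one_screen(host_contaminated):
    truth, profiles = host_contaminated
    g1 = sorted(s for s, g in truth.scaffold_origin.items() if g == "g1")
    host = sorted(s for s, g in truth.scaffold_origin.items() if g == "host")[:1]
    bin_ = Bin(bin_id="b1", scaffold_ids=g1 + host)
    single = screen_scaffolds(binning._bin_stats(Bin(bin_id="b1", scaffold_ids=g1 + host), profiles), profiles)
    refined, _ = refine([bin_], profiles, max_rounds=1)
    assert sorted(refined[0].scaffold_ids) == sorted(single.accepted)


def test_refine_is_monotone(host_contaminated):
    truth, profiles = host_contaminated
    g1 = sorted(s for s, g in truth.scaffold_origin.items() if g == "g1")
    host = sorted(s for s, g in truth.scaffold_origin.items() if g == "host")[:2]
    sets = []
    for rounds in (1, 2, 3):
        refined, _ = refine([Bin(bin_id="b1", scaffold_ids=g1 + host)], profiles, max_rounds=rounds)
        sets.append(set(refined[0].scaffold_ids))
    assert sets[1] <= sets[0]
    assert sets[2] <= sets[1]


def test_marker_qc_tallies():
    marker_set = [f"m{i + 1:03d}" for i in range(100)]
    bin_ = Bin(bin_id="b1", scaffold_ids=[f"s{i}" for i in range(100)])
    full = pd.DataFrame({"scaffold_id": [f"s{i}" for i in range(100)], "marker_family": marker_set})
    assert marker_qc(bin_, full, marker_set) == (100.0, 0.0)
    half = full.iloc[:50]
    assert marker_qc(bin_, half, marker_set) == (50.0, 0.0)
    duplicated = pd.concat([full, full.iloc[[0]]], ignore_index=True)
    assert marker_qc(bin_, duplicated, marker_set) == (100.0, 1.0)


def test_marker_qc_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(8)
    marker_set = [f"m{i + 1:03d}" for i in range(30)]
    scaffolds = [f"s{i}" for i in range(12)]
    rows = [
        {"scaffold_id": scaffolds[rng.integers(len(scaffolds))], "marker_family": marker_set[rng.integers(30)]}
        for _ in range(80)
    ]
    annotations = pd.DataFrame(rows)
    bin_scaffolds = scaffolds[:7]
    bin_ = Bin(bin_id="b1", scaffold_ids=bin_scaffolds)
    completeness, contamination = marker_qc(bin_, annotations, marker_set)
    copies = collections.Counter(
        r["marker_family"] for r in rows if r["scaffold_id"] in bin_scaffolds
    )
    assert completeness == pytest.approx(100.0 * len(copies) / 30)
    assert contamination == pytest.approx(100.0 * sum(c - 1 for c in copies.values()) / 30)


def test_marker_qc_rejects_unknown_family():
    bin_ = Bin(bin_id="b1", scaffold_ids=["s1"])
    annotations = pd.DataFrame({"scaffold_id": ["s1"], "marker_family": ["mystery"]})
    with pytest.raises(ValueError, match="unknown"):
        marker_qc(bin_, annotations, ["m001"])


def test_bin_summary_mirrors_bin_contents(default_truth, default_profiles):
    bins = preliminary_bins(default_profiles)
    annotations = synthetic.marker_annotations(default_truth)
    marker_set = [f"m{i + 1:03d}" for i in range(100)]
    summary = bin_summary(bins, default_profiles, annotations, marker_set)
    assert len(summary) == len(bins)
    by_id = summary.set_index("bin_id")
    for b in bins:
        assert by_id.loc[b.bin_id, "n_scaffolds"] == len(b.scaffold_ids)
        assert by_id.loc[b.bin_id, "total_length"] == b.total_length
    # complete single-genome bins tally all 100 families exactly once
    bacterial = summary[~summary["taxonomy"].str.startswith("Eukaryota")]
    assert (bacterial["completeness"] == 100.0).all()
    assert (bacterial["contamination"] == 0.0).all()
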